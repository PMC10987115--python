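# Methods

This note documents the models behind `slugflow`: what the in-silico reactor
emulates, the assumptions in each optimization stage, the parameters that
matter, the numerical choices, and what the package's passing tests do and
do not establish about real laboratory data.

## The chemistry and the design space

The modelled reaction is a Pd/Xantphos-catalysed Buchwald–Hartwig amination
of an aryl bromide (**1**, the limiting reagent) by a thiophene-based
aniline (**2**) with DBU as base, forming a diaryl amine (**3**). Six
continuous variables are optimizable:

| variable      | unit  | broad (self-opt) range | narrowed (DoE) range |
|---------------|-------|------------------------|----------------------|
| amine loading | equiv | 1.0 – 2.0              | 1.07 – 1.28          |
| concentration | mol/L | 0.1 – 0.5              | fixed 0.33           |
| residence time| min   | 0.5 – 12               | fixed 6.5            |
| temperature   | °C    | 80 – 140               | 130 – 140            |
| DBU loading   | equiv | 1.07 – 2.13            | 1.07 – 1.61          |
| catalyst      | mol%  | 1 – 6                  | 4.3 – 5.4            |

The ligand:Pd ratio is constant (1.5). The narrowed box and its fixed values
are the documented second-stage conditions; the broad bounds for
temperature, concentration, amine and catalyst are this package's own
defaults, chosen to be as wide as the simulated hardware permits while
remaining mutually consistent, and are overridable in every config.

Coded units: x ↦ 2(x − low)/(high − low) − 1, so the box is [−1, +1]ⁿ.
Latin-hypercube samples use centered points within equal-width strata and a
seeded permutation per dimension (`scipy.stats.qmc.LatinHypercube`,
`scramble=False`); the seed is a mandatory argument so campaigns are
reproducible by construction.

## Kinetic model

Four productive steps and one side reaction:

    r1  Cat + A   → CatA          k₁(T) = 10^logA · exp(−Eₐ / RT)   (rate-limiting)
    r2  CatA + B  → CatAB         k_fast
    r3  CatAB + DBU → CatAm       k_fast      (DBU·HBr tracked implicitly)
    r4  CatAm     → Cat + P       k_fast · 1 M  (made unimolecular)
    r5  Cat + A   → CatD + I      k_side      (temperature-independent)

Assumptions: only oxidative addition is rate-limiting; all downstream steps
share one arbitrarily high bimolecular constant (default 10⁴ L mol⁻¹ s⁻¹);
no reverse reactions; no off-cycle Pd speciation. The reductive elimination
is made first-order by multiplying `k_fast` by a 1 mol/L reference
concentration, since the molecularity of that step is not observable when it
is fast.

The side reaction is deliberately placed on the catalyst resting state,
competing directly with oxidative addition. One pathway then covers both
catalyst deactivation (CatD is dead Pd) and impurity formation (I consumes
aryl), and its branching ratio k_side/(k₁ + k_side) contains no k_fast.
This preserves the defining structural property — product trajectories move
by far less than 0.1 % when k_fast is doubled — while keeping k_side
identifiable from concentration data. An alternative formulation with the
side reaction on the oxidative-addition adduct (CatA → CatD + I) couples the
branching to k_fast·[B] and cannot satisfy both properties at once, which is
why it was rejected.

Two exact invariants hold along every trajectory and are tested at 1e-9
relative tolerance: aryl balance A + P + I + CatA + CatAB + CatAm = A₀ and
Pd balance Cat + CatA + CatAB + CatAm + CatD = Cat₀.

Integration: stiff LSODA with an analytic Jacobian, rtol 1e-10 / atol 1e-14
for data generation (1e-8/1e-12 inside fitting loops, where speed matters
and residuals are noise-dominated); a BDF retry catches the rare LSODA
failures at extreme trial parameters. Public API in minutes and °C;
internals in seconds and Kelvin. R = 8.314 J mol⁻¹ K⁻¹.

Generating ("true") parameters: Eₐ = 80 kJ/mol, log A = 9.8,
k_side = 6·10⁻³ L mol⁻¹ s⁻¹. These put the narrowed box at roughly 68–93 %
yield at 6.5 min with a few percent of material lost to the side channel —
a realistic, identifiable regime. They live in the configuration, not in
code.

## The synthetic reactor

`synthetic_reactor` emulates the physical platform:

* **Slug makeup.** Five pumps (four reagent stocks + solvent) run at a
  constant total rate; each reagent pump's share is `target conc / stock
  conc`, the solvent absorbs the balance, and infeasible compositions raise
  an error naming the offending pump. Stock concentrations (2 M aryl, 4 M
  amine, 4 M DBU, 0.2 M Pd) are chosen so the whole broad box is reachable.
  Residence time is decoupled from makeup (the carrier solvent sets it), as
  on the real platform.
* **Impurity channels.** Two phenomenological low-level impurities are
  grafted onto the kinetic output so the DoE impurity surfaces have
  something real to model: nitrobenzene (protodehalogenation), promoted by
  temperature and amine loading, disfavoured by catalyst loading, scaled to
  stay below 7 mM over the narrowed box; and an unknown impurity growing
  with the square of the DBU charge, at the same few-mM order over the box.
  Both divert product-destined material (the protodehalogenated aryl never
  couples; the unknown channel is treated as base-mediated product
  degradation), so the pure catalytic-cycle model is a slightly-wrong model
  of the generator — and the mismatch grows with residence time, reagent
  excess and distance from the narrowed box. That gradient is what makes
  the kinetic model validate better in the narrow region than across the
  broad campaign, the behaviour the validation stage is designed to show.
* **Measurement.** UHPLC-like records carry multiplicative Gaussian noise,
  2 % relative per species, independent, clipped at zero. The magnitude is
  an assumption (chromatography-grade precision).
* **Spectra.** Pure-component signatures are sums of 3–5 Gaussian bands on
  a 650–1800 cm⁻¹ grid at 2 cm⁻¹, fixed by a library seed. While the slug
  is in the flow cell (detection time = dead volume / analytics flow;
  window = slug volume / analytics flow) each 5-s spectrum is the
  Beer–Lambert mixture of species 1/2/3 plus a slow sinusoidal baseline and
  white noise; outside the window only baseline is seen.

What the generator does **not** model: slug-internal mixing and axial
dispersion, gas compressibility, valve timing beyond a constant delay,
pump-rate error, instrument drift between days, and any chemistry beyond
the declared cycle. Passing tests therefore demonstrate the correctness and
statistical behaviour of the *methods* under a faithful but idealized data
source — not that the fitted constants or surfaces transfer to a physical
reactor.

## Self-optimization

Per objective (yield %, space-time yield, cost — the last computed from the
stock volumes one slug consumes at configured prices, carrier solvent
excluded; STY referenced to the slug volume) a GP surrogate is fitted on
coded inputs and standardized outputs: anisotropic Matérn-5/2 times a signal
variance, plus a white-noise term, hyperparameters by restarted
marginal-likelihood maximization (scikit-learn backend). All objectives are
minimized internally (yield and STY negated).

Acquisition is pool-based Thompson sampling: a joint posterior draw per
objective over a seeded LHC candidate pool (Cholesky with jitter escalating
tenfold from 1e-6 to 1e-2), scored by exact hypervolume improvement over the
incumbent Pareto front against a reference point 10 % of the observed range
beyond the componentwise worst observation. Hypervolume is computed exactly
for up to three objectives by a sweep over the third coordinate with a 2-D
staircase subroutine. Pool-based selection was chosen over spectral
sampling + evolutionary inner optimization because it preserves the same
Thompson/hypervolume-improvement semantics while being deterministic per
seed and directly testable against a naive exhaustive scan; the pool size
is configuration (2000 by default; desk-scale runs in the tests and the
acceptance script use 150–250, which changes only how finely the pool covers
the box).

A fixed check-point setpoint is re-run every 10th guided iteration (the
cadence is a package choice; only "several times per campaign" is
documented) to monitor drift; check-point runs are logged but never enter
the surrogate training set. Infeasible selections are logged and skipped
without a model update.

## Response-surface stage

Full quadratic OLS in coded units (15 terms for n = 4). No term pruning
ever: determinism and transparency beat parsimony here, so coefficients are
reported with t-based confidence intervals but never auto-dropped. R² = 1 −
SSE/SST, with the zero-variance response fixed at R² = 0 by convention. Q²
= 1 − PRESS/SST with PRESS obtained exactly from the hat-matrix identity
eᵢ/(1 − hᵢᵢ); a leverage of 1 (rank-deficient leave-one-out refit) raises.
Rank deficiency of the basis raises an error naming the aliased terms found
by column-pivoted QR. Impurity responses are fitted on the mM concentration
scale. Surface optimization is multi-start L-BFGS-B from every corner, face
center, the box center and the best of a coarse grid, clipped to the box.

## Kinetic fitting

(Eₐ, log A, log₁₀ k_side) are estimated by trust-region least squares on the
residuals of species 1, 2 and 3 jointly (uniform weights in mol/L), with
k_fast fixed; bounds Eₐ ∈ [10, 200] kJ/mol, log A ∈ [3, 15], log₁₀ k_side ∈
[−6, 0]. Positivity is guaranteed by fitting log-scale parameters. One ODE
solve per condition covers all of its residence times. Multi-start (default
4: bound-box center plus seeded uniform draws) is not optional decoration —
on some noise draws the center start demonstrably converges to a poor local
optimum that a single restart recovers from. Identifiability preconditions
are enforced: at least three distinct (condition, time) pairs and at least
two temperatures, otherwise Eₐ and log A are confounded.

The default campaign crosses six conditions spanning three temperature
levels and contrasts in catalyst, amine, DBU and concentration near the
narrowed box, with residence times {0.5, 1.5, 3, 6, 9, 12} min. Validation
reports the product-3 RMSE in mM on an independent log.

## Chemometrics

Spectra are windowed per experiment at [detection + 10 s, + 40 s] (the
trigger delay is a configurable assumption), averaged — averaging rather
than apex-picking, for noise reduction and determinism — and joined to
reference concentrations by experiment id, with hard errors on duplicate
ids, missing batches, grid mismatches and empty windows. The PLS2 model
(NIPALS backend, mean-centering only since all channels share absorbance
units) is cross-validated leave-one-out; the latent-variable count is the
minimizer of the mean RMSECV across the three analytes. Models persist to
JSON with exact round-trip.

## Problem sizes

Test-suite and acceptance-script runs use: 60-record campaigns (12 LHC + 48
guided) with a 150–250-point candidate pool and 1 GP restart; 10 paired
seeds for the guided-vs-random comparison; 10 noise seeds for the
parameter-recovery study; 1e6 Monte-Carlo samples for the hypervolume
oracle; a 17⁴ coded grid for the surface-optimizer oracle. These sizes are
the package's desk-scale defaults and are all configurable.

## Known limitations

* The generator and the fitted kinetic model share the same cycle, so
  parameter-recovery results quantify estimator behaviour, not model
  adequacy; the impurity channels are the only structural mismatch.
* Exact hypervolume is implemented for ≤ 3 objectives only.
* GP hyperparameter optimization is non-convex; restarts make selections
  reproducible per seed but not globally optimal.
* Cost covers stock solutions in the slug only — no solvent carrier, gas,
  energy or Pd-recovery terms.
* The PLS stage assumes a common, exactly aligned wavenumber grid; no
  baseline-correction or wavelength-selection research is attempted.
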