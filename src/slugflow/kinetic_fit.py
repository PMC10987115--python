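"""Kinetic parameter estimation from multi-condition time-course data.

Six reaction conditions, each run at six residence times spanning 0.5–12
minutes, give a 36-point campaign.  Three parameters are estimated jointly
by multi-start nonlinear least squares on the measured concentrations of
aryl bromide 1, amine 2 and product 3:

* ``Ea``    activation energy of the rate-limiting oxidative addition,
* ``logA``  log10 of its pre-exponential factor,
* ``k_side`` (fitted as log10) the temperature-independent deactivation /
  impurity rate constant,

with the fast downstream rate constant ``k_fast`` held fixed.  Ea is only
identifiable when the data span at least two temperatures; that precondition
is enforced.  Fitted models are validated by predicting independent
campaigns and reporting the product-concentration RMSE in mmol/L.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .design_space import Setpoint
from .kinetics import KineticParams, simulate
from .synthetic_reactor import ExperimentRecord

__all__ = [
    "FitResult",
    "DEFAULT_BOUNDS",
    "default_kinetic_conditions",
    "DEFAULT_TIMES",
    "make_kinetic_campaign",
    "fit_params",
    "validate",
]

#: (Ea J/mol, logA, log10 k_side) box constraints for the fit
DEFAULT_BOUNDS = {
    "Ea": (1.0e4, 2.0e5),
    "logA": (3.0, 15.0),
    "log10_k_side": (-6.0, 0.0),
}

#: residence times (min) of the default kinetic campaign
DEFAULT_TIMES = (0.5, 1.5, 3.0, 6.0, 9.0, 12.0)

_FIT_SPECIES = (("1", "A"), ("2", "B"), ("3", "P"))


def default_kinetic_conditions() -> list[Setpoint]:
    """Six conditions spanning the productive region: three temperature
    levels and contrasts in catalyst, amine, DBU and concentration.  The
    residence time placeholder is replaced per campaign time point."""
    return [
        Setpoint(amine_equiv=1.07, conc=0.33, t_res=6.5, temp=130.0, dbu_equiv=1.07, cat_loading=4.3),
        Setpoint(amine_equiv=1.28, conc=0.33, t_res=6.5, temp=140.0, dbu_equiv=1.61, cat_loading=5.4),
        Setpoint(amine_equiv=1.18, conc=0.30, t_res=6.5, temp=135.0, dbu_equiv=1.34, cat_loading=4.85),
        Setpoint(amine_equiv=1.28, conc=0.36, t_res=6.5, temp=130.0, dbu_equiv=1.61, cat_loading=5.4),
        Setpoint(amine_equiv=1.07, conc=0.33, t_res=6.5, temp=140.0, dbu_equiv=1.07, cat_loading=4.3),
        Setpoint(amine_equiv=1.20, conc=0.33, t_res=6.5, temp=135.0, dbu_equiv=1.50, cat_loading=5.0),
    ]


def make_kinetic_campaign(conditions: list[Setpoint],
                          times=DEFAULT_TIMES) -> list[Setpoint]:
    """Cartesian product of reaction conditions and residence times: each
    condition is reproduced at every time point."""
    times = [float(t) for t in times]
    if any(t < 0.5 - 1e-12 or t > 12.0 + 1e-12 for t in times):
        raise ValueError("residence times must lie within [0.5, 12] min")
    return [cond.replace(t_res=t) for cond, t in itertools.product(conditions, times)]


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start kinetic fit."""

    params: KineticParams
    rss: float
    per_dataset_rmse: dict[str, float]       # condition key -> RMSE (mol/L)
    n_starts: int
    n_converged: int
    start_results: tuple[tuple[float, bool], ...] = field(default=())

    def to_json(self, path: str, bounds: dict | None = None) -> None:
        payload = {
            "Ea_J_per_mol": self.params.Ea,
            "logA": self.params.logA,
            "k_fast_L_per_mol_s": self.params.k_fast,
            "k_side_L_per_mol_s": self.params.k_side,
            "rss": self.rss,
            "per_dataset_rmse_mol_L": self.per_dataset_rmse,
            "n_starts": self.n_starts,
            "n_converged": self.n_converged,
            "bounds": bounds or DEFAULT_BOUNDS,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _condition_key(sp: Setpoint) -> tuple:
    return (sp.amine_equiv, sp.conc, sp.temp, sp.dbu_equiv, sp.cat_loading)


def _group_by_condition(records: list[ExperimentRecord]):
    groups: dict[tuple, list[ExperimentRecord]] = {}
    for rec in records:
        groups.setdefault(_condition_key(rec.setpoint), []).append(rec)
    for key in groups:
        groups[key].sort(key=lambda r: r.setpoint.t_res)
    return groups


def _predict_conditions(groups, theta: np.ndarray, k_fast: float,
                        rtol: float = 1e-8, atol: float = 1e-12):
    """Predicted concentrations of species 1/2/3 per record, one stiff solve
    per condition covering all of its residence times."""
    Ea, logA, log_ks = theta
    params = KineticParams(Ea=Ea, logA=logA, k_fast=k_fast, k_side=10.0 ** log_ks)
    preds: dict[str, np.ndarray] = {}
    for key, recs in groups.items():
        times = np.array([0.0] + [r.setpoint.t_res for r in recs])
        course = simulate(recs[0].setpoint, params, times, rtol=rtol, atol=atol)
        for i, rec in enumerate(recs, start=1):
            row = course.states.iloc[i]
            preds[rec.id] = np.array([row[kin] for _, kin in _FIT_SPECIES])
    return preds


def fit_params(records: list[ExperimentRecord], k_fast: float = 1.0e4,
               bounds: dict | None = None, n_starts: int = 4,
               seed: int = 0) -> FitResult:
    """Fit (Ea, logA, k_side) to an experiment log by multi-start
    trust-region least squares on species 1, 2 and 3 jointly.

    Raises ``ValueError`` if the data contain fewer than three distinct
    (condition, time) pairs or span fewer than two temperatures, in which
    case Ea and logA are not separately identifiable.
    """
    from scipy.optimize import least_squares

    bounds = bounds or DEFAULT_BOUNDS
    pairs = {(_condition_key(r.setpoint), r.setpoint.t_res) for r in records}
    temps = {r.setpoint.temp for r in records}
    if len(pairs) < 3:
        raise ValueError("need >= 3 distinct (condition, time) pairs to fit 3 parameters")
    if len(temps) < 2:
        raise ValueError("data span a single temperature: Ea is not identifiable")

    groups = _group_by_condition(records)
    y_obs = {r.id: np.array([r.measured[m] for m, _ in _FIT_SPECIES]) for r in records}

    def residuals(theta):
        preds = _predict_conditions(groups, theta, k_fast)
        return np.concatenate([preds[r.id] - y_obs[r.id] for r in records])

    lo = np.array([bounds["Ea"][0], bounds["logA"][0], bounds["log10_k_side"][0]])
    hi = np.array([bounds["Ea"][1], bounds["logA"][1], bounds["log10_k_side"][1]])
    rng = np.random.default_rng(seed)
    starts = [0.5 * (lo + hi)]
    for _ in range(n_starts - 1):
        starts.append(lo + rng.uniform(0.15, 0.85, size=3) * (hi - lo))

    best = None
    start_log = []
    n_converged = 0
    for x0 in starts:
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                x_scale=np.array([1e4, 1.0, 1.0]),
                                xtol=1e-12, ftol=1e-12, gtol=1e-10)
        except Exception:
            start_log.append((np.inf, False))
            continue
        ok = bool(res.success)
        n_converged += ok
        start_log.append((float(res.cost), ok))
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"all {n_starts} optimizer starts failed; log: {start_log}")

    theta = best.x
    fitted = KineticParams(Ea=float(theta[0]), logA=float(theta[1]),
                           k_fast=k_fast, k_side=float(10.0 ** theta[2]))
    preds = _predict_conditions(groups, theta, k_fast)
    per_rmse = {}
    for key, recs in groups.items():
        errs = np.concatenate([preds[r.id] - y_obs[r.id] for r in recs])
        label = f"T{recs[0].setpoint.temp:g}_cat{recs[0].setpoint.cat_loading:g}_am{recs[0].setpoint.amine_equiv:g}_dbu{recs[0].setpoint.dbu_equiv:g}"
        per_rmse[label] = float(np.sqrt(np.mean(errs ** 2)))
    rss = float(2.0 * best.cost)
    return FitResult(params=fitted, rss=rss, per_dataset_rmse=per_rmse,
                     n_starts=n_starts, n_converged=n_converged,
                     start_results=tuple(start_log))


def validate(fit: FitResult, records: list[ExperimentRecord],
             rtol: float = 1e-8) -> float:
    """RMSE (mmol/L) of predicted vs measured product-3 concentration over
    an independent experiment log."""
    errs = []
    for rec in records:
        course = simulate(rec.setpoint, fit.params,
                          np.array([0.0, rec.setpoint.t_res]),
                          rtol=rtol, atol=1e-12)
        pred = float(course.states["P"].iloc[-1])
        errs.append(pred - rec.measured["3"])
    return float(np.sqrt(np.mean(np.square(errs)))) * 1000.0
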