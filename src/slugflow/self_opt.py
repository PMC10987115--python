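"""Multi-objective Bayesian self-optimization (TSEMO-style).

The campaign maps the broad six-variable design space against three
objectives (yield, space-time yield, cost).  One Gaussian-process surrogate
is fitted per objective (anisotropic Matérn-5/2, white measurement-noise
term, hyperparameters by restarted marginal-likelihood maximization).  At
each iteration a joint Thompson draw is taken from every posterior over a
seeded Latin-hypercube candidate pool and the candidate whose sampled
objective vector yields the largest hypervolume improvement over the
incumbent Pareto front is run next.

This is pool-based Thompson sampling: it preserves the Thompson-sampling /
hypervolume-improvement semantics of the original spectral-sampling TSEMO
algorithm while staying exactly reproducible at desk scale.  The pool size
is configuration, not a constant.

All objectives are handled internally in a minimization convention (yield
and STY are negated); hypervolume is computed exactly for up to three
objectives against a reference point placed 10% of the observed range beyond
the componentwise worst observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .design_space import DesignSpace, Setpoint, encode, sample_lhc
from .objectives import OBJECTIVE_NAMES, OBJECTIVE_SENSES
from .synthetic_reactor import (ExperimentRecord, InfeasibleSetpointError,
                                run_experiment)

__all__ = [
    "SurrogateModel",
    "ParetoSet",
    "fit_gp",
    "thompson_sample",
    "pareto_front",
    "hypervolume",
    "select_next",
    "run_campaign",
    "random_campaign",
    "CampaignResult",
    "reference_point",
    "parallel_coordinates_frame",
]


# ---------------------------------------------------------------------------
# GP surrogate

@dataclass
class SurrogateModel:
    """GP regression surrogate for one objective, trained on coded inputs
    and internally standardized outputs."""

    gpr: GaussianProcessRegressor
    X: np.ndarray
    y_mean: float
    y_std: float

    @property
    def kernel_(self):
        return self.gpr.kernel_

    def predict(self, X: np.ndarray, return_std: bool = False):
        if return_std:
            m, s = self.gpr.predict(np.asarray(X, float), return_std=True)
            return m * self.y_std + self.y_mean, s * self.y_std
        m = self.gpr.predict(np.asarray(X, float))
        return m * self.y_std + self.y_mean

    @property
    def noise_std(self) -> float:
        """Fitted observation-noise SD on the original output scale."""
        for k in _kernel_terms(self.gpr.kernel_):
            if isinstance(k, WhiteKernel):
                return float(np.sqrt(k.noise_level)) * self.y_std
        return 0.0


def _kernel_terms(kernel):
    if hasattr(kernel, "k1"):
        yield from _kernel_terms(kernel.k1)
        yield from _kernel_terms(kernel.k2)
    else:
        yield kernel


def fit_gp(X: np.ndarray, y: np.ndarray, seed: int = 0,
           n_restarts: int = 2) -> SurrogateModel:
    """Fit an anisotropic Matérn-5/2 GP with a white-noise term.

    ``X`` are coded points in [-1, 1]^n; ``y`` is standardized internally.
    Hyperparameters are chosen by marginal-likelihood maximization with
    ``n_restarts`` extra random restarts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) < 2 or len(X) != len(y):
        raise ValueError("need >= 2 training points with matching X and y")
    if np.all(np.all(X == X[0], axis=1)):
        raise ValueError("degenerate training set: all input rows identical")
    y_mean = float(np.mean(y))
    y_std = float(np.std(y))
    if y_std == 0.0:
        y_std = 1.0
    ys = (y - y_mean) / y_std
    n_dim = X.shape[1]
    kernel = (ConstantKernel(1.0, (1e-3, 1e6))
              * Matern(length_scale=np.ones(n_dim),
                       length_scale_bounds=(1e-2, 1e3), nu=2.5)
              + WhiteKernel(noise_level=1e-4, noise_level_bounds=(1e-12, 1.0)))
    gpr = GaussianProcessRegressor(kernel=kernel, normalize_y=False,
                                   n_restarts_optimizer=n_restarts,
                                   random_state=int(seed))
    with warnings.catch_warnings():
        # hyperparameters pinned at their (deliberately wide) bounds are fine
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        gpr.fit(X, ys)
    return SurrogateModel(gpr=gpr, X=X, y_mean=y_mean, y_std=y_std)


_JITTER_START = 1e-6
_JITTER_MAX = 1e-2


def thompson_sample(model: SurrogateModel, candidates: np.ndarray,
                    seed: int) -> np.ndarray:
    """One joint draw from the GP posterior over the candidate set.

    Uses the Cholesky factor of the posterior covariance with jitter
    escalated tenfold from 1e-6 up to 1e-2 before failing.
    """
    candidates = np.asarray(candidates, dtype=float)
    if candidates.ndim != 2 or len(candidates) == 0:
        raise ValueError("candidate set must be a non-empty 2-D array")
    mean_s, cov_s = model.gpr.predict(candidates, return_cov=True)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(len(candidates))
    jitter = _JITTER_START
    while True:
        try:
            L = np.linalg.cholesky(cov_s + jitter * np.eye(len(candidates)))
            break
        except np.linalg.LinAlgError:
            jitter *= 10.0
            if jitter > _JITTER_MAX:
                raise RuntimeError(
                    "posterior covariance not PSD even at maximum jitter")
    draw_s = mean_s + L @ z
    return draw_s * model.y_std + model.y_mean


# ---------------------------------------------------------------------------
# Pareto front and hypervolume

@dataclass(frozen=True)
class ParetoSet:
    """Non-dominated subset of evaluated records.

    ``objectives_min`` holds the member rows sign-adjusted so that every
    objective is minimized; ``hypervolume`` is measured against ``reference``
    in that convention.
    """

    member_ids: tuple[str, ...]
    objectives_min: np.ndarray
    reference: np.ndarray
    hypervolume: float


def _to_min(F: np.ndarray, senses) -> np.ndarray:
    signs = np.array([-1.0 if s > 0 else 1.0 for s in senses])
    return np.asarray(F, dtype=float) * signs


def pareto_mask(F_min: np.ndarray) -> np.ndarray:
    """Boolean mask of non-dominated rows under minimization; ties kept."""
    F_min = np.asarray(F_min, dtype=float)
    n = len(F_min)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        if not mask[i]:
            continue
        dominates_i = (np.all(F_min <= F_min[i], axis=1)
                       & np.any(F_min < F_min[i], axis=1))
        if np.any(dominates_i):
            mask[i] = False
    return mask


def pareto_front(F: np.ndarray, senses=OBJECTIVE_SENSES) -> np.ndarray:
    """Indices of the non-dominated rows of ``F`` under the given senses
    (+1 maximize, -1 minimize).  Tied (duplicate) optima are all kept."""
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("objective matrix contains non-finite values")
    return np.nonzero(pareto_mask(_to_min(F, senses)))[0]


def _hv_2d(points: np.ndarray, ref: np.ndarray) -> float:
    # minimization; points all <= ref componentwise
    pts = points[np.lexsort((points[:, 1], points[:, 0]))]
    hv = 0.0
    best_y = ref[1]
    for x, y in pts:
        if y < best_y:
            hv += (ref[0] - x) * (best_y - y)
            best_y = y
    return hv


def hypervolume(front: np.ndarray, reference: np.ndarray) -> float:
    """Exact hypervolume (Lebesgue measure of the region dominated by
    ``front`` and bounded by ``reference``), minimization convention,
    for 1–3 objectives."""
    front = np.atleast_2d(np.asarray(front, dtype=float))
    ref = np.asarray(reference, dtype=float)
    if front.shape[1] != ref.size:
        raise ValueError("front and reference dimensionality differ")
    if np.any(front > ref + 1e-12):
        raise ValueError("every front point must dominate the reference point")
    m = ref.size
    if m == 1:
        return float(ref[0] - front[:, 0].min())
    if m == 2:
        return float(_hv_2d(front, ref))
    if m == 3:
        # sweep along the third coordinate: between consecutive z-levels the
        # dominated cross-section is the 2-D hypervolume of the points with
        # z at or below the slab
        order = np.argsort(front[:, 2])
        pts = front[order]
        zs = pts[:, 2]
        levels = np.unique(zs)
        hv = 0.0
        uppers = np.append(levels[1:], ref[2])
        for z, z_next in zip(levels, uppers):
            active = pts[zs <= z][:, :2]
            hv += _hv_2d(active, ref[:2]) * (z_next - z)
        return float(hv)
    raise NotImplementedError("exact hypervolume implemented for <= 3 objectives")


def reference_point(F_min: np.ndarray, margin: float = 0.1) -> np.ndarray:
    """Reference point: componentwise worst observation plus ``margin`` of
    the observed range (a fixed offset where an objective has zero range)."""
    F_min = np.atleast_2d(np.asarray(F_min, dtype=float))
    worst = F_min.max(axis=0)
    rng = F_min.max(axis=0) - F_min.min(axis=0)
    pad = np.where(rng > 0, margin * rng, np.maximum(margin * np.abs(worst), 1e-9))
    return worst + pad


def make_pareto_set(records: list[ExperimentRecord],
                    senses=OBJECTIVE_SENSES) -> ParetoSet:
    """Pareto set of an experiment log, with hypervolume vs the automatic
    reference point."""
    F = np.array([r.objectives.as_tuple() for r in records])
    F_min = _to_min(F, senses)
    idx = np.nonzero(pareto_mask(F_min))[0]
    ref = reference_point(F_min)
    hv = hypervolume(F_min[idx], ref)
    return ParetoSet(member_ids=tuple(records[i].id for i in idx),
                     objectives_min=F_min[idx], reference=ref, hypervolume=hv)


# ---------------------------------------------------------------------------
# acquisition and campaign loop

def hv_improvement(front_min: np.ndarray, point_min: np.ndarray,
                   ref: np.ndarray) -> float:
    """Hypervolume gained by adding ``point_min`` to the front."""
    point_min = np.asarray(point_min, dtype=float)
    clipped = np.minimum(point_min, ref)
    if front_min.size == 0:
        return hypervolume(clipped[None, :], ref)
    base = hypervolume(front_min, ref)
    aug = np.vstack([front_min, clipped])
    return hypervolume(aug, ref) - base


def select_next(models: list[SurrogateModel], candidates: np.ndarray,
                front_min: np.ndarray, reference: np.ndarray,
                seed: int) -> int:
    """Index of the pool candidate whose joint Thompson draw maximizes
    hypervolume improvement over the incumbent front."""
    candidates = np.asarray(candidates, dtype=float)
    if len(candidates) == 0:
        raise ValueError("empty candidate pool")
    draws = np.column_stack([
        thompson_sample(m, candidates, seed=seed + 7919 * j)
        for j, m in enumerate(models)
    ])
    best_idx, best_hvi = 0, -np.inf
    frozen = pareto_mask(front_min) if len(front_min) else np.array([], bool)
    front_nd = front_min[frozen] if len(front_min) else front_min
    for i, d in enumerate(draws):
        hvi = hv_improvement(front_nd, d, reference)
        if hvi > best_hvi:
            best_hvi, best_idx = hvi, i
    return int(best_idx)


@dataclass
class CampaignResult:
    """Full log of a self-optimization campaign."""

    records: list[ExperimentRecord]          # in run order, incl. checkpoints
    pareto: ParetoSet
    seed: int

    @property
    def training_records(self) -> list[ExperimentRecord]:
        return [r for r in self.records if not r.is_checkpoint]

    def hypervolume_trace(self, reference: np.ndarray | None = None) -> np.ndarray:
        """Hypervolume of the incumbent front after each training record,
        against a fixed reference (default: the final campaign reference)."""
        recs = self.training_records
        F_min = _to_min(np.array([r.objectives.as_tuple() for r in recs]),
                        OBJECTIVE_SENSES)
        ref = self.pareto.reference if reference is None else np.asarray(reference)
        trace = []
        for i in range(1, len(recs) + 1):
            sub = np.minimum(F_min[:i], ref)
            nd = sub[pareto_mask(sub)]
            trace.append(hypervolume(nd, ref))
        return np.array(trace)


def _spawn_seeds(seed: int, n: int, salt: int = 0) -> np.ndarray:
    rng = np.random.default_rng([int(seed), int(salt)])
    return rng.integers(0, 2**31 - 1, size=n)


def run_campaign(space: DesignSpace, stocks, true_params, noise,
                 budget: tuple[int, int] = (12, 48),
                 checkpoint: Setpoint | None = None,
                 checkpoint_period: int = 10,
                 seed: int = 0, pool_size: int = 2000,
                 gp_restarts: int = 2) -> CampaignResult:
    """Run a TSEMO-style campaign on the in-silico reactor.

    ``budget = (n_init, n_guided)``: the campaign opens with an ``n_init``
    point Latin hypercube, then runs ``n_guided`` iterations selected by
    Thompson sampling / hypervolume improvement, giving
    ``n_init + n_guided`` model-training records.  The fixed ``checkpoint``
    setpoint is re-run every ``checkpoint_period`` guided iterations to
    monitor reproducibility; checkpoint runs are logged but excluded from
    model training.  Infeasible selections are logged as skipped and do not
    update the model.  Bit-reproducible for fixed (seed, configuration).
    """
    n_init, n_guided = budget
    if n_init < 2 or n_guided < 0:
        raise ValueError("budget must be at least (2, 0)")
    n_total = n_init + n_guided
    noise_seeds = _spawn_seeds(seed, n_total + max(1, n_guided // max(checkpoint_period, 1)) + 2, salt=1)
    algo_seeds = _spawn_seeds(seed, 2 * n_guided + 2, salt=2)

    records: list[ExperimentRecord] = []
    X_train: list[np.ndarray] = []
    F_train: list[tuple[float, float, float]] = []
    exp_counter = 0

    def _run(sp: Setpoint, is_checkpoint: bool = False) -> ExperimentRecord | None:
        nonlocal exp_counter
        rid = f"so-{exp_counter:03d}" + ("-chk" if is_checkpoint else "")
        try:
            rec = run_experiment(sp, stocks, true_params, noise,
                                 seed=int(noise_seeds[exp_counter]),
                                 record_id=rid, is_checkpoint=is_checkpoint)
        except InfeasibleSetpointError:
            exp_counter += 1
            return None
        exp_counter += 1
        records.append(rec)
        return rec

    for sp in sample_lhc(space, n_init, seed=int(algo_seeds[0])):
        rec = _run(sp)
        if rec is not None:
            X_train.append(encode(space, sp))
            F_train.append(rec.objectives.as_tuple())

    guided_done = 0
    it = 0
    while guided_done < n_guided:
        if (checkpoint is not None and checkpoint_period > 0
                and it > 0 and it % checkpoint_period == 0):
            _run(checkpoint, is_checkpoint=True)
        it += 1
        X = np.array(X_train)
        F_min = _to_min(np.array(F_train), OBJECTIVE_SENSES)
        ref = reference_point(F_min)
        models = [fit_gp(X, F_min[:, j], seed=int(algo_seeds[1 + 2 * guided_done]),
                         n_restarts=gp_restarts)
                  for j in range(F_min.shape[1])]
        pool_sps = sample_lhc(space, pool_size,
                              seed=int(algo_seeds[2 + 2 * guided_done]) )
        pool = np.array([encode(space, sp) for sp in pool_sps])
        front_min = F_min[pareto_mask(F_min)]
        pick = select_next(models, pool, front_min, ref,
                           seed=int(algo_seeds[1 + 2 * guided_done]))
        rec = _run(pool_sps[pick])
        if rec is not None:
            X_train.append(pool[pick])
            F_train.append(rec.objectives.as_tuple())
        guided_done += 1

    pareto = make_pareto_set([r for r in records if not r.is_checkpoint])
    return CampaignResult(records=records, pareto=pareto, seed=seed)


def random_campaign(space: DesignSpace, stocks, true_params, noise,
                    n_runs: int = 60, seed: int = 0) -> CampaignResult:
    """Baseline: the same number of experiments drawn uniformly at random
    from the design space, with the same per-experiment noise seeds as a
    TSEMO campaign of equal length and seed (paired comparison)."""
    noise_seeds = _spawn_seeds(seed, n_runs + 8, salt=1)
    rng = np.random.default_rng([int(seed), 3])
    records = []
    for i in range(n_runs):
        u = rng.uniform(-1.0, 1.0, size=space.n)
        sp = space.to_setpoint(space.lows + (u + 1) / 2 * (space.highs - space.lows))
        try:
            rec = run_experiment(sp, stocks, true_params, noise,
                                 seed=int(noise_seeds[i]), record_id=f"rs-{i:03d}")
        except InfeasibleSetpointError:
            continue
        records.append(rec)
    return CampaignResult(records=records, pareto=make_pareto_set(records), seed=seed)


def parallel_coordinates_frame(records: list[ExperimentRecord],
                               min_yield_pct: float | None = None):
    """Long-format table (record id, variable, value) for parallel-coordinate
    plots; optionally filtered to records above a yield threshold."""
    import pandas as pd

    rows = []
    for r in records:
        if r.is_checkpoint:
            continue
        if min_yield_pct is not None and r.objectives.yield_pct <= min_yield_pct:
            continue
        d = r.setpoint.as_dict()
        d.pop("ligand_ratio")
        d.update(dict(zip(OBJECTIVE_NAMES, r.objectives.as_tuple())))
        for var, val in d.items():
            rows.append({"id": r.id, "variable": var, "value": val})
    return pd.DataFrame(rows)
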