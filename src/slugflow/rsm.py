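"""Response-surface modelling on face-centered factorial designs.

Fits a full quadratic polynomial in coded units (intercept, n linear terms,
n(n-1)/2 two-way interactions, n pure quadratics; 15 terms for n = 4) by
ordinary least squares and reports the usual DoE diagnostics:

* R²  = 1 - SSE/SST (goodness of fit; 0 by convention for a zero-variance
  response);
* Q²  = 1 - PRESS/SST, the leave-one-out predictive coefficient, computed
  exactly through the OLS hat-matrix identity e_i / (1 - h_ii).

No term pruning is performed: the full quadratic is kept so that fits are
deterministic and every coefficient is reported with its confidence
interval.  Surface optimization is box-constrained multi-start local search
polished against a dense coded grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy import stats

from .design_space import DesignSpace, Setpoint, decode, encode

__all__ = [
    "RSModel",
    "quadratic_terms",
    "quadratic_basis",
    "fit_rsm",
    "q2_loo",
    "predict",
    "optimize_surface",
]


def quadratic_terms(names: list[str]) -> list[str]:
    """Term labels of the full quadratic basis, in column order."""
    terms = ["1"] + list(names)
    terms += [f"{a}:{b}" for a, b in itertools.combinations(names, 2)]
    terms += [f"{n}^2" for n in names]
    return terms


def quadratic_basis(X: np.ndarray) -> np.ndarray:
    """Design matrix of the full quadratic basis on coded inputs ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[1]
    cols = [np.ones(len(X))]
    cols += [X[:, i] for i in range(n)]
    cols += [X[:, i] * X[:, j] for i, j in itertools.combinations(range(n), 2)]
    cols += [X[:, i] ** 2 for i in range(n)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class RSModel:
    """Fitted quadratic response surface in coded units."""

    response: str
    terms: tuple[str, ...]
    coef: np.ndarray
    coef_se: np.ndarray
    r2: float
    q2: float
    n_runs: int

    def coef_table(self, conf: float = 0.95) -> pd.DataFrame:
        dof = max(self.n_runs - len(self.terms), 1)
        tcrit = stats.t.ppf(0.5 + conf / 2, dof)
        return pd.DataFrame({
            "term": self.terms,
            "coef": self.coef,
            "se": self.coef_se,
            "ci_lower": self.coef - tcrit * self.coef_se,
            "ci_upper": self.coef + tcrit * self.coef_se,
        })


class AliasedTermsError(np.linalg.LinAlgError):
    def __init__(self, aliased: list[str]):
        super().__init__(f"rank-deficient quadratic basis; aliased terms: {aliased}")
        self.aliased = aliased


def _check_rank(B: np.ndarray, terms: list[str]) -> None:
    # column-pivoted QR flags the columns that fall outside the numerical rank
    from scipy.linalg import qr

    _, R, piv = qr(B, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(B.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < B.shape[1]:
        aliased = [terms[i] for i in sorted(piv[rank:])]
        raise AliasedTermsError(aliased)


def fit_rsm(design: np.ndarray, response: np.ndarray,
            response_name: str = "response") -> RSModel:
    """Ordinary-least-squares fit of the full quadratic surface.

    ``design`` is the coded run matrix (rows = runs), ``response`` the
    measured values.  Raises :class:`AliasedTermsError` when the basis is
    rank-deficient, naming the aliased terms.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(response, dtype=float)
    if len(X) != len(y):
        raise ValueError("design and response lengths differ")
    terms = quadratic_terms([f"x{i+1}" for i in range(X.shape[1])])
    B = quadratic_basis(X)
    if len(y) < B.shape[1]:
        raise ValueError(f"need at least {B.shape[1]} runs for {B.shape[1]} terms, got {len(y)}")
    _check_rank(B, terms)
    coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    dof = len(y) - B.shape[1]
    sigma2 = sse / dof if dof > 0 else 0.0
    XtX_inv = np.linalg.inv(B.T @ B)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    q2 = q2_loo(X, y)
    return RSModel(response=response_name, terms=tuple(terms), coef=coef,
                   coef_se=se, r2=r2, q2=q2, n_runs=len(y))


def q2_loo(design: np.ndarray, response: np.ndarray) -> float:
    """Leave-one-out Q² = 1 - PRESS/SST.

    PRESS is computed exactly from the single full fit via the hat-matrix
    identity: the LOO residual of run i equals e_i / (1 - h_ii).  A leverage
    of one means the corresponding leave-one-out refit is rank-deficient.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(response, dtype=float)
    B = quadratic_basis(X)
    if len(y) <= B.shape[1]:
        raise ValueError("Q² requires more runs than model terms")
    terms = quadratic_terms([f"x{i+1}" for i in range(X.shape[1])])
    _check_rank(B, terms)
    coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    XtX_inv = np.linalg.inv(B.T @ B)
    h = np.einsum("ij,jk,ik->i", B, XtX_inv, B)
    if np.any(h >= 1.0 - 1e-10):
        raise np.linalg.LinAlgError(
            "leave-one-out refit rank-deficient (leverage of 1 detected)")
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0
    return 1.0 - press / sst


def predict(model: RSModel, design: np.ndarray) -> np.ndarray:
    """Predicted response at coded points (rows)."""
    B = quadratic_basis(design)
    if B.shape[1] != len(model.coef):
        raise ValueError("dimensionality differs from the fitted model")
    return B @ model.coef


def optimize_surface(model: RSModel, space: DesignSpace, sense: str = "max",
                     grid_points: int = 9) -> tuple[Setpoint, float]:
    """Box-constrained optimum of the fitted surface.

    Multi-start L-BFGS-B from every corner, face center and the box center,
    plus a dense coded-grid polish; returns the decoded Setpoint and the
    predicted response there.  Deterministic.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    sign = -1.0 if sense == "max" else 1.0
    n = space.n

    def f(x):
        return sign * float(predict(model, x[None, :])[0])

    starts = [np.zeros(n)]
    for corner in itertools.product((-1.0, 1.0), repeat=n):
        starts.append(np.array(corner))
    for i in range(n):
        for lvl in (-1.0, 1.0):
            face = np.zeros(n)
            face[i] = lvl
            starts.append(face)
    # coarse grid polish start
    axes = [np.linspace(-1, 1, grid_points)] * n
    grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(n, -1).T
    vals = sign * predict(model, grid)
    starts.append(grid[np.argmin(vals)])

    best_x, best_v = None, np.inf
    for x0 in starts:
        res = minimize(f, x0, method="L-BFGS-B", bounds=[(-1.0, 1.0)] * n)
        if res.fun < best_v:
            best_v, best_x = res.fun, res.x
    return decode(space, np.clip(best_x, -1, 1)), sign * best_v


def diagnostics_frame(model: RSModel, design: np.ndarray,
                      response: np.ndarray) -> pd.DataFrame:
    """Predicted-vs-observed pairs for a fitted model."""
    return pd.DataFrame({
        "observed": np.asarray(response, dtype=float),
        "predicted": predict(model, design),
    })
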