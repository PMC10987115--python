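"""Chemometric calibration: automated spectra sorting and PLS modelling.

Reproduces the automated data-handling workflow of the platform: timestamped
FTIR-like spectra from each experiment are windowed around the slug's
detection time, averaged into one calibration spectrum per experiment, and
joined to the UHPLC-reported reference concentrations of aryl bromide 1,
amine 2 and product 3.  A PLS2 regression (NIPALS, mean-centering only —
spectra share units) is then cross-validated leave-one-out, the number of
latent variables chosen at the minimum mean RMSECV, giving an inline
quantification model for the three major species.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .synthetic_reactor import ExperimentRecord, SpectrumBatch

__all__ = [
    "CalibrationTable",
    "PLSModel",
    "sort_and_merge",
    "fit_pls",
    "predict_pls",
    "save_pls",
    "load_pls",
]

ANALYTES = ("1", "2", "3")


@dataclass(frozen=True)
class CalibrationTable:
    """One averaged slug spectrum per experiment, matched to reference
    concentrations (mol/L) of the three quantified species."""

    ids: tuple[str, ...]
    wavenumbers: np.ndarray
    spectra: np.ndarray            # (n_experiments, n_wavenumbers)
    concentrations: np.ndarray     # (n_experiments, 3) in ANALYTES order

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate experiment ids in calibration table")
        if self.spectra.shape != (len(self.ids), self.wavenumbers.size):
            raise ValueError("spectra shape inconsistent with ids/grid")
        if self.concentrations.shape != (len(self.ids), len(ANALYTES)):
            raise ValueError("concentration block shape mismatch")
        if np.any(~np.isfinite(self.concentrations)):
            raise ValueError("missing reference concentrations")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.spectra,
                          columns=[f"wn_{w:g}" for w in self.wavenumbers])
        df.insert(0, "id", self.ids)
        for j, a in enumerate(ANALYTES):
            df[f"conc_{a}"] = self.concentrations[:, j]
        return df


def sort_and_merge(batches: list[SpectrumBatch],
                   records: list[ExperimentRecord],
                   window: tuple[float, float] = (10.0, 30.0)) -> CalibrationTable:
    """Window, average and join incoming spectra to reference concentrations.

    For each experiment, spectra with timestamps inside
    ``[detect + delay, detect + delay + duration]`` (``window = (delay,
    duration)`` in seconds) are averaged into a single calibration row;
    spectra outside every window are discarded.  Raises if an experiment has
    no in-window spectra or if ids are duplicated.
    """
    delay, duration = window
    by_id: dict[str, SpectrumBatch] = {}
    for b in batches:
        if b.experiment_id in by_id:
            raise ValueError(f"duplicate spectra batch for experiment {b.experiment_id!r}")
        by_id[b.experiment_id] = b
    ids_seen = set()
    rows, concs, ids = [], [], []
    wn = None
    for rec in records:
        if rec.id in ids_seen:
            raise ValueError(f"duplicate experiment id {rec.id!r} in log")
        ids_seen.add(rec.id)
        batch = by_id.get(rec.id)
        if batch is None:
            raise ValueError(f"experiment {rec.id!r} has no spectra batch")
        if wn is None:
            wn = batch.wavenumbers
        elif not np.array_equal(batch.wavenumbers, wn):
            raise ValueError(f"experiment {rec.id!r}: wavenumber grid mismatch")
        t0 = rec.slug_detect_time + delay
        sel = (batch.timestamps >= t0) & (batch.timestamps <= t0 + duration)
        if not np.any(sel):
            raise ValueError(f"experiment {rec.id!r} has no spectra inside its window")
        rows.append(batch.absorbances[sel].mean(axis=0))
        concs.append([rec.measured[a] for a in ANALYTES])
        ids.append(rec.id)
    return CalibrationTable(ids=tuple(ids), wavenumbers=wn,
                            spectra=np.array(rows),
                            concentrations=np.array(concs))


@dataclass(frozen=True)
class PLSModel:
    """Fitted PLS2 calibration: regression matrix plus centering vectors."""

    n_components: int
    wavenumbers: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    coef: np.ndarray               # (n_wavenumbers, 3)
    rmsecv: dict[str, float]       # per analyte, mmol/L
    rmsecv_by_lv: np.ndarray       # (max_lv, 3) in mol/L

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("need at least one latent variable")


def _loo_rmsecv(X: np.ndarray, Y: np.ndarray, lv: int) -> np.ndarray:
    """Leave-one-out RMSECV per analyte (mol/L) at a fixed LV count."""
    n = len(X)
    errs = np.empty_like(Y)
    with warnings.catch_warnings():
        # NIPALS reports an exactly-fitted Y block as "constant residual"
        warnings.filterwarnings("ignore", message="y residual is constant")
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            pls = PLSRegression(n_components=lv, scale=False)
            pls.fit(X[keep], Y[keep])
            errs[i] = pls.predict(X[i][None, :])[0] - Y[i]
    return np.sqrt(np.mean(errs ** 2, axis=0))


def fit_pls(table: CalibrationTable, max_lv: int = 6) -> PLSModel:
    """Fit and cross-validate the PLS2 calibration model.

    The latent-variable count (1..max_lv) is chosen at the minimum mean
    leave-one-out RMSECV across the three analytes; the final model is
    refitted on all rows at that count.
    """
    X, Y = table.spectra, table.concentrations
    n = len(X)
    if n <= max_lv:
        raise ValueError(f"need more than max_lv={max_lv} calibration rows, got {n}")
    if np.allclose(X, X[0]):
        raise ValueError("constant spectra: nothing to calibrate on")
    max_lv = min(max_lv, n - 1, X.shape[1])
    rmsecv_by_lv = np.array([_loo_rmsecv(X, Y, lv) for lv in range(1, max_lv + 1)])
    best_lv = int(np.argmin(rmsecv_by_lv.mean(axis=1))) + 1
    pls = PLSRegression(n_components=best_lv, scale=False)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="y residual is constant")
        pls.fit(X, Y)
    rmsecv = {a: float(rmsecv_by_lv[best_lv - 1, j] * 1000.0)
              for j, a in enumerate(ANALYTES)}
    return PLSModel(
        n_components=best_lv,
        wavenumbers=table.wavenumbers.copy(),
        x_mean=pls._x_mean.copy(),
        y_mean=pls._y_mean.copy(),
        coef=pls.coef_.T.copy(),
        rmsecv=rmsecv,
        rmsecv_by_lv=rmsecv_by_lv,
    )


def predict_pls(model: PLSModel, spectra: np.ndarray,
                wavenumbers: np.ndarray | None = None) -> np.ndarray:
    """Concentrations (mol/L) of species 1, 2, 3 for one or more spectra."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if wavenumbers is not None and not np.array_equal(wavenumbers, model.wavenumbers):
        raise ValueError("spectrum wavenumber grid differs from the training grid")
    if spectra.shape[1] != model.wavenumbers.size:
        raise ValueError("spectrum length differs from the training grid")
    return (spectra - model.x_mean) @ model.coef + model.y_mean


def save_pls(model: PLSModel, path: str) -> None:
    """Persist the model as JSON (exact round-trip)."""
    payload = {
        "n_components": model.n_components,
        "wavenumbers": model.wavenumbers.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean.tolist(),
        "coef": model.coef.tolist(),
        "rmsecv": model.rmsecv,
        "rmsecv_by_lv": model.rmsecv_by_lv.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_pls(path: str) -> PLSModel:
    with open(path) as fh:
        payload = json.load(fh)
    return PLSModel(
        n_components=int(payload["n_components"]),
        wavenumbers=np.array(payload["wavenumbers"]),
        x_mean=np.array(payload["x_mean"]),
        y_mean=np.array(payload["y_mean"]),
        coef=np.array(payload["coef"]),
        rmsecv={k: float(v) for k, v in payload["rmsecv"].items()},
        rmsecv_by_lv=np.array(payload["rmsecv_by_lv"]),
    )
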