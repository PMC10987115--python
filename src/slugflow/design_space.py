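"""Optimizable-variable space, coded-unit transforms and experimental designs.

The reaction under study (a Pd-catalysed Buchwald–Hartwig amination run in a
slug-flow reactor) exposes up to six continuous optimizable variables: amine
loading (equivalents vs the limiting aryl bromide), reaction concentration,
residence time, temperature, DBU base loading and catalyst loading.  The
ligand:catalyst ratio is held constant at 1.5 within a campaign.

Designs are generated in coded units on the box [-1, +1]^n and decoded into
physical units:

* Latin-hypercube samples (centered strata, seeded permutations) initialise
  self-optimization campaigns with ``2n`` evenly spread points.
* Face-centered full factorial designs (``2^n`` corner points, ``2n`` face
  points, optional center replicates) feed the response-surface stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

__all__ = [
    "VariableBound",
    "DesignSpace",
    "Setpoint",
    "sample_lhc",
    "face_centered_design",
    "encode",
    "decode",
    "default_selfopt_space",
    "default_doe_space",
    "space_from_config",
    "space_to_config",
    "design_to_frame",
]

#: canonical unit for each settable Setpoint field
_FIELD_UNITS = {
    "amine_equiv": "equiv",
    "conc": "mol/L",
    "t_res": "min",
    "temp": "degC",
    "dbu_equiv": "equiv",
    "cat_loading": "mol%",
}

_ALLOWED_UNITS = {"equiv", "mol/L", "min", "degC", "mol%"}
_UNIT_ALIASES = {"°C": "degC", "C": "degC", "mol.%": "mol%"}


@dataclass(frozen=True)
class Setpoint:
    """One operating point of the reactor, in physical units.

    ``conc`` is the concentration of the limiting aryl bromide (species 1);
    ``amine_equiv`` and ``dbu_equiv`` are molar equivalents relative to it;
    ``cat_loading`` is in mol% of the limiting reagent.  The Xantphos
    ligand:Pd ratio is fixed per campaign (default 1.5) and is carried along
    for provenance only.
    """

    amine_equiv: float
    conc: float
    t_res: float
    temp: float
    dbu_equiv: float
    cat_loading: float
    ligand_ratio: float = 1.5

    def __post_init__(self) -> None:
        for name in ("amine_equiv", "conc", "t_res", "temp", "dbu_equiv",
                     "cat_loading", "ligand_ratio"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"Setpoint field {name!r} must be finite and > 0, got {v}")

    def replace(self, **kw) -> "Setpoint":
        return replace(self, **kw)

    def as_dict(self) -> dict[str, float]:
        return {
            "amine_equiv": self.amine_equiv,
            "conc": self.conc,
            "t_res": self.t_res,
            "temp": self.temp,
            "dbu_equiv": self.dbu_equiv,
            "cat_loading": self.cat_loading,
            "ligand_ratio": self.ligand_ratio,
        }


@dataclass(frozen=True)
class VariableBound:
    """Closed physical range [low, high] for one optimizable variable."""

    name: str
    low: float
    high: float
    unit: str

    def __post_init__(self) -> None:
        unit = _UNIT_ALIASES.get(self.unit, self.unit)
        object.__setattr__(self, "unit", unit)
        if unit not in _ALLOWED_UNITS:
            raise ValueError(f"unit {self.unit!r} not in {sorted(_ALLOWED_UNITS)}")
        if not self.low < self.high:
            raise ValueError(f"variable {self.name!r}: low ({self.low}) must be < high ({self.high})")
        if self.name not in _FIELD_UNITS:
            raise ValueError(f"unknown variable name {self.name!r}; expected one of {sorted(_FIELD_UNITS)}")


@dataclass(frozen=True)
class DesignSpace:
    """Ordered collection of variable bounds plus fixed (held-constant) variables.

    ``fixed`` supplies values for Setpoint fields that are not optimized in
    this campaign (e.g. residence time and concentration in the four-variable
    response-surface stage).
    """

    bounds: tuple[VariableBound, ...]
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bounds", tuple(self.bounds))
        names = [b.name for b in self.bounds]
        if len(names) == 0:
            raise ValueError("DesignSpace needs at least one variable")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate variable names in design space: {names}")
        overlap = set(names) & set(self.fixed)
        if overlap:
            raise ValueError(f"variables both free and fixed: {sorted(overlap)}")

    @property
    def n(self) -> int:
        return len(self.bounds)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bounds]

    @property
    def lows(self) -> np.ndarray:
        return np.array([b.low for b in self.bounds], dtype=float)

    @property
    def highs(self) -> np.ndarray:
        return np.array([b.high for b in self.bounds], dtype=float)

    def to_setpoint(self, values: np.ndarray) -> Setpoint:
        """Build a Setpoint from physical values of the free variables."""
        kw = dict(zip(self.names, np.asarray(values, dtype=float)))
        kw.update(self.fixed)
        missing = set(_FIELD_UNITS) - set(kw)
        if missing:
            raise ValueError(f"design space leaves Setpoint fields undefined: {sorted(missing)}")
        return Setpoint(**kw)

    def values_of(self, sp: Setpoint) -> np.ndarray:
        """Physical values of the free variables, in bound order."""
        d = sp.as_dict()
        return np.array([d[name] for name in self.names], dtype=float)


def encode(space: DesignSpace, sp: Setpoint) -> np.ndarray:
    """Map a Setpoint to coded units: low -> -1, midpoint -> 0, high -> +1."""
    x = space.values_of(sp)
    lo, hi = space.lows, space.highs
    for name, v, l, h in zip(space.names, x, lo, hi):
        if v < l - 1e-12 * (h - l) or v > h + 1e-12 * (h - l):
            raise ValueError(f"variable {name!r} = {v} outside bounds [{l}, {h}]")
    return 2.0 * (x - lo) / (hi - lo) - 1.0

def decode(space: DesignSpace, coded: np.ndarray) -> Setpoint:
    """Inverse of :func:`encode` (coded units -> physical Setpoint)."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape != (space.n,):
        raise ValueError(f"coded vector has shape {coded.shape}, expected ({space.n},)")
    x = space.lows + (coded + 1.0) / 2.0 * (space.highs - space.lows)
    return space.to_setpoint(x)


def sample_lhc(space: DesignSpace, size: int, seed: int) -> list[Setpoint]:
    """Latin-hypercube sample: one centered point per equal-width stratum
    and dimension, strata assigned by a seeded permutation per dimension."""
    if size < 1:
        raise ValueError("LHC size must be >= 1")
    sampler = qmc.LatinHypercube(d=space.n, scramble=False, rng=int(seed))
    u = sampler.random(size)
    phys = qmc.scale(u, space.lows, space.highs)
    return [space.to_setpoint(row) for row in phys]


def face_centered_design(space: DesignSpace, n_center: int = 0) -> list[Setpoint]:
    """Face-centered full factorial: 2^n corners (all coordinates ±1 coded),
    2n face points (one coordinate ±1, rest 0) and ``n_center`` center
    replicates, decoded to physical units, in that order."""
    if n_center < 0:
        raise ValueError("n_center must be >= 0")
    n = space.n
    rows: list[np.ndarray] = []
    for corner in itertools.product((-1.0, 1.0), repeat=n):
        rows.append(np.array(corner))
    for i in range(n):
        for lvl in (-1.0, 1.0):
            face = np.zeros(n)
            face[i] = lvl
            rows.append(face)
    for _ in range(n_center):
        rows.append(np.zeros(n))
    return [decode(space, row) for row in rows]


# ---------------------------------------------------------------------------
# default spaces and config I/O

def default_selfopt_space() -> DesignSpace:
    """Six-variable space for the coarse self-optimization stage, ranges as
    broad as the platform allows."""
    return DesignSpace(bounds=(
        VariableBound("amine_equiv", 1.0, 2.0, "equiv"),
        VariableBound("conc", 0.1, 0.5, "mol/L"),
        VariableBound("t_res", 0.5, 12.0, "min"),
        VariableBound("temp", 80.0, 140.0, "degC"),
        VariableBound("dbu_equiv", 1.07, 2.13, "equiv"),
        VariableBound("cat_loading", 1.0, 6.0, "mol%"),
    ))


def default_doe_space() -> DesignSpace:
    """Narrowed four-variable space for the response-surface stage; residence
    time and concentration are fixed at their productive values."""
    return DesignSpace(
        bounds=(
            VariableBound("amine_equiv", 1.07, 1.28, "equiv"),
            VariableBound("temp", 130.0, 140.0, "degC"),
            VariableBound("dbu_equiv", 1.07, 1.61, "equiv"),
            VariableBound("cat_loading", 4.3, 5.4, "mol%"),
        ),
        fixed={"t_res": 6.5, "conc": 0.33},
    )


def space_from_config(cfg: dict | str) -> DesignSpace:
    """Build a DesignSpace from a config mapping or a YAML file path.

    Expected layout::

        variables:
          - {name: amine_equiv, low: 1.0, high: 2.0, unit: equiv}
          ...
        fixed: {t_res: 6.5}
    """
    if isinstance(cfg, str):
        with open(cfg) as fh:
            cfg = yaml.safe_load(fh)
    bounds = tuple(
        VariableBound(v["name"], float(v["low"]), float(v["high"]), v["unit"])
        for v in cfg["variables"]
    )
    fixed = {k: float(v) for k, v in (cfg.get("fixed") or {}).items()}
    return DesignSpace(bounds=bounds, fixed=fixed)


def space_to_config(space: DesignSpace) -> dict:
    return {
        "variables": [
            {"name": b.name, "low": b.low, "high": b.high, "unit": b.unit}
            for b in space.bounds
        ],
        "fixed": dict(space.fixed),
    }


def design_to_frame(space: DesignSpace, setpoints: list[Setpoint]) -> pd.DataFrame:
    """One row per setpoint: physical columns plus ``coded_*`` columns."""
    recs = []
    for sp in setpoints:
        row = sp.as_dict()
        coded = encode(space, sp)
        row.update({f"coded_{name}": c for name, c in zip(space.names, coded)})
        recs.append(row)
    return pd.DataFrame(recs)
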