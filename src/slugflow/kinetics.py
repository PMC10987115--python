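"""Mechanistic kinetic model of the Pd-catalysed amination.

The catalytic cycle carries four productive steps:

* r1  (rate-limiting oxidative addition):  ``Cat + A -> CatA`` with an
  Arrhenius rate constant ``k1(T) = 10^logA * exp(-Ea / (R T))``;
* r2  (amine coordination):                ``CatA + B -> CatAB`` at ``k_fast``;
* r3  (base-mediated deprotonation):       ``CatAB + DBU -> CatAm`` at
  ``k_fast`` (the DBU·HBr salt is tracked implicitly through DBU consumption);
* r4  (reductive elimination):             ``CatAm -> Cat + P`` at
  ``k_fast * 1 mol/L`` (made unimolecular by multiplying the fast bimolecular
  constant by a 1 M reference concentration).

One temperature-independent side reaction accounts jointly for catalyst
deactivation and impurity formation:

* r5  (deactivation/impurity):             ``Cat + A -> CatD + I`` at
  ``k_side`` (L mol^-1 s^-1).

Putting the side channel on the catalyst resting state (competing directly
with oxidative addition) keeps its branching ratio ``k_side / (k1 + k_side)``
independent of ``k_fast``, so the "all downstream steps arbitrarily fast"
structure is preserved exactly: doubling ``k_fast`` leaves product
trajectories unchanged to well below 0.1%.

Species: A (aryl bromide 1, limiting), B (amine 2), P (product 3), DBU,
Cat (active Pd0·L), CatA, CatAB, CatAm (cycle intermediates), CatD
(deactivated Pd), I (side-reaction impurity).  Two exact balances hold along
every trajectory: the aryl balance ``A + P + I + CatA + CatAB + CatAm = A0``
and the Pd balance ``Cat + CatA + CatAB + CatAm + CatD = Cat0``.

Public API uses minutes and °C; internals integrate in seconds and Kelvin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .design_space import Setpoint

__all__ = [
    "R_GAS",
    "SPECIES",
    "KineticParams",
    "arrhenius",
    "initial_state",
    "simulate",
    "TimeCourse",
]

R_GAS = 8.314  # J mol^-1 K^-1

SPECIES = ("A", "B", "P", "DBU", "Cat", "CatA", "CatAB", "CatAm", "CatD", "I")
_IDX = {s: i for i, s in enumerate(SPECIES)}


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameters of the cycle.

    Ea      activation energy of oxidative addition, J/mol
    logA    log10 of its pre-exponential factor, L mol^-1 s^-1
    k_fast  fixed high rate constant for the non-limiting steps, L mol^-1 s^-1
    k_side  temperature-independent deactivation/impurity constant, L mol^-1 s^-1
    """

    Ea: float
    logA: float
    k_fast: float = 1.0e4
    k_side: float = 1.0e-2

    def __post_init__(self) -> None:
        if self.Ea < 0:
            raise ValueError("Ea must be >= 0")
        if self.k_fast <= 0:
            raise ValueError("k_fast must be > 0")
        if self.k_side < 0:
            raise ValueError("k_side must be >= 0")


def arrhenius(params: KineticParams, temp: float) -> float:
    """Oxidative-addition rate constant at ``temp`` (°C), L mol^-1 s^-1."""
    if temp <= -273.15:
        raise ValueError("temperature below absolute zero")
    T = temp + 273.15
    return 10.0 ** params.logA * np.exp(-params.Ea / (R_GAS * T))


def initial_state(setpoint: Setpoint) -> pd.Series:
    """Initial concentrations (mol/L) in the freshly formed reaction slug."""
    c = setpoint.conc
    y0 = np.zeros(len(SPECIES))
    y0[_IDX["A"]] = c
    y0[_IDX["B"]] = c * setpoint.amine_equiv
    y0[_IDX["DBU"]] = c * setpoint.dbu_equiv
    y0[_IDX["Cat"]] = c * setpoint.cat_loading / 100.0
    return pd.Series(y0, index=SPECIES)


def _rhs(t: float, y: np.ndarray, k1: float, kf: float, ks: float) -> np.ndarray:
    A, B, P, DBU, Cat, CatA, CatAB, CatAm, CatD, I = y
    r1 = k1 * Cat * A
    r2 = kf * CatA * B
    r3 = kf * CatAB * DBU
    r4 = kf * 1.0 * CatAm  # unimolecular via 1 M reference concentration
    r5 = ks * Cat * A
    return np.array([
        -r1 - r5,             # A
        -r2,                  # B
        r4,                   # P
        -r3,                  # DBU
        -r1 + r4 - r5,        # Cat
        r1 - r2,              # CatA
        r2 - r3,              # CatAB
        r3 - r4,              # CatAm
        r5,                   # CatD
        r5,                   # I
    ])


def _jac(t: float, y: np.ndarray, k1: float, kf: float, ks: float) -> np.ndarray:
    A, B, P, DBU, Cat, CatA, CatAB, CatAm, CatD, I = y
    J = np.zeros((10, 10))
    iA, iB, iDBU, iCat, iCatA, iCatAB, iCatAm = 0, 1, 3, 4, 5, 6, 7
    d_r1_A, d_r1_Cat = k1 * Cat, k1 * A
    d_r5_A, d_r5_Cat = ks * Cat, ks * A
    d_r2_CatA, d_r2_B = kf * B, kf * CatA
    d_r3_CatAB, d_r3_DBU = kf * DBU, kf * CatAB
    d_r4_CatAm = kf * 1.0
    # dA/dt = -r1 - r5
    J[0, iA] = -d_r1_A - d_r5_A
    J[0, iCat] = -d_r1_Cat - d_r5_Cat
    # dB/dt = -r2
    J[1, iCatA] = -d_r2_CatA
    J[1, iB] = -d_r2_B
    # dP/dt = r4
    J[2, iCatAm] = d_r4_CatAm
    # dDBU/dt = -r3
    J[3, iCatAB] = -d_r3_CatAB
    J[3, iDBU] = -d_r3_DBU
    # dCat/dt = -r1 + r4 - r5
    J[4, iA] = -d_r1_A - d_r5_A
    J[4, iCat] = -d_r1_Cat - d_r5_Cat
    J[4, iCatAm] = d_r4_CatAm
    # dCatA/dt = r1 - r2
    J[5, iA] = d_r1_A
    J[5, iCat] = d_r1_Cat
    J[5, iCatA] = -d_r2_CatA
    J[5, iB] = -d_r2_B
    # dCatAB/dt = r2 - r3
    J[6, iCatA] = d_r2_CatA
    J[6, iB] = d_r2_B
    J[6, iCatAB] = -d_r3_CatAB
    J[6, iDBU] = -d_r3_DBU
    # dCatAm/dt = r3 - r4
    J[7, iCatAB] = d_r3_CatAB
    J[7, iDBU] = d_r3_DBU
    J[7, iCatAm] = -d_r4_CatAm
    # dCatD/dt = dI/dt = r5
    J[8, iA] = d_r5_A
    J[8, iCat] = d_r5_Cat
    J[9, iA] = d_r5_A
    J[9, iCat] = d_r5_Cat
    return J


@dataclass(frozen=True)
class TimeCourse:
    """Simulated trajectory: ``times`` in minutes, ``states`` one row per
    time with one column per species (mol/L)."""

    times: np.ndarray
    states: pd.DataFrame
    setpoint: Setpoint
    params: KineticParams

    def yield_at(self, t: float) -> float:
        """Fractional yield P(t)/A0, linearly interpolated between stored times."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"t={t} min outside simulated range "
                             f"[{self.times[0]}, {self.times[-1]}]")
        P = float(np.interp(t, self.times, self.states["P"].to_numpy()))
        return P / self.setpoint.conc

    def concentrations_at(self, t: float) -> pd.Series:
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"t={t} min outside simulated range")
        vals = {s: float(np.interp(t, self.times, self.states[s].to_numpy()))
                for s in SPECIES}
        return pd.Series(vals)

    def to_frame(self) -> pd.DataFrame:
        out = self.states.copy()
        out.insert(0, "time_min", self.times)
        return out

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


class IntegrationError(RuntimeError):
    def __init__(self, message: str, setpoint: Setpoint, params: KineticParams):
        super().__init__(message)
        self.setpoint = setpoint
        self.params = params


def simulate(setpoint: Setpoint, params: KineticParams, times,
             rtol: float = 1e-10, atol: float = 1e-14) -> TimeCourse:
    """Integrate the cycle from the slug's initial composition.

    ``times`` are output times in minutes, strictly increasing from 0.  The
    stiff LSODA integrator is run with an analytic Jacobian; tolerances are
    tight enough that the aryl and Pd balances hold to ~1e-9 relative.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or times[0] != 0.0:
        raise ValueError("times must be a 1-D vector starting at 0")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")

    y0 = initial_state(setpoint).to_numpy()
    if times.size == 1:
        states = pd.DataFrame([y0], columns=SPECIES)
        return TimeCourse(times=times, states=states, setpoint=setpoint, params=params)

    k1 = arrhenius(params, setpoint.temp)
    args = (k1, params.k_fast, params.k_side)
    t_end = times[-1] * 60.0
    sol = None
    for method in ("LSODA", "BDF"):  # BDF picks up the rare LSODA failures
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="lsoda")
            sol = solve_ivp(_rhs, (0.0, t_end), y0, t_eval=times * 60.0,
                            method=method, jac=_jac, args=args,
                            rtol=rtol, atol=atol)
        if sol.success:
            break
    if not sol.success:
        raise IntegrationError(f"kinetic integration failed: {sol.message}",
                               setpoint, params)
    states = pd.DataFrame(sol.y.T, columns=SPECIES)
    return TimeCourse(times=times, states=states, setpoint=setpoint, params=params)
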