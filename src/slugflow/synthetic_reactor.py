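"""In-silico slug-flow reactor platform.

Emulates the physical platform end to end: five HPLC pumps (four reagent
stocks plus solvent) mix a 300 µL reaction slug bracketed by 45 µL gas slugs;
the slug is pushed through the heated coil for the requested residence time,
then through the analytics path at a constant flow rate where an FTIR-like
flow cell records a spectrum every 5 s and a UHPLC-like measurement reports
species concentrations.

Everything downstream of a :class:`~slugflow.design_space.Setpoint` is
deterministic given a seed:

* :func:`compute_pump_rates` solves the linear mixing balance (rates sum to
  the constant slug-makeup rate; residence time is decoupled from slug
  formation by construction);
* :func:`run_experiment` integrates the kinetic model to the residence time,
  grafts on two low-level impurity channels (protodehalogenation to
  nitrobenzene; a DBU-derived unknown), applies multiplicative Gaussian
  measurement noise and returns an :class:`ExperimentRecord`;
* :func:`generate_spectra` renders timestamped Beer–Lambert mixture spectra
  with baseline drift and white noise for the chemometrics stage.

The impurity channels are phenomenological: nitrobenzene is promoted by
temperature and amine loading and disfavoured by catalyst loading; the
unknown impurity grows with the square of the DBU charge.  Their magnitudes
stay in the few-mmol/L range over the response-surface box.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import objectives as _objectives
from .design_space import Setpoint
from .kinetics import R_GAS, KineticParams, initial_state, simulate

__all__ = [
    "PumpStock",
    "StockSolutions",
    "NoiseSpec",
    "ImpurityChannels",
    "ExperimentRecord",
    "SpectrumLibrary",
    "SpectrumBatch",
    "default_stocks",
    "compute_pump_rates",
    "run_experiment",
    "generate_spectra",
    "make_spectrum_library",
    "material_usage",
    "records_to_frame",
    "records_from_frame",
]

MEASURED_SPECIES = ("1", "2", "3", "nitrobenzene", "unknown")
#: kinetic species backing each quantified analyte
_KINETIC_OF = {"1": "A", "2": "B", "3": "P"}


@dataclass(frozen=True)
class PumpStock:
    """One pump line: the stock solution it delivers and its flow envelope."""

    name: str
    species: dict[str, float]          # mol/L per kinetic species, {} = pure solvent
    price_per_l: float                 # currency units per litre
    flow_min: float = 0.0              # mL/min
    flow_max: float = 2.5              # mL/min

    def __post_init__(self) -> None:
        if self.price_per_l < 0:
            raise ValueError(f"pump {self.name!r}: price must be >= 0")
        if not 0 <= self.flow_min < self.flow_max:
            raise ValueError(f"pump {self.name!r}: bad flow limits")


@dataclass(frozen=True)
class StockSolutions:
    """Plumbing configuration: stocks, slug geometry and analytics path."""

    pumps: dict[str, PumpStock]
    slug_volume_ul: float = 300.0
    gas_slug_volume_ul: float = 45.0
    reactor_volume_ul: float = 2000.0
    slug_makeup_rate: float = 2.0       # total mL/min during slug formation
    analytics_flow: float = 0.3         # mL/min pushing the slug past the PAT cells
    downstream_volume_ul: float = 1000.0  # valve-to-FTIR dead volume

    def __post_init__(self) -> None:
        if self.slug_volume_ul <= 0:
            raise ValueError("slug volume must be > 0")
        reagent = [p for p in self.pumps.values() if p.species]
        solvent = [p for p in self.pumps.values() if not p.species]
        if len(reagent) != 4 or len(solvent) != 1:
            raise ValueError("expected 4 reagent pumps and 1 solvent pump")

    @property
    def solvent_pump(self) -> str:
        return next(n for n, p in self.pumps.items() if not p.species)

    @property
    def slug_detect_time(self) -> float:
        """Travel time (s) from the analytics valve to the FTIR flow cell."""
        return (self.downstream_volume_ul * 1e-3) / self.analytics_flow * 60.0

    @property
    def slug_window_s(self) -> float:
        """Time (s) the reaction slug spends passing the FTIR cell."""
        return (self.slug_volume_ul * 1e-3) / self.analytics_flow * 60.0


def default_stocks() -> StockSolutions:
    """Default stock set: concentrations chosen so every point of the broad
    six-variable design box is reachable within the constant makeup rate."""
    return StockSolutions(pumps={
        "aryl_bromide": PumpStock("aryl_bromide", {"A": 2.0}, price_per_l=120.0),
        "amine": PumpStock("amine", {"B": 4.0}, price_per_l=80.0),
        "dbu": PumpStock("dbu", {"DBU": 4.0}, price_per_l=40.0),
        "catalyst": PumpStock("catalyst", {"Cat": 0.2}, price_per_l=600.0),
        "solvent": PumpStock("solvent", {}, price_per_l=5.0),
    })


class InfeasibleSetpointError(ValueError):
    def __init__(self, message: str, pump: str | None = None):
        super().__init__(message)
        self.pump = pump


def compute_pump_rates(setpoint: Setpoint, stocks: StockSolutions) -> dict[str, float]:
    """Per-pump flow rates (mL/min) that realise the setpoint's slug
    composition at the constant total makeup rate.

    Each reagent pump runs at ``total * target_conc / stock_conc`` for the
    species it carries; the solvent pump absorbs the balance.
    """
    targets = initial_state(setpoint)
    total = stocks.slug_makeup_rate
    rates: dict[str, float] = {}
    used = 0.0
    for name, pump in stocks.pumps.items():
        if not pump.species:
            continue
        frac = 0.0
        for sp, c_stock in pump.species.items():
            if c_stock <= 0:
                raise InfeasibleSetpointError(f"pump {name!r}: stock concentration must be > 0", name)
            frac += targets[sp] / c_stock
        rate = frac * total
        if rate < -1e-12:
            raise InfeasibleSetpointError(f"pump {name!r}: negative flow rate {rate:.4g}", name)
        if rate > pump.flow_max + 1e-12:
            raise InfeasibleSetpointError(
                f"pump {name!r}: required rate {rate:.4g} mL/min exceeds limit {pump.flow_max}", name)
        if 0 < rate < pump.flow_min:
            raise InfeasibleSetpointError(
                f"pump {name!r}: required rate {rate:.4g} mL/min below minimum {pump.flow_min}", name)
        rates[name] = rate
        used += rate
    solvent = stocks.solvent_pump
    balance = total - used
    if balance < -1e-12:
        raise InfeasibleSetpointError(
            f"pump {solvent!r}: reagent rates exceed total makeup rate "
            f"({used:.4g} > {total:.4g} mL/min)", solvent)
    rates[solvent] = max(balance, 0.0)
    return rates


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian measurement noise, independent per species."""

    rel_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.rel_sd < 0:
            raise ValueError("relative noise SD must be >= 0")


@dataclass(frozen=True)
class ImpurityChannels:
    """Phenomenological low-level impurity model grafted onto the kinetics.

    nitrobenzene (protodehalogenation of 1):
        c = nb_scale * exp(-nb_ea/R * (1/T - 1/T_ref)) * (B0/b_ref)
            * (t_res/t_ref) * (cat_ref/cat_loading)
    unknown impurity:  c = unk_scale * DBU0^2
    """

    nb_scale: float = 4.0e-3       # mol/L at the reference corner
    nb_ea: float = 6.0e4           # J/mol apparent activation energy
    nb_t_ref: float = 140.0        # °C
    nb_b_ref: float = 0.4224       # mol/L amine at the reference corner
    nb_tres_ref: float = 6.5       # min
    nb_cat_ref: float = 4.3        # mol%
    unk_scale: float = 2.5e-2      # L/mol

    def nitrobenzene(self, setpoint: Setpoint) -> float:
        T = setpoint.temp + 273.15
        T_ref = self.nb_t_ref + 273.15
        b0 = setpoint.conc * setpoint.amine_equiv
        return (self.nb_scale
                * np.exp(-self.nb_ea / R_GAS * (1.0 / T - 1.0 / T_ref))
                * (b0 / self.nb_b_ref)
                * (setpoint.t_res / self.nb_tres_ref)
                * (self.nb_cat_ref / setpoint.cat_loading))

    def unknown(self, setpoint: Setpoint) -> float:
        dbu0 = setpoint.conc * setpoint.dbu_equiv
        return self.unk_scale * dbu0 ** 2


@dataclass(frozen=True)
class ExperimentRecord:
    """One completed experiment: setpoint, UHPLC-like measurements,
    objectives and provenance."""

    id: str
    setpoint: Setpoint
    measured: dict[str, float]          # mol/L per analyte in MEASURED_SPECIES
    yield_frac: float
    objectives: _objectives.ObjectiveVector
    seed: int
    slug_detect_time: float             # s
    is_checkpoint: bool = False

    def __post_init__(self) -> None:
        missing = set(MEASURED_SPECIES) - set(self.measured)
        if missing:
            raise ValueError(f"record {self.id}: missing analytes {sorted(missing)}")
        if any(v < 0 for v in self.measured.values()):
            raise ValueError(f"record {self.id}: negative measured concentration")


def run_experiment(setpoint: Setpoint, stocks: StockSolutions,
                   true_params: KineticParams, noise: NoiseSpec, seed: int,
                   record_id: str | None = None,
                   impurities: ImpurityChannels | None = None,
                   product_mw: float = _objectives.PRODUCT_MW,
                   is_checkpoint: bool = False) -> ExperimentRecord:
    """Run one in-silico experiment and return its measured record.

    Pump feasibility is checked first (raising
    :class:`InfeasibleSetpointError` if the slug cannot be made up), the
    kinetics are integrated to the residence time, impurity channels are
    added, and every analyte is perturbed by multiplicative Gaussian noise
    then clipped at zero.  Identical seeds give identical records.
    """
    impurities = impurities or ImpurityChannels()
    compute_pump_rates(setpoint, stocks)  # raises if infeasible

    course = simulate(setpoint, true_params, np.array([0.0, setpoint.t_res]),
                      rtol=1e-10, atol=1e-14)
    final = course.states.iloc[-1]
    c_nb = impurities.nitrobenzene(setpoint)
    c_unk = impurities.unknown(setpoint)
    # both impurity channels drain product-destined material: protodehalogenated
    # aryl never couples, and excess base degrades formed product, so the
    # measured product carries the summed deficit while A + 3 + nitrobenzene
    # stays consistent with the cycle's conversion
    true_conc = {
        "1": final["A"],
        "2": final["B"],
        "3": max(final["P"] - c_nb - c_unk, 0.0),
        "nitrobenzene": min(c_nb, final["P"]),
        "unknown": c_unk,
    }
    rng = np.random.default_rng(seed)
    measured = {}
    for sp in MEASURED_SPECIES:
        v = true_conc[sp] * (1.0 + noise.rel_sd * rng.standard_normal())
        measured[sp] = max(v, 0.0)

    rid = record_id if record_id is not None else f"exp-{seed}"
    rec = ExperimentRecord(
        id=rid, setpoint=setpoint, measured=measured,
        yield_frac=measured["3"] / setpoint.conc,
        objectives=_objectives.ObjectiveVector(0.0, 0.0, 0.0),
        seed=int(seed), slug_detect_time=stocks.slug_detect_time,
        is_checkpoint=is_checkpoint,
    )
    obj = _objectives.compute_objectives(rec, stocks, product_mw)
    return replace(rec, objectives=obj)


# ---------------------------------------------------------------------------
# FTIR-like spectra

@dataclass(frozen=True)
class SpectrumLibrary:
    """Pure-component mid-IR signatures on a common wavenumber grid."""

    wavenumbers: np.ndarray             # cm^-1
    pure: dict[str, np.ndarray]         # analyte -> absorbance per mol/L

    def __post_init__(self) -> None:
        for name, spec in self.pure.items():
            if spec.shape != self.wavenumbers.shape:
                raise ValueError(f"pure spectrum {name!r} not on the library grid")


def make_spectrum_library(seed: int = 1234, lo: float = 650.0, hi: float = 1800.0,
                          step: float = 2.0,
                          analytes: tuple[str, ...] = ("1", "2", "3")) -> SpectrumLibrary:
    """Synthetic pure-component spectra: 3–5 Gaussian bands per analyte on a
    650–1800 cm^-1 grid, fixed by the seed."""
    rng = np.random.default_rng(seed)
    wn = np.arange(lo, hi + step / 2, step)
    pure = {}
    for name in analytes:
        n_peaks = int(rng.integers(3, 6))
        spec = np.zeros_like(wn)
        for _ in range(n_peaks):
            center = rng.uniform(lo + 50, hi - 50)
            width = rng.uniform(8.0, 40.0)
            height = rng.uniform(0.3, 1.5)
            spec += height * np.exp(-0.5 * ((wn - center) / width) ** 2)
        pure[name] = spec
    return SpectrumLibrary(wavenumbers=wn, pure=pure)


@dataclass(frozen=True)
class SpectrumBatch:
    """Timestamped spectra recorded while one experiment's slug passes the
    flow cell (plus solvent baseline before and after)."""

    wavenumbers: np.ndarray
    timestamps: np.ndarray              # s
    absorbances: np.ndarray             # (n_times, n_wavenumbers)
    experiment_id: str

    def to_frame(self) -> pd.DataFrame:
        """FTIR-export layout: first column wavenumber, one column per timestamp."""
        out = pd.DataFrame({"wavenumber": self.wavenumbers})
        for t, row in zip(self.timestamps, self.absorbances):
            out[f"{t:.1f}"] = row
        return out

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_spectra(record: ExperimentRecord, library: SpectrumLibrary,
                     seed: int, stocks: StockSolutions | None = None,
                     cadence_s: float = 5.0, total_time_s: float | None = None,
                     baseline_amp: float = 5e-3, noise_sd: float = 2e-3) -> SpectrumBatch:
    """Render the FTIR record of one experiment.

    While the slug is in the cell (a window starting at the record's
    ``slug_detect_time`` and lasting ``slug_volume / analytics_flow``), each
    spectrum is the Beer–Lambert mixture of the pure spectra of analytes 1, 2
    and 3 weighted by the record's concentrations, plus a slowly varying
    baseline and white noise.  Outside the window only the baseline is seen.
    """
    stocks = stocks or default_stocks()
    for analyte in ("1", "2", "3"):
        if analyte not in library.pure:
            raise ValueError(f"library lacks a pure spectrum for analyte {analyte!r}")
    window_start = record.slug_detect_time
    window_len = stocks.slug_window_s
    if total_time_s is None:
        total_time_s = window_start + window_len + 40.0
    times = np.arange(0.0, total_time_s + cadence_s / 2, cadence_s)
    rng = np.random.default_rng(seed)
    wn = library.wavenumbers
    mixture = sum(record.measured[a] * library.pure[a] for a in ("1", "2", "3"))
    phase = rng.uniform(0, 2 * np.pi)
    spectra = np.empty((times.size, wn.size))
    for i, t in enumerate(times):
        baseline = baseline_amp * np.sin(2 * np.pi * wn / (wn[-1] - wn[0]) + phase + 0.01 * t)
        spec = baseline + noise_sd * rng.standard_normal(wn.size)
        if window_start <= t <= window_start + window_len:
            spec = spec + mixture
        spectra[i] = spec
    return SpectrumBatch(wavenumbers=wn, timestamps=times,
                        absorbances=spectra, experiment_id=record.id)


# ---------------------------------------------------------------------------
# bookkeeping

def material_usage(records: list[ExperimentRecord], stocks: StockSolutions) -> pd.DataFrame:
    """Stock-solution consumption: volume (µL) and moles per pump, summed
    over the given records (one 300 µL slug each)."""
    rows = {name: {"volume_ul": 0.0, "moles": 0.0} for name in stocks.pumps}
    for rec in records:
        rates = compute_pump_rates(rec.setpoint, stocks)
        total = sum(rates.values())
        for name, rate in rates.items():
            vol_ul = stocks.slug_volume_ul * rate / total
            rows[name]["volume_ul"] += vol_ul
            conc = sum(stocks.pumps[name].species.values())
            rows[name]["moles"] += vol_ul * 1e-6 * conc
    return pd.DataFrame.from_dict(rows, orient="index")


def steady_state_equivalent_volume(n_experiments: int, stocks: StockSolutions,
                                   n_residence_times: float = 3.0) -> float:
    """Volume (µL) the same campaign would need in conventional continuous
    flow, flushing ``n_residence_times`` reactor volumes per condition."""
    return n_experiments * n_residence_times * stocks.reactor_volume_ul


# CSV round-trip for experiment logs ----------------------------------------

def records_to_frame(records: list[ExperimentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"id": r.id, **r.setpoint.as_dict()}
        row.update({f"conc_{k}": v for k, v in r.measured.items()})
        row.update({
            "yield_frac": r.yield_frac,
            "yield_pct": r.objectives.yield_pct,
            "sty": r.objectives.sty,
            "cost": r.objectives.cost,
            "seed": r.seed,
            "slug_detect_time": r.slug_detect_time,
            "is_checkpoint": r.is_checkpoint,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[ExperimentRecord]:
    records = []
    for _, row in df.iterrows():
        sp = Setpoint(amine_equiv=row["amine_equiv"], conc=row["conc"],
                      t_res=row["t_res"], temp=row["temp"],
                      dbu_equiv=row["dbu_equiv"], cat_loading=row["cat_loading"],
                      ligand_ratio=row.get("ligand_ratio", 1.5))
        measured = {k: float(row[f"conc_{k}"]) for k in MEASURED_SPECIES}
        records.append(ExperimentRecord(
            id=str(row["id"]), setpoint=sp, measured=measured,
            yield_frac=float(row["yield_frac"]),
            objectives=_objectives.ObjectiveVector(
                float(row["yield_pct"]), float(row["sty"]), float(row["cost"])),
            seed=int(row["seed"]), slug_detect_time=float(row["slug_detect_time"]),
            is_checkpoint=bool(row["is_checkpoint"]),
        ))
    return records
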