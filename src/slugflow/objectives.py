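"""The three campaign objectives: yield, space-time yield and reagent cost.

Yield (%) rewards conversion; space-time yield (kg L^-1 h^-1, referenced to
the 300 µL reaction-slug volume) rewards fast reactions; cost (currency units
per experiment, from the stock solutions consumed in one slug) penalises
reagent excess.  The three pull in different directions, which is what makes
the campaign genuinely multi-objective.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ObjectiveVector",
    "OBJECTIVE_NAMES",
    "OBJECTIVE_SENSES",
    "compute_yield",
    "compute_sty",
    "compute_cost",
    "compute_objectives",
]

OBJECTIVE_NAMES = ("yield_pct", "sty", "cost")
#: optimization sense per objective: +1 maximize, -1 minimize
OBJECTIVE_SENSES = (1, 1, -1)

#: molar mass of diaryl amine product 3, g/mol
PRODUCT_MW = 259.28


@dataclass(frozen=True)
class ObjectiveVector:
    yield_pct: float    # %
    sty: float          # kg L^-1 h^-1
    cost: float         # currency units per experiment

    def __post_init__(self) -> None:
        if self.sty < 0 or self.cost < 0:
            raise ValueError("STY and cost must be >= 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.yield_pct, self.sty, self.cost)


def compute_yield(record) -> float:
    """Yield in %, 100 * [3]_measured / A0 with A0 the charged aryl bromide."""
    a0 = record.setpoint.conc
    if a0 <= 0:
        raise ValueError("initial aryl bromide concentration must be > 0")
    return 100.0 * record.measured["3"] / a0

def compute_sty(record, product_mw: float = PRODUCT_MW) -> float:
    """Space-time yield in kg L^-1 h^-1 from the measured product
    concentration and the residence time."""
    t_res = record.setpoint.t_res
    if t_res <= 0:
        raise ValueError("residence time must be > 0")
    return record.measured["3"] * product_mw * (60.0 / t_res) / 1000.0

def compute_cost(setpoint_or_record, stocks) -> float:
    """Cost of the stock solutions consumed by one reaction slug.

    Each pump contributes its volume fraction of the slug at its configured
    price per litre; the carrier solvent pushing the slug is not counted.
    """
    from .synthetic_reactor import compute_pump_rates  # avoid import cycle

    setpoint = getattr(setpoint_or_record, "setpoint", setpoint_or_record)
    rates = compute_pump_rates(setpoint, stocks)
    total = sum(rates.values())
    slug_l = stocks.slug_volume_ul * 1e-6
    cost = 0.0
    for pump_name, rate in rates.items():
        pump = stocks.pumps[pump_name]
        if pump.price_per_l is None or pump.price_per_l < 0:
            raise ValueError(f"pump {pump_name!r} has no valid price")
        cost += (rate / total) * slug_l * pump.price_per_l
    return cost


def compute_objectives(record, stocks, product_mw: float = PRODUCT_MW) -> ObjectiveVector:
    """All three objectives from a measured experiment record."""
    return ObjectiveVector(
        yield_pct=compute_yield(record),
        sty=compute_sty(record, product_mw),
        cost=compute_cost(record.setpoint, stocks),
    )
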