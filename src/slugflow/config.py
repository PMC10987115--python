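"""Campaign configuration: one structured file drives every stage.

A single :class:`CampaignConfig` bundles the design spaces, stock solutions
and prices, the generating ("true") kinetic parameters, the measurement
noise, budgets and seeds, so the self-optimization, DoE, kinetic and
chemometric stages all run against the same reactor instance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .design_space import (DesignSpace, Setpoint, default_doe_space,
                           default_selfopt_space, space_from_config,
                           space_to_config)
from .kinetics import KineticParams
from .synthetic_reactor import (ImpurityChannels, NoiseSpec, PumpStock,
                                StockSolutions, default_stocks)

__all__ = ["CampaignConfig", "default_config", "load_config", "save_config"]


#: generating parameters of the in-silico reactor; chosen so the narrowed
#: response-surface box yields roughly 70–93% at 6.5 min with a few percent
#: lost to the deactivation/impurity channel
DEFAULT_TRUE_PARAMS = KineticParams(Ea=8.0e4, logA=9.8, k_fast=1.0e4, k_side=6.0e-3)


def default_checkpoint() -> Setpoint:
    """Fixed reproducibility check-point re-run periodically during
    self-optimization."""
    return Setpoint(amine_equiv=1.2, conc=0.33, t_res=6.5, temp=135.0,
                    dbu_equiv=1.3, cat_loading=5.0)


@dataclass
class CampaignConfig:
    selfopt_space: DesignSpace
    doe_space: DesignSpace
    stocks: StockSolutions
    true_params: KineticParams
    noise: NoiseSpec
    impurities: ImpurityChannels
    checkpoint: Setpoint
    budget: tuple[int, int] = (12, 48)
    checkpoint_period: int = 10
    doe_center_points: int = 6
    pool_size: int = 2000
    gp_restarts: int = 2
    product_mw: float = 259.28
    seed: int = 0


def default_config(seed: int = 0) -> CampaignConfig:
    return CampaignConfig(
        selfopt_space=default_selfopt_space(),
        doe_space=default_doe_space(),
        stocks=default_stocks(),
        true_params=DEFAULT_TRUE_PARAMS,
        noise=NoiseSpec(),
        impurities=ImpurityChannels(),
        checkpoint=default_checkpoint(),
        seed=seed,
    )


def _config_to_dict(cfg: CampaignConfig) -> dict:
    return {
        "selfopt_space": space_to_config(cfg.selfopt_space),
        "doe_space": space_to_config(cfg.doe_space),
        "stocks": {
            "pumps": {n: {"species": dict(p.species), "price_per_l": p.price_per_l,
                          "flow_min": p.flow_min, "flow_max": p.flow_max}
                      for n, p in cfg.stocks.pumps.items()},
            "slug_volume_ul": cfg.stocks.slug_volume_ul,
            "gas_slug_volume_ul": cfg.stocks.gas_slug_volume_ul,
            "reactor_volume_ul": cfg.stocks.reactor_volume_ul,
            "slug_makeup_rate": cfg.stocks.slug_makeup_rate,
            "analytics_flow": cfg.stocks.analytics_flow,
            "downstream_volume_ul": cfg.stocks.downstream_volume_ul,
        },
        "true_params": asdict(cfg.true_params),
        "noise": asdict(cfg.noise),
        "impurities": asdict(cfg.impurities),
        "checkpoint": cfg.checkpoint.as_dict(),
        "budget": list(cfg.budget),
        "checkpoint_period": cfg.checkpoint_period,
        "doe_center_points": cfg.doe_center_points,
        "pool_size": cfg.pool_size,
        "gp_restarts": cfg.gp_restarts,
        "product_mw": cfg.product_mw,
        "seed": cfg.seed,
    }


def save_config(cfg: CampaignConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


class ConfigError(ValueError):
    pass


def load_config(path: str) -> CampaignConfig:
    """Load a campaign configuration, reporting the offending field on error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = default_config()
    try:
        if "selfopt_space" in raw:
            base.selfopt_space = space_from_config(raw["selfopt_space"])
        if "doe_space" in raw:
            base.doe_space = space_from_config(raw["doe_space"])
        if "stocks" in raw:
            s = raw["stocks"]
            pumps = {n: PumpStock(n, dict(p.get("species") or {}),
                                  float(p["price_per_l"]),
                                  float(p.get("flow_min", 0.0)),
                                  float(p.get("flow_max", 2.5)))
                     for n, p in s["pumps"].items()}
            base.stocks = StockSolutions(
                pumps=pumps,
                slug_volume_ul=float(s.get("slug_volume_ul", 300.0)),
                gas_slug_volume_ul=float(s.get("gas_slug_volume_ul", 45.0)),
                reactor_volume_ul=float(s.get("reactor_volume_ul", 2000.0)),
                slug_makeup_rate=float(s.get("slug_makeup_rate", 2.0)),
                analytics_flow=float(s.get("analytics_flow", 0.3)),
                downstream_volume_ul=float(s.get("downstream_volume_ul", 1000.0)),
            )
        if "true_params" in raw:
            base.true_params = KineticParams(**raw["true_params"])
        if "noise" in raw:
            base.noise = NoiseSpec(**raw["noise"])
        if "impurities" in raw:
            base.impurities = ImpurityChannels(**raw["impurities"])
        if "checkpoint" in raw:
            base.checkpoint = Setpoint(**raw["checkpoint"])
        for key in ("checkpoint_period", "doe_center_points", "pool_size",
                    "gp_restarts", "product_mw", "seed"):
            if key in raw:
                setattr(base, key, type(getattr(base, key))(raw[key]))
        if "budget" in raw:
            b = raw["budget"]
            base.budget = (int(b[0]), int(b[1]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed config near field {exc!s}") from exc
    return base
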