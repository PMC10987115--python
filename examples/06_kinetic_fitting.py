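"""Kinetic parameter estimation from the 6 x 6 time-course campaign.

Fits the activation energy, pre-exponential factor and the side-reaction
constant to noisy multi-condition data, then validates the model on an
independent DoE log.
"""

import numpy as np

from slugflow import default_config, face_centered_design, run_experiment
from slugflow.kinetic_fit import (default_kinetic_conditions, fit_params,
                                  make_kinetic_campaign, validate)

cfg = default_config(seed=2)
tp = cfg.true_params

campaign = make_kinetic_campaign(default_kinetic_conditions())
rng = np.random.default_rng([2, 12])
records = [run_experiment(sp, cfg.stocks, tp, cfg.noise,
                          seed=int(rng.integers(2**31 - 1)), record_id=f"kin-{i:02d}")
           for i, sp in enumerate(campaign)]
print(f"kinetic campaign: {len(records)} experiments "
      "(6 conditions x 6 residence times, 0.5-12 min)")

fit = fit_params(records, k_fast=tp.k_fast, n_starts=4, seed=2)
print(f"fitted Ea   = {fit.params.Ea / 1000:.1f} kJ/mol "
      f"(generating value {tp.Ea / 1000:.1f})")
print(f"fitted logA = {fit.params.logA:.2f} (generating value {tp.logA:.2f})")
print(f"fitted k_side = {fit.params.k_side:.4f} L/(mol s) "
      f"(generating value {tp.k_side:.4f})")

rng2 = np.random.default_rng([2, 11])
doe = [run_experiment(sp, cfg.stocks, tp, cfg.noise,
                      seed=int(rng2.integers(2**31 - 1)), record_id=f"doe-{i:02d}")
       for i, sp in enumerate(face_centered_design(cfg.doe_space, 6))]
print(f"\nvalidation RMSE on independent DoE log: {validate(fit, doe):.1f} mM")
print("A few mM of error against 2% measurement noise on ~250 mM product "
      "means the mechanistic model transfers well inside the studied region.")
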