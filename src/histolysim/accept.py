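"""Desk-scale reproduction battery for the headline simulation results.

Runs the study conditions at a density-preserving reduced field (the field
side is scaled and particle counts scaled with its square, so per-particle
statistics are preserved) and recomputes:

* the percent decrease of median muscle-unit speed between 30 and 50 hAPF
  under spatial confinement at the regression-calibrated wall thickness;
* the Brunner-Munzel comparison of per-muscle-unit nearby counts before
  versus after confinement;
* the median hemocyte speed of the baseline between 15 and 24 hAPF.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .experiments import (median_speed_over, pooled_nearby_counts,
                          speed_retention_percent)
from .mechanics import Kind, hapf_to_step
from .scenarios import (CalibrationResult, FatMode, Heterogeneity,
                        ScenarioConfig, Stabilization, Trajectory,
                        calibrate_stabilization, run_trials)
from .stats import brunner_munzel

__all__ = ["confinement_battery", "baseline_battery", "compute_targets"]

#: default reduced-field scale (300-um field, quarter counts)
DEFAULT_SCALE = 0.5
#: wall-thickness sweep for the confinement calibration [m]
CONFINE_SWEEP = (45.0e-6, 90.0e-6, 135.0e-6)


def confinement_battery(seed: int, scale: float = DEFAULT_SCALE,
                        sweep=CONFINE_SWEEP, trials_per_magnitude: int = 1,
                        n_trials: int = 6
                        ) -> tuple[CalibrationResult, list[Trajectory]]:
    """Calibrate the confinement wall thickness by linear regression and
    rerun the scenario at the calibrated magnitude."""
    cfg = ScenarioConfig(fat_mode=FatMode.FLOATING,
                         heterogeneity=Heterogeneity.HOMOG,
                         scale=scale, seed=seed,
                         steps=hapf_to_step(50.0))
    cal = calibrate_stabilization(Stabilization.CONFINE, sweep,
                                  trials_per_magnitude, cfg, base_seed=seed)
    final = replace(cfg, stabilization=Stabilization.CONFINE,
                    magnitude=cal.magnitude, n_trials=n_trials)
    return cal, run_trials(final)


def baseline_battery(seed: int, scale: float = DEFAULT_SCALE,
                     n_trials: int = 3) -> list[Trajectory]:
    """Floating-fat homogeneous baseline to 24 hAPF."""
    cfg = ScenarioConfig(fat_mode=FatMode.FLOATING,
                         heterogeneity=Heterogeneity.HOMOG,
                         scale=scale, seed=seed, n_trials=n_trials,
                         steps=hapf_to_step(24.0))
    return run_trials(cfg)


def compute_targets(seed: int, scale: float = DEFAULT_SCALE) -> dict:
    """Recompute the reported quantities from scratch at the given seed.

    Returns ``{target: {"value": float, "n": int}}`` with

    * ``t4`` — achieved stabilization-calibration percentage (median
      muscle-unit speed at 50 hAPF relative to 30 hAPF) at the calibrated
      confinement magnitude; the calibration aims at 80;
    * ``t6`` — two-sided Brunner-Munzel p-value for per-muscle-unit nearby
      counts at 30 versus 50 hAPF, pooled over the confinement trials;
    * ``t7`` — median hemocyte speed [um/min] of the baseline over
      15–24 hAPF.
    """
    cal, conf_trajs = confinement_battery(seed, scale)
    t4 = speed_retention_percent(conf_trajs)

    nb30 = pooled_nearby_counts(conf_trajs, 30.0)
    nb50 = pooled_nearby_counts(conf_trajs, 50.0)
    bm = brunner_munzel(nb30, nb50)

    base_trajs = baseline_battery(seed, scale)
    t7 = median_speed_over(base_trajs, 15.0, 24.0, Kind.HEMOCYTE)

    n_muscle = int(np.sum(conf_trajs[0].kind == int(Kind.MUSCLE)))
    n_hem = int(np.sum(base_trajs[0].kind == int(Kind.HEMOCYTE)))
    return {
        "t4": {"value": float(t4), "n": n_muscle * len(conf_trajs)},
        "t6": {"value": float(bm.p_value), "n": int(nb30.size + nb50.size)},
        "t7": {"value": float(t7), "n": n_hem * len(base_trajs)},
    }
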