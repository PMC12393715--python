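"""Trajectory-level analyses: the quantities the simulation studies report.

These bridge :class:`~histolysim.scenarios.Trajectory` objects and the
point/track metrics: pooled muscle-unit and hemocyte speeds, horizontal
variance, nearby counts and ring radii at chosen times, engulfment
bookkeeping, and the before/after contrasts used to compare stabilization
operations.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import metrics
from .mechanics import Kind, MuscleState
from .scenarios import Trajectory
from .stats import brunner_munzel

__all__ = [
    "speeds_at", "median_speed_at", "speed_retention_percent",
    "percent_speed_decrease", "median_speed_over", "horizontal_variance_at",
    "pooled_nearby_counts", "pooled_ring_radii", "engulfment_shares",
    "max_simultaneous_cargo", "arrangement_contrast",
]


def speeds_at(traj: Trajectory, hapf: float, kind: Kind = Kind.MUSCLE,
              window_min: float = 6.0) -> np.ndarray:
    """Window-displacement speeds [um/min] of one particle kind at the
    sample closest to ``hapf`` (minimum-image displacements)."""
    i1 = traj.index_at(hapf)
    lag = int(round(window_min * 120 / traj.sample_every))
    if i1 < lag:
        raise ValueError("not enough history for the speed window")
    sel = traj.kind == int(kind)
    pos = np.asarray(traj.pos_um[[i1 - lag, i1]][:, sel], float)
    d = pos[1] - pos[0]
    L = traj.field_um
    d -= L * np.round(d / L)
    return np.hypot(d[:, 0], d[:, 1]) / window_min


def median_speed_at(trajs: Sequence[Trajectory], hapf: float,
                    kind: Kind = Kind.MUSCLE) -> float:
    """Median speed pooled over units and trials at one time point."""
    return float(np.median(np.concatenate(
        [speeds_at(t, hapf, kind) for t in trajs])))


def speed_retention_percent(trajs: Sequence[Trajectory],
                            hapf_before: float = 30.0,
                            hapf_after: float = 50.0,
                            kind: Kind = Kind.MUSCLE) -> float:
    """Pooled median speed after the stabilization window as a percentage
    of that before it (100 = unchanged, 80 = slowed to four fifths)."""
    before = median_speed_at(trajs, hapf_before, kind)
    after = median_speed_at(trajs, hapf_after, kind)
    if before == 0:
        return float("nan")
    return 100.0 * after / before


def percent_speed_decrease(trajs: Sequence[Trajectory],
                           hapf_before: float = 30.0,
                           hapf_after: float = 50.0,
                           kind: Kind = Kind.MUSCLE) -> float:
    """Percent decrease of the pooled median speed between two times."""
    return 100.0 - speed_retention_percent(trajs, hapf_before, hapf_after,
                                           kind)


def median_speed_over(trajs: Sequence[Trajectory], hapf_lo: float,
                      hapf_hi: float, kind: Kind = Kind.HEMOCYTE,
                      window_min: float = 6.0) -> float:
    """Median speed pooled over cells, minute-cadence window end times in
    [hapf_lo, hapf_hi], and trials."""
    out = []
    for traj in trajs:
        sel = traj.kind == int(kind)
        h = traj.hapf
        keep = (h >= hapf_lo - window_min / 60.0) & (h <= hapf_hi)
        pos = np.asarray(traj.pos_um[keep][:, sel], float)
        sp = metrics.displacement_speeds(
            pos, dt_min=traj.sample_every / 120.0, window_min=window_min,
            field_um=traj.field_um)
        ends = h[keep][int(round(window_min * 120 / traj.sample_every)):]
        out.append(sp[ends >= hapf_lo].ravel())
    return float(np.median(np.concatenate(out)))


def horizontal_variance_at(traj: Trajectory, hapf: float) -> float:
    return metrics.horizontal_variance(
        traj.positions_at(hapf, Kind.MUSCLE), traj.field_um)


def pooled_nearby_counts(trajs: Sequence[Trajectory], hapf: float,
                         radius: float = 30.0) -> np.ndarray:
    """Per-muscle-unit nearby counts pooled across trials."""
    return np.concatenate([
        metrics.nearby_counts(t.positions_at(hapf, Kind.MUSCLE), radius)
        for t in trajs])


def pooled_ring_radii(trajs: Sequence[Trajectory], hapf: float,
                      life_min: float = 10.0) -> np.ndarray:
    """Ring radii of the muscle-unit arrangements pooled across trials."""
    return np.concatenate([
        metrics.ring_radii(t.positions_at(hapf, Kind.MUSCLE), life_min)
        for t in trajs])


def engulfment_shares(trajs: Sequence[Trajectory],
                      hapf: float = 24.0) -> dict[str, float]:
    """Fraction of eaten muscle units per host hemocyte subtype at one
    time, pooled over trials."""
    from .mechanics import SUBTYPE_LABELS
    counts: dict[str, int] = {}
    total = 0
    for traj in trajs:
        i = traj.index_at(hapf)
        eaten = np.flatnonzero(
            (traj.kind == int(Kind.MUSCLE))
            & (traj.state[i] == int(MuscleState.EATEN)))
        for m in eaten:
            host = traj.host[i][m]
            lab = SUBTYPE_LABELS[traj.subtype[host]]
            counts[lab] = counts.get(lab, 0) + 1
            total += 1
    return {lab: c / total for lab, c in counts.items()} if total else {}


def max_simultaneous_cargo(trajs: Sequence[Trajectory]) -> int:
    """Largest number of muscle units bonded to a single host hemocyte at
    any sampled step of any trial."""
    best = 0
    for traj in trajs:
        for i in range(traj.n_samples):
            hosts = traj.host[i][(traj.state[i] == int(MuscleState.EATEN))
                                 & (traj.kind == int(Kind.MUSCLE))]
            if hosts.size:
                best = max(best, int(np.bincount(hosts).max()))
    return best


def arrangement_contrast(trajs: Sequence[Trajectory],
                         hapf_before: float = 30.0,
                         hapf_after: float = 50.0) -> dict:
    """Before/after contrast of the muscle-unit arrangement.

    Reports the Brunner-Munzel test on pooled nearby counts (with the
    direction of the rank-average change), and the change in pooled median
    ring radius."""
    nb_before = pooled_nearby_counts(trajs, hapf_before)
    nb_after = pooled_nearby_counts(trajs, hapf_after)
    bm = brunner_munzel(nb_before, nb_after)
    rr_before = pooled_ring_radii(trajs, hapf_before)
    rr_after = pooled_ring_radii(trajs, hapf_after)
    return {
        "nearby_bm": bm,
        "nearby_increased": bm.p_hat > 0.5,
        "nearby_median_before": float(np.median(nb_before)),
        "nearby_median_after": float(np.median(nb_after)),
        "ring_median_before": float(np.median(rr_before)),
        "ring_median_after": float(np.median(rr_after)),
        "ring_decreased": float(np.median(rr_after))
        < float(np.median(rr_before)),
    }
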