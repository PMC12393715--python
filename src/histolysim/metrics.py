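"""Arrangement and motion statistics for cell coordinates and tracks.

These operate identically on simulated trajectories and on external
coordinate tables: speeds from 6-minute displacement windows, the
horizontal (x-coordinate) variance of the left and right field halves,
counts of neighbours within 30 um, persistent-homology ring radii, and the
steering consistency of individual tracks.  Lengths are micrometres and
times minutes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._persistence import alpha_h1_pairs

__all__ = [
    "TrackSet", "muscle_speed_series", "horizontal_variance",
    "nearby_counts", "ring_radii", "steering_consistency",
    "displacement_speeds",
]

#: default speed window [min] (displacement per 6 min divided by six)
SPEED_WINDOW_MIN = 6
#: neighbour-count radius [um]
NEARBY_RADIUS_UM = 30.0
#: minimum persistence lifetime [um] for a class to count as a ring
RING_LIFETIME_UM = 10.0


@dataclass
class TrackSet:
    """Per-cell position time series: (T, n, 2) array [um] at uniform
    frame interval ``dt_min`` [min]."""

    positions: np.ndarray
    dt_min: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        if self.positions.ndim == 2:
            self.positions = self.positions[:, None, :]
        if self.dt_min <= 0:
            raise ValueError("dt_min must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


def _wrap_disp(d: np.ndarray, field_um: float | None,
               periodic_y: bool = True) -> np.ndarray:
    if field_um is None:
        return d
    d = d.copy()
    d[..., 0] -= field_um * np.round(d[..., 0] / field_um)
    if periodic_y:
        d[..., 1] -= field_um * np.round(d[..., 1] / field_um)
    return d


def displacement_speeds(positions: np.ndarray, dt_min: float,
                        window_min: float = SPEED_WINDOW_MIN,
                        field_um: float | None = None,
                        periodic_y: bool = True) -> np.ndarray:
    """Window-displacement speeds [um/min] from minute-cadence positions.

    ``positions`` is (T, n, 2); the speed at frame t is the minimum-image
    displacement over the preceding ``window_min`` minutes divided by the
    window, evaluated at every frame with enough history (sliding window at
    the sampling cadence).  Returns (T', n) with T' = T - window frames.
    """
    pos = np.asarray(positions, float)
    if pos.ndim == 2:
        pos = pos[:, None, :]
    lag = int(round(window_min / dt_min))
    if lag < 1 or pos.shape[0] <= lag:
        return np.empty((0, pos.shape[1]))
    d = _wrap_disp(pos[lag:] - pos[:-lag], field_um, periodic_y)
    return np.hypot(d[..., 0], d[..., 1]) / window_min


def muscle_speed_series(positions: np.ndarray, dt_min: float = 1.0,
                        window_min: float = SPEED_WINDOW_MIN,
                        field_um: float | None = None,
                        periodic_y: bool = True) -> np.ndarray:
    """Per-unit speed series [um/min]; see :func:`displacement_speeds`."""
    return displacement_speeds(positions, dt_min, window_min, field_um,
                               periodic_y)


def horizontal_variance(points: np.ndarray, field_um: float) -> float:
    """Mean of the x-coordinate sample variances of the left and right
    field halves [um^2], on raw coordinates (no periodic unwrapping).

    Returns NaN when either half has fewer than two points.
    """
    pts = np.asarray(points, float)
    x = pts[:, 0]
    out = []
    for half in (x[x < field_um / 2], x[x >= field_um / 2]):
        if half.size < 2:
            return float("nan")
        out.append(np.var(half, ddof=1))
    return float(np.mean(out))


def nearby_counts(points: np.ndarray,
                  radius: float = NEARBY_RADIUS_UM) -> np.ndarray:
    """For each point, the number of other points within ``radius``
    (inclusive, plain Euclidean distance, no periodic wrap)."""
    pts = np.asarray(points, float)
    if len(pts) == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, radius, return_length=True)
    return np.asarray(counts, dtype=int) - 1  # drop self


def ring_radii(points: np.ndarray,
               life_min: float = RING_LIFETIME_UM) -> np.ndarray:
    """Ring radii [um]: death radii of degree-1 persistence classes of the
    growing-disk filtration whose lifetime exceeds ``life_min``."""
    pts = np.asarray(points, float)
    if len(pts) < 3:
        raise ValueError("persistence needs at least 3 points")
    pairs = alpha_h1_pairs(pts)
    return np.array([d for b, d in pairs if d - b > life_min])


def steering_consistency(track: np.ndarray, dt_min: float = 1.0) -> float:
    """Mean cosine of the turning angles along one track, in [-1, 1].

    The velocity at frame n is the displacement from frame n-1; each of the
    N-2 interior frames contributes the cosine of the angle between the
    incoming and outgoing velocities.  Frames adjoining a zero displacement
    are skipped and the divisor reduced; NaN if every term is skipped.
    """
    pos = np.asarray(track, float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("track must be an (N, 2) array")
    if pos.shape[0] < 3:
        raise ValueError("steering consistency needs at least 3 frames")
    v = np.diff(pos, axis=0) / dt_min
    norms = np.hypot(v[:, 0], v[:, 1])
    a, b = v[:-1], v[1:]
    na, nb = norms[:-1], norms[1:]
    ok = (na > 0) & (nb > 0)
    if not np.any(ok):
        return float("nan")
    cos = np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok])
    return float(np.mean(np.clip(cos, -1.0, 1.0)))
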