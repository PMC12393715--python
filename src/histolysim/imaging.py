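"""Frame-difference motility index and a synthetic stack renderer.

The motility index mimics the image-calculator workflow applied to
time-lapse microscopy: per-pixel absolute difference of consecutive frames,
spatially averaged (dF), normalized by the mean intensity of the earlier
frame (F0).  The renderer turns simulation states into grayscale stacks
(particles as filled disks, Gaussian blur, optional noise) so the index is
testable end to end without real microscopy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .mechanics import Kind

__all__ = ["ImageStack", "MotilityIndexSeries", "frame_difference_series",
           "render_world", "render_trajectory"]

MAX_RENDER_SIDE = 4096


@dataclass
class ImageStack:
    """T x H x W non-negative intensity stack."""

    frames: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_min: float = 1.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def save(self, path) -> None:
        import tifffile
        tifffile.imwrite(path, self.frames, photometric="minisblack")

    @classmethod
    def load(cls, path, **kw) -> "ImageStack":
        import tifffile
        return cls(tifffile.imread(path), **kw)


@dataclass
class MotilityIndexSeries:
    """Per-interval dF, F0 and dF/F0 (NaN where F0 = 0)."""

    dF: np.ndarray
    F0: np.ndarray
    ratio: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.dF = np.asarray(self.dF, float)
        self.F0 = np.asarray(self.F0, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.ratio = np.where(self.F0 > 0, self.dF / self.F0, np.nan)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"t": np.arange(len(self.dF)), "dF": self.dF,
                             "F0": self.F0, "dF_over_F0": self.ratio})


def frame_difference_series(stack: ImageStack | np.ndarray) -> MotilityIndexSeries:
    """Signal-intensity difference per consecutive frame pair.

    dF(t) is the spatial mean of |frame(t+1) - frame(t)| over all pixels;
    F0(t) the spatial mean of frame t.  No thresholding, masking, or
    background subtraction is applied.
    """
    frames = stack.frames if isinstance(stack, ImageStack) else \
        np.asarray(stack)
    if frames.shape[0] < 2:
        raise ValueError("need at least two frames")
    f = frames.astype(np.float64)
    dF = np.abs(np.diff(f, axis=0)).mean(axis=(1, 2))
    F0 = f[:-1].mean(axis=(1, 2))
    return MotilityIndexSeries(dF, F0)


def _draw_disks(img: np.ndarray, centers_px: np.ndarray,
                radii_px: np.ndarray, value: float) -> None:
    h, w = img.shape
    for (cx, cy), r in zip(centers_px, radii_px):
        if r <= 0:
            continue
        x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
        y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        mask = (xs + 0.5 - cx) ** 2 + (ys + 0.5 - cy) ** 2 <= r * r
        img[y0:y1, x0:x1][mask] = value


def render_world(positions_um, radii_um, field_um: float,
                 pixel_size_um: float = 1.0, blur_sigma_px: float = 1.0,
                 noise_level: float = 0.0, bit_depth: int = 8,
                 rng=None) -> ImageStack:
    """Render a sequence of particle configurations as a grayscale stack.

    ``positions_um`` is (T, n, 2) and ``radii_um`` (n,) or (T, n); selected
    particles are drawn as filled foreground disks, blurred with a Gaussian
    of ``blur_sigma_px``, optionally degraded with additive Gaussian noise
    (``noise_level`` as a fraction of full scale), and quantized.
    """
    pos = np.asarray(positions_um, float)
    if pos.ndim == 2:
        pos = pos[None]
    rad = np.asarray(radii_um, float)
    if rad.ndim == 1:
        rad = np.broadcast_to(rad, (pos.shape[0], rad.shape[0]))
    side = int(round(field_um / pixel_size_um))
    if side > MAX_RENDER_SIDE:
        raise ValueError(f"rendered side {side} px exceeds "
                         f"{MAX_RENDER_SIDE} px; increase pixel_size_um")
    full = float(2 ** bit_depth - 1)
    rng = rng if rng is not None else np.random.default_rng()
    frames = np.empty((pos.shape[0], side, side),
                      dtype=np.uint8 if bit_depth <= 8 else np.uint16)
    for t in range(pos.shape[0]):
        img = np.zeros((side, side), float)
        _draw_disks(img, pos[t] / pixel_size_um, rad[t] / pixel_size_um, full)
        if blur_sigma_px > 0:
            img = ndimage.gaussian_filter(img, blur_sigma_px)
        if noise_level > 0:
            img = img + rng.normal(0.0, noise_level * full, img.shape)
        frames[t] = np.clip(np.round(img), 0, full).astype(frames.dtype)
    return ImageStack(frames, pixel_size_um)


def render_trajectory(traj, kind: Kind = Kind.MUSCLE,
                      hapf_range=None, every: int = 1, **kw) -> ImageStack:
    """Render one particle kind of a simulated trajectory (see
    :func:`render_world` for rendering options)."""
    sel = traj.kind == int(kind)
    idx = np.arange(traj.n_samples)
    if hapf_range is not None:
        h = traj.hapf
        idx = idx[(h >= hapf_range[0]) & (h <= hapf_range[1])]
    idx = idx[::every]
    pos = np.asarray(traj.pos_um[idx][:, sel], float)
    rad = np.asarray(traj.radius_um[idx][:, sel], float)
    stack = render_world(pos, rad, traj.field_um, **kw)
    stack.frame_interval_min = every * traj.sample_every / 120.0
    return stack
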