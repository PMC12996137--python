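"""Slice-based input construction, normalization, and training augmentation.

The network is 2-D: each training sample is a three-channel stack of an
axial slice with its immediate neighbours (edge slices replicate), paired
with the center slice of the lesion mask.  Volumes are z-score normalized
over the nonzero brain region (scans are assumed skull-stripped, as the
phantom generator guarantees by construction).

Augmentations: random rotations within ±15°, horizontal/vertical flips and
a mask-centered crop are applied identically to the channels and the target
(nearest-neighbour for the target, so labels stay binary); a monotone cubic
bezier mapping distorts channel intensities only, emulating contrast
variability across scanners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
from scipy import ndimage

from .phantom import Volume


@dataclass
class SliceSample:
    """A 3×H×W network input (previous/center/next slice) with its target."""

    channels: np.ndarray
    target: Optional[np.ndarray]
    subject_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError("channels must be a 3×H×W array")
        if self.target is not None:
            self.target = np.asarray(self.target)
            if self.target.shape != self.channels.shape[1:]:
                raise ValueError("target shape must equal channel shape")


@dataclass(frozen=True)
class AugmentConfig:
    rotation_max_deg: float = 15.0
    hflip: bool = True
    vflip: bool = True
    bezier_distortion: bool = True
    mask_centered_crop: bool = True
    crop_jitter: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_max_deg < 0:
            raise ValueError("rotation_max_deg must be non-negative")


def zscore_normalize(volume: Volume, region: np.ndarray | None = None) -> Volume:
    """Standardize intensities to zero mean / unit variance over the brain.

    The normalization region defaults to the nonzero voxels (the brain, for
    skull-stripped input); voxels outside the region stay at zero, so the
    background remains identifiable.  Constant-intensity input raises
    ``ValueError``.
    """
    x = np.asarray(volume.intensities, dtype=np.float64)
    if region is None:
        region = x != 0
    vals = x[region]
    if vals.size < 2:
        raise ValueError("normalization region has fewer than 2 voxels")
    mu = vals.mean()
    sd = vals.std()
    if sd == 0:
        raise ValueError("constant-intensity input: zero variance in region")
    out = np.where(region, (x - mu) / sd, 0.0).astype(np.float32)
    return Volume(
        intensities=out,
        spacing=volume.spacing,
        mask=volume.mask,
        lesion_table=volume.lesion_table,
        subject_id=volume.subject_id,
    )


def stack_slices(volume: Volume, slice_index: int) -> SliceSample:
    """Three-channel stack [i−1, i, i+1] with edge replication; the target is
    the mask slice i, omitted when the volume carries no mask."""
    nz = volume.shape[0]
    if not 0 <= slice_index < nz:
        raise IndexError(f"slice_index {slice_index} outside [0, {nz})")
    lo = max(slice_index - 1, 0)
    hi = min(slice_index + 1, nz - 1)
    ch = np.stack(
        [volume.intensities[lo], volume.intensities[slice_index], volume.intensities[hi]]
    )
    tgt = volume.mask[slice_index] if volume.mask is not None else None
    return SliceSample(ch, tgt, subject_id=volume.subject_id, slice_index=slice_index)


def iter_samples(volume: Volume) -> Iterator[SliceSample]:
    """One sample per axial slice: each center slice appears exactly once."""
    for i in range(volume.shape[0]):
        yield stack_slices(volume, i)


def bezier_intensity_map(x: np.ndarray, p1: tuple[float, float], p2: tuple[float, float]) -> np.ndarray:
    """Map values in [0, 1] through a cubic bezier from (0,0) to (1,1) with
    interior control points ``p1``, ``p2``.

    With sorted interior x-coordinates the curve is monotone non-decreasing,
    so the ordering of intensities is preserved.  ``p1 = p2 = (0.5, 0.5)``
    yields the identity mapping.
    """
    t = np.linspace(0.0, 1.0, 257)
    bx = 3 * (1 - t) ** 2 * t * p1[0] + 3 * (1 - t) * t**2 * p2[0] + t**3
    by = 3 * (1 - t) ** 2 * t * p1[1] + 3 * (1 - t) * t**2 * p2[1] + t**3
    return np.interp(x, bx, by)


def _rotate_pair(ch: np.ndarray, tgt: Optional[np.ndarray], angle: float):
    chr_ = np.stack(
        [ndimage.rotate(c, angle, reshape=False, order=1, mode="constant", cval=0.0) for c in ch]
    ).astype(np.float32)
    tr = None
    if tgt is not None:
        tr = ndimage.rotate(
            tgt.astype(np.float32), angle, reshape=False, order=0, mode="constant", cval=0.0
        ).astype(tgt.dtype)
    return chr_, tr


def _crop_shift(ch: np.ndarray, tgt: np.ndarray, jitter: float, rng: np.random.Generator):
    """Translate so the window stays centered near the lesion bounding box,
    jittered by up to ``jitter``×window size; lesion pixels remain in-frame."""
    H, W = tgt.shape
    ys, xs = np.nonzero(tgt)
    cy, cx = (ys.min() + ys.max()) / 2.0, (xs.min() + xs.max()) / 2.0
    jy = rng.uniform(-jitter, jitter) * H
    jx = rng.uniform(-jitter, jitter) * W
    dy = int(round(H / 2.0 - cy + jy))
    dx = int(round(W / 2.0 - cx + jx))
    # clamp so every lesion pixel stays inside the frame after the shift
    dy = int(np.clip(dy, -ys.min(), H - 1 - ys.max()))
    dx = int(np.clip(dx, -xs.min(), W - 1 - xs.max()))

    def shift2d(a: np.ndarray) -> np.ndarray:
        out = np.zeros_like(a)
        src_y = slice(max(0, -dy), min(H, H - dy))
        src_x = slice(max(0, -dx), min(W, W - dx))
        dst_y = slice(max(0, dy), min(H, H + dy))
        dst_x = slice(max(0, dx), min(W, W + dx))
        out[dst_y, dst_x] = a[src_y, src_x]
        return out

    return np.stack([shift2d(c) for c in ch]), shift2d(tgt)


def augment(
    sample: SliceSample,
    cfg: AugmentConfig,
    rng: np.random.Generator | None = None,
) -> SliceSample:
    """Apply the configured augmentations; geometric transforms act
    identically on all channels and the target."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ch = sample.channels.copy()
    tgt = None if sample.target is None else sample.target.copy()

    if cfg.rotation_max_deg > 0:
        angle = float(rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg))
        ch, tgt = _rotate_pair(ch, tgt, angle)
    if cfg.hflip and rng.random() < 0.5:
        ch = ch[:, :, ::-1].copy()
        if tgt is not None:
            tgt = tgt[:, ::-1].copy()
    if cfg.vflip and rng.random() < 0.5:
        ch = ch[:, ::-1, :].copy()
        if tgt is not None:
            tgt = tgt[::-1, :].copy()
    if cfg.mask_centered_crop and tgt is not None and tgt.any():
        ch, tgt = _crop_shift(ch, tgt, cfg.crop_jitter, rng)
    if cfg.bezier_distortion:
        x1, x2 = sorted(rng.uniform(0.0, 1.0, size=2))
        y1, y2 = sorted(rng.uniform(0.0, 1.0, size=2))
        lo, hi = float(ch.min()), float(ch.max())
        if hi > lo:
            norm = (ch - lo) / (hi - lo)
            ch = (bezier_intensity_map(norm, (x1, y1), (x2, y2)) * (hi - lo) + lo).astype(
                np.float32
            )
    return SliceSample(ch, tgt, subject_id=sample.subject_id, slice_index=sample.slice_index)
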