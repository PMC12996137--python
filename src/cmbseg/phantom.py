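"""Synthetic susceptibility-weighted-like brain phantoms.

Real microbleed studies rely on T2*-GRE/SWI scans in which microbleeds appear
as small round hypointense foci, easily confused with veins (elongated dark
tubes) and small calcifications (focal dark spots).  The phantom generator
reproduces exactly that detection problem at desk scale: an ellipsoidal
"brain" of mid-gray intensity containing

* hypointense spheres — the microbleeds, recorded in the ground-truth mask
  and lesion table;
* dark tubular polyline sweeps — vessel-like confounders, *not* in the mask;
* small, fainter dark blobs — calcification-like distractors, *not* in the
  mask;
* a smooth multiplicative bias field and additive Gaussian noise.

Everything is a pure function of :class:`PhantomSpec` (including its seed),
so any downstream stage can be tested deterministically with known ground
truth and without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class PlacementError(RuntimeError):
    """Raised when lesions cannot be placed inside the brain without overlap."""


@dataclass(frozen=True)
class Lesion:
    """One connected hypointense component.

    ``centroid`` is the mean of the component's voxel coordinates in (z, y, x)
    voxel units; ``equiv_diameter_mm`` is the diameter of the sphere (or disk,
    in 2-D mode) with the same physical volume.
    """

    id: int
    centroid: tuple[float, float, float]
    voxels: frozenset[tuple[int, int, int]]
    equiv_diameter_mm: float

    def __post_init__(self) -> None:
        if self.equiv_diameter_mm <= 0:
            raise ValueError("equiv_diameter_mm must be positive")


@dataclass
class Volume:
    """A 3-D intensity array with voxel spacing and optional lesion ground truth.

    Arrays are indexed (z, y, x); axial slices are taken along axis 0.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: Optional[np.ndarray] = None
    lesion_table: Optional[list[Lesion]] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.intensities.shape:
                raise ValueError("mask shape must equal intensity shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom subject.

    ``cmb_diameter_range`` is in mm; typical cerebral microbleeds measure
    roughly 2–10 mm, which is the default range.  ``noise_sigma`` is in the
    same (arbitrary) units as the brain background intensity of 1.0, and
    ``bias_field_amplitude`` is the peak fractional intensity modulation of
    the multiplicative bias field.
    """

    volume_shape: tuple[int, int, int] = (24, 128, 128)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_cmb: int = 3
    cmb_diameter_range: tuple[float, float] = (2.0, 10.0)
    n_vessels: int = 3
    n_calcifications: int = 2
    noise_sigma: float = 0.08
    bias_field_amplitude: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cmb < 0 or self.n_vessels < 0 or self.n_calcifications < 0:
            raise ValueError("object counts must be non-negative")
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        lo, hi = self.cmb_diameter_range
        extent = min(n * v for n, v in zip(self.volume_shape, self.voxel_size))
        if not (0 < lo <= hi < extent):
            raise ValueError("cmb_diameter_range must lie within (0, min brain extent)")


_BRAIN_INTENSITY = 1.0
# Hypointense objects span 30–60 % of the brain background so that microbleed
# and vessel intensities overlap and discrimination has to rely on shape.
_DARK_FRACTION = (0.3, 0.6)
_CALC_FRACTION = (0.7, 0.85)
_CALC_DIAMETER = (1.0, 1.8)


def _brain_ellipsoid(shape: Sequence[int], spacing: Sequence[float]) -> np.ndarray:
    """Boolean ellipsoid with per-axis radii 0.8× the half-extent."""
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    term = np.zeros(tuple(shape), dtype=np.float64)
    for g, n, v in zip(grids, shape, spacing):
        c = (n - 1) / 2.0
        r = 0.8 * (n * v) / 2.0
        term += (((g - c) * v) / r) ** 2
    return term <= 1.0


def _rasterize_sphere(
    center_mm: np.ndarray, diameter_mm: float, shape: Sequence[int], spacing: Sequence[float]
) -> np.ndarray:
    """Voxel coordinates (N×3) whose centers fall inside the sphere."""
    r = diameter_mm / 2.0
    lo = [max(0, int(np.floor((c - r) / v)) - 1) for c, v in zip(center_mm, spacing)]
    hi = [min(n - 1, int(np.ceil((c + r) / v)) + 1) for c, v, n in zip(center_mm, spacing, shape)]
    axes = [np.arange(a, b + 1) for a, b in zip(lo, hi)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
    d2 = (((coords * np.asarray(spacing)) - center_mm) ** 2).sum(axis=1)
    return coords[d2 <= r * r]


def _dist_point_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab if np.ndim(t) else a + t * ab
    return np.linalg.norm(p - proj, axis=-1)


def _rasterize_tube(
    points_mm: np.ndarray, radius_mm: float, shape: Sequence[int], spacing: Sequence[float]
) -> np.ndarray:
    """Voxels within ``radius_mm`` of a polyline, via per-segment bounding boxes."""
    sel: set[tuple[int, int, int]] = set()
    sp = np.asarray(spacing)
    for a, b in zip(points_mm[:-1], points_mm[1:]):
        lo_mm = np.minimum(a, b) - radius_mm
        hi_mm = np.maximum(a, b) + radius_mm
        lo = [max(0, int(np.floor(c / v))) for c, v in zip(lo_mm, spacing)]
        hi = [min(n - 1, int(np.ceil(c / v))) for c, v, n in zip(hi_mm, spacing, shape)]
        if any(l > h for l, h in zip(lo, hi)):
            continue
        axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        coords = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
        mm = coords * sp
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip(((mm - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else np.zeros(len(mm))
        d = np.linalg.norm(mm - (a + t[:, None] * ab), axis=1)
        for c in coords[d <= radius_mm]:
            sel.add((int(c[0]), int(c[1]), int(c[2])))
    if not sel:
        return np.empty((0, 3), dtype=np.intp)
    return np.array(sorted(sel), dtype=np.intp)


def _bias_field(
    shape: Sequence[int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude·q where q is a random
    quadratic polynomial surface normalized to [-1, 1]."""
    if amplitude == 0:
        return np.ones(tuple(shape), dtype=np.float64)
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) for n in shape], indexing="ij"
    )
    coef = rng.normal(size=10)
    z, y, x = grids
    q = (
        coef[0] * z + coef[1] * y + coef[2] * x
        + coef[3] * z * y + coef[4] * y * x + coef[5] * z * x
        + coef[6] * z * z + coef[7] * y * y + coef[8] * x * x
        + coef[9]
    )
    peak = np.max(np.abs(q))
    if peak > 0:
        q = q / peak
    return 1.0 + amplitude * q


def generate_phantom(spec: PhantomSpec) -> Volume:
    """Generate one phantom subject from ``spec``.

    The returned :class:`Volume` carries the noisy intensities, a binary mask
    marking exactly the microbleed spheres, and a lesion table with each
    planted microbleed's rasterized centroid and true diameter.

    Raises
    ------
    PlacementError
        If ``n_cmb`` non-overlapping spheres cannot be placed inside the
        brain within a bounded number of rejection-sampling attempts.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.volume_shape
    spacing = spec.voxel_size
    brain = _brain_ellipsoid(shape, spacing)
    if not brain.any():
        raise PlacementError("degenerate brain region")

    img = np.where(brain, _BRAIN_INTENSITY, 0.0)
    mask = np.zeros(shape, dtype=np.uint8)

    center_mm = (np.asarray(shape) - 1) / 2.0 * np.asarray(spacing)
    radii_mm = 0.8 * np.asarray(shape) * np.asarray(spacing) / 2.0

    def inside_brain(p_mm: np.ndarray, margin_mm: float) -> bool:
        shr = radii_mm - margin_mm
        if np.any(shr <= 0):
            return False
        return float((((p_mm - center_mm) / shr) ** 2).sum()) <= 1.0

    def sample_point(margin_mm: float) -> np.ndarray:
        for _ in range(1000):
            u = rng.uniform(-1.0, 1.0, size=3)
            p = center_mm + u * radii_mm
            if inside_brain(p, margin_mm):
                return p
        raise PlacementError("could not sample a point inside the brain")

    # --- microbleeds -----------------------------------------------------
    lesions: list[Lesion] = []
    placed: list[tuple[np.ndarray, float]] = []  # (center_mm, radius_mm)
    max_attempts = 200 * max(1, spec.n_cmb)
    attempts = 0
    while len(placed) < spec.n_cmb:
        if attempts >= max_attempts:
            raise PlacementError(
                f"failed to place {spec.n_cmb} non-overlapping microbleeds "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        d = rng.uniform(*spec.cmb_diameter_range)
        r = d / 2.0
        c = sample_point(margin_mm=r)
        if any(np.linalg.norm(c - pc) < r + pr + 1.0 for pc, pr in placed):
            continue
        vox = _rasterize_sphere(c, d, shape, spacing)
        if len(vox) == 0:
            continue
        level = rng.uniform(*_DARK_FRACTION) * _BRAIN_INTENSITY
        img[vox[:, 0], vox[:, 1], vox[:, 2]] = level
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = 1
        centroid = tuple(vox.mean(axis=0).tolist())
        lesions.append(
            Lesion(
                id=len(lesions) + 1,
                centroid=centroid,  # type: ignore[arg-type]
                voxels=frozenset((int(a), int(b), int(cc)) for a, b, cc in vox),
                equiv_diameter_mm=float(d),
            )
        )
        placed.append((c, r))

    # --- vessels (confounders, never in the mask) ------------------------
    for _ in range(spec.n_vessels):
        for _try in range(50):
            radius = rng.uniform(0.5, 1.0)
            n_seg = rng.integers(3, 6)
            seg_len = rng.uniform(8.0, 15.0)
            start = sample_point(margin_mm=radius)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pts = [start]
            for _s in range(n_seg):
                direction = direction + rng.normal(scale=0.35, size=3)
                direction /= np.linalg.norm(direction)
                pts.append(pts[-1] + direction * seg_len / n_seg)
            pts_mm = np.array(pts)
            # keep clear of planted microbleeds so mask components stay crisp
            clear = all(
                _dist_point_segment(pc, a, b) > pr + radius + 1.0
                for pc, pr in placed
                for a, b in zip(pts_mm[:-1], pts_mm[1:])
            )
            if not clear:
                continue
            vox = _rasterize_tube(pts_mm, radius, shape, spacing)
            if len(vox) == 0:
                continue
            keep = brain[vox[:, 0], vox[:, 1], vox[:, 2]]
            vox = vox[keep]
            if len(vox) == 0:
                continue
            level = rng.uniform(*_DARK_FRACTION) * _BRAIN_INTENSITY
            img[vox[:, 0], vox[:, 1], vox[:, 2]] = level
            break

    # --- calcification-like distractors (smaller, fainter, unlabeled) ----
    for _ in range(spec.n_calcifications):
        for _try in range(50):
            d = rng.uniform(*_CALC_DIAMETER)
            c = sample_point(margin_mm=d / 2.0)
            if any(np.linalg.norm(c - pc) < d / 2.0 + pr + 1.0 for pc, pr in placed):
                continue
            vox = _rasterize_sphere(c, d, shape, spacing)
            if len(vox) == 0:
                continue
            level = rng.uniform(*_CALC_FRACTION) * _BRAIN_INTENSITY
            img[vox[:, 0], vox[:, 1], vox[:, 2]] = level
            break

    # --- bias field and noise --------------------------------------------
    img = img * _bias_field(shape, spec.bias_field_amplitude, rng)
    if spec.noise_sigma > 0:
        img = img + np.where(brain, rng.normal(0.0, spec.noise_sigma, size=shape), 0.0)
    img = np.clip(img, 0.0, None).astype(np.float32)

    return Volume(
        intensities=img,
        spacing=spacing,
        mask=mask,
        lesion_table=lesions,
        subject_id=f"phantom-{spec.seed}",
    )


def write_phantom(volume: Volume, path_prefix: str) -> list[str]:
    """Write intensities/mask as NIfTI and the lesion table as CSV.

    Files written: ``<prefix>_image.nii.gz``, ``<prefix>_mask.nii.gz`` (if a
    mask is present) and ``<prefix>_lesions.csv`` (if a lesion table is
    present, header-only when empty).  Returns the list of paths written.
    """
    from .io import write_volume  # local import to avoid a cycle

    paths = [f"{path_prefix}_image.nii.gz"]
    write_volume(volume, paths[0])
    if volume.mask is not None:
        p = f"{path_prefix}_mask.nii.gz"
        write_volume(Volume(volume.mask.astype(np.uint8), volume.spacing), p)
        paths.append(p)
    if volume.lesion_table is not None:
        p = f"{path_prefix}_lesions.csv"
        rows = [
            {
                "id": l.id,
                "z": l.centroid[0],
                "y": l.centroid[1],
                "x": l.centroid[2],
                "diameter_mm": l.equiv_diameter_mm,
            }
            for l in volume.lesion_table
        ]
        pd.DataFrame(rows, columns=["id", "z", "y", "x", "diameter_mm"]).to_csv(
            p, index=False
        )
        paths.append(p)
    return paths


def phantom_cohort(
    n_subjects: int,
    base_spec: PhantomSpec,
    seed: int,
    n_cmb_range: tuple[int, int] | None = None,
) -> list[Volume]:
    """Generate a cohort of phantoms with per-subject seeds derived from ``seed``.

    When ``n_cmb_range`` is given, each subject's microbleed count is drawn
    uniformly from the inclusive range, emulating the spread of lesion burden
    across a study population.
    """
    rng = np.random.default_rng(seed)
    vols = []
    for i in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(base_spec, seed=sub_seed)
        if n_cmb_range is not None:
            spec = replace(spec, n_cmb=int(rng.integers(n_cmb_range[0], n_cmb_range[1] + 1)))
        v = generate_phantom(spec)
        v.subject_id = f"phantom-{i:03d}"
        vols.append(v)
    return vols
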