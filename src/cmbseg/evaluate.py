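"""Lesion-level detection scoring and subject-level burden assessment.

Detection is scored on a lesion-wise basis: predicted and ground-truth
connected components are paired one-to-one when their centroids lie within
a fixed Euclidean radius (4 voxels by default), and precision, recall, F1
and the average number of false positives per subject (FP_avg) are pooled
across subjects.  Subject-level microbleed counts are binned into the four
ARIA-H severity intervals (0, 1–4, 5–9, ≥10) used for treatment-eligibility
decisions in anti-amyloid trials, with a 4×4 confusion matrix and a
Spearman correlation (Fisher-z confidence interval) between predicted and
true counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import spearmanr

from .phantom import Lesion, Volume

ARIA_CATEGORIES = ("0", "1-4", "5-9", ">=10")

_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)   # 26-connectivity
_STRUCT_2D = np.ones((3, 3), dtype=bool)      # 8-connectivity


@dataclass
class MatchResult:
    """One-to-one pairing of predicted vs ground-truth lesions for a subject."""

    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    fp_list: list[int] = field(default_factory=list)
    fn_list: list[int] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_list)

    @property
    def fn(self) -> int:
        return len(self.fn_list)


@dataclass(frozen=True)
class DetectionMetrics:
    precision: float
    recall: float
    f1: float
    fp_avg: float
    n_subjects: int = 1
    tp: int = 0
    fp: int = 0
    fn: int = 0


def extract_lesions(
    mask: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    threshold: float = 0.5,
    min_size: int = 2,
    mode: str = "3d",
) -> list[Lesion]:
    """Connected components of a (probability or binary) volume as lesions.

    ``mode='3d'`` merges components across slices with 26-connectivity so a
    microbleed spanning several slices counts once; ``mode='2d'`` labels each
    axial slice independently with 8-connectivity (slice-level evaluation).
    Components smaller than ``min_size`` voxels are discarded as specks.
    Equivalent diameter is that of the sphere (3-D) or disk (2-D) with the
    same physical volume/area.
    """
    arr = np.asarray(mask)
    binary = arr > threshold if arr.dtype.kind == "f" else arr > 0
    spacing = tuple(float(s) for s in spacing)
    lesions: list[Lesion] = []

    def add_component(coords: np.ndarray, dims: str) -> None:
        if len(coords) < min_size:
            return
        centroid = coords.mean(axis=0)
        if dims == "3d":
            vol_mm3 = len(coords) * spacing[0] * spacing[1] * spacing[2]
            d = 2.0 * (3.0 * vol_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
        else:
            area_mm2 = len(coords) * spacing[1] * spacing[2]
            d = 2.0 * np.sqrt(area_mm2 / np.pi)
        lesions.append(
            Lesion(
                id=len(lesions) + 1,
                centroid=tuple(float(c) for c in centroid),  # type: ignore[arg-type]
                voxels=frozenset(tuple(int(v) for v in c) for c in coords),
                equiv_diameter_mm=float(d),
            )
        )

    if mode == "3d":
        labels, n = ndimage.label(binary, structure=_STRUCT_3D)
        for comp in range(1, n + 1):
            coords = np.argwhere(labels == comp)
            add_component(coords, "3d")
    elif mode == "2d":
        for z in range(binary.shape[0]):
            labels, n = ndimage.label(binary[z], structure=_STRUCT_2D)
            for comp in range(1, n + 1):
                yx = np.argwhere(labels == comp)
                coords = np.column_stack([np.full(len(yx), z), yx])
                add_component(coords, "2d")
    else:
        raise ValueError("mode must be '3d' or '2d'")
    return lesions


def match_lesions(
    pred: Sequence[Lesion], gt: Sequence[Lesion], match_radius: float = 4.0
) -> MatchResult:
    """Greedy one-to-one matching in ascending centroid distance.

    A predicted lesion is a true positive when its centroid lies within
    ``match_radius`` voxels (inclusive) of an unmatched ground-truth
    centroid; distance ties are broken by lower predicted id.  Leftover
    predictions are false positives, leftover ground truths false negatives.
    """
    cands = []
    for p in pred:
        for g in gt:
            d = float(np.linalg.norm(np.asarray(p.centroid) - np.asarray(g.centroid)))
            if d <= match_radius:
                cands.append((d, p.id, g.id))
    cands.sort()
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for d, pid, gid in cands:
        if pid in used_p or gid in used_g:
            continue
        pairs.append((pid, gid, d))
        used_p.add(pid)
        used_g.add(gid)
    return MatchResult(
        pairs=pairs,
        fp_list=[p.id for p in pred if p.id not in used_p],
        fn_list=[g.id for g in gt if g.id not in used_g],
    )


def detection_metrics(results: Sequence[MatchResult]) -> DetectionMetrics:
    """Micro-averaged precision/recall/F1 and false positives per subject.

    TP/FP/FN are pooled over subjects before forming the ratios; FP_avg
    divides the pooled FP count by the number of subjects, which therefore
    includes lesion-free subjects with no detections.  Zero-denominator
    conventions: precision = 1 with no predictions, recall = 1 with no
    ground truth (a subject with neither contributes nothing but still
    counts in the FP_avg denominator).
    """
    if len(results) == 0:
        raise ValueError("at least one subject is required")
    tp = sum(r.tp for r in results)
    fp = sum(r.fp for r in results)
    fn = sum(r.fn for r in results)
    precision = tp / (tp + fp) if tp + fp > 0 else 1.0
    recall = tp / (tp + fn) if tp + fn > 0 else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return DetectionMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        fp_avg=fp / len(results),
        n_subjects=len(results),
        tp=tp,
        fp=fp,
        fn=fn,
    )


def stratify_small(
    per_subject: Sequence[tuple[Sequence[Lesion], Sequence[Lesion]]],
    max_diameter_mm: float = 3.0,
    match_radius: float = 4.0,
) -> Optional[DetectionMetrics]:
    """Detection metrics restricted to small ground-truth lesions.

    ``per_subject`` holds (predicted, ground-truth) lesion lists.  Ground
    truth is restricted to lesions with equivalent diameter ≤
    ``max_diameter_mm``; predictions that the full matching paired with an
    excluded larger lesion are removed from the pool rather than counted as
    false positives, so the stratification itself creates no spurious FPs.
    Returns ``None`` when no subject has a small lesion (empty stratum).
    """
    results = []
    any_small = False
    for pred, gt in per_subject:
        full = match_lesions(pred, gt, match_radius)
        small_ids = {g.id for g in gt if g.equiv_diameter_mm <= max_diameter_mm}
        any_small = any_small or bool(small_ids)
        pairs = [(p, g, d) for (p, g, d) in full.pairs if g in small_ids]
        fn = [g.id for g in gt if g.id in small_ids and g.id not in {x[1] for x in full.pairs}]
        results.append(MatchResult(pairs=pairs, fp_list=list(full.fp_list), fn_list=fn))
    if not any_small:
        return None
    return detection_metrics(results)


def aria_category(count: int) -> str:
    """ARIA-H severity interval for a microbleed count: 0, 1–4, 5–9, ≥10."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return ARIA_CATEGORIES[0]
    if count <= 4:
        return ARIA_CATEGORIES[1]
    if count <= 9:
        return ARIA_CATEGORIES[2]
    return ARIA_CATEGORIES[3]


def fisher_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient:
    tanh(atanh ρ ± z·(1/√(n−3)))."""
    if n <= 3:
        raise ValueError("n must exceed 3 for a Fisher-z interval")
    from scipy.stats import norm

    z = np.arctanh(rho)
    se = 1.0 / np.sqrt(n - 3)
    q = norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - q * se)), float(np.tanh(z + q * se))


@dataclass
class BurdenReport:
    """Per-subject burden assessment with the 4×4 ARIA-H confusion matrix."""

    subjects: list[tuple[int, int, str, str]]  # (true, predicted, true_cat, pred_cat)
    confusion: np.ndarray                      # rows = GT category, cols = predicted
    spearman_rho: float
    rho_ci_95: Optional[tuple[float, float]]
    categories: tuple[str, ...] = ARIA_CATEGORIES

    def row_agreement(self, category: str) -> tuple[int, int]:
        """(correct, total) for one ground-truth category row."""
        i = self.categories.index(category)
        return int(self.confusion[i, i]), int(self.confusion[i].sum())


def burden_report(counts: Sequence[tuple[int, int]]) -> BurdenReport:
    """Build the subject-level burden report from (true, predicted) counts."""
    subjects = []
    confusion = np.zeros((4, 4), dtype=int)
    for true_c, pred_c in counts:
        tc, pc = aria_category(true_c), aria_category(pred_c)
        subjects.append((int(true_c), int(pred_c), tc, pc))
        confusion[ARIA_CATEGORIES.index(tc), ARIA_CATEGORIES.index(pc)] += 1
    true_counts = np.array([c[0] for c in counts], dtype=float)
    pred_counts = np.array([c[1] for c in counts], dtype=float)
    if np.ptp(true_counts) == 0 or np.ptp(pred_counts) == 0:
        rho = 1.0 if np.array_equal(true_counts, pred_counts) else 0.0
    else:
        rho = float(spearmanr(true_counts, pred_counts).statistic)
    n = len(counts)
    ci: Optional[tuple[float, float]] = None
    if n > 3 and abs(rho) < 1.0:
        ci = fisher_ci(rho, n)
    elif n <= 3:
        warnings.warn("fewer than 4 subjects: Fisher-z CI omitted", stacklevel=2)
    return BurdenReport(subjects=subjects, confusion=confusion, spearman_rho=rho, rho_ci_95=ci)


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def gradcam(
    net,
    sample,
    target_layer: str = "dec1",
    out_path: Optional[str] = None,
) -> np.ndarray:
    """Gradient-weighted class-activation map at a decoder stage.

    The score is the sum of final-output logits over the predicted lesion
    region (all positive-probability pixels; falls back to all pixels when
    nothing is predicted).  Channel weights are the spatially averaged
    gradients at the chosen decoder block; the CAM is their ReLU-rectified
    weighted activation sum, upsampled to the input resolution and
    normalized to [0, 1].  With ``out_path`` set, an overlay PNG is written.
    """
    layers = {"dec1": net.dec1, "dec2": net.dec2, "dec3": net.dec3}
    if target_layer not in layers:
        raise KeyError(
            f"unknown layer {target_layer!r}; valid layers: {sorted(layers)}"
        )
    stage = layers[target_layer]

    x = sample.channels if hasattr(sample, "channels") else np.asarray(sample)
    outputs = net.forward(x, train=False)
    final = outputs[0]
    prob = 1.0 / (1.0 + np.exp(-final))
    region = prob > 0.5
    if not region.any():
        region = np.ones_like(final, dtype=bool)
    dfinal = region.astype(np.float32)
    net.zero_grad()
    net.backward([dfinal] + [np.zeros_like(o) for o in outputs[1:]])

    acts = stage.last_activation[0]          # (C, h, w)
    grads = stage.last_grad[0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)

    H, W = x.shape[-2], x.shape[-1]
    if cam.shape != (H, W):
        zoom = (H / cam.shape[0], W / cam.shape[1])
        cam = ndimage.zoom(cam, zoom, order=1)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    cam = np.clip(np.nan_to_num(cam, nan=0.0), 0.0, 1.0)

    if out_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        base = x[1] if x.ndim == 3 else x[0, 1]
        ax.imshow(base, cmap="gray")
        ax.imshow(cam, cmap="jet", alpha=0.4, vmin=0.0, vmax=1.0)
        ax.axis("off")
        fig.savefig(out_path, dpi=100, bbox_inches="tight")
        plt.close(fig)
    return cam
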