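"""Lesion extraction, centroid matching, detection metrics, stratification,
ARIA-H binning, burden statistics, and Grad-CAM contracts."""

import itertools

import numpy as np
import pytest

from cmbseg.evaluate import (
    ARIA_CATEGORIES,
    MatchResult,
    aria_category,
    burden_report,
    detection_metrics,
    extract_lesions,
    fisher_ci,
    gradcam,
    match_lesions,
    stratify_small,
)
from cmbseg.phantom import Lesion, PhantomSpec, generate_phantom


def lesion_at(i, z, y, x, d=3.0):
    return Lesion(id=i, centroid=(z, y, x), voxels=frozenset(), equiv_diameter_mm=d)


class TestExtractLesions:
    def test_empty_mask(self):
        assert extract_lesions(np.zeros((4, 8, 8))) == []

    def test_two_blobs_with_flood_fill_centroids(self):
        mask = np.zeros((6, 10, 10), dtype=np.uint8)
        blob1 = [(1, 2, 2), (1, 2, 3), (1, 3, 2)]
        blob2 = [(4, 7, 7), (4, 7, 8), (5, 7, 7)]
        for z, y, x in blob1 + blob2:
            mask[z, y, x] = 1
        lesions = extract_lesions(mask)
        assert len(lesions) == 2
        got = sorted(tuple(l.centroid) for l in lesions)
        want = sorted(tuple(np.mean(b, axis=0)) for b in (blob1, blob2))
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_min_size_filters_specks(self):
        mask = np.zeros((4, 8, 8), dtype=np.uint8)
        mask[1, 1, 1] = 1  # single voxel
        mask[2, 4:6, 4:6] = 1
        assert len(extract_lesions(mask, min_size=2)) == 1

    def test_planted_sphere_recovered(self):
        spec = PhantomSpec(
            volume_shape=(16, 48, 48), n_cmb=1, cmb_diameter_range=(5.0, 5.0),
            n_vessels=0, n_calcifications=0, noise_sigma=0.0,
            bias_field_amplitude=0.0, seed=4,
        )
        vol = generate_phantom(spec)
        found = extract_lesions(vol.mask, vol.spacing)
        assert len(found) == 1
        truth = vol.lesion_table[0]
        assert np.linalg.norm(np.array(found[0].centroid) - truth.centroid) < 0.5
        assert abs(found[0].equiv_diameter_mm - 5.0) < 1.0

    def test_probability_map_threshold(self):
        prob = np.zeros((4, 8, 8))
        prob[1, 2:4, 2:4] = 0.9
        prob[3, 5:7, 5:7] = 0.3
        assert len(extract_lesions(prob, threshold=0.5)) == 1
        assert len(extract_lesions(prob, threshold=0.2)) == 2

    def test_2d_mode_counts_per_slice(self):
        mask = np.zeros((3, 8, 8), dtype=np.uint8)
        mask[0, 2:4, 2:4] = 1
        mask[1, 2:4, 2:4] = 1  # same in-plane blob on two slices
        assert len(extract_lesions(mask, mode="3d")) == 1
        assert len(extract_lesions(mask, mode="2d")) == 2
        with pytest.raises(ValueError):
            extract_lesions(mask, mode="4d")

    def test_anisotropic_spacing_enters_diameter(self):
        mask = np.zeros((2, 4, 4), dtype=np.uint8)
        mask[0, :2, :2] = 1
        d_iso = extract_lesions(mask, (1.0, 1.0, 1.0))[0].equiv_diameter_mm
        d_aniso = extract_lesions(mask, (1.0, 0.45, 0.45))[0].equiv_diameter_mm
        assert d_aniso == pytest.approx(d_iso * 0.45 ** (2 / 3), rel=1e-6)


def brute_force_best_matching(pred, gt, radius):
    """Exhaustive max-cardinality / min-distance one-to-one assignment."""
    pairs = [
        (p.id, g.id, float(np.linalg.norm(np.subtract(p.centroid, g.centroid))))
        for p in pred
        for g in gt
    ]
    feasible = [x for x in pairs if x[2] <= radius]
    best = (0, 0.0)
    n = min(len(pred), len(gt))
    for r in range(n, -1, -1):
        candidates = []
        for combo in itertools.combinations(feasible, r):
            pids = [c[0] for c in combo]
            gids = [c[1] for c in combo]
            if len(set(pids)) == r and len(set(gids)) == r:
                candidates.append(sum(c[2] for c in combo))
        if candidates:
            return r, min(candidates)
    return 0, 0.0


class TestMatching:
    def test_exact_hit(self):
        res = match_lesions([lesion_at(1, 2, 3, 4)], [lesion_at(1, 2, 3, 4)])
        assert res.tp == 1 and res.pairs[0][2] == 0.0

    def test_boundary_inclusive_four_voxels(self):
        gt = [lesion_at(1, 0, 0, 0)]
        assert match_lesions([lesion_at(1, 0, 0, 4.0)], gt).tp == 1
        res = match_lesions([lesion_at(1, 0, 0, 4.01)], gt)
        assert res.tp == 0 and res.fp == 1 and res.fn == 1

    def test_two_preds_one_gt_takes_closer(self):
        gt = [lesion_at(7, 5, 5, 5)]
        pred = [lesion_at(1, 5, 5, 7), lesion_at(2, 5, 5, 6)]
        res = match_lesions(pred, gt)
        assert res.tp == 1
        assert res.pairs[0][0] == 2  # the closer prediction
        assert res.fp_list == [1]

    def test_conservation_identities(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pred = [
                lesion_at(i + 1, *rng.uniform(0, 10, 3)) for i in range(rng.integers(0, 5))
            ]
            gt = [
                lesion_at(i + 1, *rng.uniform(0, 10, 3)) for i in range(rng.integers(0, 5))
            ]
            res = match_lesions(pred, gt)
            assert res.tp + res.fn == len(gt)
            assert res.tp + res.fp == len(pred)
            assert all(d <= 4.0 for (_, _, d) in res.pairs)

    def test_greedy_equals_exhaustive_on_small_instances(self):
        # ground-truth lesions separated by more than twice the match
        # radius: the regime the centroid rule presumes, where greedy
        # matching is equivalent to the exhaustive optimal assignment
        rng = np.random.default_rng(1)
        for _ in range(100):
            gt_pts = []
            while len(gt_pts) < rng.integers(0, 5):
                c = rng.uniform(0, 20, 3)
                if all(np.linalg.norm(c - q) > 8.5 for q in gt_pts):
                    gt_pts.append(c)
            gt = [lesion_at(i + 1, *c) for i, c in enumerate(gt_pts)]
            pred_pts = [c + rng.normal(0, 2.0, 3) for c in gt_pts if rng.random() < 0.8]
            pred_pts += [rng.uniform(0, 20, 3) for _ in range(rng.integers(0, 3))]
            pred = [lesion_at(i + 1, *c) for i, c in enumerate(pred_pts)]
            res = match_lesions(pred, gt)
            best_tp, _ = brute_force_best_matching(pred, gt, 4.0)
            assert res.tp == best_tp


class TestDetectionMetrics:
    def test_pooled_arithmetic(self):
        results = [
            MatchResult(pairs=[(1, 1, 0.0)] * 5, fp_list=[9], fn_list=[]),
            MatchResult(pairs=[(1, 1, 0.0)] * 4, fp_list=[], fn_list=[8]),
        ]
        m = detection_metrics(results)
        assert m.precision == pytest.approx(0.9)
        assert m.recall == pytest.approx(0.9)
        assert m.f1 == pytest.approx(0.9)
        assert m.fp_avg == pytest.approx(0.5)

    def test_all_correct(self):
        m = detection_metrics([MatchResult(pairs=[(1, 1, 0.0)])])
        assert (m.precision, m.recall, m.f1, m.fp_avg) == (1.0, 1.0, 1.0, 0.0)

    def test_lesion_free_subject_counts_in_fp_avg_denominator(self):
        results = [
            MatchResult(pairs=[(1, 1, 0.0)], fp_list=[2], fn_list=[]),
            MatchResult(),  # zero-CMB subject, no detections
        ]
        m = detection_metrics(results)
        assert m.fp_avg == pytest.approx(0.5)
        assert m.n_subjects == 2

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        results = [
            MatchResult(
                pairs=[(1, 1, 0.0)] * int(rng.integers(0, 4)),
                fp_list=list(range(int(rng.integers(0, 3)))),
                fn_list=list(range(int(rng.integers(0, 3)))),
            )
            for _ in range(6)
        ]
        a = detection_metrics(results)
        b = detection_metrics(results[::-1])
        assert a == b

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            detection_metrics([])


class TestStratifySmall:
    def test_empty_stratum_is_not_applicable(self):
        gt = [lesion_at(1, 1, 1, 1, d=6.0)]
        assert stratify_small([([], gt)]) is None

    def test_perfect_detection_small_recall(self):
        gt = [lesion_at(i + 1, 0, 0, 10 * i, d=2.5 if i < 5 else 6.0) for i in range(10)]
        pred = [lesion_at(i + 1, 0, 0, 10 * i) for i in range(10)]
        m = stratify_small([(pred, gt)])
        assert m.recall == 1.0
        assert m.tp == 5
        assert m.fp == 0  # matches to large lesions are removed, not penalized

    def test_only_large_missed_leaves_small_recall_unchanged(self):
        gt = [lesion_at(i + 1, 0, 0, 10 * i, d=2.5 if i < 3 else 8.0) for i in range(6)]
        pred = [lesion_at(i + 1, 0, 0, 10 * i) for i in range(3)]  # misses the large
        m = stratify_small([(pred, gt)])
        assert m.recall == 1.0 and m.fn == 0


class TestAria:
    @pytest.mark.parametrize(
        "count,cat", [(0, "0"), (1, "1-4"), (4, "1-4"), (5, "5-9"), (7, "5-9"), (9, "5-9"), (10, ">=10"), (25, ">=10")]
    )
    def test_interval_boundaries(self, count, cat):
        assert aria_category(count) == cat

    def test_exhaustive_against_lookup(self):
        table = {c: ("0" if c == 0 else "1-4" if c <= 4 else "5-9" if c <= 9 else ">=10") for c in range(31)}
        assert {c: aria_category(c) for c in range(31)} == table

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            aria_category(-1)


class TestBurdenReport:
    def test_identical_counts_give_diagonal_and_rho_one(self):
        counts = [(c, c) for c in [0, 2, 3, 7, 12, 1, 5, 9]]
        rep = burden_report(counts)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.confusion.sum() == len(counts)
        assert np.all(rep.confusion == np.diag(np.diag(rep.confusion)))

    def test_fisher_ci_published_case(self):
        lo, hi = fisher_ci(0.93, 72)
        assert round(lo, 2) == 0.89
        assert round(hi, 2) == 0.96

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (10, 30, 100, 1000):
            lo, hi = fisher_ci(0.8, n)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_small_n_omits_ci_with_warning(self):
        with pytest.warns(UserWarning):
            rep = burden_report([(1, 1), (2, 3), (0, 0)])
        assert rep.rho_ci_95 is None

    def test_cells_partition_subjects(self):
        rng = np.random.default_rng(3)
        counts = [(int(rng.integers(0, 15)), int(rng.integers(0, 15))) for _ in range(40)]
        rep = burden_report(counts)
        assert rep.confusion.sum() == 40
        for (t, p, tc, pc) in rep.subjects:
            assert tc == aria_category(t) and pc == aria_category(p)


class TestGradCam:
    def test_contract_and_degenerate_input(self, micro_net, tmp_path):
        from cmbseg.preprocess import SliceSample

        x = np.random.default_rng(0).standard_normal((3, 16, 16)).astype(np.float32)
        sample = SliceSample(x, None)
        out_file = tmp_path / "cam.png"
        cam = gradcam(micro_net, sample, "dec1", out_path=str(out_file))
        assert cam.shape == (16, 16)
        assert np.all(cam >= 0) and np.all(cam <= 1) and np.all(np.isfinite(cam))
        assert out_file.exists()
        # zeroed head -> constant-zero logits must not produce NaNs
        micro_net.head.w.value[...] = 0.0
        micro_net.head.b.value[...] = 0.0
        cam0 = gradcam(micro_net, sample, "dec2")
        assert np.all(np.isfinite(cam0))

    def test_unknown_layer_lists_valid_names(self, micro_net):
        from cmbseg.preprocess import SliceSample

        sample = SliceSample(np.zeros((3, 16, 16), np.float32), None)
        with pytest.raises(KeyError, match="dec1"):
            gradcam(micro_net, sample, "nope")
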