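"""Metric correctness against brute-force oracles; Grad-CAM sanity."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cacaflow as cf
from cacaflow.io import MaskImage


def _mask(arr):
    return MaskImage(pixels=np.asarray(arr, np.uint8))


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        assert cf.classification_metrics([1, 0, 1], [1, 0, 1]) == (1.0, 1.0, 1.0)

    def test_known_confusion_counts(self):
        true = [1] * 10 + [0] * 10
        pred = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8   # TP=8 FP=2 FN=2
        p, r, f1 = cf.classification_metrics(pred, true)
        assert (p, r, f1) == (0.8, 0.8, pytest.approx(0.8))

    def test_all_negative_prediction_flagged(self):
        with pytest.warns(UserWarning, match="no predicted positives"):
            p, r, _ = cf.classification_metrics([0, 0, 0], [1, 0, 1])
        assert p == 0.0 and r == 0.0

    def test_exhaustive_four_element_sets_match_confusion_oracle(self):
        for true in itertools.product([0, 1], repeat=4):
            for pred in itertools.product([0, 1], repeat=4):
                tp = sum(p and t for p, t in zip(pred, true))
                fp = sum(p and not t for p, t in zip(pred, true))
                fn = sum(t and not p for p, t in zip(pred, true))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p_, r_, f_ = cf.classification_metrics(pred, true)
                assert p_ == (tp / (tp + fp) if tp + fp else 0.0)
                assert r_ == (tp / (tp + fn) if tp + fn else 0.0)
                expect_f = 2 * p_ * r_ / (p_ + r_) if p_ + r_ else 0.0
                assert f_ == pytest.approx(expect_f)


class TestIoM:
    def test_identical_masks(self):
        m = _mask(np.eye(8))
        assert cf.iom(m, m) == 1.0

    def test_subset_gives_one(self):
        a = np.zeros((16, 16)); a[4:8, 4:8] = 1
        b = np.zeros((16, 16)); b[2:12, 2:12] = 1
        assert cf.iom(_mask(a), _mask(b)) == 1.0

    def test_empty_mask_flagged_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert cf.iom(_mask(np.zeros((4, 4))), _mask(np.ones((4, 4)))) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 2 ** 20 - 1))
    def test_matches_pixel_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, (16, 16))
        b = rng.integers(0, 2, (16, 16))
        if a.sum() == 0 or b.sum() == 0:
            return
        inter = sum(1 for r in range(16) for c in range(16) if a[r, c] and b[r, c])
        assert cf.iom(_mask(a), _mask(b)) == inter / min(a.sum(), b.sum())

    def test_iom_at_least_iou(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.integers(0, 2, (12, 12))
            b = rng.integers(0, 2, (12, 12))
            if a.sum() == 0 or b.sum() == 0:
                continue
            inter = np.sum(a & b)
            union = np.sum(a | b)
            assert cf.iom(_mask(a), _mask(b)) >= inter / union - 1e-12


def _brute_hausdorff(a, b, spacing):
    """O(n^2) all-pairs directed max-min distance over boundary pixels."""
    def boundary(m):
        pts = []
        for r in range(m.shape[0]):
            for c in range(m.shape[1]):
                if not m[r, c]:
                    continue
                nb = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
                if any(not (0 <= rr < m.shape[0] and 0 <= cc < m.shape[1]) or not m[rr, cc]
                       for rr, cc in nb):
                    pts.append((r, c))
        return pts

    pa, pb = boundary(a), boundary(b)
    h_ab = max(min(np.hypot(x[0] - y[0], x[1] - y[1]) for y in pb) for x in pa)
    h_ba = max(min(np.hypot(x[0] - y[0], x[1] - y[1]) for y in pa) for x in pb)
    return max(h_ab, h_ba) * spacing


class TestHausdorff:
    def test_identical_masks_zero(self):
        m = np.zeros((10, 10)); m[2:5, 2:5] = 1
        assert cf.hausdorff_mm(_mask(m), _mask(m), 0.3) == 0.0

    def test_three_four_five_triangle(self):
        a = np.zeros((8, 8)); a[0, 0] = 1
        b = np.zeros((8, 8)); b[3, 4] = 1
        assert cf.hausdorff_mm(_mask(a), _mask(b), 0.3) == pytest.approx(1.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            a = (rng.random((12, 12)) < 0.3).astype(np.uint8)
            b = (rng.random((12, 12)) < 0.3).astype(np.uint8)
            if a.sum() == 0 or b.sum() == 0:
                continue
            got = cf.hausdorff_mm(_mask(a), _mask(b), 0.25)
            assert got == pytest.approx(_brute_hausdorff(a, b, 0.25), abs=1e-9)

    def test_scales_linearly_with_spacing(self):
        rng = np.random.default_rng(4)
        a = (rng.random((10, 10)) < 0.4).astype(np.uint8)
        b = (rng.random((10, 10)) < 0.4).astype(np.uint8)
        d1 = cf.hausdorff_mm(_mask(a), _mask(b), 0.2)
        d2 = cf.hausdorff_mm(_mask(a), _mask(b), 0.4)
        assert d2 == pytest.approx(2 * d1)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            cf.hausdorff_mm(_mask(np.zeros((4, 4))), _mask(np.ones((4, 4))), 0.3)


class TestAggregate:
    def test_one_to_five(self):
        assert cf.aggregate([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_single_value(self):
        assert cf.aggregate([7.0]) == (7.0, 7.0, 7.0)

    def test_permutation_invariant(self):
        vals = [3.0, 1.0, 4.0, 1.5, 9.0]
        assert cf.aggregate(vals) == cf.aggregate(vals[::-1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cf.aggregate([])


class TestGradCam:
    def test_bounds_and_determinism(self, overfit_run):
        ds = overfit_run["ds"]
        nc, ce = ds.pairs[0, 0], ds.pairs[0, 1]
        cam1 = cf.gradcam(overfit_run["model"], nc, ce)
        cam2 = cf.gradcam(overfit_run["model"], nc, ce)
        assert cam1.min() >= 0.0 and cam1.max() <= 1.0
        assert cam1.shape == nc.shape
        assert np.array_equal(cam1, cam2)

    def test_overfit_model_heat_concentrates_on_cac_region(self, overfit_run):
        """On a positive training patch, mean heat inside the ROI target is
        at least the mean heat outside it."""
        ds = overfit_run["ds"]
        pos = int(np.flatnonzero(ds.labels == 1)[0])
        cam = cf.gradcam(overfit_run["model"], ds.pairs[pos, 0], ds.pairs[pos, 1])
        region = ds.roi_gt[pos].astype(bool)
        assert cam[region].mean() >= cam[~region].mean()
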