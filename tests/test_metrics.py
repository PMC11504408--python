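"""Metric identities and independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from mrdb.metrics import (
    ConfusionCounts,
    boundary_pixels,
    confusion_counts,
    dsc,
    evaluate_pair,
    hd95,
    jaccard,
    pr_curve,
    sensitivity_fnr,
    write_report_csv,
)


def brute_force_hd95(a, b, percentile=95.0):
    """All-pairs boundary distance-matrix oracle (O(n^2))."""
    pa, pb = boundary_pixels(a), boundary_pixels(b)
    dm = cdist(pa, pb)
    d_ab = dm.min(axis=1)
    d_ba = dm.min(axis=0)
    return max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile))


def brute_force_pr(scores, gts):
    """Threshold-sweep oracle over every distinct score."""
    s = np.asarray(scores, float).ravel()
    g = np.asarray(gts, bool).ravel()
    npos = g.sum()
    pts = []
    for t in sorted(set(s), reverse=True):
        pred = s >= t
        tp = np.sum(pred & g)
        pts.append((t, tp / pred.sum(), tp / npos))
    rec = np.array([0.0] + [p[2] for p in pts])
    prec = np.array([pts[0][1]] + [p[1] for p in pts])
    return pts, np.trapezoid(prec, rec)


def random_mask(rng, shape=(16, 16), p=0.3):
    return rng.random(shape) < p


class TestOverlapMetrics:
    def test_identical_nonempty(self, rng):
        m = random_mask(rng)
        assert dsc(m, m) == 1.0
        assert jaccard(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dsc(a, b) == 0.0
        assert jaccard(a, b) == 0.0

    def test_hand_counts_on_4x4(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :4] = True                      # |A| = 4
        b[0, 2:4] = b[1, 0:2] = True         # |B| = 4, overlap 2
        assert dsc(a, b) == pytest.approx(0.5)
        assert jaccard(a, b) == pytest.approx(2 / 6)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3), bool)
        assert dsc(z, z) == 1.0
        assert jaccard(z, z) == 1.0

    def test_dsc_jaccard_identity_50_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            a, b = random_mask(rng), random_mask(rng)
            j = jaccard(a, b)
            assert dsc(a, b) == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dsc(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            dsc(np.full((2, 2), 0.5), np.zeros((2, 2), bool))


class TestSensitivityFNR:
    def test_direct_arithmetic(self):
        assert sensitivity_fnr(ConfusionCounts(3, 0, 1, 0)) == (0.75, 0.25)

    def test_edge_cases(self):
        assert sensitivity_fnr(ConfusionCounts(5, 2, 0, 3)) == (1.0, 0.0)
        assert sensitivity_fnr(ConfusionCounts(0, 2, 4, 3)) == (0.0, 1.0)

    def test_undefined_sentinel(self):
        s, f = sensitivity_fnr(ConfusionCounts(0, 1, 0, 5))
        assert np.isnan(s) and np.isnan(f)

    @given(tp=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_sum_to_one_exactly(self, tp, fn):
        if tp + fn == 0:
            return
        s, f = sensitivity_fnr(ConfusionCounts(tp, 0, fn, 0))
        assert s + f == 1.0

    def test_confusion_totals(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        c = confusion_counts(a, b)
        assert c.total == a.size


class TestHD95:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng)
        m[0, 0] = True  # ensure nonempty
        assert hd95(m, m) == 0.0

    def test_single_pixels_5_apart(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[2, 1] = True
        b[2, 6] = True
        assert hd95(a, b) == pytest.approx(5.0)

    def test_empty_mask_sentinel(self):
        assert np.isnan(hd95(np.zeros((4, 4), bool), np.ones((4, 4), bool)))

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = random_mask(rng), random_mask(rng)
            if not (a.any() and b.any()):
                continue
            assert hd95(a, b) == hd95(b, a)

    def test_oracle_30_random_pairs(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 30:
            shape = (int(rng.integers(4, 33)), int(rng.integers(4, 33)))
            a = rng.random(shape) < 0.25
            b = rng.random(shape) < 0.25
            if not (a.any() and b.any()):
                continue
            assert hd95(a, b) == pytest.approx(brute_force_hd95(a, b), abs=1e-9)
            checked += 1

    def test_hd95_below_full_hausdorff(self):
        rng = np.random.default_rng(6)
        for _ in range(15):
            a = rng.random((20, 20)) < 0.2
            b = rng.random((20, 20)) < 0.2
            if not (a.any() and b.any()):
                continue
            assert hd95(a, b) <= hd95(a, b, percentile=100.0) + 1e-12


class TestPRCurve:
    def test_perfect_scores(self, rng):
        g = random_mask(rng)
        g[0, 0] = True
        _, auc = pr_curve(g.astype(float), g)
        assert auc == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self, rng):
        g = random_mask(rng, p=0.2)
        g[0, 0] = True
        _, auc = pr_curve(np.full(g.shape, 0.7), g)
        assert auc == pytest.approx(g.mean())

    def test_threshold_sweep_oracle_200_pixels(self):
        rng = np.random.default_rng(11)
        s = np.round(rng.random(200), 2)  # duplicates exercise tie handling
        g = rng.random(200) < 0.3
        g[0] = True
        _, auc = pr_curve(s.reshape(20, 10), g.reshape(20, 10))
        _, auc_oracle = brute_force_pr(s, g)
        assert auc == pytest.approx(auc_oracle, abs=1e-12)

    def test_matches_sklearn_average_precision_loosely(self):
        # cross-check against an independent library implementation
        from sklearn.metrics import auc as sk_auc
        from sklearn.metrics import precision_recall_curve
        rng = np.random.default_rng(4)
        s = rng.random(500)
        g = rng.random(500) < 0.4
        g[0] = True
        _, ours = pr_curve(s, g)
        prec, rec, _ = precision_recall_curve(g.astype(int), s)
        theirs = sk_auc(rec, prec)
        assert ours == pytest.approx(theirs, abs=5e-3)

    def test_no_positives_raises(self):
        with pytest.raises(ValueError):
            pr_curve(np.zeros((2, 2)), np.zeros((2, 2), bool))


class TestReport:
    def test_evaluate_pair_self_comparison(self, rng):
        g = random_mask(rng)
        g[3, 3] = True
        rep = evaluate_pair(g, g.astype(float))
        assert rep.dsc == 1.0 and rep.hd95 == 0.0 and rep.fnr == 0.0

    def test_csv_layout(self, tmp_path, rng):
        g = random_mask(rng)
        g[0, 0] = True
        rows = [(f"img{i}", evaluate_pair(g, g.astype(float))) for i in range(3)]
        path = tmp_path / "report.csv"
        write_report_csv(path, rows, pr_auc=0.9)
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("image_id,dsc,jaccard,sensitivity,hd95,fnr")
        assert len(lines) == 1 + 3 + 1  # header + rows + summary
        assert lines[-1].startswith("mean,")
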