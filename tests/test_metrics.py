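"""DSC, HD95, confusion metrics and the paired t-test report."""

import numpy as np
import pytest
from scipy import stats

from scaleformer.metrics import (confusion_metrics, dsc, dsc_per_class, hd95,
                                 paired_t_test, write_ttest_csv)

import oracles


class TestDSC:
    def test_identical_masks_score_100(self, rng):
        m = rng.random((8, 8)) > 0.5
        assert dsc(m, m) == 100.0

    def test_disjoint_masks_score_0(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dsc(a, b) == 0.0

    def test_half_overlap_scores_50(self):
        p = np.zeros((4, 4), bool)
        g = np.zeros((4, 4), bool)
        p[0, :4] = True
        g[:2, :2] = True            # |P∩G|=2, |P|=|G|=4
        assert dsc(p, g) == pytest.approx(50.0)

    def test_empty_vs_empty_is_100(self):
        z = np.zeros((4, 4), bool)
        assert dsc(z, z) == 100.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random((6, 6)) > 0.5
            b = rng.random((6, 6)) > 0.5
            assert dsc(a, b) == dsc(b, a)

    def test_per_class_vector(self):
        pred = np.array([[0, 1], [2, 2]])
        gt = np.array([[0, 1], [2, 0]])
        scores = dsc_per_class(pred, gt, 3)
        assert scores[1] == 100.0
        assert scores[2] == pytest.approx(200 * 1 / 3, abs=1e-9)


class TestHD95:
    def test_identical_masks_distance_zero(self, rng):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:6] = True
        assert hd95(m, m) == 0.0

    def test_single_pixels_euclidean(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[3, 4] = True
        assert hd95(a, b) == pytest.approx(5.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[0, 1] = True
        assert hd95(a, b, spacing=(1.0, 2.5)) == pytest.approx(2.5)

    def test_empty_mask_reports_diagonal_with_flag(self):
        m = np.zeros((9, 9), bool)
        g = np.zeros((9, 9), bool)
        g[4, 4] = True
        value, flagged = hd95(m, g, return_flag=True)
        assert flagged
        assert value == pytest.approx(np.sqrt(2) * 8)
        # never silently zero
        assert value > 0

    def test_matches_bruteforce_oracle_50_seeds(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            p = rng.random((16, 16)) > 0.6
            g = rng.random((16, 16)) > 0.6
            if not p.any() or not g.any():
                continue
            ref95, refmax = oracles.ref_hd95(p, g)
            got = hd95(p, g)
            assert got == pytest.approx(ref95, abs=1e-12)
            assert got <= refmax + 1e-12      # HD95 <= full Hausdorff


class TestConfusionMetrics:
    def test_perfect_prediction_all_ones(self):
        g = np.zeros((4, 4), bool)
        g[1:3, 1:3] = True
        m = confusion_metrics(g, g)
        assert m["mIoU"] == 1.0 and m["Acc"] == 1.0
        assert m["Sen"] == 1.0 and m["Spe"] == 1.0

    def test_all_background_prediction_has_zero_sensitivity(self):
        g = np.zeros((4, 4), bool)
        g[0, 0] = True
        m = confusion_metrics(np.zeros((4, 4), bool), g)
        assert m["Sen"] == 0.0

    def test_hand_counted_example(self):
        # TP=2, FP=1, FN=1, TN=12 on a 4x4 grid
        pred = np.zeros((4, 4), bool)
        gt = np.zeros((4, 4), bool)
        pred[0, 0] = pred[0, 1] = pred[0, 2] = True
        gt[0, 0] = gt[0, 1] = gt[0, 3] = True
        m = confusion_metrics(pred, gt)
        assert m["Sen"] == pytest.approx(2 / 3)
        assert m["Spe"] == pytest.approx(12 / 13)
        assert m["Acc"] == pytest.approx(14 / 16)
        assert m["mIoU"] == pytest.approx(0.5 * (2 / 4 + 12 / 14))

    def test_undefined_ratio_reported_missing(self):
        z = np.zeros((3, 3), bool)
        m = confusion_metrics(z, z)
        assert m["Sen"] is None          # TP+FN == 0


class TestPairedTTest:
    def test_identical_scores_not_significant(self):
        r = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_stat == 0.0 and r.p_value == 1.0 and not r.significant

    def test_closed_form_agreement(self):
        a = np.array([1, 2, 3, 4, 5.0])
        b = np.array([1.1, 2.2, 2.9, 4.3, 5.1])
        r = paired_t_test(a, b)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_hand = 2 * stats.t.sf(abs(t_hand), len(d) - 1)
        assert r.t_stat == pytest.approx(t_hand, abs=1e-10)
        assert r.p_value == pytest.approx(p_hand, abs=1e-10)
        # textbook mean CI for each model's scores
        half = stats.t.ppf(0.975, 4) * a.std(ddof=1) / np.sqrt(5)
        assert r.ci_a == pytest.approx((a.mean() - half, a.mean() + half),
                                       abs=1e-10)

    def test_significance_threshold_at_0_05(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=40)
        shift = 0.5 + 0.1 * rng.normal(size=40)   # strong noisy paired shift
        r = paired_t_test(base + shift, base)
        assert r.p_value < 0.05 and r.significant
        assert r.significant == (r.p_value < 0.05)

    @pytest.mark.filterwarnings(
        "ignore:Precision loss occurred:RuntimeWarning")
    def test_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=12)
        b = a + rng.normal(scale=0.3, size=12)
        r1 = paired_t_test(a, b)
        r2 = paired_t_test(b, a)
        assert r1.t_stat == pytest.approx(-r2.t_stat, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_too_few_cases_raise(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])

    def test_csv_report_shape(self, tmp_path):
        import pandas as pd
        r = paired_t_test([1, 2, 3.0], [0.5, 2.5, 2.0])
        write_ttest_csv({"other_model": r}, tmp_path / "t.csv")
        df = pd.read_csv(tmp_path / "t.csv")
        assert list(df.columns) == ["method", "t_statistic", "p_value",
                                    "significant", "ci_low", "ci_high"]
        assert df.loc[0, "method"] == "other_model"
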