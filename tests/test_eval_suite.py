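"""Overlap metrics, detection statistics, rater-panel selection,
stratification, correlation and pixel-level precision-recall."""

import itertools
import math

import numpy as np
import pytest

from endobleed import eval_suite as es
from endobleed import scene_synth as ss


def _mask(*idx, shape=(4, 4)):
    m = np.zeros(shape, bool)
    for i in idx:
        m.flat[i] = True
    return m


class TestDiceIou:
    def test_identical_nonempty_masks(self):
        m = _mask(0, 1, 5)
        sc = es.dice_iou(m, m)
        assert sc.dice == 1.0 and sc.iou == 1.0 and sc.gt_positive

    def test_disjoint_masks(self):
        sc = es.dice_iou(_mask(0, 1), _mask(2, 3))
        assert sc.dice == 0.0 and sc.iou == 0.0

    def test_counting_oracle_and_identity(self):
        a = _mask(0, 1, 2, 3, 4, 5)  # |A| = 6
        b = _mask(4, 5, 6, 7)  # |B| = 4, overlap 2
        sc = es.dice_iou(a, b)
        assert sc.dice == pytest.approx(0.4)
        assert sc.iou == pytest.approx(0.25)
        assert sc.dice == pytest.approx(2 * sc.iou / (1 + sc.iou))

    def test_both_empty_convention(self):
        sc = es.dice_iou(_mask(), _mask())
        assert (sc.dice, sc.iou) == (1.0, 1.0) and not sc.gt_positive

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            es.dice_iou(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestImageClassAndConfusion:
    FOV = np.ones((4, 4), bool)

    def test_positivity_rules(self):
        assert not es.image_class(_mask(), self.FOV)
        assert es.image_class(_mask(5), self.FOV)
        fov = _mask(0, 1, 2, 3)
        assert not es.image_class(_mask(8), fov)  # positives outside FOV

    def test_empty_fov_rejected(self):
        with pytest.raises(ValueError):
            es.image_class(_mask(0), np.zeros((4, 4), bool))

    def test_perfect_predictions(self):
        gts = [_mask(1), _mask(), _mask(2, 3)] * 10
        c = es.confusion(gts, gts, self.FOV)
        assert c.fp == c.fn == 0 and c.tp + c.tn == 30

    def test_all_empty_predictions(self):
        gts = [_mask(1), _mask()]
        c = es.confusion([_mask(), _mask()], gts, self.FOV)
        assert c.tp == 0 and c.fp == 0 and c.fn == 1 and c.tn == 1

    def test_random_fixture_matches_brute_tally(self, rng):
        preds = [rng.random((4, 4)) > 0.6 for _ in range(40)]
        gts = [rng.random((4, 4)) > 0.6 for _ in range(40)]
        c = es.confusion(preds, gts, self.FOV)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for p, g in zip(preds, gts):
            key = ("t" if p.any() == g.any() else "f") + ("p" if p.any() else "n")
            tally[key] += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (
            tally["tp"], tally["tn"], tally["fp"], tally["fn"],
        )
        assert c.total == 40


class TestDetectionMetrics:
    def test_perfect_counts(self):
        m = es.detection_metrics(es.ConfusionCounts(10, 10, 0, 0))
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert getattr(m, name).value == 1.0

    def test_random_counts_match_hand_formulas(self, rng):
        for _ in range(10):
            tp, tn, fp, fn = (int(x) for x in rng.integers(1, 50, 4))
            m = es.detection_metrics(es.ConfusionCounts(tp, tn, fp, fn))
            assert m.accuracy.value == pytest.approx((tp + tn) / (tp + tn + fp + fn))
            assert m.sensitivity.value == pytest.approx(tp / (tp + fn))
            assert m.specificity.value == pytest.approx(tn / (tn + fp))
            assert m.ppv.value == pytest.approx(tp / (tp + fp))
            assert m.npv.value == pytest.approx(tn / (tn + fn))
            for met in (m.accuracy, m.sensitivity, m.specificity, m.ppv, m.npv):
                assert met.lo <= met.value <= met.hi

    def test_undefined_denominator_reported_as_none(self):
        m = es.detection_metrics(es.ConfusionCounts(0, 5, 0, 0))
        assert m.sensitivity is None and m.ppv is None

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            es.detection_metrics(es.ConfusionCounts(0, 0, 0, 0))


class TestScoreCI:
    def test_certain_outcome_upper_bound_is_one(self):
        for method in ("wilson", "clopper_pearson"):
            lo, hi = es.score_ci(20, 20, method=method)
            assert hi == pytest.approx(1.0)

    def test_both_methods_contain_point_estimate(self):
        for k, n in [(1, 10), (5, 10), (129, 138), (25, 42)]:
            for method in ("wilson", "clopper_pearson"):
                lo, hi = es.score_ci(k, n, method=method)
                assert lo <= k / n <= hi

    def test_clopper_pearson_never_narrower_than_wilson(self):
        for k, n in [(2, 20), (10, 20), (18, 20), (50, 200), (129, 138)]:
            wlo, whi = es.score_ci(k, n, method="wilson")
            clo, chi = es.score_ci(k, n, method="clopper_pearson")
            assert chi - clo >= whi - wlo - 1e-12

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            es.score_ci(5, 4)


class TestRaterPanel:
    @staticmethod
    def _rater_fixture(rng, n_images=4):
        truth = [rng.random((24, 24)) > 0.7 for _ in range(n_images)]
        masks = {}
        for rid, sd in [("a", 0.5), ("b", 0.5), ("c", 0.5), ("d", 4.0), ("e", 5.0)]:
            masks[rid] = [
                ss.make_rater_mask(
                    t, ss.RaterNoise(boundary_jitter_sd=sd,
                                     seed=int(rng.integers(2**31)))
                )
                for t in truth
            ]
        return masks

    def test_identical_raters_give_unit_offdiagonal(self):
        masks = [_mask(0, 5), _mask(3)]
        panel = es.pairwise_agreement({"a": masks, "b": masks, "c": masks})
        off = panel.dice_matrix[~np.eye(3, dtype=bool)]
        assert (off == 1.0).all()

    def test_two_raters_match_direct_computation(self):
        a = [_mask(0, 1, 2)]
        b = [_mask(2, 3)]
        panel = es.pairwise_agreement({"a": a, "b": b})
        assert panel.dice_matrix[0, 1] == es.dice_iou(a[0], b[0]).dice

    def test_matrix_equals_brute_force_double_loop(self, rng):
        masks = self._rater_fixture(rng)
        panel = es.pairwise_agreement(masks)
        ids = panel.rater_ids
        for i, j in itertools.combinations(range(len(ids)), 2):
            brute = np.mean(
                [
                    es.dice_iou(a, b).dice
                    for a, b in zip(masks[ids[i]], masks[ids[j]])
                ]
            )
            assert panel.dice_matrix[i, j] == pytest.approx(brute)

    def test_missing_annotations_rejected(self):
        with pytest.raises(ValueError):
            es.pairwise_agreement({"a": [_mask(0)], "b": []})

    def test_select_panel_full_set_when_k_equals_n(self):
        panel = es.pairwise_agreement({"a": [_mask(0)], "b": [_mask(0)]})
        assert es.select_panel(panel, 2).selected == ["a", "b"]

    def test_select_panel_prefers_low_noise_trio(self, rng):
        panel = es.pairwise_agreement(self._rater_fixture(rng))
        assert sorted(es.select_panel(panel, 3).selected) == ["a", "b", "c"]

    def test_tie_breaks_lexicographically(self):
        masks = [_mask(0, 1)]
        panel = es.pairwise_agreement({r: masks for r in "abcd"})
        assert es.select_panel(panel, 2).selected == ["a", "b"]

    def test_selected_subset_beats_full_panel_mean(self, rng):
        panel = es.pairwise_agreement(self._rater_fixture(rng))
        sel = es.select_panel(panel, 3)
        n = len(panel.rater_ids)
        full_mean = panel.dice_matrix[~np.eye(n, dtype=bool)].mean()
        assert sel.selection_score >= full_mean

    def test_k_larger_than_n_rejected(self):
        panel = es.pairwise_agreement({"a": [_mask(0)], "b": [_mask(0)]})
        with pytest.raises(ValueError):
            es.select_panel(panel, 3)


class TestRaterVsConsensus:
    def test_leave_one_out_excludes_self_agreement(self):
        fov = np.ones((4, 4), bool)
        # raters a, b always agree; c marks an extra image positive
        masks = {
            "a": [_mask(0), _mask()],
            "b": [_mask(0), _mask()],
            "c": [_mask(0), _mask(5)],
        }
        loo = es.rater_vs_consensus(masks, ["a", "b", "c"], fov)
        # c's extra positive disagrees with the a+b consensus -> one FP
        assert loo["c"].fp == 1 and loo["c"].tp == 1
        assert loo["a"].fp == 0 and loo["a"].fn == 0
        # including the judged rater in the jury changes the verdict:
        # a 2-member jury of b+c has no majority on the disputed image
        fixed = es.rater_vs_consensus(masks, ["a", "b", "c"], fov,
                                      leave_one_out=False)
        assert fixed["c"].fp == 1  # 2/3 majority still excludes the extra


class TestGtAgreement:
    def test_identical_masks_agree_fully(self):
        m = _mask(0, 1)
        assert es.gt_agreement([m, m, m]) == (1.0, 1.0)

    def test_mean_of_pairwise_dices(self):
        masks = [_mask(0, 1, 2, 3), _mask(0, 1), _mask(2, 3, 4)]
        d, _ = es.gt_agreement(masks)
        brute = np.mean(
            [es.dice_iou(a, b).dice for a, b in itertools.combinations(masks, 2)]
        )
        assert d == pytest.approx(brute)

    def test_missing_mask_rejected(self):
        with pytest.raises(ValueError):
            es.gt_agreement([_mask(0), None])


def _record(dice, agreement=0.8, area=0.3, iou=None):
    iou = dice / (2 - dice) if iou is None else iou
    return es.EvalRecord("img", "r", dice, iou, agreement, area)


class TestStratification:
    def test_agreement_groups_are_cumulative(self):
        records = [
            _record(0.5, agreement=a) for a in (0.65, 0.72, 0.85, 0.95)
        ]
        strata = es.stratify_by_agreement(records)
        assert [s.n for s in strata] == [3, 2, 1]

    def test_all_below_lowest_threshold_gives_empty_groups(self):
        records = [_record(0.5, agreement=0.5)]
        assert [s.n for s in es.stratify_by_agreement(records)] == [0, 0, 0]

    def test_area_partition_and_boundary(self):
        records = [
            _record(0.5, area=0.15), _record(0.6, area=0.25),
            _record(0.7, area=0.0), _record(0.8, area=0.20),
        ]
        low, high = es.stratify_by_area(records)
        assert low.n == 2  # 0.15 and the boundary case 0.20
        assert high.n == 1
        # the GT-negative record is excluded entirely
        assert low.n + high.n == 3

    def test_summaries_match_independent_quantile_oracle(self, rng):
        dices = rng.uniform(0, 1, 25)
        records = [_record(float(d)) for d in dices]
        summary = es.stratify_by_area(records)[1]  # all area 0.3 -> high group
        assert summary.n == 25
        assert summary.dice_median == pytest.approx(float(np.median(dices)))
        assert summary.dice_mean == pytest.approx(float(dices.mean()))
        assert summary.dice_sd == pytest.approx(float(dices.std(ddof=1)))
        q1, q3 = np.percentile(dices, [25, 75])
        assert summary.dice_iqr == pytest.approx((q1, q3))


class TestSpearmanAndShapiro:
    def test_monotone_sequences(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert es.spearman(x, [2.0, 3.0, 5.0, 9.0]).rho == pytest.approx(1.0)
        assert es.spearman(x, [9.0, 5.0, 3.0, 2.0]).rho == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        x = rng.integers(0, 5, 10).astype(float)
        y = rng.integers(0, 5, 10).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:  # pragma: no cover
            pytest.skip("degenerate draw")
        from scipy.stats import pearsonr, rankdata

        oracle = pearsonr(rankdata(x), rankdata(y)).statistic
        assert es.spearman(x, y).rho == pytest.approx(oracle)

    def test_constant_vector_flagged_undefined(self):
        res = es.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.undefined and math.isnan(res.rho)

    def test_shapiro_rejects_near_constant_with_outlier(self):
        values = np.r_[np.full(20, 1.0) + np.arange(20) * 1e-6, 10.0]
        assert not es.shapiro_gate(values).normal

    def test_shapiro_accepts_normal_sample(self, rng):
        assert es.shapiro_gate(rng.standard_normal(100)).p_value > 0.001

    def test_shapiro_sample_size_bounds(self):
        with pytest.raises(ValueError):
            es.shapiro_gate([1.0, 2.0])


class TestPixelPR:
    FOV = np.ones((4, 4), bool)

    def test_perfect_probability_map(self):
        gt = _mask(0, 1, 2)
        prob = gt.astype(float)
        res = es.pixel_pr([prob], [gt], self.FOV)
        assert res.average_precision == pytest.approx(1.0)

    def test_uninformative_scores_approach_prevalence(self, rng):
        gt = rng.random((100, 100)) > 0.7
        prob = rng.random((100, 100))
        res = es.pixel_pr([prob], [gt], np.ones((100, 100), bool))
        prevalence = gt.mean()
        assert abs(res.average_precision - prevalence) < 0.05

    def test_six_pixel_hand_enumeration(self):
        """Scores 0.9>0.8>0.7>0.6>0.5>0.4, labels 1,1,0,1,0,0."""
        prob = np.array([[0.9, 0.8, 0.7], [0.6, 0.5, 0.4]])
        gt = np.array([[True, True, False], [True, False, False]])
        res = es.pixel_pr([prob], [gt], np.ones((2, 3), bool))
        # AP = sum over hits of (recall step * precision at hit)
        expected = (1 / 3) * (1 / 1) + (1 / 3) * (2 / 2) + (1 / 3) * (3 / 4)
        assert res.average_precision == pytest.approx(expected)
        # the precision-recall pairs contain the hand-enumerated points
        pr = set(zip(np.round(res.precision, 6), np.round(res.recall, 6)))
        assert (1.0, round(1 / 3, 6)) in pr
        assert (0.75, 1.0) in pr

    def test_no_positive_pixels_rejected(self):
        with pytest.raises(ValueError):
            es.pixel_pr([np.zeros((2, 2))], [np.zeros((2, 2), bool)],
                        np.ones((2, 2), bool))


class TestGeometryAndRounding:
    def test_circular_fov_recovers_a_disc(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disc = (yy - 30) ** 2 + (xx - 33) ** 2 <= 20**2
        circ = es.circular_fov(disc)
        inter = (circ & disc).sum()
        assert inter / circ.sum() > 0.99  # inscribed
        assert inter / disc.sum() > 0.9

    def test_round_half_up(self):
        assert es.round_half_up(0.735) == 0.74
        assert es.round_half_up(0.855) == 0.86
        assert es.round_half_up(0.5949999) == 0.59
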