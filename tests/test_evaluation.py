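import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hsimargin.evaluation import (
    EvalCase,
    PredictionMap,
    aggregate_distance_report,
    distance_report,
    metrics_at_threshold,
    optimal_operating_point,
    paired_one_tailed_ttest,
    roc_auc,
    specimen_confusion,
)
from hsimargin.hypercube_io import ConfigurationError, NORMAL, TUMOR, trim_tissue_edge
from hsimargin.margin_geometry import distance_to_margin


def mann_whitney_auc(scores, labels):
    """O(n^2) pair-counting oracle: (concordant + ties/2) / (n1 * n0)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        assert roc_auc([0.9, 0.1], [1, 0]).auc == 1.0

    def test_constant_scores_give_random_guess(self):
        assert roc_auc([0.5] * 10, [1, 0] * 5).auc == pytest.approx(0.5)

    def test_twelve_point_toy_matches_pair_counting(self):
        scores = np.array([0.1, 0.8, 0.5, 0.5, 0.3, 0.9, 0.2, 0.7, 0.5, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1, 0, 1, 0, 0, 1, 1, 0, 1])
        assert roc_auc(scores, labels).auc == pytest.approx(
            mann_whitney_auc(scores, labels)
        )

    def test_trapezoid_equals_pair_counting_exhaustively(self):
        """Trapezoidal AUC = Mann-Whitney statistic on random score sets up
        to 200 points, including heavy ties."""
        rng = np.random.default_rng(0)
        for n in (2, 5, 17, 63, 128, 200):
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert roc_auc(scores, labels).auc == pytest.approx(
                mann_whitney_auc(scores, labels)
            )

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(1)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        base = roc_auc(scores, labels).auc
        for f in (lambda s: 2 * s + 3, np.exp, lambda s: s**3):
            assert roc_auc(f(scores), labels).auc == pytest.approx(base)

    def test_negated_scores_complement_auc(self):
        rng = np.random.default_rng(2)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels).auc
        b = roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            roc_auc([0.1, 0.9], [1, 1])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        scores=st.lists(st.integers(0, 6), min_size=2, max_size=60),
        seed=st.integers(0, 2**16),
    )
    def test_pair_counting_property(self, scores, seed):
        """Property: trapezoidal AUC equals Mann-Whitney pair counting for
        arbitrary integer-valued (heavily tied) scores."""
        scores = np.asarray(scores, dtype=float)
        labels = np.random.default_rng(seed).integers(0, 2, len(scores))
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels).auc == pytest.approx(
            mann_whitney_auc(scores, labels)
        )


class TestOperatingPoint:
    def test_separated_scores_achieve_full_youden(self):
        roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        op = optimal_operating_point(roc)
        assert op.youden_j == pytest.approx(1.0)
        assert 0.2 < op.threshold <= 0.9

    def test_overlapping_gaussians_threshold_between_means(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(0.3, 0.1, 500), rng.normal(0.7, 0.1, 500)])
        labels = np.repeat([0, 1], 500)
        roc = roc_auc(scores, labels)
        op = optimal_operating_point(roc)
        # grid-search oracle over all candidate thresholds
        best_j, best_thr = -1, None
        for thr in np.unique(scores):
            m = metrics_at_threshold(scores, labels, thr)
            j = m.sensitivity + m.specificity - 1
            if j > best_j:
                best_j, best_thr = j, thr
        assert op.youden_j == pytest.approx(best_j, abs=1e-9)
        assert 0.3 < op.threshold < 0.7

    def test_degenerate_single_threshold(self):
        roc = roc_auc([0.4, 0.4, 0.4, 0.6], [0, 0, 1, 1])
        op = optimal_operating_point(roc)
        assert op.threshold == pytest.approx(0.6)


class TestThresholdMetrics:
    def test_perfect_predictor(self):
        m = metrics_at_threshold([0.9, 0.8, 0.1], [1, 1, 0], 0.5)
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_inverted_predictor(self):
        m = metrics_at_threshold([0.1, 0.2, 0.9], [1, 1, 0], 0.5)
        assert m.sensitivity == 0.0 and m.specificity == 0.0

    def test_hand_tabulated_confusion(self):
        # scores >= 0.5: rows 0,1,4 predicted positive
        scores = [0.7, 0.6, 0.4, 0.2, 0.9]
        labels = [1, 0, 1, 0, 1]
        m = metrics_at_threshold(scores, labels, 0.5)
        assert (m.tp, m.fp, m.tn, m.fn) == (2, 1, 1, 1)
        assert m.accuracy == pytest.approx(3 / 5)
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.specificity == pytest.approx(1 / 2)
        assert m.ppv == pytest.approx(2 / 3)
        assert m.npv == pytest.approx(1 / 2)

    def test_empty_set_flagged_undefined(self):
        with pytest.warns(UserWarning, match="empty"):
            m = metrics_at_threshold([], [], 0.5)
        assert np.isnan(m.accuracy) and m.n == 0


class TestPairedTTest:
    def test_identical_samples_give_t_zero_p_half(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = paired_one_tailed_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0 and res.p_one_tailed == 0.5
        assert res.degenerate

    def test_closed_form_example(self):
        # diffs [1, 2, 3]: t = 2 / (1 / sqrt(3)) = 2 sqrt(3), df = 2
        res = paired_one_tailed_ttest([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(2 * np.sqrt(3))
        assert res.p_one_tailed == pytest.approx(
            float(stats.t.sf(2 * np.sqrt(3), df=2)), abs=1e-12
        )
        assert res.p_one_tailed == pytest.approx(0.0371, abs=2e-4)

    def test_swapping_sides_flips_t_and_complements_p(self):
        rng = np.random.default_rng(4)
        a = rng.random(12)
        b = rng.random(12)
        fwd = paired_one_tailed_ttest(a, b)
        rev = paired_one_tailed_ttest(b, a)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic)
        assert fwd.p_one_tailed == pytest.approx(1.0 - rev.p_one_tailed)

    def test_matches_scipy_paired_test(self):
        rng = np.random.default_rng(5)
        a = rng.random(15)
        b = rng.random(15) + 0.1
        ours = paired_one_tailed_ttest(a, b, "greater")
        ref = stats.ttest_rel(a, b, alternative="greater")
        assert ours.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p_one_tailed == pytest.approx(ref.pvalue, abs=1e-10)

    def test_incomplete_pairs_dropped(self):
        a = [0.9, np.nan, 0.7, 0.6]
        b = [0.8, 0.5, np.nan, 0.4]
        res = paired_one_tailed_ttest(a, b)
        assert res.n_pairs == 2

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ConfigurationError):
            paired_one_tailed_ttest([1.0], [0.5])


class TestSpecimenConfusion:
    def test_true_tn_predicted_t_counts_tp_and_fp(self):
        c = specimen_confusion(["TN"], ["T"])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 0, 0)

    def test_true_t_predicted_tn_counts_tp_and_fn(self):
        c = specimen_confusion(["T"], ["TN"])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 0, 1)

    def test_all_correct_gives_unit_metrics(self):
        types = ["T", "N", "TN", "T", "N", "TN"]
        c = specimen_confusion(types, types)
        assert c.accuracy == c.sensitivity == c.specificity == c.ppv == c.npv == 1.0

    def test_ten_specimen_hand_tabulation(self):
        truth = ["T", "T", "N", "N", "TN", "TN", "TN", "T", "N", "TN"]
        pred_ = ["T", "N", "N", "T", "TN", "T", "N", "TN", "N", "TN"]
        # hand count: T/T -> TP; T/N -> FN; N/N -> TN; N/T -> FP;
        # TN/TN -> TP+TN (x3 total); TN/T -> TP+FP; TN/N -> TN+FN;
        # T/TN -> TP+FN
        c = specimen_confusion(truth, pred_)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 2, 5, 3)
        assert c.accuracy == pytest.approx(10 / 15)
        assert c.sensitivity == pytest.approx(5 / 8)
        assert c.specificity == pytest.approx(5 / 7)
        assert c.ppv == pytest.approx(5 / 7)
        assert c.npv == pytest.approx(5 / 8)

    def test_unknown_type_rejected(self):
        with pytest.raises(ConfigurationError):
            specimen_confusion(["T"], ["X"])


class TestDistanceReport:
    @pytest.fixture
    def toy_case(self):
        """Vertical-margin toy scene with a noisy left-to-right score ramp."""
        h, w = 30, 80
        gt = np.full((h, w), NORMAL, np.uint8)
        gt[:, 40:] = TUMOR
        rng = np.random.default_rng(6)
        values = np.clip(
            np.linspace(0.2, 0.8, w)[None, :] + rng.normal(0, 0.15, (h, w)), 0, 1
        )
        predmap = PredictionMap(values=values, valid=np.ones((h, w), bool))
        distmap = distance_to_margin(gt, 25.0)
        return EvalCase(
            patient_id="P0",
            modality="reflectance",
            predmap=predmap,
            gt_mask=gt,
            distmap=distmap,
            tissue_eval=np.ones((h, w), bool),
            threshold=0.5,
        )

    def test_d_zero_uses_all_eligible_pixels(self, toy_case):
        rep = distance_report([toy_case], (0.0,))
        assert rep.iloc[0].n_pixels == 30 * 80

    def test_pixel_count_nonincreasing_and_auc_improves(self, toy_case):
        rep = distance_report([toy_case], (0.0, 0.25, 0.5))
        n = rep.n_pixels.to_numpy()
        assert np.all(np.diff(n) <= 0)
        auc = rep.auc.to_numpy()
        assert auc[-1] >= auc[0]

    def test_unattainable_distance_marked(self, toy_case):
        rep = distance_report([toy_case], (0.0, 50.0))
        assert bool(rep[rep.d_mm == 50.0].attainable.iloc[0]) is False
        assert np.isnan(rep[rep.d_mm == 50.0].auc.iloc[0])

    def test_aggregate_matches_brute_force_recomputation(self, toy_case):
        import copy

        case2 = copy.deepcopy(toy_case)
        case2.patient_id = "P1"
        case2.predmap.values = 1.0 - case2.predmap.values  # a worse patient
        rep = distance_report([toy_case, case2], (0.0, 0.25))
        agg = aggregate_distance_report(rep)
        for d in (0.0, 0.25):
            rows = rep[(rep.d_mm == d) & rep.attainable]
            got = agg[agg.d_mm == d]
            assert got.median_auc.iloc[0] == pytest.approx(rows.auc.median())
            assert got.mean_auc.iloc[0] == pytest.approx(rows.auc.mean())
            assert got.n_patients.iloc[0] == rows.patient_id.nunique()
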