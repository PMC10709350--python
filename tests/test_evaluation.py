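"""Metrics against independent oracles: pair-counting AUC, exhaustive
threshold search, closed-form kappa, and the bootstrap-Wilcoxon machinery."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flairmatch.evaluation import (
    BootstrapResult,
    augment_ratings,
    bootstrap_wilcoxon,
    calibrate_to_sensitivity,
    cohens_kappa,
    cohens_kappa_ratings,
    confusion_metrics,
    ratings_to_calls,
    roc_auc,
    threshold_scores,
    youden_threshold,
)

RNG = np.random.default_rng(99)


# -- independent oracles -----------------------------------------------------

def auc_pair_counting(scores, labels):
    """O(n^2) Mann-Whitney oracle: ties count one half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def sens_spec_brute(scores, labels, thr):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    calls = s >= thr
    sens = np.mean(calls[y == 1]) if (y == 1).any() else np.nan
    spec = np.mean(~calls[y == 0]) if (y == 0).any() else np.nan
    return sens, spec


def kappa_closed_form(a, b):
    """kappa from the 2x2 contingency table, straight from the definition."""
    a = np.asarray(a, int)
    b = np.asarray(b, int)
    n = len(a)
    po = np.mean(a == b)
    pe = ((a == 1).mean() * (b == 1).mean()) + ((a == 0).mean() * (b == 0).mean())
    return (po - pe) / (1 - pe)


# -- AUC --------------------------------------------------------------------

class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_independent_scores_near_half(self):
        n = 4000
        scores = RNG.random(n)
        labels = RNG.integers(0, 2, n)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.03

    def test_matches_pair_counting_oracle_exactly(self):
        for trial in range(30):
            rng = np.random.default_rng(trial)
            n = rng.integers(6, 40)
            # quantized scores force ties
            scores = np.round(rng.random(n), 1)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                labels[0], labels[1] = 0, 1
            assert roc_auc(scores, labels) == pytest.approx(
                auc_pair_counting(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


# -- thresholds ---------------------------------------------------------------

class TestYouden:
    def test_perfect_separation_reaches_j_one(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        thr = youden_threshold(scores, labels)
        sens, spec = sens_spec_brute(scores, labels, thr)
        assert sens + spec - 1 == pytest.approx(1.0)
        assert 0.2 < thr < 0.8

    def test_identical_scores_give_j_zero(self):
        thr = youden_threshold([0.5] * 6, [1, 0, 1, 0, 1, 0])
        sens, spec = sens_spec_brute([0.5] * 6, [1, 0, 1, 0, 1, 0], thr)
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_matches_exhaustive_search(self):
        for trial in range(100):
            rng = np.random.default_rng(1000 + trial)
            n = rng.integers(5, 30)
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                labels[:2] = [0, 1]
            thr = youden_threshold(scores, labels)
            s, p = sens_spec_brute(scores, labels, thr)
            # exhaustive search over a fine grid of candidate cuts
            grid = np.concatenate([[scores.min() - 1], np.unique(scores),
                                   (np.unique(scores)[:-1] + np.unique(scores)[1:]) / 2,
                                   [scores.max() + 1]])
            best = max(sum(sens_spec_brute(scores, labels, t)) for t in grid)
            assert s + p == pytest.approx(best, abs=1e-12)


class TestCalibration:
    def test_target_zero_returns_largest_candidate(self):
        scores = [0.1, 0.5, 0.9, 0.7]
        labels = [0, 1, 1, 0]
        thr = calibrate_to_sensitivity(scores, labels, target=0.0)
        assert thr > max(scores)

    def test_target_one_calls_every_positive(self):
        scores = np.array([0.1, 0.5, 0.9, 0.7])
        labels = np.array([0, 1, 1, 0])
        thr = calibrate_to_sensitivity(scores, labels, target=1.0)
        sens, _ = sens_spec_brute(scores, labels, thr)
        assert sens == 1.0

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_to_sensitivity([0.5, 0.6], [0, 1], target=1.5)

    def test_achieves_target_and_is_maximal(self):
        """On 100 random sets the achieved sensitivity meets the target and no
        larger candidate threshold would."""
        for trial in range(100):
            rng = np.random.default_rng(2000 + trial)
            n = rng.integers(6, 40)
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                labels[:2] = [0, 1]
            target = rng.choice([0.3, 0.62, 0.8])
            thr = calibrate_to_sensitivity(scores, labels, target=target)
            sens, _ = sens_spec_brute(scores, labels, thr)
            assert sens >= target
            for bigger in np.unique(scores[scores >= thr]) + 1e-9:
                s2, _ = sens_spec_brute(scores, labels, bigger)
                assert s2 < target or bigger <= thr


# -- confusion metrics -------------------------------------------------------

class TestConfusionMetrics:
    def test_human_benchmark_operating_point(self):
        """Sensitivity 0.620 with specificity 0.780 averages to the reported
        balanced accuracy of 0.700."""
        # construct calls realizing exactly sens=0.62, spec=0.78 on 1000 patients
        y = np.array([1] * 500 + [0] * 500)
        calls = np.concatenate([np.repeat([1, 0], [310, 190]),
                                np.repeat([0, 1], [390, 110])])
        rep = confusion_metrics(calls, y)
        assert rep.sensitivity == pytest.approx(0.620)
        assert rep.specificity == pytest.approx(0.780)
        assert rep.balanced_accuracy == pytest.approx(0.700)

    def test_all_correct(self):
        rep = confusion_metrics([1, 0, 1], [1, 0, 1])
        assert rep.sensitivity == rep.specificity == rep.balanced_accuracy == 1.0

    def test_balanced_accuracy_identity_random_tables(self):
        for trial in range(20):
            rng = np.random.default_rng(trial)
            y = rng.integers(0, 2, 50)
            c = rng.integers(0, 2, 50)
            if len(np.unique(y)) < 2:
                y[:2] = [0, 1]
            rep = confusion_metrics(c, y)
            tp = np.sum((c == 1) & (y == 1))
            fn = np.sum((c == 0) & (y == 1))
            tn = np.sum((c == 0) & (y == 0))
            fp = np.sum((c == 1) & (y == 0))
            assert rep.sensitivity == pytest.approx(tp / (tp + fn))
            assert rep.specificity == pytest.approx(tn / (tn + fp))
            assert rep.balanced_accuracy == pytest.approx(
                (rep.sensitivity + rep.specificity) / 2)

    def test_missing_class_yields_nan_with_warning(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            rep = confusion_metrics([0, 0], [0, 0])
        assert np.isnan(rep.sensitivity)

    def test_threshold_convention(self):
        np.testing.assert_array_equal(threshold_scores([0.3, 0.5, 0.7], 0.5),
                                      [0, 1, 1])


# -- categorical ratings -----------------------------------------------------

class TestRatings:
    def test_mapping(self):
        assert list(ratings_to_calls(["mismatch"] * 3)) == [1, 1, 1]
        assert list(ratings_to_calls(["indeterminable"] * 3)) == [0, 0, 0]
        assert list(ratings_to_calls(
            ["mismatch", "no_mismatch", "indeterminable"])) == [1, 0, 0]

    def test_unknown_value_rejected(self):
        with pytest.raises(ValueError, match="unknown rating"):
            ratings_to_calls(["maybe"])

    def test_augmentation_identity_without_indeterminables(self):
        r = ["mismatch", "no_mismatch", "mismatch"]
        np.testing.assert_array_equal(augment_ratings(r, [0, 1, 0]),
                                      ratings_to_calls(r))

    def test_augmentation_all_indeterminable_equals_dl(self):
        dl = np.array([1, 0, 1, 1])
        np.testing.assert_array_equal(
            augment_ratings(["indeterminable"] * 4, dl), dl)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["mismatch", "no_mismatch",
                                               "indeterminable"]),
                              st.integers(0, 1)), min_size=1, max_size=60))
    def test_augmentation_changes_only_indeterminables(self, pairs):
        r = [p[0] for p in pairs]
        dl = np.array([p[1] for p in pairs])
        out = augment_ratings(r, dl)
        base = ratings_to_calls(r)
        for i, rating in enumerate(r):
            if rating == "indeterminable":
                assert out[i] == dl[i]
            else:
                assert out[i] == base[i]

    def test_augmentation_with_good_dl_recovers_sensitivity(self):
        """Indeterminable positives are misses under the exclusion rule; a
        better-than-chance model can only recover them (brute-force recount)."""
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 400)
        r = np.where(y == 1, "mismatch", "no_mismatch").astype(object)
        indet = rng.random(400) < 0.2
        r[indet] = "indeterminable"
        dl = np.where(rng.random(400) < 0.75, y, 1 - y)  # 75 % accurate
        plain = confusion_metrics(ratings_to_calls(r), y)
        aug = confusion_metrics(augment_ratings(r, dl), y)
        # manual recount of augmented sensitivity
        calls = ratings_to_calls(r)
        calls[indet] = dl[indet]
        tp = np.sum((calls == 1) & (y == 1))
        assert aug.sensitivity == pytest.approx(tp / np.sum(y == 1))
        assert aug.sensitivity >= plain.sensitivity


# -- kappa --------------------------------------------------------------------

class TestKappa:
    def test_identical_raters(self):
        assert cohens_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0

    def test_constant_rater_gives_zero(self):
        assert cohens_kappa([1, 1, 1, 1], [1, 0, 1, 0]) == 0.0

    def test_textbook_2x2_table(self):
        """Counts (40, 10, 20, 30): p_o = 0.7, p_e = 0.5, kappa = 0.4."""
        a = [1] * 50 + [0] * 50
        b = [1] * 40 + [0] * 10 + [1] * 20 + [0] * 30
        assert cohens_kappa(a, b) == pytest.approx(0.4)

    def test_matches_closed_form_on_random_tables(self):
        for trial in range(30):
            rng = np.random.default_rng(trial)
            a = rng.integers(0, 2, 60)
            b = np.where(rng.random(60) < 0.7, a, rng.integers(0, 2, 60))
            if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
                continue
            assert cohens_kappa(a, b) == pytest.approx(kappa_closed_form(a, b))

    def test_symmetry_and_label_flip_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, 80)
        b = rng.integers(0, 2, 80)
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(b, a))
        assert cohens_kappa(1 - a, 1 - b) == pytest.approx(cohens_kappa(a, b))

    def test_both_constant_warns(self):
        with pytest.warns(UserWarning):
            assert cohens_kappa([1, 1], [1, 1]) == 1.0

    def test_three_category_variant(self):
        a = ["mismatch", "no_mismatch", "indeterminable", "mismatch"]
        assert cohens_kappa_ratings(a, a, three_category=True) == 1.0
        # two-category mapping folds indeterminable into no-mismatch
        b = ["mismatch", "no_mismatch", "no_mismatch", "mismatch"]
        assert cohens_kappa_ratings(a, b) == 1.0


# -- bootstrap + Wilcoxon ------------------------------------------------------

class TestBootstrapWilcoxon:
    def test_identical_schemes_not_significant(self):
        y = np.array([0, 1] * 100)
        calls = np.array([0, 1] * 100)
        with pytest.warns(UserWarning, match="zero"):
            res = bootstrap_wilcoxon(calls, calls, y, n_subset=50, m_init=20, seed=0)
        assert res.p_value == 1.0
        assert not res.significant

    def test_known_sensitivity_gap_detected(self):
        """Raters with true sensitivity 0.55 vs 0.35 (same specificity) at
        n=500, subset size 200: the gap must reach significance."""
        rng = np.random.default_rng(7)
        y = (rng.random(500) < 0.5).astype(int)
        a = y.copy()
        b = y.copy()
        pos = np.flatnonzero(y == 1)
        a[pos] = (rng.random(pos.size) < 0.55).astype(int)
        b[pos] = (rng.random(pos.size) < 0.35).astype(int)
        res = bootstrap_wilcoxon(a, b, y, metric="sensitivity",
                                 n_subset=200, m_init=1000, seed=1)
        assert res.significant
        assert res.p_value < 0.05
        assert isinstance(res, BootstrapResult)

    def test_mean_bootstrap_metric_tracks_full_set(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 500)
        a = np.where(rng.random(500) < 0.8, y, 1 - y)
        b = np.where(rng.random(500) < 0.7, y, 1 - y)
        res = bootstrap_wilcoxon(a, b, y, n_subset=200, m_init=200, seed=2)
        assert abs(res.pairs[:, 0].mean() - res.full_a) < 0.01
        assert abs(res.pairs[:, 1].mean() - res.full_b) < 0.01
        assert res.m >= 200

    def test_paired_design_same_indices(self):
        """With identical inputs every paired difference is exactly zero,
        which can only happen if both schemes see the same subsamples."""
        y = np.array([0, 1] * 50)
        calls = 1 - y
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = bootstrap_wilcoxon(calls, calls.copy(), y, n_subset=30,
                                     m_init=15, seed=3)
        assert np.all(res.pairs[:, 0] == res.pairs[:, 1])

    def test_input_validation(self):
        y = np.array([0, 1] * 20)
        with pytest.raises(ValueError, match="repetitions"):
            bootstrap_wilcoxon(y, y, y, m_init=5)
        with pytest.raises(ValueError, match="metric"):
            bootstrap_wilcoxon(y, y, y, metric="f1")
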