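import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import erplearn as el
from conftest import make_pairs
from erplearn.erp import MMN
from erplearn.sequences import DEV_LARGE


def brute_force_auc(scores, labels):
    """Exhaustive pair counting: P(pos > neg) with ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestMakeFeatures:
    def _day_pairs(self, n, day, seed):
        rng = np.random.default_rng(seed)
        dev = rng.normal(size=(n, 4, 176))
        std = rng.normal(size=(n, 4, 176))
        return make_pairs(dev, std, day=day)

    def test_trial_count_and_grid(self):
        feats = el.make_features({1: self._day_pairs(100, 1, 0),
                                  2: self._day_pairs(100, 2, 1)})
        assert feats.data.shape[0] == 200
        assert feats.data.shape[1] == 3
        assert feats.data.shape[2] == 36  # [-100, 600] ms at 50 Hz
        assert np.sum(feats.labels == 1) == 100

    def test_identical_members_give_zero_features(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 4, 176))
        pairs = make_pairs(x, x, day=1)
        feats = el.make_features({1: pairs, 2: self._day_pairs(10, 2, 3)})
        assert np.allclose(feats.data[:10], 0.0, atol=1e-12)

    def test_requires_exactly_two_days(self):
        with pytest.raises(ValueError, match="two days"):
            el.make_features({1: self._day_pairs(5, 1, 0)})


class TestLdaTrain:
    def test_spherical_classes_weight_parallel_to_mean_difference(self):
        rng = np.random.default_rng(0)
        delta = np.array([2.0, -1.0, 0.5])
        X0 = rng.normal(size=(2000, 3))
        X1 = rng.normal(size=(2000, 3)) + delta
        model = el.lda_train(np.vstack([X0, X1]),
                             np.r_[np.zeros(2000), np.ones(2000)].astype(int))
        w = model.weights / np.linalg.norm(model.weights)
        d = delta / np.linalg.norm(delta)
        assert abs(w @ d) > 0.99

    def test_full_shrinkage_gives_mean_difference_exactly(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3)) * np.array([1.0, 5.0, 0.2])
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        model = el.lda_train(X, y, shrinkage=1.0)
        md = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
        S = np.cov(np.vstack([X[y == 0] - X[y == 0].mean(0),
                              X[y == 1] - X[y == 1].mean(0)]).T, bias=True)
        nu = np.trace(S) / 3
        assert np.allclose(model.weights, md / nu, atol=1e-10)

    def test_label_swap_negates_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        y = (rng.uniform(size=30) < 0.5).astype(int)
        y[:2] = [0, 1]
        m1 = el.lda_train(X, y, shrinkage=0.3)
        m2 = el.lda_train(X, 1 - y, shrinkage=0.3)
        assert np.allclose(m1.weights, -m2.weights, atol=1e-10)

    def test_singular_covariance_without_shrinkage_raises(self):
        X = np.zeros((10, 3))
        X[:, 0] = np.arange(10)  # rank-1 features
        y = np.r_[np.zeros(5), np.ones(5)].astype(int)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            el.lda_train(X, y, shrinkage=0.0)

    def test_matches_sklearn_shrunk_lda_direction(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 3)) @ np.array(
            [[1.0, 0.3, 0.0], [0.0, 1.0, 0.2], [0.0, 0.0, 1.0]])
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        X[y == 1] += [0.8, -0.4, 0.2]
        lam = 0.25
        ours = el.lda_train(X, y, shrinkage=lam)
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=lam).fit(X, y)
        ratio = sk.coef_.ravel() / ours.weights
        assert np.allclose(ratio, ratio[0], rtol=1e-6)


class TestAuc:
    def test_perfect_separation(self):
        assert el.auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert el.auc([5.0] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_handcrafted_scores_match_pair_counting(self):
        scores = [0.9, 0.4, 0.6, 0.6, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        assert el.auc(scores, labels) == brute_force_auc(scores, labels)
        assert el.auc(scores, labels) == pytest.approx(7.5 / 9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(-5, 5), st.booleans()),
                    min_size=2, max_size=20))
    def test_rank_auc_equals_brute_force(self, pairs):
        labels = [int(b) for _, b in pairs]
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        scores = [float(s) for s, _ in pairs]
        assert el.auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-3, 3, allow_nan=False), st.booleans()),
                    min_size=2, max_size=15))
    def test_label_flip_antisymmetry(self, pairs):
        labels = [int(b) for _, b in pairs]
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        scores = [s for s, _ in pairs]
        flipped = [1 - y for y in labels]
        assert el.auc(scores, labels) + el.auc(scores, flipped) == \
            pytest.approx(1.0, abs=1e-12)


class TestTemporalDecoding:
    def _features(self, X, y):
        return el.FeatureTensor(data=X, labels=np.asarray(y),
                                times_ms=np.arange(X.shape[2], dtype=float))

    def test_null_data_decodes_at_chance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(160, 3, 12))
        y = np.r_[np.ones(80), 2 * np.ones(80)]
        curve = el.temporal_decoding(self._features(X, y), repeats=20, seed=1)
        assert abs(curve.auc_per_timepoint.mean() - 0.5) < 0.03

    def test_strong_separation_localized_in_time(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 3, 10))
        y = np.r_[np.ones(60), 2 * np.ones(60)]
        X[y == 2, :, 4] += 10.0  # 10 sigma at timepoint 4 only
        curve = el.temporal_decoding(self._features(X, y), repeats=10, seed=2)
        assert curve.auc_per_timepoint[4] > 0.99
        others = np.delete(curve.auc_per_timepoint, 4)
        # finite-sample fluctuation at n=120 trials is ~0.1 per timepoint
        assert np.all(np.abs(others - 0.5) < 0.15)
        assert abs(np.mean(others) - 0.5) < 0.05

    def test_day_relabelling_leaves_curve_invariant(self):
        """Swapping which day is called 'positive' flips both the class
        coding and the discriminant direction, so the AUC curve is a
        symmetry invariant (the score-level flip antisymmetry is checked in
        TestAuc)."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 3, 6))
        X[50:, :, 2] += 1.0
        y = np.r_[np.ones(50), 2 * np.ones(50)]
        c1 = el.temporal_decoding(self._features(X, y), repeats=60, seed=3)
        c2 = el.temporal_decoding(self._features(X, 3 - y), repeats=60, seed=3)
        assert np.allclose(c1.auc_per_timepoint, c2.auc_per_timepoint,
                           atol=0.05)

    def test_too_few_trials_per_class_raises(self):
        X = np.zeros((7, 3, 4))
        y = np.r_[np.ones(3), 2 * np.ones(4)]
        with pytest.raises(ValueError, match="stratify"):
            el.temporal_decoding(self._features(X, y), folds=5)

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3, 5))
        y = np.r_[np.ones(30), 2 * np.ones(30)]
        c1 = el.temporal_decoding(self._features(X, y), repeats=5, seed=9)
        c2 = el.temporal_decoding(self._features(X, y), repeats=5, seed=9)
        assert np.array_equal(c1.auc_per_timepoint, c2.auc_per_timepoint)


class TestWindowMeanAuc:
    def _curve(self, aucs, times):
        return el.DecodingCurve(auc_per_timepoint=np.asarray(aucs, float),
                                times_ms=np.asarray(times, float),
                                participant="sub-01", comparison=(1, 2))

    def test_constant_curve(self):
        c = self._curve([0.7] * 10, np.arange(10) * 20.0)
        win = el.AnalysisWindow(MMN, 40.0, 120.0, 80.0)
        assert el.window_mean_auc(c, win) == pytest.approx(0.7)

    def test_single_timepoint_window(self):
        c = self._curve([0.5, 0.9, 0.5], [0.0, 20.0, 40.0])
        win = el.AnalysisWindow(MMN, 20.0, 20.0, 20.0)
        assert el.window_mean_auc(c, win) == 0.9

    def test_hand_built_mean(self):
        c = self._curve([0.4, 0.6, 0.8, 1.0], [0.0, 20.0, 40.0, 60.0])
        win = el.AnalysisWindow(MMN, 20.0, 60.0, 40.0)
        assert el.window_mean_auc(c, win) == pytest.approx((0.6 + 0.8 + 1.0) / 3)


class TestGroupPermutationTtest:
    def test_exhaustive_enumeration_exact_p(self):
        # 4 strictly positive centred values: only the identity flip reaches t
        stat = el.group_permutation_ttest(
            np.array([0.6, 0.62, 0.55, 0.58]), n_perm=10_000)
        assert stat.exhaustive
        assert stat.p == pytest.approx(1 / 16)

    def test_symmetric_values_give_p_half(self):
        vals = 0.5 + np.array([-0.04, -0.02, 0.02, 0.04])
        stat = el.group_permutation_ttest(vals)
        assert 0.3 < stat.p <= 0.7

    def test_bonferroni(self):
        vals = np.array([0.6, 0.62, 0.55, 0.58])
        s1 = el.group_permutation_ttest(vals, m_comparisons=1)
        s3 = el.group_permutation_ttest(vals, m_comparisons=3)
        assert s1.p_adjusted == s1.p
        assert s3.p_adjusted == pytest.approx(3 * s3.p)
        assert s3.p_adjusted >= s3.p

    def test_adjusted_p_capped_at_one(self):
        vals = 0.5 + np.array([-0.1, 0.1, -0.1, 0.1])
        stat = el.group_permutation_ttest(vals, m_comparisons=3)
        assert stat.p_adjusted <= 1.0

    def test_too_few_participants(self):
        with pytest.raises(ValueError, match="at least 2"):
            el.group_permutation_ttest(np.array([0.6]))

    def test_monte_carlo_path_close_to_exhaustive(self):
        rng = np.random.default_rng(0)
        vals = 0.5 + rng.normal(0.02, 0.03, size=15)  # 2^15 > 10,000
        stat = el.group_permutation_ttest(vals, n_perm=10_000, seed=1)
        assert not stat.exhaustive
        from scipy import stats as sps
        t, p_t = sps.ttest_1samp(vals, 0.5, alternative="greater")
        assert stat.p == pytest.approx(p_t, abs=0.02)


def test_decoding_on_simulated_days_with_day_effect(small_study_pairs):
    """Days that differ in component amplitude should decode above chance in
    the component window; a same-day split should not."""
    p1 = {d: small_study_pairs[("sub-01", d)] for d in (1, 2)}
    feats = el.make_features(p1, deviant_type=DEV_LARGE)
    curve = el.temporal_decoding(feats, repeats=20, seed=0)
    assert curve.auc_per_timepoint.shape == feats.times_ms.shape
    assert np.all((curve.auc_per_timepoint >= 0) &
                  (curve.auc_per_timepoint <= 1))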