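"""Scale selection, SVM, repeated CV and the alpha sweep."""

import numpy as np
import pytest

import pafentropy as pe
from pafentropy.exceptions import DegenerateTrainingError, ParameterError

from conftest import gaussian_features


class TestPerScaleTtest:
    def test_planted_scales_recovered(self):
        hits = 0
        for seed in range(100):
            fm = gaussian_features(shifted_scales=(2, 6, 8), shift=2.0,
                                   seed=seed)
            if pe.per_scale_ttest(fm).chosen == (2, 6, 8):
                hits += 1
        assert hits >= 95

    def test_single_shifted_scale_always_chosen(self):
        for seed in range(100):
            fm = gaussian_features(shifted_scales=(5,), shift=2.0, seed=seed)
            assert 5 in pe.per_scale_ttest(fm).chosen

    def test_exactly_three_returned_under_null(self):
        fm = gaussian_features(seed=0)
        with pytest.warns(UserWarning):
            sel = pe.per_scale_ttest(fm)
        assert len(sel.chosen) == 3
        assert all(1 <= j <= 8 for j in sel.chosen)

    def test_zero_variance_scale_gets_p_one(self):
        fm = gaussian_features(shifted_scales=(3,), seed=1)
        fm.X[:, 0] = 0.0
        with pytest.warns(UserWarning, match="zero variance"):
            sel = pe.per_scale_ttest(fm)
        assert sel.p_values[0] == 1.0


class TestFitSvm:
    def test_separable_blobs_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-5, 1, (30, 2)), rng.normal(5, 1, (30, 2))])
        y = np.r_[-np.ones(30), np.ones(30)].astype(int)
        fm = pe.FeatureMatrix(X, y, [str(i) for i in range(60)], ["a", "b"])
        model = pe.fit_svm(fm)
        assert np.array_equal(model.predict(X), y)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-2, 1, (20, 3)), rng.normal(2, 1, (20, 3))])
        y = np.r_[-np.ones(20), np.ones(20)].astype(int)
        ids = [str(i) for i in range(40)]
        m1 = pe.fit_svm(pe.FeatureMatrix(X, y, ids, list("abc")))
        m2 = pe.fit_svm(pe.FeatureMatrix(X, -y, ids, list("abc")))
        assert np.array_equal(m1.predict(X), -m2.predict(X))

    def test_symmetric_pair_margin_midpoint(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1, 1])
        model = pe.fit_svm(pe.FeatureMatrix(X, y, ["a", "b"], ["x"]), C=1e6)
        assert model.predict(X).tolist() == [-1, 1]
        # decision function vanishes at the midpoint
        z = model.scaler.transform([[0.0]])
        assert abs(model.svc.decision_function(z)[0]) < 1e-6

    def test_single_class_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(DegenerateTrainingError):
            pe.fit_svm(pe.FeatureMatrix(X, np.ones(5, dtype=int),
                                        list("abcde"), ["u", "v"]))


class TestConfusionMetrics:
    @pytest.mark.parametrize("tp,fn,tn,fp,expected", [
        (94, 6, 90, 10, (92.0, 94.0, 90.0)),
        (45, 5, 45, 5, (90.0, 90.0, 90.0)),
        (10, 0, 20, 0, (100.0, 100.0, 100.0)),
    ])
    def test_formulas(self, tp, fn, tn, fp, expected):
        c = pe.ConfusionCounts(TP=tp, FN=fn, TN=tn, FP=fp)
        assert pe.confusion_metrics(c) == pytest.approx(expected)

    def test_undefined_metrics(self):
        with pytest.raises(ParameterError):
            pe.confusion_metrics(pe.ConfusionCounts(TP=0, FN=0, TN=5, FP=5))
        with pytest.raises(ParameterError):
            pe.confusion_metrics(pe.ConfusionCounts(TP=5, FN=5, TN=0, FP=0))


class TestRepeatedCV:
    def test_separable_classes_near_perfect(self):
        fm = gaussian_features(shifted_scales=(1, 2, 3), shift=10.0, seed=0)
        rep = pe.repeated_cv(fm, repeats=10, seed=0)
        assert rep.mean_correct_rate >= 99.0

    def test_deterministic_under_seed(self):
        fm = gaussian_features(shifted_scales=(2,), shift=1.0, seed=5)
        r1 = pe.repeated_cv(fm, repeats=5, seed=11)
        r2 = pe.repeated_cv(fm, repeats=5, seed=11)
        np.testing.assert_array_equal(r1.correct_rate, r2.correct_rate)
        np.testing.assert_array_equal(r1.sensitivity, r2.sensitivity)

    def test_metrics_identity(self):
        """correct rate == (sens*P + spec*N)/(P+N) for every repeat."""
        fm = gaussian_features(shifted_scales=(4,), shift=1.5, seed=2)
        rep = pe.repeated_cv(fm, repeats=10, seed=3)
        P = N = 25  # balanced pooled folds evaluate every record once
        combo = (rep.sensitivity * P + rep.specificity * N) / (P + N)
        np.testing.assert_allclose(rep.correct_rate, combo, atol=1e-9)

    def test_per_fold_selection_avoids_leakage_optimism(self):
        """On label-free (pure noise) features the per-fold protocol stays
        at chance, while selecting scales once on all data - the leaky
        variant - is optimistically biased above it."""
        per_fold, global_sel = [], []
        for seed in range(5):
            fm = gaussian_features(seed=seed)
            per_fold.append(pe.repeated_cv(
                fm, repeats=10, seed=1).mean_correct_rate)
            with pytest.warns(UserWarning):
                global_sel.append(pe.repeated_cv(
                    fm, repeats=10, seed=1,
                    global_selection=True).mean_correct_rate)
        assert 40.0 <= np.mean(per_fold) <= 60.0
        assert np.mean(global_sel) > np.mean(per_fold)

    def test_fold_count_validated(self):
        fm = gaussian_features(n_per_class=3, seed=0)
        with pytest.raises(ParameterError):
            pe.repeated_cv(fm, folds=5, repeats=2, seed=0)

    def test_monotone_degradation_to_chance(self):
        """Accuracy decays (within noise) as the planted effect shrinks,
        reaching chance at zero effect."""
        accs = []
        for shift in (2.0, 1.0, 0.5, 0.0):
            fm = gaussian_features(shifted_scales=(2, 6, 8), shift=shift,
                                   seed=9)
            accs.append(pe.repeated_cv(fm, repeats=10,
                                       seed=4).mean_correct_rate)
        for hi, lo in zip(accs, accs[1:]):
            assert lo <= hi + 2.0
        assert 35.0 <= accs[-1] <= 65.0


@pytest.fixture(scope="module")
def small_signals():
    records = pe.make_benchmark(6, 0, 6, seed=3, duration_s=200)
    return [pe.resample_uniform(pe.clean_rr(r)) for r in records]


class TestAlphaSweep:
    def test_grid_and_argmax_contract(self, small_signals):
        res = pe.sweep_alpha(small_signals, "PAF", 0.5, 2.0, 0.5,
                             folds=3, repeats=2, seed=0)
        np.testing.assert_allclose(res.grid, [0.5, 1.0, 1.5, 2.0])
        assert res.correct_rate_mean[
            np.flatnonzero(res.grid == res.best_alpha)[0]] == max(
            res.correct_rate_mean)

    def test_alpha_one_via_shannon_limit(self, small_signals):
        res = pe.sweep_alpha(small_signals, "PAF", 0.9, 1.1, 0.1,
                             folds=3, repeats=2, seed=0)
        assert 1.0 in res.grid.tolist()
        assert np.all(np.isfinite(res.correct_rate_mean))

    def test_deterministic_curves(self, small_signals):
        a = pe.sweep_alpha(small_signals, "PAF", 0.5, 1.5, 0.5,
                           folds=3, repeats=2, seed=8)
        b = pe.sweep_alpha(small_signals, "PAF", 0.5, 1.5, 0.5,
                           folds=3, repeats=2, seed=8)
        np.testing.assert_array_equal(a.correct_rate_mean,
                                      b.correct_rate_mean)
        np.testing.assert_array_equal(a.specificity_std, b.specificity_std)

    def test_empty_grid_rejected(self, small_signals):
        with pytest.raises(ParameterError):
            pe.sweep_alpha(small_signals, "PAF", 0.0, 1.0, 0.1)
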