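"""Probability filtering, first-order statistics, feature selection and
the patient-level random forest."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from dwiprost.aggregation import (PatientClassifier, ProbabilitySetPair,
                                  SelectedFeatures, collect_probability_sets,
                                  extract_patient_features, feature_names,
                                  filter_top_k, first_order_features,
                                  fit_feature_selector, fit_patient_classifier,
                                  predict_patient)
from dwiprost.slice_model import SliceProbability


class TestCollect:
    def test_complement_sets(self):
        sps = [SliceProbability("p", j, p, 1 - p)
               for j, p in enumerate([0.9, 0.2, 0.5])]
        pair = collect_probability_sets(sps, cnn_index=2)
        assert pair.cnn_index == 2
        assert np.allclose(pair.P, [0.9, 0.2, 0.5])
        assert np.allclose(pair.N, [0.1, 0.8, 0.5])

    def test_singleton(self):
        pair = collect_probability_sets([SliceProbability("p", 0, 0.7, 0.3)])
        assert pair.P.size == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            collect_probability_sets([])

    def test_ordered_by_slice_index(self):
        sps = [SliceProbability("p", 2, 0.3, 0.7),
               SliceProbability("p", 0, 0.1, 0.9),
               SliceProbability("p", 1, 0.2, 0.8)]
        pair = collect_probability_sets(sps)
        assert np.allclose(pair.P, [0.1, 0.2, 0.3])

    def test_inconsistent_complement_rejected(self):
        with pytest.raises(ValueError):
            ProbabilitySetPair(0, "p", np.array([0.9]), np.array([0.5]))


class TestFilterTopK:
    def test_cutoff_rule(self):
        out = filter_top_k(np.array([0.9, 0.8, 0.76, 0.75, 0.73, 0.70]))
        assert np.allclose(out, [0.9, 0.8, 0.76, 0.75])

    def test_truncation_to_k(self):
        out = filter_top_k(np.array([0.99, 0.98, 0.97, 0.96, 0.95, 0.94]))
        assert np.allclose(out, [0.99, 0.98, 0.97, 0.96, 0.95])

    def test_fallback_to_single_maximum(self):
        out = filter_top_k(np.array([0.1, 0.2, 0.3]))
        assert np.allclose(out, [0.3])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_subset_descending_bounded(self, probs):
        arr = np.array(probs)
        out = filter_top_k(arr)
        assert out.size <= 5
        assert all(np.isin(out, arr))
        assert np.all(np.diff(out) <= 0)


class TestFirstOrderFeatures:
    def test_constant_set(self):
        f = first_order_features(np.array([0.8, 0.8, 0.8]), np.array([0.2, 0.2]))
        mean, std, var, median, total, mx, skew, kurt, rng_ = f[:9]
        assert np.isclose(mean, 0.8)
        assert np.isclose(std, 0, atol=1e-7) and np.isclose(var, 0, atol=1e-12)
        assert np.isclose(median, 0.8) and np.isclose(total, 2.4)
        assert np.isclose(mx, 0.8) and skew == 0 and kurt == 0 and rng_ == 0

    def test_worked_example(self):
        p = np.array([0.75, 0.80, 0.97])
        f = first_order_features(p, np.array([0.5]))
        assert np.isclose(f[0], 0.84)       # mean
        assert np.isclose(f[4], 2.52)       # sum
        assert np.isclose(f[5], 0.97)       # max
        assert np.isclose(f[8], 0.22)       # range
        # skew/kurt from the raw-moment oracle (population convention)
        m2 = ((p - p.mean()) ** 2).mean()
        m3 = ((p - p.mean()) ** 3).mean()
        m4 = ((p - p.mean()) ** 4).mean()
        assert np.isclose(f[6], m3 / m2**1.5)
        assert np.isclose(f[7], m4 / m2**2 - 3)

    def test_pca_takes_max_non_takes_min(self):
        f = first_order_features(np.array([0.8, 0.9]), np.array([0.1, 0.3]))
        assert np.isclose(f[5], 0.9)   # PCa block extremum = max
        assert np.isclose(f[14], 0.1)  # non-PCa block extremum = min

    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=5))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_statistics_match_scipy_oracle(self, vals):
        x = np.array(vals)
        f = first_order_features(x, x)[:9]
        assert np.isclose(f[0], x.mean(), atol=1e-10)
        assert np.isclose(f[1], x.std(), atol=1e-10)
        assert np.isclose(f[2], x.var(), atol=1e-10)
        assert np.isclose(f[3], np.median(x), atol=1e-10)
        assert np.isclose(f[4], x.sum(), atol=1e-10)
        if x.var() > 1e-6:  # skew/kurt are unstable near zero variance
            assert np.isclose(f[6], scipy.stats.skew(x, bias=True), atol=1e-8)
            assert np.isclose(f[7], scipy.stats.kurtosis(x, fisher=True, bias=True),
                              atol=1e-8)


class TestExtractPatientFeatures:
    def _pairs(self, n_cnns, rng):
        out = []
        for k in range(n_cnns):
            p = rng.uniform(0.01, 0.99, 7)
            out.append(ProbabilitySetPair(k, "pt", p, 1 - p))
        return out

    def test_five_cnns_give_90_named_features(self, rng):
        feats = extract_patient_features(self._pairs(5, rng))
        assert feats.shape == (90,)
        assert len(feature_names(5)) == 90
        assert np.isfinite(feats).all()

    def test_single_cnn_gives_18(self, rng):
        feats = extract_patient_features(self._pairs(1, rng), n_cnns=1)
        assert feats.shape == (18,)

    def test_slice_order_invariance(self, rng):
        p = rng.uniform(0.01, 0.99, 9)
        a = extract_patient_features([ProbabilitySetPair(0, "x", p, 1 - p)], n_cnns=1)
        perm = rng.permutation(p)
        b = extract_patient_features([ProbabilitySetPair(0, "x", perm, 1 - perm)],
                                     n_cnns=1)
        assert np.allclose(a, b, atol=1e-12)

    def test_missing_member_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_patient_features(self._pairs(4, rng), n_cnns=5)


class TestFeatureSelector:
    def test_planted_signal_recovered(self, rng):
        n = 60
        y = np.arange(n) % 2
        x = rng.normal(size=(n, 12))
        x[:, 0] = y + 0.1 * rng.normal(size=n)  # only feature 0 informative
        sel = fit_feature_selector(x, y, n_folds=10, seed=0)
        assert sel.indices[0] == 0

    def test_constant_features_keep_top_one(self):
        x = np.ones((20, 5))
        y = np.arange(20) % 2
        sel = fit_feature_selector(x, y, n_folds=5, seed=0)
        assert sel.indices.size == 1

    def test_fixed_k_override(self, rng):
        x = rng.normal(size=(40, 10))
        y = np.arange(40) % 2
        sel = fit_feature_selector(x, y, n_folds=5, seed=0, n_keep=3)
        assert sel.indices.size == 3

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_feature_selector(rng.normal(size=(10, 3)), np.zeros(10), n_folds=2)

    def test_too_many_folds_rejected(self, rng):
        x = rng.normal(size=(6, 3))
        y = np.arange(6) % 2
        with pytest.raises(ValueError):
            fit_feature_selector(x, y, n_folds=10)


class TestPatientClassifier:
    def test_separable_features_perfect_training_accuracy(self, rng):
        n = 30
        y = np.arange(n) % 2
        x = rng.normal(size=(n, 4))
        x[:, 1] = 3.0 * y + 0.05 * rng.normal(size=n)
        clf = fit_patient_classifier(x, y, n_folds=5, seed=0)
        preds = (np.atleast_1d(predict_patient(clf, x)) > 0.5).astype(int)
        assert (preds == y).all()

    def test_label_permuted_null_auc_near_half(self, rng):
        from sklearn.metrics import roc_auc_score
        n = 100
        x = rng.normal(size=(n, 6))
        aucs = []
        for b in range(5):
            y = rng.permutation(np.arange(n) % 2)
            clf = fit_patient_classifier(x[: n // 2], y[: n // 2], n_folds=5, seed=b)
            scores = np.atleast_1d(predict_patient(clf, x[n // 2:]))
            aucs.append(roc_auc_score(y[n // 2:], scores))
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_identical_seed_identical_predictions(self, rng):
        x = rng.normal(size=(20, 5))
        y = np.arange(20) % 2
        c1 = fit_patient_classifier(x, y, n_folds=4, seed=9)
        c2 = fit_patient_classifier(x, y, n_folds=4, seed=9)
        assert np.array_equal(np.atleast_1d(predict_patient(c1, x)),
                              np.atleast_1d(predict_patient(c2, x)))

    def test_probability_in_unit_interval_and_argmax_consistency(self, rng):
        x = rng.normal(size=(16, 3))
        y = np.arange(16) % 2
        clf = fit_patient_classifier(x, y, n_folds=4, seed=0)
        p = np.atleast_1d(predict_patient(clf, x))
        assert np.all((p >= 0) & (p <= 1))
        ties = p == 0.5
        preds = clf.forest.predict(x[:, clf.selected.indices])
        assert np.array_equal(preds[~ties], (p[~ties] > 0.5).astype(int))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_patient_classifier(rng.normal(size=(8, 2)), np.ones(8))

    def test_wrong_dimensionality_rejected(self, rng):
        x = rng.normal(size=(12, 90))
        y = np.arange(12) % 2
        sel = SelectedFeatures(indices=np.array([5, 80]), importances=np.ones(2))
        clf = fit_patient_classifier(x, y, selected=sel, n_folds=3, seed=0)
        with pytest.raises(ValueError):
            predict_patient(clf, np.zeros(7))
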