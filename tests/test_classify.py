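import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from aphasiamap import (
    AphasiaClassifier,
    fit_binary_logistic,
    fit_multinomial,
    permutation_chance,
)


class TestBinaryLogistic:
    def test_separable_clusters_reach_full_accuracy_with_flag(self, rng):
        X = np.r_[rng.normal(0, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))]
        y = ["a"] * 20 + ["b"] * 20
        res = fit_binary_logistic(X, y)
        assert res.accuracy == 100.0 and res.separation

    def test_constant_predictor_predicts_majority_class(self):
        y = ["fluent"] * 33 + ["nonfluent"] * 37
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_binary_logistic(np.ones((70, 1)), y)
        assert res.accuracy == pytest.approx(100 * 37 / 70, abs=1e-9)
        assert set(res.predicted) == {"nonfluent"}

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_binary_logistic(rng.normal(size=(10, 2)), ["a"] * 10)

    def test_wald_pvalues_reported(self, rng):
        X = rng.normal(size=(80, 2))
        logit = 1.5 * X[:, 0]
        y = (rng.random(80) < 1 / (1 + np.exp(-logit))).astype(int)
        res = fit_binary_logistic(X, y)
        assert res.coef_pvalues.iloc[1, 0] < 0.05  # slope term

    def test_confusion_marginals(self, rng):
        X = rng.normal(size=(50, 2))
        y = rng.choice(["a", "b"], 50)
        res = fit_binary_logistic(X, y)
        true_counts = pd.Series(y).value_counts()
        assert (res.confusion.sum(axis=1)[true_counts.index] == true_counts).all()
        assert res.confusion.to_numpy().trace() / 50 * 100 == pytest.approx(res.accuracy)

    def test_accuracy_invariant_to_label_renaming(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.choice(["a", "b"], 40)
        renamed = np.where(y == "a", "zzz", "qqq")
        r1 = fit_binary_logistic(X, y)
        r2 = fit_binary_logistic(X, renamed)
        assert r1.accuracy == pytest.approx(r2.accuracy)


class TestMultinomial:
    def test_well_separated_clusters_fully_classified(self, rng):
        centres = np.arange(7)[:, None] * 8.0
        X = np.concatenate([rng.normal(c, 0.3, size=(8, 2)) for c in centres])
        y = np.repeat([f"c{i}" for i in range(7)], 8)
        res = fit_multinomial(X, y)
        assert res.accuracy == 100.0

    def test_two_class_reduction_matches_binary(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.choice(["x", "y"], 60)
        rb = fit_binary_logistic(X, y)
        rm = fit_multinomial(X, y)
        assert abs(rb.accuracy - rm.accuracy) < 1e-6
        assert np.array_equal(rb.predicted, rm.predicted)

    def test_tiny_class_warns_but_fits(self, rng):
        X = rng.normal(size=(30, 2))
        y = ["a"] * 15 + ["b"] * 14 + ["c"]
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = fit_multinomial(X, y)
        assert res.n == 30

    def test_confusion_column_sums_are_predicted_counts(self, rng):
        X = rng.normal(size=(60, 2))
        y = rng.choice(["a", "b", "c"], 60)
        res = fit_multinomial(X, y)
        pred_counts = pd.Series(res.predicted).value_counts()
        for c in res.classes:
            assert res.confusion[c].sum() == pred_counts.get(c, 0)


class TestPermutationChance:
    def test_observed_above_all_nulls_gives_minimal_p(self, rng):
        X = np.r_[rng.normal(0, 0.3, (15, 2)), rng.normal(5, 0.3, (15, 2))]
        y = ["a"] * 15 + ["b"] * 15
        _, p, _ = permutation_chance(X, y, n_iter=100, rng_seed=0)
        assert p == pytest.approx(1 / 101)

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.choice(["a", "b"], 30)
        a = permutation_chance(X, y, n_iter=100, rng_seed=7)
        b = permutation_chance(X, y, n_iter=100, rng_seed=7)
        assert np.array_equal(a[2], b[2]) and a[0] == b[0]

    def test_balanced_noise_mean_chance_at_least_majority(self, rng):
        X = rng.normal(size=(20, 2))
        y = ["a"] * 10 + ["b"] * 10
        mean_chance, _, null = permutation_chance(X, y, n_iter=150, rng_seed=1)
        assert mean_chance >= 50.0  # in-sample optimism floor

    def test_matches_brute_force_refit_loop(self, rng):
        # oracle: explicit statsmodels Logit refits on the same permutations
        X = rng.normal(size=(20, 2))
        y = np.array(["a"] * 11 + ["b"] * 9)
        _, _, null = permutation_chance(X, y, n_iter=100, rng_seed=3)
        rng2 = np.random.default_rng(3)
        codes = (y == "b").astype(int)
        Xc = sm.add_constant(X)
        for i in range(5):
            yp = rng2.permutation(codes)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(yp, Xc).fit(disp=0, maxiter=200)
                acc = 100.0 * ((np.asarray(res.predict(Xc)) >= 0.5) == yp).mean()
            assert null[i] == pytest.approx(acc, abs=1e-6)

    def test_shuffled_labels_fall_in_null_band(self, rng):
        X = rng.normal(size=(70, 4))
        y = rng.permutation(["f"] * 33 + ["n"] * 37)
        res = AphasiaClassifier(X, y).fit(permutations=200, rng_seed=0)
        lo, hi = np.quantile(res.null_accuracies, [0.025, 0.975])
        assert lo - 1e-9 <= res.accuracy <= hi + 1e-9 or res.permutation_p > 0.05


class TestAphasiaClassifier:
    def test_auto_selects_multinomial_for_many_classes(self, medium_cohort):
        pred = pd.DataFrame(
            {
                "LV": 100
                * medium_cohort.lesions.flat().mean(axis=1),
                "age": medium_cohort.demographics["age"].to_numpy(),
            }
        )
        res = AphasiaClassifier(pred, medium_cohort.subtype).fit()
        assert "multinomial" in res.model
        assert 0 <= res.accuracy <= 100

    def test_cross_validated_accuracy_not_above_insample_typically(self, medium_cohort):
        pred = pd.DataFrame(
            {"LV": 100 * medium_cohort.lesions.flat().mean(axis=1),
             "age": medium_cohort.demographics["age"].to_numpy()}
        )
        labels = medium_cohort.fluency.map({True: "f", False: "n"})
        ins = AphasiaClassifier(pred, labels).fit()
        cv = AphasiaClassifier(pred, labels).fit(cv=5, rng_seed=0)
        assert cv.accuracy <= ins.accuracy + 10.0  # CV should not beat in-sample by much
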