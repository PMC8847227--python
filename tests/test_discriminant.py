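"""rLDA against a textbook-LDA oracle; validation protocol contracts."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hempspec.discriminant import (
    DELTA_RANGE,
    GAMMA_RANGE,
    RLDAHyperparams,
    cv_error,
    fisher_lsd,
    pooled_confusion,
    repeated_holdout,
    rlda_fit,
    rlda_predict,
    standardize_apply,
    standardize_fit,
    tune_hyperparameters,
)


def textbook_lda_predict(X_train, y_train, X_test):
    """Direct textbook LDA: pooled covariance solve, Gaussian scores."""
    classes = np.array(sorted(set(y_train.tolist())))
    n, p = X_train.shape
    means = np.vstack([X_train[y_train == c].mean(axis=0) for c in classes])
    S = np.zeros((p, p))
    for i, c in enumerate(classes):
        d = X_train[y_train == c] - means[i]
        S += d.T @ d
    S /= n - len(classes)
    Sinv = np.linalg.inv(S)
    priors = np.array([(y_train == c).mean() for c in classes])
    scores = (
        X_test @ Sinv @ means.T
        - 0.5 * np.einsum("kp,pq,kq->k", means, Sinv, means)
        + np.log(priors)
    )
    return classes[np.argmax(scores, axis=1)]


def _toy_problem(seed, n=60, p=5, k=3, sd=1.0, sep=2.0):
    r = np.random.default_rng(seed)
    means = r.normal(0, sep, (k, p))
    X = np.vstack([r.normal(means[i], sd, (n // k, p)) for i in range(k)])
    y = np.repeat([f"c{i}" for i in range(k)], n // k)
    return X, y, means


class TestStandardization:
    def test_transformed_columns_zero_mean_unit_variance(self, rng):
        X = rng.normal(3, 2, (40, 6))
        params = standardize_fit(X)
        Z = standardize_apply(params, X)
        assert np.all(np.abs(Z.mean(axis=0)) < 1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0)

    def test_training_mean_row_maps_to_zero(self, rng):
        X = rng.normal(size=(20, 4))
        params = standardize_fit(X)
        np.testing.assert_allclose(standardize_apply(params, X.mean(axis=0)), 0.0, atol=1e-12)

    def test_constant_column_floored_to_zeros(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="floored"):
            params = standardize_fit(X)
        Z = standardize_apply(params, X)
        np.testing.assert_array_equal(Z[:, 1], 0.0)


class TestRLDA:
    def test_equals_textbook_lda_at_zero_regularization(self):
        # Oracle equivalence on 20 random full-rank instances.
        for seed in range(20):
            X, y, _ = _toy_problem(seed)
            r = np.random.default_rng(1000 + seed)
            X_test = r.normal(0, 2, (40, X.shape[1]))
            model = rlda_fit(X, y, RLDAHyperparams(gamma=0.0, delta=0.0))
            np.testing.assert_array_equal(
                rlda_predict(model, X_test), textbook_lda_predict(X, y, X_test)
            )

    def test_huge_delta_scores_by_priors_alone(self):
        X, y, _ = _toy_problem(3, n=60, k=3)
        y = y.copy()
        y[y == "c2"] = "c1"  # make class sizes unequal: c1 is largest
        model = rlda_fit(X, y, RLDAHyperparams(gamma=0.005, delta=1e9))
        assert np.all(model.coefficients == 0)
        pred = rlda_predict(model, np.random.default_rng(0).normal(size=(10, 5)))
        assert set(pred.tolist()) == {"c1"}

    def test_separable_training_accuracy_is_one(self):
        r = np.random.default_rng(5)
        X = np.vstack([r.normal(0, 1, (30, 4)), r.normal(0, 1, (30, 4))])
        X[30:, 0] += 10.0  # means +/- 5 sd on one feature
        y = np.array(["a"] * 30 + ["b"] * 30)
        model = rlda_fit(X, y, RLDAHyperparams(0.0, 0.0))
        assert np.mean(rlda_predict(model, X) == y) == 1.0

    def test_class_mean_classified_to_its_class(self):
        X, y, _ = _toy_problem(7, sep=5.0)
        model = rlda_fit(X, y, RLDAHyperparams(0.0, 0.0))
        for i, c in enumerate(model.classes):
            assert rlda_predict(model, model.means[i])[0] == c

    def test_tie_broken_alphabetically(self):
        # Symmetric two-class problem scored at the exact midpoint.
        X = np.array([[-1.0, 0.0], [-1.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array(["b", "b", "a", "a"])
        model = rlda_fit(X, y, RLDAHyperparams(0.0, 0.0))
        assert rlda_predict(model, np.array([[0.0, 0.5]]))[0] == "a"

    def test_batch_equals_rowwise(self):
        X, y, _ = _toy_problem(11)
        model = rlda_fit(X, y, RLDAHyperparams(0.005, 0.01))
        X_test = np.random.default_rng(2).normal(size=(15, 5))
        batch = rlda_predict(model, X_test)
        rows = np.array([rlda_predict(model, row)[0] for row in X_test])
        np.testing.assert_array_equal(batch, rows)

    def test_singular_covariance_handled_at_gamma_zero(self):
        # n <= p: pooled covariance singular; the ridge floor must keep the
        # solve finite and the model usable.
        r = np.random.default_rng(4)
        X = r.normal(size=(20, 50))
        X[10:, :5] += 6.0
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = rlda_fit(X, y, RLDAHyperparams(gamma=0.0, delta=0.0))
        assert np.all(np.isfinite(model.coefficients))
        assert np.mean(rlda_predict(model, X) == y) == 1.0

    def test_class_with_single_row_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="< 2 rows"):
            rlda_fit(X, y, RLDAHyperparams(0.0, 0.0))

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(0, 1000))
    def test_sparsity_monotone_in_delta(self, seed):
        X, y, _ = _toy_problem(seed, n=40, p=8, k=2)
        deltas = [0.0, 0.05, 0.2, 1.0, 5.0]
        nonzeros = [
            int((rlda_fit(X, y, RLDAHyperparams(0.0, d)).coefficients != 0).sum())
            for d in deltas
        ]
        assert all(a >= b for a, b in zip(nonzeros, nonzeros[1:]))


class TestCVError:
    def test_separable_data_zero_error(self):
        r = np.random.default_rng(6)
        X = np.vstack([r.normal(0, 0.5, (30, 4)), r.normal(6, 0.5, (30, 4))])
        y = np.array(["a"] * 30 + ["b"] * 30)
        assert cv_error(X, y, RLDAHyperparams(0.001, 0.001), seed=0) == 0.0

    def test_random_labels_near_chance(self):
        r = np.random.default_rng(8)
        X = r.normal(size=(200, 6))
        y = np.array(["a", "b"] * 100)
        err = cv_error(X, y, RLDAHyperparams(0.005, 0.01), seed=1)
        assert 0.4 <= err <= 0.6  # 3-sigma binomial band around 0.5 at n=200

    def test_same_seed_same_error(self):
        X, y, _ = _toy_problem(9, n=60, sep=0.5)
        p = RLDAHyperparams(0.002, 0.1)
        assert cv_error(X, y, p, seed=3) == cv_error(X, y, p, seed=3)

    def test_folds_degrade_gracefully_for_small_classes(self):
        X, y, _ = _toy_problem(10, n=12, k=2)  # 6 per class < 10 folds
        err = cv_error(X, y, RLDAHyperparams(0.0, 0.0), k=10, seed=0)
        assert 0.0 <= err <= 1.0


class TestTuning:
    def test_result_within_declared_ranges(self):
        X, y, _ = _toy_problem(12, n=40, sep=1.0)
        for strategy in ("bayes", "grid"):
            res = tune_hyperparameters(X, y, budget=12, seed=0, strategy=strategy)
            assert GAMMA_RANGE[0] <= res.params.gamma <= GAMMA_RANGE[1]
            assert DELTA_RANGE[0] <= res.params.delta <= DELTA_RANGE[1]
            assert len(res.trajectory) == 12

    def test_separable_data_reaches_zero_cv_error(self):
        r = np.random.default_rng(13)
        X = np.vstack([r.normal(0, 0.5, (40, 4)), r.normal(8, 0.5, (40, 4))])
        y = np.array(["a"] * 40 + ["b"] * 40)
        res = tune_hyperparameters(X, y, budget=10, seed=0)
        assert res.cv_error == 0.0

    def test_fixed_seed_reproducible(self):
        X, y, _ = _toy_problem(14, n=50, sep=0.8)
        a = tune_hyperparameters(X, y, budget=8, seed=5)
        b = tune_hyperparameters(X, y, budget=8, seed=5)
        assert a.trajectory == b.trajectory
        assert (a.params.gamma, a.params.delta) == (b.params.gamma, b.params.delta)

    def test_budget_too_small_rejected(self):
        X, y, _ = _toy_problem(15)
        with pytest.raises(ValueError, match="budget"):
            tune_hyperparameters(X, y, budget=3)


class TestRepeatedHoldout:
    def test_separated_classes_perfect_accuracy(self):
        # Two classes at +/- 6 sd on many features: every replicate perfect.
        r = np.random.default_rng(16)
        X = np.vstack([r.normal(0, 1, (40, 10)), r.normal(12, 1, (40, 10))])
        y = np.array(["flower"] * 40 + ["leaf"] * 40)
        rep = repeated_holdout(X, y, reps=5, base_seed=0, tune_budget=6)
        assert rep.mean_accuracy == 1.0
        assert rep.se_accuracy == 0.0

    def test_single_replicate_se_flagged_undefined(self):
        X, y, _ = _toy_problem(17, n=40, k=2)
        rep = repeated_holdout(X, y, reps=1, base_seed=0, fixed_params=RLDAHyperparams(0.0, 0.0))
        assert rep.mean_accuracy == rep.accuracies[0]
        assert rep.se_accuracy is None

    def test_stratified_test_proportions(self):
        X, y, _ = _toy_problem(18, n=60, k=3)
        rep = repeated_holdout(X, y, reps=3, base_seed=2, fixed_params=RLDAHyperparams(0.0, 0.0))
        per_rep = rep.records.groupby("replicate")["true"].value_counts()
        for r in range(3):
            counts = per_rep.loc[r]
            # 20 per class, 25% test -> 5 per class, within 1 sample
            assert counts.min() >= 4 and counts.max() <= 6

    def test_mean_and_se_recomputable(self):
        X, y, _ = _toy_problem(19, n=48, k=2, sep=0.8)
        rep = repeated_holdout(X, y, reps=4, base_seed=1, fixed_params=RLDAHyperparams(0.001, 0.01))
        assert rep.mean_accuracy == pytest.approx(np.mean(rep.accuracies))
        assert rep.se_accuracy == pytest.approx(
            np.std(rep.accuracies, ddof=1) / np.sqrt(len(rep.accuracies))
        )

    def test_class_too_small_rejected(self):
        X = np.random.default_rng(0).normal(size=(7, 3))
        y = np.array(["a"] * 4 + ["b"] * 3)
        with pytest.raises(ValueError, match=">= 4 rows"):
            repeated_holdout(X, y, reps=2)


class TestPooledConfusion:
    def test_all_correct_gives_identity(self):
        X, y, _ = _toy_problem(20, sep=8.0)
        rep = repeated_holdout(X, y, reps=2, base_seed=0, fixed_params=RLDAHyperparams(0.0, 0.0))
        cm = pooled_confusion(rep)
        np.testing.assert_array_equal(cm.proportions, np.eye(3))

    def test_hand_built_records(self):
        from hempspec.discriminant import ReplicationReport

        records = pd.DataFrame(
            {
                "replicate": [0, 0, 0, 1, 1, 1],
                "true": ["a", "a", "b", "a", "b", "b"],
                "predicted": ["a", "b", "b", "a", "a", "b"],
            }
        )
        rep = ReplicationReport(
            accuracies=np.array([2 / 3, 2 / 3]),
            hyperparams=[],
            records=records,
            classes=np.array(["a", "b"]),
        )
        cm = pooled_confusion(rep)
        np.testing.assert_array_equal(cm.counts, [[2, 1], [1, 2]])

    def test_rows_sum_to_one_exactly(self):
        X, y, _ = _toy_problem(21, n=45, k=3, sep=0.5)
        rep = repeated_holdout(X, y, reps=3, base_seed=4, fixed_params=RLDAHyperparams(0.005, 0.1))
        cm = pooled_confusion(rep)
        for row in cm.proportions_exact():
            assert sum(row, Fraction(0)) == 1

    def test_empty_records_rejected(self):
        from hempspec.discriminant import ReplicationReport

        rep = ReplicationReport(
            accuracies=np.array([]),
            hyperparams=[],
            records=pd.DataFrame(columns=["replicate", "true", "predicted"]),
            classes=np.array(["a"]),
        )
        with pytest.raises(ValueError, match="no prediction"):
            pooled_confusion(rep)


class TestFisherLSD:
    def test_identical_groups_share_letter(self):
        vals = [0.9, 0.91, 0.92]
        res = fisher_lsd({"m1": vals, "m2": vals})
        assert res.letters["m1"] == res.letters["m2"]
        assert not res.significant[("m1", "m2")]

    def test_large_gap_different_letters(self):
        r = np.random.default_rng(0)
        res = fisher_lsd(
            {
                "high": 0.99 + 0.002 * r.standard_normal(30),
                "low": 0.80 + 0.002 * r.standard_normal(30),
            }
        )
        assert res.significant[("high", "low")]
        assert set(res.letters["high"]) & set(res.letters["low"]) == set()

    def test_lsd_matches_t_oracle(self):
        groups = {
            "a": [0.91, 0.93, 0.90, 0.94],
            "b": [0.88, 0.86, 0.89],
            "c": [0.95, 0.96, 0.97, 0.99, 0.94],
        }
        res = fisher_lsd(groups, alpha=0.05)
        # independent closed-form: pooled MSE and t-quantile
        all_n = sum(len(v) for v in groups.values())
        df = all_n - 3
        mse = sum(
            ((np.array(v) - np.mean(v)) ** 2).sum() for v in groups.values()
        ) / df
        assert res.mse == pytest.approx(mse, abs=1e-15)
        t_crit = stats.t.ppf(0.975, df)
        for (g1, g2), sig in res.significant.items():
            lsd = t_crit * np.sqrt(mse * (1 / len(groups[g1]) + 1 / len(groups[g2])))
            expected = abs(np.mean(groups[g1]) - np.mean(groups[g2])) > lsd
            assert sig == expected

    def test_intermediate_group_bridges_letters(self):
        # Means 1.0 / 0.9 / 0.8 with pooled LSD ~ 0.146: only the extreme
        # pair differs, so the middle group must carry both letters.
        groups = {
            "hi": [1.1, 0.9, 1.05, 0.95],
            "mid": [1.0, 0.8, 0.95, 0.85],
            "lo": [0.9, 0.7, 0.85, 0.75],
        }
        res = fisher_lsd(groups)
        assert res.significant[("hi", "lo")]
        assert not res.significant[("hi", "mid")] and not res.significant[("lo", "mid")]
        assert res.letters == {"hi": "a", "mid": "ab", "lo": "b"}

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            fisher_lsd({"a": [1.0], "b": [0.9]})
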