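"""Penalized models, cutoff selection, metrics and the resampling protocol."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from octnvep.model import (
    DegenerateLabelsError,
    EvaluationReport,
    PenalizedModel,
    TuneConfig,
    compute_metrics,
    feature_importance,
    fit_localization_models,
    fit_penalized_linear,
    fit_penalized_logistic,
    model_selection,
    r_squared,
    repeated_evaluation,
    select_cutoff,
    train_final_classifier,
    tune_lambda,
)


def _toy_data(n=80, p=4, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.uniform(size=(n, p)), columns=[f"f{i}" for i in range(p)])
    eta = 3.0 * X["f0"] - 2.0 * X["f1"] - 0.5
    y = rng.random(n) < expit(eta)
    return X, np.asarray(y)


class TestPenalizedLogistic:
    def test_large_lambda_gives_intercept_only_model(self):
        X, y = _toy_data()
        m = fit_penalized_logistic(X, y, lam=50.0)
        assert all(c == 0.0 for c in m.coefficients.values())
        prevalence = y.mean()
        assert m.intercept == pytest.approx(np.log(prevalence / (1 - prevalence)), abs=1e-3)

    def test_lambda_zero_matches_mle_oracle(self):
        import statsmodels.api as sm

        X, y = _toy_data()
        m = fit_penalized_logistic(X, y, lam=0.0)
        ref = sm.Logit(y.astype(float), sm.add_constant(X)).fit(disp=0)
        assert m.intercept == pytest.approx(ref.params["const"], abs=1e-4)
        for col in X.columns:
            assert m.coefficients[col] == pytest.approx(ref.params[col], abs=1e-4)

    def test_duplicated_column_leaves_predictions_unchanged(self):
        X, y = _toy_data()
        lam = 0.05
        base = fit_penalized_logistic(X, y, lam)
        X2 = X.copy()
        X2["f0_copy"] = X["f0"]
        dup = fit_penalized_logistic(X2, y, lam)
        np.testing.assert_allclose(
            base.predict_proba(X), dup.predict_proba(X2), atol=1e-4
        )

    def test_single_class_rejected(self):
        X, _ = _toy_data()
        with pytest.raises(DegenerateLabelsError):
            fit_penalized_logistic(X, np.zeros(len(X), dtype=bool), 0.1)

    def test_nonfinite_rejected(self):
        X, y = _toy_data()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_penalized_logistic(X, y, 0.1)

    def test_penalty_norm_monotone_in_lambda(self):
        X, y = _toy_data()
        norms = [
            sum(abs(c) for c in fit_penalized_logistic(X, y, g).coefficients.values())
            for g in np.logspace(-3, 1, 10)
        ]
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_json_round_trip(self, tmp_path):
        X, y = _toy_data()
        m = fit_penalized_logistic(X, y, 0.02)
        m.cutoff = 0.4
        path = tmp_path / "model.json"
        m.to_json(path)
        back = PenalizedModel.from_json(path)
        assert back.coefficients == m.coefficients
        assert back.cutoff == m.cutoff
        np.testing.assert_allclose(back.predict_proba(X), m.predict_proba(X))


class TestPenalizedLinear:
    def test_lambda_zero_matches_ols_normal_equations(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.uniform(size=(30, 3)), columns=list("abc"))
        y = 2.0 * X["a"] - 1.0 * X["c"] + 0.3 + rng.normal(0, 0.1, 30)
        m = fit_penalized_linear(X, y, 0.0)
        A = np.column_stack([np.ones(30), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert m.intercept == pytest.approx(beta[0], abs=1e-6)
        np.testing.assert_allclose(
            [m.coefficients[c] for c in X.columns], beta[1:], atol=1e-6
        )

    def test_r_squared_identities(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(np.full(4, y.mean()), y) == pytest.approx(0.0)
        with pytest.raises(ValueError, match="constant"):
            r_squared(y, np.full(4, 2.0))


def _brute_force_cutoff(scores, labels):
    """Exhaustive oracle: every achievable prediction set under a >= rule is
    produced by thresholding at an observed score (or +/- inf), so scanning a
    dense grid augmented with the scores themselves covers all optima."""
    s = np.asarray(scores)
    y = np.asarray(labels, dtype=bool)
    grid = np.concatenate(
        ([-np.inf], np.linspace(s.min() - 1, s.max() + 1, 2001), np.unique(s), [np.inf])
    )
    best_j, best_c = -np.inf, None
    for c in grid:
        pred = s >= c
        j = (pred & y).sum() / y.sum() + (~pred & ~y).sum() / (~y).sum()
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return best_j


class TestSelectCutoff:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [False, False, True, True]
        c = select_cutoff(scores, labels)
        assert 0.2 < c < 0.8
        m = compute_metrics(scores, labels, c)
        assert m.sensitivity + m.specificity == pytest.approx(2.0)

    def test_identical_scores_hit_sentinel(self):
        c = select_cutoff([0.5, 0.5, 0.5], [True, False, True])
        assert c == -np.inf

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = rng.random(n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            c = select_cutoff(scores, labels)
            pred = scores >= c
            j = (pred & labels).sum() / labels.sum() + (
                (~pred & ~labels).sum() / (~labels).sum()
            )
            assert j == pytest.approx(_brute_force_cutoff(scores, labels), abs=1e-9)


def _trapezoid_auc(scores, labels):
    """Trapezoidal area under the empirical ROC curve."""
    s = np.asarray(scores)
    y = np.asarray(labels, dtype=bool)
    thresholds = np.concatenate(([np.inf], np.sort(np.unique(s))[::-1]))
    tpr = [(s >= t)[y].mean() for t in thresholds] + [1.0]
    fpr = [(s >= t)[~y].mean() for t in thresholds] + [1.0]
    return float(np.trapezoid(tpr, fpr))


class TestMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics([0.9, 0.8, 0.1, 0.2], [True, True, False, False], 0.5)
        assert m.as_dict() == pytest.approx(
            {k: 1.0 for k in ("auc", "accuracy", "sensitivity", "specificity", "ppv", "npv", "mcc")}
        )

    def test_uninformative_scores_near_half_auc(self):
        rng = np.random.default_rng(2)
        scores = rng.random(4000)
        labels = rng.random(4000) < 0.3
        m = compute_metrics(scores, labels, 0.5)
        assert m.auc == pytest.approx(0.5, abs=0.03)
        assert m.mcc == pytest.approx(0.0, abs=0.05)

    def test_auc_equals_trapezoid_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(6, 60))
            scores = rng.choice(np.linspace(0, 1, 11), n)  # force ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            m = compute_metrics(scores, labels, 0.5)
            assert m.auc == pytest.approx(_trapezoid_auc(scores, labels), abs=1e-12)

    def test_zero_denominator_reported_missing(self):
        # no predicted positives -> PPV undefined
        m = compute_metrics([0.1, 0.2, 0.3], [True, False, False], cutoff=0.9)
        assert np.isnan(m.ppv)
        assert m.sensitivity == 0.0

    def test_mcc_symmetric_under_joint_swap(self):
        scores = np.array([0.9, 0.6, 0.4, 0.2, 0.7])
        labels = np.array([True, False, True, False, True])
        m1 = compute_metrics(scores, labels, 0.5)
        m2 = compute_metrics(1 - scores, ~labels, 0.5000001)
        assert m1.mcc == pytest.approx(m2.mcc)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.random(50)
        labels = rng.random(50) < 0.4
        a1 = compute_metrics(scores, labels, 0.5).auc
        a2 = compute_metrics(np.exp(3 * scores), labels, 0.5).auc
        assert a1 == pytest.approx(a2)


class TestTuneLambda:
    def test_singleton_grid_returned(self):
        X, y = _toy_data()
        assert tune_lambda(X, y, [0.123]) == 0.123

    def test_recovers_true_predictors_on_sparse_truth(self):
        # 3 informative features among 20; the tuned model should keep them
        rng = np.random.default_rng(5)
        hits = 0
        runs = 10
        for r in range(runs):
            X = pd.DataFrame(
                rng.uniform(size=(150, 20)), columns=[f"f{i}" for i in range(20)]
            )
            eta = 4.0 * X["f0"] - 4.0 * X["f1"] + 3.0 * X["f2"] - 1.5
            y = rng.random(150) < expit(eta)
            if y.all() or not y.any():
                continue
            lam = tune_lambda(X, y, np.logspace(-4, 0, 15), folds=3, repeats=1, seed=r)
            m = fit_penalized_logistic(X, y, lam)
            kept = set(m.nonzero_features())
            hits += {"f0", "f1", "f2"} <= kept
        assert hits >= 0.8 * runs


class TestRepeatedEvaluation:
    def test_fixed_seed_bit_reproducible(self, smoke_study, fast_tune):
        X = smoke_study.X_raw
        y = smoke_study.characterized["lof"].to_numpy()
        r1 = repeated_evaluation(X, y, iterations=4, seed=9, tune=fast_tune)
        r2 = repeated_evaluation(X, y, iterations=4, seed=9, tune=fast_tune)
        pd.testing.assert_frame_equal(r1.metrics, r2.metrics)
        assert r1.cutoffs == r2.cutoffs

    def test_split_sizes_follow_test_fraction(self, smoke_study, fast_tune):
        X = smoke_study.X_raw
        y = smoke_study.characterized["lof"].to_numpy()
        rep = repeated_evaluation(
            X, y, iterations=2, test_fraction=0.3, seed=0, tune=fast_tune
        )
        assert rep.n_test == round(0.3 * len(y))
        assert rep.n_train + rep.n_test == len(y)

    def test_single_class_labels_rejected(self, smoke_study):
        X = smoke_study.X_raw
        with pytest.raises(DegenerateLabelsError):
            repeated_evaluation(X, np.ones(len(X), dtype=bool), iterations=1)

    def test_aggregate_within_per_split_range(self, smoke_study, fast_tune):
        X = smoke_study.X_raw
        y = smoke_study.characterized["lof"].to_numpy()
        rep = repeated_evaluation(X, y, iterations=5, seed=3, tune=fast_tune)
        agg = rep.aggregate()
        assert rep.metrics["auc"].min() <= agg.loc["auc", "mean"] <= rep.metrics["auc"].max()


class TestFeatureImportance:
    def test_zeroed_feature_summary(self):
        C = pd.DataFrame({"dead": [0.0] * 6, "live": [1.0, 1.2, 0.9, 1.1, 1.0, 0.8]})
        rep = EvaluationReport(
            metrics=pd.DataFrame({"auc": [0.9] * 6}), coefficients=C,
            cutoffs=[0.5] * 6, lambdas=[0.01] * 6, n_train=10, n_test=3, seed=0,
        )
        imp = feature_importance(rep)
        assert imp.loc["dead", "median"] == 0.0
        assert imp.loc["dead", "q3"] - imp.loc["dead", "q1"] == 0.0
        assert imp.loc["dead", "frac_nonzero"] == 0.0
        assert imp.index[0] == "live"  # ranked by |median|

    def test_invariant_to_fold_order(self):
        rng = np.random.default_rng(0)
        C = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        mk = lambda c: EvaluationReport(
            metrics=pd.DataFrame({"auc": [0.5] * len(c)}), coefficients=c,
            cutoffs=[0.5] * len(c), lambdas=[0.01] * len(c), n_train=1, n_test=1, seed=0,
        )
        a = feature_importance(mk(C))
        b = feature_importance(mk(C.sample(frac=1, random_state=1).reset_index(drop=True)))
        pd.testing.assert_frame_equal(a, b)


class TestModelSelection:
    def test_single_cell_reduces_to_repeated_evaluation(self, smoke_study, fast_tune):
        X = smoke_study.X_raw
        y = smoke_study.characterized["lof"].to_numpy()
        grid = model_selection(
            {"all": X}, y, model_types=("penalized",), iterations=3, seed=5, tune=fast_tune
        )
        direct = repeated_evaluation(X, y, iterations=3, seed=5, tune=fast_tune)
        assert grid.loc[0, "mean_auc"] == pytest.approx(
            float(direct.aggregate().loc["auc", "mean"])
        )

    def test_missing_feature_source_marked_unavailable(self, smoke_study, fast_tune):
        X = smoke_study.X_raw
        y = smoke_study.characterized["lof"].to_numpy()
        grid = model_selection(
            {"all": X, "structure": None}, y, model_types=("penalized",),
            iterations=2, seed=0, tune=fast_tune,
        )
        row = grid[grid["feature_set"] == "structure"].iloc[0]
        assert not row["available"] and np.isnan(row["mean_auc"])

    def test_tree_ensembles_run_under_protocol(self, smoke_study):
        X = smoke_study.X_raw
        y = smoke_study.characterized["lof"].to_numpy()
        grid = model_selection(
            {"all": X}, y, model_types=("random_forest",), iterations=2, seed=0, tune=None
        )
        assert grid.loc[0, "available"]
        assert 0.4 <= grid.loc[0, "mean_auc"] <= 1.0


class TestLocalizationModels:
    def test_membrane_model_invariant_to_mixed_intracellular_swap(self, smoke_study, fast_tune):
        X = smoke_study.X_raw
        loc = smoke_study.characterized["localization"]
        reports = fit_localization_models(X, loc, iterations=3, seed=2, tune=fast_tune)
        swapped = loc.replace({"mixed": "intracellular", "intracellular": "mixed"})
        reports2 = fit_localization_models(X, swapped, iterations=3, seed=2, tune=fast_tune)
        pd.testing.assert_frame_equal(
            reports["membrane"].metrics, reports2["membrane"].metrics
        )

    def test_collapsed_class_rejected(self, smoke_study, fast_tune):
        X = smoke_study.X_raw
        with pytest.raises(DegenerateLabelsError):
            fit_localization_models(X, ["membrane"] * len(X), tune=fast_tune)

    def test_perfectly_informative_feature_gives_auc_one(self, fast_tune):
        rng = np.random.default_rng(6)
        n = 60
        loc = np.array(["membrane", "mixed", "intracellular"])[rng.integers(0, 3, n)]
        X = pd.DataFrame(
            {
                "is_mem": (loc == "membrane").astype(float),
                "is_intra": (loc == "intracellular").astype(float),
                "noise": rng.uniform(size=n),
            }
        )
        reports = fit_localization_models(X, loc, iterations=3, seed=0, tune=fast_tune)
        assert reports["membrane"].aggregate().loc["auc", "mean"] == pytest.approx(1.0)
        assert reports["intracellular"].aggregate().loc["auc", "mean"] == pytest.approx(1.0)


class TestFinalClassifier:
    def test_trained_model_carries_cutoff_and_scaling(self, smoke_study, fast_tune):
        X = smoke_study.X_raw
        y = smoke_study.characterized["lof"].to_numpy()
        model, fm = train_final_classifier(X, y, tune=fast_tune, seed=0)
        assert model.cutoff is not None and 0 < model.cutoff < 1
        assert set(model.scaling["min"]) == set(X.columns)
        p = model.predict_proba(fm.transform())
        assert ((p >= 0) & (p <= 1)).all()
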