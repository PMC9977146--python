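import numpy as np
import pandas as pd
import pytest

from shmclass.classify import (
    ElasticNetTuning,
    FittedClassifier,
    binary_metrics_with_ci,
    clopper_pearson,
    cross_cohort_transfer,
    fit_elasticnet_at,
    fit_elasticnet_logistic,
    loo_cross_validate,
    shuffled_label_null,
    student_t_feature_selection,
)

FAST = ElasticNetTuning(alphas=(0.5, 1.0), n_lambda=6)


def gaussian_table(rng, n_per_class=10, n_noise=50, effect=0.0, prefix="f"):
    """Noise features plus one optionally shifted feature `sig`."""
    n = 2 * n_per_class
    data = rng.normal(0, 1, size=(n, n_noise))
    labels = ["case"] * n_per_class + ["control"] * n_per_class
    signal = rng.normal(0, 1, size=n)
    signal[:n_per_class] += effect
    df = pd.DataFrame(data, columns=[f"{prefix}{i}" for i in range(n_noise)],
                      index=[f"s{i}" for i in range(n)])
    df["sig"] = signal
    return df, dict(zip(df.index, labels))


def test_selection_finds_planted_feature(rng):
    df, labels = gaussian_table(rng, effect=3.0)
    top = student_t_feature_selection(df, list(labels.values()), top_k=1)
    assert top == ["sig"]


def test_selection_top_k_zero_returns_all_valid(rng):
    df, labels = gaussian_table(rng)
    assert len(student_t_feature_selection(df, list(labels.values()), 0)) == 51


def test_selection_excludes_constant(rng):
    df, labels = gaussian_table(rng)
    df["const"] = 1.0
    selected = student_t_feature_selection(df, list(labels.values()), 0)
    assert "const" not in selected


def test_fit_separable_data_perfect_training_accuracy(rng):
    df, labels = gaussian_table(rng, n_noise=2, effect=8.0)
    model = fit_elasticnet_logistic(df, list(labels.values()), FAST, seed=0)
    pred = model.predict(df)
    assert (pred == (np.array(list(labels.values())) == "case")).all()


def test_fit_huge_lambda_gives_null_model(rng):
    df, labels = gaussian_table(rng, n_per_class=12, n_noise=5, effect=2.0)
    y = np.array(list(labels.values())) == "case"
    model = fit_elasticnet_at(df, y, alpha=1.0, lam=1e4)
    np.testing.assert_allclose(model.coefficients, 0.0, atol=1e-8)
    prevalence = y.mean()
    assert model.intercept == pytest.approx(
        np.log(prevalence / (1 - prevalence)), abs=1e-3
    )


def proximal_gradient_lasso_logistic(X, y, lam, n_iter=200000, lr=None):
    """Independent minimiser of mean NLL + lam*||b||_1 (ISTA)."""
    n, p = X.shape
    if lr is None:
        lr = 1.0 / (np.linalg.norm(X, 2) ** 2 / (4 * n) + 1e-12)
    beta = np.zeros(p)
    b0 = 0.0
    for _ in range(n_iter):
        z = X @ beta + b0
        prob = 1 / (1 + np.exp(-z))
        grad = X.T @ (prob - y) / n
        grad0 = (prob - y).mean()
        beta_new = beta - lr * grad
        beta_new = np.sign(beta_new) * np.maximum(np.abs(beta_new) - lr * lam, 0)
        b0_new = b0 - lr * grad0
        if np.abs(beta_new - beta).max() < 1e-12 and abs(b0_new - b0) < 1e-12:
            beta, b0 = beta_new, b0_new
            break
        beta, b0 = beta_new, b0_new
    return beta, b0


def test_lasso_matches_proximal_gradient_oracle(rng):
    X = rng.normal(0, 1, size=(6, 3))
    y = np.array([1, 1, 1, 0, 0, 0])
    df = pd.DataFrame(X, columns=list("abc"))
    lam = 0.05
    model = fit_elasticnet_at(df, y, alpha=1.0, lam=lam,
                              tuning=ElasticNetTuning(tol=1e-10, max_iter=200000))
    Xs = (X - model.scale_means) / model.scale_sds
    beta, b0 = proximal_gradient_lasso_logistic(Xs, y, lam)
    np.testing.assert_allclose(model.coefficients, beta, atol=1e-4)
    assert model.intercept == pytest.approx(b0, abs=1e-4)


def test_fit_rejects_single_class(rng):
    df, _ = gaussian_table(rng, n_per_class=4, n_noise=3)
    with pytest.raises(ValueError, match="single class"):
        fit_elasticnet_logistic(df, ["case"] * 8, FAST)


def test_objective_not_worse_than_null_model(rng):
    df, labels = gaussian_table(rng, n_noise=5, effect=1.5)
    y = (np.array(list(labels.values())) == "case").astype(int)
    model = fit_elasticnet_logistic(df, list(labels.values()), FAST, seed=0)
    null = FittedClassifier(
        feature_names=model.feature_names,
        impute_means=model.impute_means,
        scale_means=model.scale_means,
        scale_sds=model.scale_sds,
        coefficients=np.zeros_like(model.coefficients),
        intercept=float(np.log(y.mean() / (1 - y.mean()))),
        alpha=model.alpha,
        lam=model.lam,
    )
    assert model.objective(df, y) <= null.objective(df, y) + 1e-9


def test_metrics_hand_confusion_matrix():
    pred = [1] * 3 + [1] + [0] + [0] * 5
    true = [1] * 3 + [0] + [1] + [0] * 5
    m = binary_metrics_with_ci(np.array(pred, bool), np.array(true, bool))
    assert m["confusion"] == {"tp": 3, "fp": 1, "fn": 1, "tn": 5}
    assert m["f1"]["value"] == pytest.approx(0.75)
    assert m["accuracy"]["value"] == pytest.approx(0.8)
    assert m["sensitivity"]["value"] == pytest.approx(0.75)
    assert m["specificity"]["value"] == pytest.approx(5 / 6)


def test_metrics_all_correct_ci_lower_bound():
    pred = true = np.array([1] * 6 + [0] * 4, bool)
    m = binary_metrics_with_ci(pred, true)
    for name in ("f1", "accuracy", "sensitivity", "specificity"):
        assert m[name]["value"] == 1.0
    lo, hi = m["accuracy"]["ci95"]
    assert lo == pytest.approx(0.025 ** (1 / 10), abs=1e-9)  # 0.692
    assert hi == 1.0


def test_metrics_undefined_flagged():
    pred = np.zeros(5, bool)
    true = np.zeros(5, bool)
    m = binary_metrics_with_ci(pred, true)
    assert m["f1"]["undefined"] and m["f1"]["value"] is None
    assert m["sensitivity"]["undefined"]
    assert m["specificity"]["value"] == 1.0


def test_metrics_empty_rejected():
    with pytest.raises(ValueError):
        binary_metrics_with_ci(np.array([], bool), np.array([], bool))


def test_clopper_pearson_closed_form():
    lo, hi = clopper_pearson(10, 10)
    assert lo == pytest.approx(0.025 ** 0.1, abs=1e-12)
    assert hi == 1.0
    lo0, hi0 = clopper_pearson(0, 10)
    assert lo0 == 0.0
    assert hi0 == pytest.approx(1 - 0.025 ** 0.1, abs=1e-12)


def test_loo_minimal_cohort_runs(rng):
    df, labels = gaussian_table(rng, n_per_class=2, n_noise=4, effect=2.0)
    result = loo_cross_validate(df, labels, top_k=2, tuning=FAST, seed=0)
    assert len(result.predictions) == 4
    assert set(result.predictions.index) == set(df.index)


def test_loo_separable_cohort_perfect_f1(rng):
    df, labels = gaussian_table(rng, n_per_class=10, n_noise=20, effect=6.0)
    result = loo_cross_validate(df, labels, top_k=5, tuning=FAST, seed=0)
    assert result.metrics["f1"]["value"] == 1.0


def test_loo_metrics_recomputable_from_predictions(rng):
    df, labels = gaussian_table(rng, n_per_class=5, n_noise=10, effect=2.0)
    result = loo_cross_validate(df, labels, top_k=5, tuning=FAST, seed=3)
    again = binary_metrics_with_ci(
        result.predictions["predicted_label"].values,
        result.predictions["true_label"].values,
    )
    assert again == result.metrics


def test_loo_no_leakage_from_held_out_subject(rng):
    """Perturbing only the held-out subject's features leaves its fold's
    model unchanged: selection and all other predictions are identical."""
    df, labels = gaussian_table(rng, n_per_class=5, n_noise=15, effect=1.0)
    target = df.index[0]
    r1 = loo_cross_validate(df, labels, top_k=5, tuning=FAST, seed=7)
    df2 = df.copy()
    df2.loc[target] = df2.loc[target] + 100.0
    r2 = loo_cross_validate(df2, labels, top_k=5, tuning=FAST, seed=7)
    assert r1.fold_features[target] == r2.fold_features[target]
    m1, m2 = r1.fold_models[target], r2.fold_models[target]
    np.testing.assert_array_equal(m1.coefficients, m2.coefficients)
    np.testing.assert_array_equal(m1.scale_means, m2.scale_means)
    np.testing.assert_array_equal(m1.impute_means, m2.impute_means)
    assert m1.intercept == m2.intercept and m1.lam == m2.lam


def test_null_preserves_class_counts_and_reproducible(rng):
    df, labels = gaussian_table(rng, n_per_class=3, n_noise=6)
    null1 = shuffled_label_null(df, labels, n_permutations=1, top_k=3,
                                tuning=FAST, seed=5)
    null2 = shuffled_label_null(df, labels, n_permutations=1, top_k=3,
                                tuning=FAST, seed=5)
    assert len(null1) == 1
    pd.testing.assert_frame_equal(null1, null2)


def test_permutation_preserves_counts(rng):
    # the permutation machinery itself: shuffled labels keep class sizes
    base = np.array(["case"] * 4 + ["control"] * 6)
    perm = rng.permutation(base)
    assert (perm == "case").sum() == 4


def test_transfer_resubstitution_separable(rng):
    df, labels = gaussian_table(rng, n_per_class=8, n_noise=10, effect=6.0)
    metrics, report, predictions = cross_cohort_transfer(
        df, labels, df, labels, top_k=5, tuning=FAST, seed=0
    )
    assert metrics["accuracy"]["value"] == 1.0
    assert len(predictions) == len(df)
    assert set(report.table["direction"]) <= {"favor_case", "favor_control", "zero"}


def test_transfer_disjoint_features_rejected(rng):
    df1, labels1 = gaussian_table(rng, n_per_class=3, n_noise=4, prefix="x")
    df2, labels2 = gaussian_table(rng, n_per_class=3, n_noise=4, prefix="y")
    df1 = df1.drop(columns="sig")
    df2 = df2.drop(columns="sig")
    with pytest.raises(ValueError, match="share no features"):
        cross_cohort_transfer(df1, labels1, df2, labels2, tuning=FAST)
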