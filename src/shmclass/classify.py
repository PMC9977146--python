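"""Leave-one-out elastic-net classification of repertoire feature tables.

The procedure mirrors a nested, leakage-free protocol: for every held-out
subject, features are screened on the remaining subjects by two-sample
Student's t-test (top-k lowest p-values), training-fold means impute
missing values, columns are standardised with training-fold parameters, and
an elastic-net-regularised logistic regression is fitted with (alpha,
lambda) chosen by inner stratified cross-validation.  Metrics (F1,
accuracy, sensitivity, specificity; `case` is the positive class) carry
95% Clopper-Pearson intervals, and a shuffled-label null puts every score
in context.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .features import FeatureTable

POSITIVE = "case"


@dataclass(frozen=True)
class ElasticNetTuning:
    """Grid for the inner (alpha, lambda) search.

    ``alphas`` are elastic-net mixing values (1 = LASSO, 0 = ridge);
    ``n_lambda`` log-spaced penalties descend ``lambda_decades`` decades
    from the data-driven lambda_max; ``inner_folds`` stratified folds pick
    the pair with the lowest validation deviance.  The tuning path uses the
    looser ``path_tol`` (only validation losses are compared); the final
    refit converges to ``tol``.
    """

    alphas: tuple[float, ...] = (0.0, 0.5, 1.0)
    n_lambda: int = 12
    lambda_decades: float = 4.0
    inner_folds: int = 3
    max_iter: int = 5000
    tol: float = 1e-6
    path_tol: float = 1e-3

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphas", tuple(self.alphas))


@dataclass
class FittedClassifier:
    """A trained elastic-net logistic model with its preprocessing state."""

    feature_names: list[str]
    impute_means: np.ndarray
    scale_means: np.ndarray
    scale_sds: np.ndarray
    coefficients: np.ndarray
    intercept: float
    alpha: float
    lam: float

    def _design(self, table: pd.DataFrame) -> np.ndarray:
        X = table.reindex(columns=self.feature_names).to_numpy(dtype=float)
        for j in range(X.shape[1]):
            miss = np.isnan(X[:, j])
            X[miss, j] = self.impute_means[j]
        return (X - self.scale_means) / self.scale_sds

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        z = self._design(table) @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.predict_proba(table) > 0.5  # ties predict control

    def objective(self, table: pd.DataFrame, y: np.ndarray) -> float:
        """Mean negative log-likelihood plus the elastic-net penalty."""
        p = np.clip(self.predict_proba(table), 1e-12, 1 - 1e-12)
        nll = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        b = self.coefficients
        penalty = self.lam * (
            self.alpha * np.abs(b).sum() + (1 - self.alpha) / 2 * (b**2).sum()
        )
        return float(nll + penalty)


@dataclass
class CVResult:
    """Pooled leave-one-out predictions and derived metrics."""

    predictions: pd.DataFrame  # index subject; true_label, predicted_label, prob
    metrics: dict
    fold_features: dict[str, list[str]] = field(default_factory=dict)
    fold_models: dict[str, FittedClassifier] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "predictions": self.predictions.reset_index().to_dict(orient="records"),
            "metrics": self.metrics,
            "fold_features": self.fold_features,
        }


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "bif":
        return arr.astype(int)
    return (arr == POSITIVE).astype(int)


def student_t_feature_selection(
    table: pd.DataFrame, labels, top_k: int
) -> list[str]:
    """Rank features by two-sample pooled-variance t-test p-value.

    Returns the ``top_k`` feature names (all valid features when
    ``top_k == 0``); ties broken by descending |t| then name.  Features
    that are constant, all-missing, or have fewer than two observed values
    in either class are excluded before ranking.
    """
    y = _as_binary(labels).astype(bool)
    X = table.to_numpy(dtype=float)
    if y.sum() < 2 or (~y).sum() < 2:
        # t-test undefined with a one-subject class: no ranking possible
        warnings.warn(
            "fewer than two training subjects in a class; "
            "returning all non-constant features unranked",
            stacklevel=2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            spread = np.nanmax(X, axis=0) - np.nanmin(X, axis=0)
        return [c for c, s in zip(table.columns, spread) if np.isfinite(s) and s > 0]
    case, ctrl = X[y], X[~y]
    n1 = np.sum(~np.isnan(case), axis=0)
    n0 = np.sum(~np.isnan(ctrl), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1, m0 = np.nanmean(case, axis=0), np.nanmean(ctrl, axis=0)
        v1 = np.nanvar(case, axis=0, ddof=1)
        v0 = np.nanvar(ctrl, axis=0, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        t = (m1 - m0) / np.sqrt(sp2 * (1 / n1 + 1 / n0))
        p = 2 * stats.t.sf(np.abs(t), df=n1 + n0 - 2)
    valid = (n1 >= 2) & (n0 >= 2) & (sp2 > 0) & np.isfinite(t)
    order = sorted(
        np.flatnonzero(valid),
        key=lambda j: (p[j], -abs(t[j]), table.columns[j]),
    )
    if top_k == 0 or top_k >= len(order):
        if 0 < len(order) < top_k:
            warnings.warn(
                f"only {len(order)} valid features (requested {top_k})", stacklevel=2
            )
        return [table.columns[j] for j in order]
    return [table.columns[j] for j in order[:top_k]]


def _lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    resid = y - y.mean()
    grad = np.abs(X.T @ resid).max() / len(y)
    return grad / max(alpha, 1e-3)


def _fix_null_intercept(clf: LogisticRegression, y: np.ndarray) -> None:
    # saga's stopping rule watches only the coefficients; for a fully
    # penalised (all-zero) model the unpenalised intercept MLE is closed-form
    if np.all(clf.coef_ == 0):
        prevalence = y.mean()
        clf.intercept_[:] = np.log(prevalence / (1 - prevalence))


def _fit_at(
    X: np.ndarray, y: np.ndarray, alpha: float, lam: float, tuning: ElasticNetTuning
) -> LogisticRegression:
    C = 1.0 / (len(y) * lam)
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        C=C,
        max_iter=tuning.max_iter,
        tol=tuning.tol,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    _fix_null_intercept(clf, y)
    return clf


def _path_val_loss(
    X_tr, y_tr, X_val, y_val, alpha, lambdas, tuning
) -> np.ndarray:
    """Validation log-loss along a descending lambda path (warm-started)."""
    losses = np.empty(len(lambdas))
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        warm_start=True,
        max_iter=tuning.max_iter,
        tol=tuning.path_tol,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, lam in enumerate(lambdas):
            clf.C = 1.0 / (len(y_tr) * lam)
            clf.fit(X_tr, y_tr)
            _fix_null_intercept(clf, y_tr)
            p = np.clip(clf.predict_proba(X_val)[:, 1], 1e-12, 1 - 1e-12)
            losses[i] = -np.mean(y_val * np.log(p) + (1 - y_val) * np.log(1 - p))
    return losses


def fit_elasticnet_at(
    table: pd.DataFrame,
    labels,
    alpha: float,
    lam: float,
    tuning: ElasticNetTuning = ElasticNetTuning(),
) -> FittedClassifier:
    """Fit at a fixed (alpha, lambda) with the standard preprocessing."""
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X_raw = table.to_numpy(dtype=float)
    impute_means = np.nanmean(X_raw, axis=0)
    X = np.where(np.isnan(X_raw), impute_means, X_raw)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    clf = _fit_at((X - means) / sds, y, alpha, lam, tuning)
    return FittedClassifier(
        feature_names=list(table.columns),
        impute_means=impute_means,
        scale_means=means,
        scale_sds=sds,
        coefficients=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        alpha=alpha,
        lam=lam,
    )


def fit_elasticnet_logistic(
    table: pd.DataFrame,
    labels,
    tuning: ElasticNetTuning = ElasticNetTuning(),
    seed: int = 0,
) -> FittedClassifier:
    """Fit elastic-net logistic regression with inner-CV (alpha, lambda) choice.

    Imputation means and standardisation parameters come from the training
    rows only.  The objective is mean negative log-likelihood plus
    lambda * [alpha*||b||_1 + (1-alpha)/2*||b||_2^2]; ties in validation
    deviance prefer the larger lambda, then the larger alpha.
    """
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X_raw = table.to_numpy(dtype=float)
    all_missing = np.isnan(X_raw).all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} all-missing feature(s)", stacklevel=2
        )
    keep = ~all_missing
    names = [c for c, k in zip(table.columns, keep) if k]
    X_raw = X_raw[:, keep]
    impute_means = np.nanmean(X_raw, axis=0)
    X = np.where(np.isnan(X_raw), impute_means, X_raw)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    X = (X - means) / sds

    lam_max = max(_lambda_max(X, y, max(tuning.alphas)), 1e-6)
    lambdas = np.geomspace(lam_max, lam_max * 10**-tuning.lambda_decades,
                           tuning.n_lambda)

    min_class = min(np.bincount(y))
    n_splits = min(tuning.inner_folds, min_class)
    if n_splits >= 2:
        losses = np.zeros((len(tuning.alphas), len(lambdas)))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for tr_idx, val_idx in skf.split(X, y):
            for a_i, alpha in enumerate(tuning.alphas):
                losses[a_i] += _path_val_loss(
                    X[tr_idx], y[tr_idx], X[val_idx], y[val_idx],
                    alpha, lambdas, tuning,
                )
        best = None
        for a_i, alpha in enumerate(tuning.alphas):
            for l_i, lam in enumerate(lambdas):
                key = (round(losses[a_i, l_i], 10), l_i, -alpha)
                if best is None or key < best[0]:
                    best = (key, alpha, lam)
        _, alpha, lam = best
    else:  # too few subjects for inner CV: fixed mid-grid choice
        alpha = tuning.alphas[len(tuning.alphas) // 2]
        lam = lam_max * 1e-2

    clf = _fit_at(X, y, alpha, lam, tuning)
    return FittedClassifier(
        feature_names=names,
        impute_means=impute_means,
        scale_means=means,
        scale_sds=sds,
        coefficients=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        alpha=alpha,
        lam=lam,
    )


def clopper_pearson(successes: float, n: int, level: float = 0.95) -> tuple:
    """Clopper-Pearson interval, generalised to non-integer success counts."""
    a = (1 - level) / 2
    lower = 0.0 if successes <= 0 else float(stats.beta.ppf(a, successes, n - successes + 1))
    upper = 1.0 if successes >= n else float(stats.beta.ppf(1 - a, successes + 1, n - successes))
    return lower, upper


def binary_metrics_with_ci(predicted, true_labels) -> dict:
    """F1/accuracy/sensitivity/specificity with 95% binomial CIs.

    Each metric is treated as a proportion of n = number of subjects for
    its Clopper-Pearson interval.  A metric with a zero denominator is
    reported as None (undefined), not 0.
    """
    y_pred = _as_binary(predicted).astype(bool)
    y_true = _as_binary(true_labels).astype(bool)
    if len(y_pred) != len(y_true) or len(y_true) == 0:
        raise ValueError("prediction and label vectors must be equal-length, non-empty")
    tp = int(np.sum(y_pred & y_true))
    fp = int(np.sum(y_pred & ~y_true))
    fn = int(np.sum(~y_pred & y_true))
    tn = int(np.sum(~y_pred & ~y_true))
    n = len(y_true)

    def ratio(num, den):
        return None if den == 0 else num / den

    values = {
        "f1": ratio(2 * tp, 2 * tp + fp + fn),
        "accuracy": (tp + tn) / n,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
    }
    out = {"confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn}, "n": n}
    for name, value in values.items():
        if value is None:
            out[name] = {"value": None, "ci95": None, "undefined": True}
        else:
            lo, hi = clopper_pearson(value * n, n)
            out[name] = {"value": value, "ci95": [lo, hi], "undefined": False}
    return out


def loo_cross_validate(
    table: FeatureTable | pd.DataFrame,
    labels: dict[str, str],
    top_k: int = 30,
    tuning: ElasticNetTuning = ElasticNetTuning(),
    selection_scope: str = "per_fold",
    seed: int = 0,
) -> CVResult:
    """Leave-one-out cross-validation of the full selection + fit pipeline.

    ``per_fold`` repeats the t-test screening inside every fold (no
    information from the held-out subject touches selection, imputation,
    standardisation or tuning); ``global`` selects once on all subjects,
    mirroring protocols that fix one feature list for every iteration.
    """
    df = table.values if isinstance(table, FeatureTable) else table
    if len(df) < 4:
        raise ValueError("leave-one-out needs at least 4 subjects")
    if selection_scope not in ("per_fold", "global"):
        raise ValueError(f"unknown selection_scope {selection_scope!r}")
    y = pd.Series({s: labels[s] for s in df.index})
    global_features = None
    if selection_scope == "global":
        global_features = student_t_feature_selection(df, y.values, top_k)
    rows = []
    fold_features: dict[str, list[str]] = {}
    fold_models: dict[str, FittedClassifier] = {}
    for i, subject in enumerate(df.index):
        train = df.drop(index=subject)
        y_train = y.drop(index=subject).values
        selected = (
            global_features
            if global_features is not None
            else student_t_feature_selection(train, y_train, top_k)
        )
        model = fit_elasticnet_logistic(
            train[selected], y_train, tuning, seed=seed + i
        )
        prob = float(model.predict_proba(df.loc[[subject], selected])[0])
        rows.append(
            {
                "subject_id": subject,
                "true_label": y[subject],
                "predicted_label": POSITIVE if prob > 0.5 else "control",
                "prob": prob,
            }
        )
        fold_features[subject] = selected
        fold_models[subject] = model
    predictions = pd.DataFrame(rows).set_index("subject_id")
    metrics = binary_metrics_with_ci(
        predictions["predicted_label"].values, predictions["true_label"].values
    )
    return CVResult(predictions, metrics, fold_features, fold_models)


def shuffled_label_null(
    table: FeatureTable | pd.DataFrame,
    labels: dict[str, str],
    n_permutations: int = 25,
    top_k: int = 30,
    tuning: ElasticNetTuning = ElasticNetTuning(),
    selection_scope: str = "per_fold",
    seed: int = 0,
) -> pd.DataFrame:
    """Shuffled-label null distribution of the LOO metrics.

    Labels are permuted uniformly (class sizes preserved) and the entire
    LOO pipeline is rerun per permutation; with label-independent features
    the median F1 is expected near 0.5.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    df = table.values if isinstance(table, FeatureTable) else table
    rng = np.random.default_rng(seed)
    base = np.array([labels[s] for s in df.index])
    rows = []
    for perm in range(n_permutations):
        shuffled = dict(zip(df.index, rng.permutation(base)))
        result = loo_cross_validate(
            df, shuffled, top_k=top_k, tuning=tuning,
            selection_scope=selection_scope,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        row = {"permutation": perm}
        for m in ("f1", "accuracy", "sensitivity", "specificity"):
            row[m] = result.metrics[m]["value"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("permutation")


@dataclass
class CoefficientReport:
    """Signed model coefficients with their class direction."""

    table: pd.DataFrame  # feature -> coefficient, direction

    @classmethod
    def from_model(cls, model: FittedClassifier) -> "CoefficientReport":
        df = pd.DataFrame(
            {
                "coefficient": model.coefficients,
                "direction": [
                    "favor_case" if c > 0 else ("favor_control" if c < 0 else "zero")
                    for c in model.coefficients
                ],
            },
            index=model.feature_names,
        )
        return cls(df)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature")


def cross_cohort_transfer(
    train_table: FeatureTable | pd.DataFrame,
    train_labels: dict[str, str],
    test_table: FeatureTable | pd.DataFrame,
    test_labels: dict[str, str],
    top_k: int = 30,
    tuning: ElasticNetTuning = ElasticNetTuning(),
    seed: int = 0,
) -> tuple[dict, CoefficientReport, pd.DataFrame]:
    """Train on one cohort, predict every subject of another.

    Selection, imputation and standardisation come from the training cohort
    only; the model is fitted over the feature-name intersection, and
    features missing in the test cohort fall back to training means.
    """
    tr = train_table.values if isinstance(train_table, FeatureTable) else train_table
    te = test_table.values if isinstance(test_table, FeatureTable) else test_table
    shared = [c for c in tr.columns if c in set(te.columns)]
    if not shared:
        raise ValueError("train and test cohorts share no features")
    y_train = np.array([train_labels[s] for s in tr.index])
    selected = student_t_feature_selection(tr[shared], y_train, top_k)
    model = fit_elasticnet_logistic(tr[selected], y_train, tuning, seed=seed)
    prob = model.predict_proba(te)
    predictions = pd.DataFrame(
        {
            "true_label": [test_labels[s] for s in te.index],
            "predicted_label": np.where(prob > 0.5, POSITIVE, "control"),
            "prob": prob,
        },
        index=te.index,
    )
    metrics = binary_metrics_with_ci(
        predictions["predicted_label"].values, predictions["true_label"].values
    )
    return metrics, CoefficientReport.from_model(model), predictions
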