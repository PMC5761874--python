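"""Subject-level classification from dFC features.

Random Forests are trained on the 17-feature dFC vectors and compared, under
identical repeated stratified 5-fold cross-validation splits, against the
standard alternatives: a logistic classifier and a Random Forest on static
FC, Random Forests on sliding-window mean/variance, and a naive
majority-class rule.  Hyperparameters (features-per-split and minimum node
size) are tuned by an inner grid search on the training folds only, so no
information leaks from the held-out fold.  Variable importance uses the
conditional permutation scheme: a feature's out-of-bag values are permuted
within strata defined by the tree's own split points on correlated
covariates, which strips off importance a variable inherits merely through
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

MODEL_IDS = ("rf_dfc", "rf_sfc", "logistic_sfc", "rf_sw_mean", "rf_sw_var",
             "rf_sw_meanvar", "naive")


# ---------------------------------------------------------------------------
# accuracy & naive rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be nonnegative")


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FP + FN + TN)."""
    total = c.TP + c.TN + c.FP + c.FN
    if total == 0:
        raise ValueError("empty confusion table")
    return (c.TP + c.TN) / total


def naive_classifier(train_labels, test_size: int):
    """Predict the training-set majority class for every test sample.

    Ties are broken by the first label in sorted order.
    """
    train_labels = np.asarray(train_labels)
    if len(train_labels) == 0:
        raise ValueError("empty training labels")
    classes, counts = np.unique(train_labels, return_counts=True)  # sorted
    majority = classes[np.argmax(counts)]  # argmax takes first on ties
    return np.full(test_size, majority, dtype=classes.dtype)


# ---------------------------------------------------------------------------
# settings / results
# ---------------------------------------------------------------------------

def default_grid(n_features: int):
    """Features-per-split x minimum-node-size axes of the tuning grid."""
    p = n_features
    mf = sorted({1, int(np.ceil(np.sqrt(p))), int(np.ceil(p / 3)), p})
    return {"max_features": mf, "min_samples_leaf": [1, 3, 5]}


@dataclass(frozen=True)
class CVSettings:
    k: int = 5
    repetitions: int = 30
    inner_cv: int = 5
    n_estimators: int = 500
    grid: dict | None = None        # None -> default_grid(p)
    importance_threshold: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.k < 2 or self.repetitions < 1:
            raise ValueError("need k >= 2 and repetitions >= 1")


@dataclass
class CVResult:
    model: str
    records: pd.DataFrame        # repetition, fold, accuracy, n_test
    chosen_params: list
    mean_accuracy: float
    ci_normal: tuple
    ci_percentile: tuple


def _summarize(records: pd.DataFrame):
    rep_means = records.groupby("repetition")["accuracy"].mean().to_numpy()
    m = float(rep_means.mean())
    if len(rep_means) > 1:
        se = rep_means.std(ddof=1) / np.sqrt(len(rep_means))
        ci_n = (m - 1.96 * se, m + 1.96 * se)
        ci_p = tuple(np.quantile(rep_means, [0.025, 0.975]))
    else:
        ci_n = ci_p = (m, m)
    return m, ci_n, ci_p


# ---------------------------------------------------------------------------
# repeated CV
# ---------------------------------------------------------------------------

def _make_model(model: str, settings: CVSettings, n_features: int, rng_seed: int):
    if model.startswith("rf"):
        rf = RandomForestClassifier(n_estimators=settings.n_estimators,
                                    random_state=rng_seed)
        grid = dict(settings.grid or default_grid(n_features))
        if "max_features" in grid:
            # clip the features-per-split axis to the design's width
            mf = sorted({min(v, n_features) if isinstance(v, (int, np.integer))
                         else v for v in grid["max_features"]},
                        key=lambda v: (isinstance(v, str), v))
            grid["max_features"] = mf

        return GridSearchCV(rf, grid, cv=settings.inner_cv, scoring="accuracy",
                            n_jobs=1)
    if model == "logistic_sfc":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=1000))
    raise ValueError(f"unknown model {model!r}")


def cv_splits(labels, settings: CVSettings):
    """Stratified fold index pairs for every repetition (shared across models)."""
    labels = np.asarray(labels)
    splits = []
    for rep in range(settings.repetitions):
        skf = StratifiedKFold(n_splits=settings.k, shuffle=True,
                              random_state=settings.seed + 7919 * rep)
        splits.append(list(skf.split(np.zeros(len(labels)), labels)))
    return splits


def repeated_cv(X, y, model: str = "rf_dfc",
                settings: CVSettings = CVSettings(),
                splits=None) -> CVResult:
    """Repeated stratified k-fold CV accuracy of one model.

    The inner grid search, like any scaling, is fitted on training folds
    only.  ``splits`` (from :func:`cv_splits`) can be passed to force
    identical fold assignments across models.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < settings.k:
        raise ValueError("need at least k subjects per class")
    if splits is None:
        splits = cv_splits(y, settings)

    records, chosen = [], []
    for rep, folds in enumerate(splits):
        for fold, (tr, te) in enumerate(folds):
            if model == "naive":
                pred = naive_classifier(y[tr], len(te))
                params = None
            else:
                est = _make_model(model, settings, X.shape[1],
                                  rng_seed=settings.seed + 104729 * rep + fold)
                est.fit(X[tr], y[tr])
                pred = est.predict(X[te])
                params = getattr(est, "best_params_", None)
            acc = float(np.mean(pred == y[te]))
            records.append({"repetition": rep, "fold": fold,
                            "accuracy": acc, "n_test": len(te)})
            chosen.append(params)
    rec = pd.DataFrame(records)
    m, ci_n, ci_p = _summarize(rec)
    return CVResult(model=model, records=rec, chosen_params=chosen,
                    mean_accuracy=m, ci_normal=ci_n, ci_percentile=ci_p)


# ---------------------------------------------------------------------------
# conditional permutation importance
# ---------------------------------------------------------------------------

def _tree_strata(tree, X_oob, cond_features):
    """Stratum labels for OOB rows from the tree's split points on the
    conditioning features; a single stratum when there are none."""
    if not cond_features:
        return np.zeros(len(X_oob), dtype=int)
    t = tree.tree_
    codes = np.zeros(len(X_oob), dtype=np.int64)
    for l in cond_features:
        cuts = np.unique(t.threshold[t.feature == l])
        if len(cuts) == 0:
            continue
        codes = codes * (len(cuts) + 1) + np.digitize(X_oob[:, l], cuts)
    return codes


def conditional_importance(forest: RandomForestClassifier, X, y,
                           threshold: float = 0.2,
                           seed: int | None = None) -> pd.Series:
    """Conditional permutation importance (mean decrease in OOB accuracy).

    For each feature, its out-of-bag values are permuted *within strata*
    defined by each tree's split points on the features whose absolute
    Pearson correlation with it exceeds ``threshold``; with no conditioning
    feature above threshold this reduces to marginal permutation
    importance.  Scores are averaged over trees.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not forest.bootstrap:
        raise ValueError("forest must be fitted with bootstrap=True (OOB needed)")
    p = X.shape[1]
    corr = np.corrcoef(X.T) if p > 1 else np.ones((1, 1))
    corr = np.nan_to_num(corr, nan=0.0)
    rng = np.random.default_rng(seed)
    scores = np.zeros(p)
    counts = np.zeros(p)
    n = len(X)
    for tree, sample_idx in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), sample_idx)
        if len(oob) == 0:
            continue
        X_oob, y_oob = X[oob], y[oob]
        base = np.mean(tree.predict(X_oob) == y_oob)
        for j in range(p):
            cond = [l for l in range(p)
                    if l != j and abs(corr[j, l]) > threshold]
            strata = _tree_strata(tree, X_oob, cond)
            Xp = X_oob.copy()
            for s in np.unique(strata):
                idx = np.nonzero(strata == s)[0]
                if len(idx) > 1:
                    Xp[idx, j] = X_oob[rng.permutation(idx), j]
            perm = np.mean(tree.predict(Xp) == y_oob)
            scores[j] += base - perm
            counts[j] += 1
    counts[counts == 0] = 1
    names = getattr(forest, "feature_names_in_", None)
    index = list(names) if names is not None else list(range(p))
    return pd.Series(scores / counts, index=index, name="importance")


def marginal_importance(forest, X, y, seed=None) -> pd.Series:
    """Plain OOB permutation importance (threshold above any correlation)."""
    return conditional_importance(forest, X, y, threshold=1.1, seed=seed)


def repeated_conditional_importance(X, y, settings: CVSettings = CVSettings()
                                    ) -> pd.Series:
    """Conditional importance averaged over ``settings.repetitions`` forests."""
    X = np.asarray(X, dtype=float)
    out = None
    for rep in range(settings.repetitions):
        rf = RandomForestClassifier(n_estimators=settings.n_estimators,
                                    random_state=settings.seed + rep,
                                    bootstrap=True).fit(X, y)
        s = conditional_importance(rf, X, y,
                                   threshold=settings.importance_threshold,
                                   seed=settings.seed + rep)
        out = s if out is None else out + s
    return out / settings.repetitions


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def run_model_comparison(dfc_features: pd.DataFrame,
                         baseline_features: pd.DataFrame, labels,
                         settings: CVSettings = CVSettings()) -> pd.DataFrame:
    """All seven classifiers under identical (paired) fold assignments.

    ``dfc_features`` holds the 17 dFC features; ``baseline_features`` must
    contain columns ``sFC``, ``SW_Mean`` and ``SW_Var`` for the same
    subjects, in the same row order.  Returns a tidy table with one row per
    (model, repetition, fold).
    """
    labels = np.asarray(labels)
    if len(dfc_features) != len(baseline_features) or len(labels) != len(dfc_features):
        raise ValueError("mismatched subject sets across feature tables")
    for col in ("sFC", "SW_Mean", "SW_Var"):
        if col not in baseline_features:
            raise ValueError(f"baseline_features missing column {col!r}")

    design = {
        "rf_dfc": dfc_features.to_numpy(dtype=float),
        "rf_sfc": baseline_features[["sFC"]].to_numpy(dtype=float),
        "logistic_sfc": baseline_features[["sFC"]].to_numpy(dtype=float),
        "rf_sw_mean": baseline_features[["SW_Mean"]].to_numpy(dtype=float),
        "rf_sw_var": baseline_features[["SW_Var"]].to_numpy(dtype=float),
        "rf_sw_meanvar": baseline_features[["SW_Mean", "SW_Var"]].to_numpy(dtype=float),
        "naive": np.zeros((len(labels), 1)),
    }
    splits = cv_splits(labels, settings)
    frames = []
    for model in MODEL_IDS:
        res = repeated_cv(design[model], labels, model=model,
                          settings=settings, splits=splits)
        rec = res.records.copy()
        rec.insert(0, "model", model)
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)


def summarize_comparison(results: pd.DataFrame) -> pd.DataFrame:
    """Per-model mean accuracy and 95% CIs over repetition means."""
    rows = []
    for model, grp in results.groupby("model", sort=False):
        m, ci_n, ci_p = _summarize(grp)
        rows.append({"model": model, "mean_accuracy": m,
                     "ci_lo": ci_n[0], "ci_hi": ci_n[1],
                     "ci_lo_pct": ci_p[0], "ci_hi_pct": ci_p[1]})
    return pd.DataFrame(rows)
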