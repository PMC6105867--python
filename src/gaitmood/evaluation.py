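"""Personal and cross-user model evaluation with user-lift inference.

Three validation schemes are implemented:

* ``stratified_kfold_repeated`` — the conventional per-user evaluation:
  stratified k-fold (default 10) repeated (default 10 times) with windows
  shuffled, which is optimistic when adjacent windows are correlated
  (neighborhood bias);
* ``emotion_block`` — the leakage-aware variant: each held-out fold is a
  contiguous, single-emotion block of windows (5 blocks per class for 10
  folds), so a model can only score well by recognising the emotion, not the
  walking period;
* ``leave_one_user_out`` — train on all other users pooled, test on the
  held-out user.

A *user lift* is a personal model's mean accuracy minus the personal
majority-baseline's mean accuracy under the same scheme; whether lifts have
positive mean across users is tested with a one-sided sign-flip permutation
test (exact when the number of users permits, Monte-Carlo with add-one
correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from gaitmood.features import FULL_SUBSET, FilterSpec, WindowSpec, build_dataset, feature_names
from gaitmood.sensor_io import FeatureMatrix

MODEL_KINDS = ("baseline_majority", "logistic_l2", "random_forest")
SCHEME_KINDS = ("stratified_kfold_repeated", "emotion_block", "leave_one_user_out")


@dataclass
class ModelSpec:
    """Which classifier to train and with what (minimal) hyperparameters."""

    kind: str = "logistic_l2"
    n_estimators: int = 100  # random forest only
    C: float = 1.0  # inverse L2 strength, logistic only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "random_forest" and self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.kind == "logistic_l2" and self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class CVScheme:
    kind: str = "stratified_kfold_repeated"
    k: int = 10
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCHEME_KINDS:
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind != "leave_one_user_out" and self.k < 2:
            raise ValueError("k must be >= 2")


class MajorityClassifier(BaseEstimator, ClassifierMixin):
    """Predicts the modal training label; ties break lexicographically.

    ``predict_proba`` returns the training class frequencies for every row,
    so its ROC-AUC is 0.5 by construction (constant scores).
    """

    def fit(self, X, y):
        y = np.asarray(y)
        if y.size < 1:
            raise ValueError("at least one training label required")
        self.classes_, counts = np.unique(y, return_counts=True)
        # np.unique sorts, so argmax on counts already breaks ties toward the
        # lexicographically smallest label
        self.majority_ = self.classes_[int(np.argmax(counts))]
        self.proba_ = counts / counts.sum()
        return self

    def predict(self, X):
        return np.full(np.shape(X)[0], self.majority_, dtype=object)

    def predict_proba(self, X):
        return np.tile(self.proba_, (np.shape(X)[0], 1))


def fit_baseline(labels) -> MajorityClassifier:
    """Majority-class baseline fitted on a label sequence."""
    return MajorityClassifier().fit(np.zeros((len(labels), 1)), labels)


def make_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for a :class:`ModelSpec`.

    Logistic regression is wrapped in a pipeline with a standard scaler so
    standardization statistics come from the training fold only.
    """
    if spec.kind == "baseline_majority":
        return MajorityClassifier()
    if spec.kind == "logistic_l2":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    # default penalty is ridge (L2); C is its inverse strength
                    LogisticRegression(C=spec.C, solver="lbfgs", max_iter=2000),
                ),
            ]
        )
    return RandomForestClassifier(
        n_estimators=spec.n_estimators, random_state=spec.seed, n_jobs=1
    )


@dataclass
class EvalResult:
    """Per-fold and aggregate metrics for one model under one CV scheme."""

    per_fold: pd.DataFrame  # columns: accuracy, f1, roc_auc (NaN if undefined)
    scheme: str
    model: str
    class_counts: dict = field(default_factory=dict)

    def _agg(self, col: str, fn) -> float:
        vals = self.per_fold[col].dropna()
        return float(fn(vals)) if len(vals) else float("nan")

    @property
    def mean_accuracy(self) -> float:
        return self._agg("accuracy", np.mean)

    @property
    def sd_accuracy(self) -> float:
        return self._agg("accuracy", lambda v: np.std(v, ddof=1) if len(v) > 1 else 0.0)

    @property
    def mean_f1(self) -> float:
        return self._agg("f1", np.mean)

    @property
    def mean_auc(self) -> float:
        return self._agg("roc_auc", np.mean)

    def summary(self) -> dict:
        return {
            "scheme": self.scheme,
            "model": self.model,
            "n_folds": len(self.per_fold),
            "accuracy": self.mean_accuracy,
            "f1": self.mean_f1,
            "roc_auc": self.mean_auc,
        }


@dataclass
class UserLiftResult:
    users: list
    per_user_lift: list
    mean_lift: float
    p_value: float


def _fold_metrics(model, X_test, y_test, classes) -> dict:
    pred = model.predict(X_test)
    row = {
        "accuracy": accuracy_score(y_test, pred),
        "f1": f1_score(
            y_test, pred, labels=list(classes), average="macro", zero_division=0
        ),
        "roc_auc": np.nan,
    }
    if len(classes) == 2 and hasattr(model, "predict_proba"):
        if len(np.unique(y_test)) == 2:
            scores = model.predict_proba(X_test)[:, 1]
            row["roc_auc"] = roc_auc_score(
                (np.asarray(y_test) == classes[1]).astype(int), scores
            )
    return row


def evaluate_personal(
    matrix: FeatureMatrix, model: ModelSpec, scheme: CVScheme | None = None
) -> EvalResult:
    """Repeated stratified k-fold evaluation of one user's personal model.

    Aggregates are means over all ``k x repeats`` held-out folds; macro-F1 is
    computed over the full label set and ROC-AUC (binary labels only) from
    predicted class probabilities of the lexicographically larger class.
    """
    scheme = scheme or CVScheme()
    if scheme.kind != "stratified_kfold_repeated":
        raise ValueError("evaluate_personal requires a stratified_kfold_repeated scheme")
    X, y = matrix.X, matrix.y
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < scheme.k:
        lacking = classes[int(np.argmin(counts))]
        raise ValueError(
            f"class {lacking!r} has {counts.min()} samples, fewer than k={scheme.k}"
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=scheme.k, n_repeats=scheme.repeats, random_state=scheme.seed
    )
    rows = []
    for train_idx, test_idx in splitter.split(X, y):
        est = clone(make_estimator(model))
        est.fit(X[train_idx], y[train_idx])
        rows.append(_fold_metrics(est, X[test_idx], y[test_idx], classes))
    return EvalResult(
        per_fold=pd.DataFrame(rows),
        scheme=scheme.kind,
        model=model.kind,
        class_counts=dict(zip(classes.tolist(), counts.tolist())),
    )


def emotion_block_cv(
    matrix: FeatureMatrix, model: ModelSpec, n_blocks_per_class: int = 5
) -> EvalResult:
    """Leakage-aware CV: each held-out fold is one contiguous same-class block.

    Binary labels only. Each class's windows, in time order, are split into
    ``n_blocks_per_class`` contiguous blocks (default 5, for 10 folds); each
    fold holds out exactly one block and trains on everything else, so the
    test fold is single-class. Reported F1 is the F1 of the held-out class
    (macro-F1 is degenerate on a single-class fold); ROC-AUC is omitted.
    """
    y = matrix.y
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("emotion_block_cv is defined for binary labels only")
    X = matrix.X
    order = np.lexsort(
        (matrix.frame["window_index"].to_numpy(), matrix.frame["participant"].to_numpy())
    )
    blocks = []
    for cls in classes:
        cls_idx = order[y[order] == cls]
        if cls_idx.size < n_blocks_per_class:
            raise ValueError(
                f"class {cls!r} has {cls_idx.size} windows, fewer than "
                f"{n_blocks_per_class} blocks"
            )
        blocks.extend((cls, part) for part in np.array_split(cls_idx, n_blocks_per_class))
    rows = []
    all_idx = np.arange(len(y))
    for cls, test_idx in blocks:
        train_idx = np.setdiff1d(all_idx, test_idx)
        est = clone(make_estimator(model))
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        acc = accuracy_score(y[test_idx], pred)
        f1 = f1_score(
            y[test_idx], pred, labels=list(classes), pos_label=cls,
            average="binary", zero_division=0,
        )
        rows.append({"accuracy": acc, "f1": f1, "roc_auc": np.nan, "held_out": cls})
    counts = dict(zip(*np.unique(y, return_counts=True)))
    return EvalResult(
        per_fold=pd.DataFrame(rows),
        scheme="emotion_block",
        model=model.kind,
        class_counts={str(k): int(v) for k, v in counts.items()},
    )


def leave_one_user_out(matrices, model: ModelSpec) -> EvalResult:
    """One fold per user: train on all other users pooled, test on the rest.

    ``matrices`` is a mapping (or list) of single-user :class:`FeatureMatrix`
    objects with identical feature columns.
    """
    if isinstance(matrices, dict):
        items = list(matrices.items())
    else:
        items = [(str(m.frame["participant"].iloc[0]), m) for m in matrices]
    if len(items) < 2:
        raise ValueError("leave-one-user-out requires at least 2 users")
    names = items[0][1].feature_names
    for _, m in items:
        if m.feature_names != names:
            raise ValueError("all users must share the same feature columns")
    Xs = {u: m.X for u, m in items}
    ys = {u: m.y for u, m in items}
    classes = np.unique(np.concatenate(list(ys.values())))
    rows = []
    for user, _ in items:
        X_train = np.vstack([Xs[u] for u, _ in items if u != user])
        y_train = np.concatenate([ys[u] for u, _ in items if u != user])
        est = clone(make_estimator(model))
        est.fit(X_train, y_train)
        row = _fold_metrics(est, Xs[user], ys[user], classes)
        row["held_out"] = user
        rows.append(row)
    y_all = np.concatenate(list(ys.values()))
    counts = dict(zip(*np.unique(y_all, return_counts=True)))
    return EvalResult(
        per_fold=pd.DataFrame(rows),
        scheme="leave_one_user_out",
        model=model.kind,
        class_counts={str(k): int(v) for k, v in counts.items()},
    )


def user_lift(model_result: EvalResult, baseline_result: EvalResult) -> float:
    """Personal-model mean accuracy minus personal-baseline mean accuracy."""
    if model_result.scheme != baseline_result.scheme:
        raise ValueError(
            f"scheme mismatch: {model_result.scheme} vs {baseline_result.scheme}"
        )
    return model_result.mean_accuracy - baseline_result.mean_accuracy


def permutation_test_mean_lift(lifts, n_perm: int = 100_000, seed: int = 0) -> float:
    """One-sided sign-flip permutation test of H0: mean lift = 0 vs > 0.

    Exact enumeration of all 2^n sign patterns when that is within ``n_perm``
    permutations; otherwise Monte-Carlo with the add-one correction
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)``. Ties count against the
    alternative, so the p-value is never zero.
    """
    lifts = np.asarray(lifts, dtype=float)
    n = lifts.size
    if n < 1:
        raise ValueError("at least one lift required")
    obs = lifts.mean()
    if 2**n <= n_perm:
        signs = 1 - 2 * ((np.arange(2**n)[:, None] >> np.arange(n)) & 1)
        perm_means = (signs * lifts).mean(axis=1)
        return float(np.count_nonzero(perm_means >= obs) / 2**n)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm_means = (signs * lifts).mean(axis=1)
    return float((1 + np.count_nonzero(perm_means >= obs)) / (1 + n_perm))


def compute_user_lifts(
    model_results: dict, baseline_results: dict, n_perm: int = 100_000, seed: int = 0
) -> UserLiftResult:
    """Lift per user plus the permutation p-value for a positive mean lift."""
    users = sorted(model_results)
    if sorted(baseline_results) != users:
        raise ValueError("model and baseline results must cover the same users")
    lifts = [user_lift(model_results[u], baseline_results[u]) for u in users]
    return UserLiftResult(
        users=users,
        per_user_lift=lifts,
        mean_lift=float(np.mean(lifts)),
        p_value=permutation_test_mean_lift(lifts, n_perm=n_perm, seed=seed),
    )


def rf_importance_cv(
    matrix: FeatureMatrix, model: ModelSpec | None = None, scheme: CVScheme | None = None
) -> np.ndarray:
    """Per-fold random-forest feature importances, shape (n_folds, n_features)."""
    model = model or ModelSpec("random_forest")
    if model.kind != "random_forest":
        raise ValueError("feature importances require a random forest model")
    scheme = scheme or CVScheme(repeats=1)
    X, y = matrix.X, matrix.y
    splitter = RepeatedStratifiedKFold(
        n_splits=scheme.k, n_repeats=scheme.repeats, random_state=scheme.seed
    )
    rows = []
    for train_idx, _ in splitter.split(X, y):
        est = clone(make_estimator(model))
        est.fit(X[train_idx], y[train_idx])
        rows.append(est.feature_importances_)
    return np.vstack(rows)


def normalized_importance(per_fold_importances, feature_names=None) -> pd.Series:
    """Fold-mean importances scaled so the top feature is exactly 1.0."""
    arr = np.atleast_2d(np.asarray(per_fold_importances, dtype=float))
    mean = arr.mean(axis=0)
    top = mean.max()
    if top <= 0:
        raise ValueError("all feature importances are zero")
    values = mean / top
    index = feature_names if feature_names is not None else range(values.size)
    return pd.Series(values, index=index)


def importance_summary(profiles) -> pd.DataFrame:
    """Per-feature distribution of normalized importances across users.

    Returns median/q25/q75 per feature, sorted by descending median — the
    tabular analogue of the usual importance boxplot.
    """
    df = pd.DataFrame(list(profiles))
    out = pd.DataFrame(
        {
            "median": df.median(axis=0),
            "q25": df.quantile(0.25, axis=0),
            "q75": df.quantile(0.75, axis=0),
        }
    )
    return out.sort_values("median", ascending=False)


# ---------------------------------------------------------------------------
# study orchestration
# ---------------------------------------------------------------------------

def split_by_participant(matrix: FeatureMatrix) -> dict[str, FeatureMatrix]:
    return {
        str(user): FeatureMatrix(group.reset_index(drop=True), list(matrix.feature_names))
        for user, group in matrix.frame.groupby("participant", sort=True)
    }


def run_study(
    segments,
    models: list[ModelSpec] | None = None,
    schemes=("stratified_kfold_repeated",),
    sensor_subsets=(FULL_SUBSET,),
    labels=("happy", "sad"),
    window_spec: WindowSpec | None = None,
    filter_spec: FilterSpec | None = None,
    cv: CVScheme | None = None,
    n_perm: int = 100_000,
    seed: int = 0,
) -> dict:
    """End-to-end study analogue over a cohort of walks.

    Returns ``{"table": DataFrame, "lifts": DataFrame}``: one table row per
    (subset, scheme, model) with mean/SD metrics across users plus the mean
    user lift and its permutation p-value, and a per-user lift listing.
    """
    models = models or [ModelSpec("logistic_l2", seed=seed), ModelSpec("random_forest", seed=seed)]
    cv = cv or CVScheme(seed=seed)
    baseline = ModelSpec("baseline_majority", seed=seed)
    full = build_dataset(
        segments,
        window_spec or WindowSpec(),
        filter_spec or FilterSpec(),
        sensor_subset=FULL_SUBSET,
    ).select_labels(labels)
    condition = segments[0].condition if segments else None

    table_rows, lift_rows = [], []
    for subset in sensor_subsets:
        sub = full.select_features(feature_names(subset))
        users = split_by_participant(sub)
        for scheme in schemes:
            if scheme == "leave_one_user_out":
                for model in models:
                    res = leave_one_user_out(users, model)
                    base = leave_one_user_out(users, baseline)
                    table_rows.append(
                        _table_row(condition, subset, scheme, model.kind, res, None, None)
                    )
                    table_rows.append(
                        _table_row(condition, subset, scheme, "baseline_majority", base, None, None)
                    )
                continue
            base_results = {
                u: _eval_one(m, baseline, scheme, cv) for u, m in users.items()
            }
            table_rows.append(
                _agg_row(condition, subset, scheme, "baseline_majority", base_results, None, None)
            )
            for model in models:
                results = {u: _eval_one(m, model, scheme, cv) for u, m in users.items()}
                lifts = compute_user_lifts(results, base_results, n_perm=n_perm, seed=seed)
                table_rows.append(
                    _agg_row(
                        condition, subset, scheme, model.kind, results,
                        lifts.mean_lift, lifts.p_value,
                    )
                )
                for u, lift in zip(lifts.users, lifts.per_user_lift):
                    lift_rows.append(
                        {
                            "condition": condition,
                            "subset": subset,
                            "scheme": scheme,
                            "model": model.kind,
                            "participant": u,
                            "lift": lift,
                        }
                    )
    return {
        "table": pd.DataFrame(table_rows),
        "lifts": pd.DataFrame(lift_rows),
    }


def _eval_one(matrix, model, scheme, cv) -> EvalResult:
    if scheme == "stratified_kfold_repeated":
        return evaluate_personal(matrix, model, cv)
    if scheme == "emotion_block":
        return emotion_block_cv(matrix, model)
    raise ValueError(f"unknown scheme {scheme!r}")


def _per_user_stats(results: dict, attr: str) -> tuple[float, float]:
    vals = np.array([getattr(r, attr) for r in results.values()], dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan"), float("nan")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def _agg_row(condition, subset, scheme, model, results, mean_lift, p_value) -> dict:
    acc_m, acc_s = _per_user_stats(results, "mean_accuracy")
    f1_m, f1_s = _per_user_stats(results, "mean_f1")
    auc_m, auc_s = _per_user_stats(results, "mean_auc")
    return {
        "condition": condition,
        "subset": subset,
        "scheme": scheme,
        "model": model,
        "n_users": len(results),
        "auc": auc_m,
        "auc_sd": auc_s,
        "f1": f1_m,
        "f1_sd": f1_s,
        "accuracy": acc_m,
        "accuracy_sd": acc_s,
        "user_lift": mean_lift,
        "p_value": p_value,
    }


def _table_row(condition, subset, scheme, model, result: EvalResult, mean_lift, p_value) -> dict:
    pf = result.per_fold
    def _sd(col):
        vals = pf[col].dropna()
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return {
        "condition": condition,
        "subset": subset,
        "scheme": scheme,
        "model": model,
        "n_users": len(pf),
        "auc": result.mean_auc,
        "auc_sd": _sd("roc_auc") if pf["roc_auc"].notna().any() else float("nan"),
        "f1": result.mean_f1,
        "f1_sd": _sd("f1"),
        "accuracy": result.mean_accuracy,
        "accuracy_sd": _sd("accuracy"),
        "user_lift": mean_lift,
        "p_value": p_value,
    }
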