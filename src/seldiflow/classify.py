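"""DLDA / linear-SVM classification under repeated balanced random splits
with nested (double) cross-validation.

The outer loop draws many random training/test splits with class
proportions preserved; inside each outer training set a 5-fold cross-
validation selects the number of top-ranked peaks (and the SVM cost), with
the feature ranking recomputed inside every inner fold so that no
information flows from any held-out data into model selection.  The
selected model is refit on the whole outer training set and evaluated once
on the untouched test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io import SpecError


@dataclass
class SplitScheme:
    n_train: int
    n_splits: int = 500
    balanced: str = "stratified"   # "stratified" | "equal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise SpecError("n_splits must be >= 1")
        if self.balanced not in ("stratified", "equal"):
            raise SpecError("balanced must be 'stratified' or 'equal'")


@dataclass
class ClassifierSpec:
    model: str = "dlda"            # "dlda" | "svm"
    feature_grid: tuple = tuple(range(5, 51, 5))
    cost_grid: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.model not in ("dlda", "svm"):
            raise SpecError("model must be 'dlda' or 'svm'")
        if not self.feature_grid:
            raise SpecError("feature_grid must be non-empty")
        if self.model == "svm" and not self.cost_grid:
            raise SpecError("cost_grid must be non-empty for SVM")
        if self.inner_folds < 2:
            raise SpecError("inner_folds must be >= 2")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def _largest_remainder(counts: np.ndarray, n: int) -> np.ndarray:
    """Integer class quotas summing to n, proportional to counts."""
    total = counts.sum()
    exact = counts * n / total
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base


def make_splits(labels, scheme: SplitScheme) -> list[tuple]:
    """Random balanced train/test splits, deterministic given the seed.

    Per-class training counts follow class proportions via largest-remainder
    rounding ("stratified"), or are forced equal ("equal").  Every class
    keeps at least one test sample; infeasible training sizes raise with the
    minimum feasible size.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise SpecError("every class needs at least 2 members")
    n_total = len(labels)
    n = scheme.n_train
    if not (0 < n < n_total):
        raise SpecError(f"n_train must be in (0, {n_total})")
    if scheme.balanced == "stratified":
        quota = _largest_remainder(counts, n)
    else:
        k = len(classes)
        if n % k:
            raise SpecError(f"'equal' balancing requires n_train divisible by {k}")
        quota = np.full(k, n // k)
    if np.any(quota < 1) or np.any(counts - quota < 1):
        k = len(classes)
        raise SpecError(
            f"infeasible n_train={n}: need >= {k} and <= {n_total - k} with "
            "at least one train and one test sample per class")
    root = np.random.SeedSequence(scheme.seed)
    splits = []
    for child in root.spawn(scheme.n_splits):
        rng = np.random.default_rng(child)
        train_idx = []
        for cls, q in zip(classes, quota):
            members = np.flatnonzero(labels == cls)
            train_idx.append(rng.choice(members, size=q, replace=False))
        train = np.sort(np.concatenate(train_idx))
        test = np.setdiff1d(np.arange(n_total), train)
        splits.append((train, test))
    return splits


# ---------------------------------------------------------------------------
# DLDA
# ---------------------------------------------------------------------------

@dataclass
class DLDAModel:
    """Gaussian classifier with class means and a shared diagonal covariance."""

    classes: np.ndarray
    means: np.ndarray           # classes x features
    pooled_var: np.ndarray      # features
    feature_ids: list = field(default_factory=list)


def train_dlda(X: np.ndarray, y, feature_ids: list | None = None) -> DLDAModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise SpecError("need at least 2 classes")
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    ss = np.zeros(X.shape[1])
    denom = 0
    for c, mu in zip(classes, means):
        sub = X[y == c]
        ss += ((sub - mu) ** 2).sum(axis=0)
        denom += len(sub) - 1
    if denom < 1:
        raise SpecError("not enough samples for a pooled variance")
    pooled = ss / denom
    bad = np.flatnonzero(pooled <= 0)
    if len(bad):
        names = ([feature_ids[j] for j in bad[:5]] if feature_ids
                 else bad[:5].tolist())
        raise SpecError(f"zero pooled variance for feature(s) {names}")
    return DLDAModel(classes=classes, means=means, pooled_var=pooled,
                     feature_ids=list(feature_ids or []))


def predict(model, X: np.ndarray) -> np.ndarray:
    """Predict labels; DLDA ties go to the class earlier in sorted order."""
    X = np.asarray(X, dtype=float)
    if isinstance(model, DLDAModel):
        if X.shape[1] != model.means.shape[1]:
            raise SpecError(
                f"feature count {X.shape[1]} != training {model.means.shape[1]}")
        # diagonal Mahalanobis distance to each class mean
        d2 = ((X[:, None, :] - model.means[None, :, :]) ** 2
              / model.pooled_var[None, None, :]).sum(axis=2)
        return model.classes[np.argmin(d2, axis=1)]
    if X.shape[1] != model.n_features_in_:
        raise SpecError(
            f"feature count {X.shape[1]} != training {model.n_features_in_}")
    return model.predict(X)


def _fit(spec: ClassifierSpec, X, y, cost):
    if spec.model == "dlda":
        return train_dlda(X, y)
    return SVC(kernel="linear", C=cost).fit(X, y)


# ---------------------------------------------------------------------------
# feature ranking
# ---------------------------------------------------------------------------

def rank_features(X: np.ndarray, y, mode: str = "auto") -> np.ndarray:
    """Feature order by descending |pooled t| (2-class) or F (>=3 classes).

    Constant features get statistic 0 and sink to the end; ties break toward
    the lower feature index (lower m/z for mass-ordered columns).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if mode == "auto":
        mode = "two_class_t" if len(classes) == 2 else "three_class_F"
    if mode == "two_class_t":
        if len(classes) != 2:
            raise SpecError("two_class_t ranking requires exactly 2 classes")
        a, b = X[y == classes[0]], X[y == classes[1]]
        na, nb = len(a), len(b)
        diff = a.mean(axis=0) - b.mean(axis=0)
        sp2 = (a.var(axis=0, ddof=1) * (na - 1) + b.var(axis=0, ddof=1) * (nb - 1)) \
            / (na + nb - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.abs(diff) / np.sqrt(sp2 * (1 / na + 1 / nb))
        stat = np.where(sp2 > 0, stat, np.where(diff != 0, np.inf, 0.0))
    elif mode == "three_class_F":
        subs = [X[y == c] for c in classes]
        ns = np.array([len(s) for s in subs])
        grand = X.mean(axis=0)
        means = np.array([s.mean(axis=0) for s in subs])
        ssb = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
        ssw = sum(((s - m) ** 2).sum(axis=0) for s, m in zip(subs, means))
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = (ssb / (len(classes) - 1)) / (ssw / (len(y) - len(classes)))
        stat = np.where(ssw > 0, stat, np.where(ssb > 0, np.inf, 0.0))
    else:
        raise SpecError(f"unknown ranking mode {mode!r}")
    return np.argsort(-stat, kind="stable")


# ---------------------------------------------------------------------------
# nested selection and double CV
# ---------------------------------------------------------------------------

def inner_cv_select(X: np.ndarray, y, spec: ClassifierSpec, seed: int):
    """5-fold grid search over feature count (and SVM cost) on training data.

    Feature ranking is recomputed inside each fold on that fold's training
    part only.  Returns (k*, cost*) with ties resolved toward smaller k,
    then smaller cost; cost* is None for DLDA.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    costs = sorted(spec.cost_grid) if spec.model == "svm" else [None]
    ks = sorted({min(k, X.shape[1]) for k in spec.feature_grid})
    skf = StratifiedKFold(n_splits=spec.inner_folds, shuffle=True,
                          random_state=seed % (2 ** 31))
    acc = np.zeros((len(ks), len(costs)))
    for tr, va in skf.split(X, y):
        order = rank_features(X[tr], y[tr])
        for ki, k in enumerate(ks):
            feats = order[:k]
            for ci, cost in enumerate(costs):
                model = _fit(spec, X[np.ix_(tr, feats)], y[tr], cost)
                pred = predict(model, X[np.ix_(va, feats)])
                acc[ki, ci] += np.mean(pred == y[va])
    best = np.unravel_index(np.argmax(acc), acc.shape)  # first max: smaller k, cost
    # argmax scans k-major, so exact ties already favor smaller k then cost
    return ks[best[0]], costs[best[1]]


@dataclass
class CVResult:
    per_split: pd.DataFrame
    aggregate: dict
    confusion: pd.DataFrame | None = None
    classes: tuple = ()


def metrics(y_true, y_pred, positive_class: str = "cancer"):
    """Accuracy / sensitivity / specificity in percent, plus confusion matrix.

    Two classes: sensitivity is the recall of the positive (cancer) class,
    specificity the recall of the other class.  Three or more classes: only
    accuracy plus the row-percentage confusion matrix (rows = true class).
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise SpecError("label vectors differ in length")
    classes = np.unique(y_true)
    if not set(np.unique(y_pred)) <= set(classes):
        extra = set(np.unique(y_pred)) - set(classes)
        raise SpecError(f"predicted label(s) outside class set: {sorted(extra)}")
    accuracy = 100.0 * np.mean(y_true == y_pred)
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=float)
    for t, p in zip(y_true, y_pred):
        counts.loc[t, p] += 1
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    if len(classes) == 2:
        if positive_class not in classes:
            raise SpecError(f"positive class {positive_class!r} not present")
        negative = [c for c in classes if c != positive_class][0]
        sens = row_pct.loc[positive_class, positive_class]
        spec_ = row_pct.loc[negative, negative]
        return {"accuracy": accuracy, "sensitivity": float(sens),
                "specificity": float(spec_), "confusion": row_pct}
    return {"accuracy": accuracy, "sensitivity": None, "specificity": None,
            "confusion": row_pct}


def double_cv(X: np.ndarray, labels, scheme: SplitScheme, spec: ClassifierSpec,
              feature_ids: list | None = None,
              positive_class: str = "cancer") -> CVResult:
    """Repeated random splits with nested hyperparameter selection.

    For each outer split: select (k*, cost*) by inner 5-fold CV on the
    training part only; rank features on the full training part; refit with
    the top k* features; evaluate on the untouched test part.  Aggregates
    are unweighted means over splits.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    splits = make_splits(labels, scheme)
    feature_ids = list(feature_ids) if feature_ids is not None else \
        [str(j) for j in range(X.shape[1])]
    classes = np.unique(labels)
    rows = []
    conf_sum = pd.DataFrame(0.0, index=classes, columns=classes)
    inner_seeds = [int(np.random.default_rng(c).integers(2 ** 31))
                   for c in np.random.SeedSequence(scheme.seed).spawn(len(splits))]
    for split_i, (train, test) in enumerate(splits):
        k_star, cost_star = inner_cv_select(
            X[train], labels[train], spec, seed=inner_seeds[split_i])
        order = rank_features(X[train], labels[train])
        feats = order[:k_star]
        model = _fit(spec, X[np.ix_(train, feats)], labels[train], cost_star)
        pred = predict(model, X[np.ix_(test, feats)])
        m = metrics(labels[test], pred, positive_class=positive_class)
        for t, p in zip(labels[test], pred):
            conf_sum.loc[t, p] += 1
        rows.append({
            "split": split_i, "accuracy": m["accuracy"],
            "sensitivity": m["sensitivity"], "specificity": m["specificity"],
            "k": k_star, "cost": cost_star,
            "features": [feature_ids[j] for j in feats]})
    per_split = pd.DataFrame(rows)
    aggregate = {
        "accuracy": float(per_split["accuracy"].mean()),
        "accuracy_sd": float(per_split["accuracy"].std(ddof=1))
        if len(per_split) > 1 else 0.0,
        "n_splits": len(per_split),
        "n_train": scheme.n_train,
        "model": spec.model,
    }
    if len(classes) == 2:
        aggregate["sensitivity"] = float(per_split["sensitivity"].mean())
        aggregate["specificity"] = float(per_split["specificity"].mean())
    confusion = conf_sum.div(conf_sum.sum(axis=1), axis=0) * 100.0
    return CVResult(per_split=per_split, aggregate=aggregate,
                    confusion=confusion, classes=tuple(classes))


def training_size_sweep(X, labels, sizes, scheme: SplitScheme,
                        spec: ClassifierSpec, **kwargs) -> pd.DataFrame:
    """Run double CV at several training sizes; per-size aggregate rows."""
    rows = []
    for n in sizes:
        sub = SplitScheme(n_train=n, n_splits=scheme.n_splits,
                          balanced=scheme.balanced, seed=scheme.seed)
        res = double_cv(X, labels, sub, spec, **kwargs)
        rows.append(res.aggregate)
    return pd.DataFrame(rows)
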