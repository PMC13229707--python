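"""Subject-level classification from channel-wise HFD features.

Each subject is an 8-dimensional feature vector (one HFD value per
channel); the parkinsonian group is the positive class.  A linear
soft-margin SVM is evaluated with nested leave-one-out cross-validation:
the outer loop holds out one subject at a time, the inner loop (LOO on
the remaining subjects) selects the regularization constant C from a
small grid ({0.1, 1, 10} by default, ties going to the smallest C), the
classifier is refit on the full outer-training set, and the held-out
subject receives a predicted label plus a signed decision score.
Features are z-scored with training-fold statistics only, so no
information leaks from the held-out subject.

Discrimination is summarized by the confusion counts, the derived
proportions (accuracy, sensitivity, specificity, precision, F1), and a
pair-counting ROC-AUC; significance of the observed accuracy is
assessed by label-permutation with the full nested procedure re-run on
every permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import config_context
from sklearn.svm import SVC

from .errors import ParameterError

__all__ = [
    "FeatureMatrix",
    "CVResult",
    "ConfusionCounts",
    "MetricsReport",
    "ROCResult",
    "PermutationResult",
    "Boundary2D",
    "build_features",
    "loocv_classify",
    "confusion",
    "metrics",
    "roc_auc",
    "permutation_test",
    "boundary_2d",
]

DEFAULT_C_GRID = (0.1, 1.0, 10.0)
POSITIVE_GROUP = "pd"


@dataclass
class FeatureMatrix:
    """Subjects x channels HFD matrix with binary labels (PD = 1)."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str]
    channel_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ParameterError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.X)):
            raise ParameterError("feature matrix contains non-finite values")
        if self.y.shape != (self.X.shape[0],):
            raise ParameterError("labels must match the number of subjects")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ParameterError("labels must be binary (PD=1, control=0)")


@dataclass
class CVResult:
    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray  # signed distance to the separating hyperplane
    selected_c: list[float]  # inner-CV choice per outer fold

    @property
    def accuracy(self) -> float:
        return float((self.y_pred == self.y_true).mean())


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class MetricsReport:
    """Derived proportions; a metric whose denominator is zero is None
    and named in ``undefined`` rather than silently reported as 0."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    undefined: list[str] = field(default_factory=list)


@dataclass
class ROCResult:
    auc: float
    roc_points: np.ndarray  # (n_thresholds + 1, 2) of (fpr, tpr)


@dataclass
class PermutationResult:
    p: float
    observed_accuracy: float
    null_accuracies: np.ndarray


@dataclass
class Boundary2D:
    pair: tuple[int, int]
    pair_ids: tuple[str, str]
    coef: np.ndarray  # hyperplane w in standardized 2-D space
    intercept: float
    grid_x: np.ndarray
    grid_y: np.ndarray
    decision: np.ndarray  # decision values over the grid
    refit_accuracy: float  # LOOCV accuracy of the 2-feature model


def build_features(
    fd_table: pd.DataFrame,
    condition: str | list[str] = ("pd", "control"),
    subject: str = "subject_id",
    group: str = "group",
    channel: str = "channel",
    fd: str = "fd",
) -> FeatureMatrix:
    """Assemble a subjects x channels matrix from a tidy FD table.

    ``condition`` filters rows (default: the baseline sessions of both
    groups, i.e. the untreated parkinsonian state vs the healthy
    control state).  Every retained subject must have exactly one FD
    value per channel; gaps and duplicates are reported, not patched.
    """
    for col in (subject, group, channel, fd):
        if col not in fd_table.columns:
            raise ParameterError(f"FD table lacks column {col!r}")
    conds = [condition] if isinstance(condition, str) else list(condition)
    sub = fd_table
    if "condition" in fd_table.columns:
        sub = fd_table[fd_table["condition"].isin(conds)]
        if sub.empty:
            raise ParameterError(f"no rows for condition(s) {conds}")
    dups = sub.duplicated([subject, channel])
    if dups.any():
        bad = sub.loc[dups, [subject, channel]].iloc[0]
        raise ParameterError(
            f"duplicate FD entry for subject {bad[subject]!r}, "
            f"channel {bad[channel]!r}"
        )
    wide = sub.pivot(index=subject, columns=channel, values=fd)
    if wide.isna().any().any():
        gaps = [
            (wide.index[i], wide.columns[j])
            for i, j in zip(*np.nonzero(wide.isna().to_numpy()))
        ]
        raise ParameterError(f"missing (subject, channel) FD values: {gaps}")
    gmap = sub.drop_duplicates(subject).set_index(subject)[group]
    labels = (gmap.loc[wide.index] == POSITIVE_GROUP).astype(int).to_numpy()
    return FeatureMatrix(
        X=wide.to_numpy(dtype=float),
        y=labels,
        subject_ids=[str(s) for s in wide.index],
        channel_ids=[str(c) for c in wide.columns],
    )


def _standardize(train: np.ndarray, *others: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return tuple((arr - mu) / sd for arr in (train, *others))


def _fit_svm(X: np.ndarray, y: np.ndarray, c: float) -> SVC:
    clf = SVC(kernel="linear", C=c)
    clf.fit(X, y)
    return clf


def _loo_accuracy(X: np.ndarray, y: np.ndarray, c: float, standardize: bool) -> float:
    """Plain (non-nested) LOO accuracy at a fixed C; the inner criterion."""
    n = len(y)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ParameterError("a training fold contains a single class")
        Xtr, Xte = X[mask], X[i : i + 1]
        if standardize:
            Xtr, Xte = _standardize(Xtr, Xte)
        clf = _fit_svm(Xtr, y[mask], c)
        correct += int(clf.predict(Xte)[0] == y[i])
    return correct / n


def loocv_classify(
    features: FeatureMatrix,
    c_grid=DEFAULT_C_GRID,
    standardize: bool = True,
) -> CVResult:
    """Nested leave-one-out cross-validation of the linear SVM.

    With a single-element ``c_grid`` the inner loop is skipped (nothing
    to select).  Inner ties resolve toward the smallest C, i.e. the
    strongest regularization.
    """
    X, y = features.X, features.y
    n = len(y)
    c_grid = sorted(float(c) for c in c_grid)
    if not c_grid:
        raise ParameterError("c_grid must not be empty")
    if min(np.bincount(y, minlength=2)) < 2:
        raise ParameterError("need at least 2 subjects per class for LOOCV")
    preds = np.empty(n, dtype=int)
    scores = np.empty(n)
    selected: list[float] = []
    with config_context(assume_finite=True):
        return _loocv_inner(features, X, y, n, c_grid, standardize, preds, scores, selected)


def _loocv_inner(features, X, y, n, c_grid, standardize, preds, scores, selected):
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr_raw, ytr = X[mask], y[mask]
        if len(np.unique(ytr)) < 2:
            raise ParameterError("a training fold contains a single class")
        if len(c_grid) == 1:
            best_c = c_grid[0]
        else:
            inner = [(_loo_accuracy(Xtr_raw, ytr, c, standardize), -c) for c in c_grid]
            # max accuracy; ties -> smallest C (hence the -c key reversed)
            best_c = -max(inner, key=lambda t: (t[0], t[1]))[1]
        Xtr, Xte = (
            _standardize(Xtr_raw, X[i : i + 1]) if standardize
            else (Xtr_raw, X[i : i + 1])
        )
        clf = _fit_svm(Xtr, ytr, best_c)
        preds[i] = int(clf.predict(Xte)[0])
        scores[i] = float(clf.decision_function(Xte)[0])
        selected.append(best_c)
    return CVResult(
        subject_ids=list(features.subject_ids),
        y_true=y.copy(),
        y_pred=preds,
        scores=scores,
        selected_c=selected,
    )


def confusion(cv: CVResult) -> ConfusionCounts:
    """Confusion counts with PD (label 1) as the positive class."""
    yt, yp = cv.y_true, cv.y_pred
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision, F1 from counts."""
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    acc = ratio(counts.tp + counts.tn, counts.total, "accuracy")
    sens = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    prec = ratio(counts.tp, counts.tp + counts.fp, "precision")
    if prec is None or sens is None or (prec + sens) == 0:
        if "f1" not in undefined:
            undefined.append("f1")
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricsReport(
        accuracy=acc, sensitivity=sens, specificity=spec, precision=prec,
        f1=f1, undefined=undefined,
    )


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and pair-counting AUC.

    AUC is the Mann-Whitney statistic: the fraction of
    (positive, negative) pairs whose positive score is larger, ties
    counted half.  ROC points sweep every distinct score threshold with
    tied scores grouped, so the trapezoid area of the returned points
    equals the pair-counting AUC exactly.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ParameterError("scores and labels must be equal-length 1-D")
    if not np.all(np.isfinite(s)):
        raise ParameterError("scores must be finite")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("both classes must be present for ROC analysis")
    pos, neg = s[y == 1], s[y == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * equal) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[order[j]] == s[order[i]]:
            tp += int(y[order[j]] == 1)
            fp += int(y[order[j]] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return ROCResult(auc=float(auc), roc_points=np.array(points))


def permutation_test(
    features: FeatureMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    c_grid=DEFAULT_C_GRID,
    standardize: bool = True,
) -> PermutationResult:
    """Label-permutation significance of the LOOCV accuracy.

    The entire nested procedure is re-run on every permuted label
    vector; p uses the add-one estimator
    ``(1 + #{null >= observed}) / (n_perm + 1)``, which can never
    return an impossible p = 0.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100 for a meaningful p-value")
    observed = loocv_classify(features, c_grid=c_grid, standardize=standardize).accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        while True:
            y_perm = rng.permutation(features.y)
            if min(np.bincount(y_perm, minlength=2)) >= 2:
                break
        perm_features = FeatureMatrix(
            X=features.X, y=y_perm,
            subject_ids=features.subject_ids, channel_ids=features.channel_ids,
        )
        null[b] = loocv_classify(
            perm_features, c_grid=c_grid, standardize=standardize
        ).accuracy
    p = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
    return PermutationResult(p=p, observed_accuracy=observed, null_accuracies=null)


def boundary_2d(
    features: FeatureMatrix,
    pair: tuple[int, int] | str = "auto",
    c: float = 1.0,
    grid_size: int = 60,
) -> Boundary2D:
    """Two-feature refit for decision-boundary visualization.

    ``pair='auto'`` picks the two channels with the largest absolute
    standardized mean difference between groups (zero-variance channels
    excluded).  The refit uses the whole cohort and is intended solely
    for plotting; the reported 2-feature accuracy comes from a fresh
    LOOCV on the selected pair.
    """
    X, y = features.X, features.y
    if isinstance(pair, str):
        if pair != "auto":
            raise ParameterError("pair must be an index pair or 'auto'")
        sd = X.std(axis=0, ddof=0)
        valid = sd > 0
        if valid.sum() < 2:
            raise ParameterError("fewer than 2 non-constant features")
        smd = np.zeros(X.shape[1])
        smd[valid] = np.abs(
            X[y == 1][:, valid].mean(axis=0) - X[y == 0][:, valid].mean(axis=0)
        ) / sd[valid]
        idx = tuple(int(i) for i in np.argsort(-smd)[:2])
    else:
        idx = (int(pair[0]), int(pair[1]))
        if idx[0] == idx[1] or max(idx) >= X.shape[1] or min(idx) < 0:
            raise ParameterError(f"invalid feature pair {idx}")
    sub = FeatureMatrix(
        X=X[:, list(idx)], y=y,
        subject_ids=features.subject_ids,
        channel_ids=[features.channel_ids[i] for i in idx],
    )
    (Xz,) = _standardize(sub.X)
    clf = _fit_svm(Xz, y, c)
    lo = Xz.min(axis=0) - 0.5
    hi = Xz.max(axis=0) + 0.5
    gx, gy = np.meshgrid(
        np.linspace(lo[0], hi[0], grid_size), np.linspace(lo[1], hi[1], grid_size)
    )
    dec = clf.decision_function(np.column_stack([gx.ravel(), gy.ravel()]))
    refit_acc = loocv_classify(sub, c_grid=(c,)).accuracy
    return Boundary2D(
        pair=idx,
        pair_ids=(features.channel_ids[idx[0]], features.channel_ids[idx[1]]),
        coef=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        grid_x=gx,
        grid_y=gy,
        decision=dec.reshape(gx.shape),
        refit_accuracy=refit_acc,
    )
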