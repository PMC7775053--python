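"""Feature selection, classifiers and validation for lesion characterization.

Forward sequential feature selection (SFS, training F1, max 10 features),
four classifiers (LDA, KNN, SVM-RBF, shallow ANN) and two validation
schemes (LOOCV and repeated stratified 70/30 hold-out; the ANN uses
70/15/15 train/validation/test). Standardization, SFS and hyperparameter
search are refit inside every training fold to avoid leakage. The
malignant class is the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from qustex.ann import LMNetwork, LMTrainConfig

POSITIVE_LABEL = "malignant"
SVM_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
SVM_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))


@dataclass
class ClassifierSpec:
    """Classifier kind plus hyperparameter settings/grids."""

    kind: str  # "LDA" | "KNN" | "SVM-RBF" | "ANN"
    knn_k_grid: tuple[int, ...] = (1, 3, 5)
    svm_c: float | None = None      # fixed values skip the grid search
    svm_gamma: float | None = None
    svm_c_grid: tuple[float, ...] = SVM_C_GRID
    svm_gamma_grid: tuple[float, ...] = SVM_GAMMA_GRID
    ann: LMTrainConfig = field(default_factory=LMTrainConfig)
    ann_sfs_max_epochs: int = 60    # reduced-epoch training inside SFS only
    max_features: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("LDA", "KNN", "SVM-RBF", "ANN"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class ClassificationReport:
    """Six ROC-derived metrics (percent except AUC) plus confusion counts."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    ppv: float
    npv: float
    tp: int
    fp: int
    tn: int
    fn: int
    selected_features: list = field(default_factory=list)
    per_realization: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rank_auc(labels01: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic of the scores (ties count 1/2)."""
    y = np.asarray(labels01)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_metrics(labels01, scores, predictions01) -> ClassificationReport:
    """Confusion metrics from hard predictions plus rank AUC from scores."""
    y = np.asarray(labels01, dtype=int)
    pred = np.asarray(predictions01, dtype=int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    def pct(num, den):
        return 100.0 * num / den if den else float("nan")
    return ClassificationReport(
        sensitivity=pct(tp, tp + fn), specificity=pct(tn, tn + fp),
        accuracy=pct(tp + tn, tp + tn + fp + fn), auc=rank_auc(y, scores),
        ppv=pct(tp, tp + fp), npv=pct(tn, tn + fn),
        tp=tp, fp=fp, tn=tn, fn=fn)


def f1_score01(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """F1 with the positive class = 1; 0 when precision+recall is 0."""
    tp = np.sum((y_pred == 1) & (y_true == 1))
    fp = np.sum((y_pred == 1) & (y_true == 0))
    fn = np.sum((y_pred == 0) & (y_true == 1))
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 0.0


# ---------------------------------------------------------------------------
# classifiers (uniform fit / predict / score interface)
# ---------------------------------------------------------------------------

class GaussianLDA:
    """Two-class shared-covariance Gaussian discriminant with posteriors.

    A singular pooled covariance is ridge-regularized by
    ``1e-6 * trace / d`` on the diagonal.
    """

    def __init__(self) -> None:
        self._fitted = False

    def fit(self, x: np.ndarray, y: np.ndarray) -> "GaussianLDA":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        d = x.shape[1]
        self.means = np.stack([x[y == c].mean(axis=0) for c in (0, 1)])
        self.log_priors = np.log([np.mean(y == 0), np.mean(y == 1)])
        centered = x - self.means[y]
        cov = centered.T @ centered / max(len(y) - 2, 1)
        if np.linalg.matrix_rank(cov) < d:
            cov = cov + np.eye(d) * max(np.trace(cov) / d, 1.0) * 1e-6
        self.cov_inv = np.linalg.inv(cov)
        self._fitted = True
        return self

    def score(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        logits = np.stack([
            x @ self.cov_inv @ self.means[c]
            - 0.5 * self.means[c] @ self.cov_inv @ self.means[c]
            + self.log_priors[c]
            for c in (0, 1)], axis=1)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e[:, 1] / e.sum(axis=1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.score(x) >= 0.5).astype(int)


class _KNN:
    def __init__(self, k: int):
        self.k = k
        self.clf = KNeighborsClassifier(n_neighbors=k)

    def fit(self, x, y):
        self.clf.fit(x, y)
        return self

    def predict(self, x):
        return self.clf.predict(x)

    def score(self, x):
        return self.clf.predict_proba(x)[:, 1]

    def loo_train_predict(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Leave-one-out prediction of the training points themselves."""
        x = np.asarray(x, dtype=float)
        d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=2)
        np.fill_diagonal(d2, np.inf)
        idx = np.argsort(d2, axis=1)[:, :self.k]
        votes = y[idx].mean(axis=1)
        return (votes > 0.5).astype(int)


class _SVM:
    def __init__(self, c: float, gamma: float):
        self.clf = SVC(kernel="rbf", C=c, gamma=gamma)

    def fit(self, x, y):
        self.clf.fit(x, y)
        return self

    def predict(self, x):
        return self.clf.predict(x)

    def score(self, x):
        return self.clf.decision_function(x)


class _ANN:
    def __init__(self, config: LMTrainConfig, seed: int):
        self.config = config
        self.seed = seed
        self.val = None  # optional (x_val, y_val)

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        self.net = LMNetwork(x.shape[1], config=self.config, seed=self.seed)
        x_val, y_val = self.val if self.val is not None else (None, None)
        self.net.fit(x, y, x_val, y_val)
        return self

    def predict(self, x):
        return self.net.predict(np.asarray(x, dtype=float))

    def score(self, x):
        return self.net.predict_proba(np.asarray(x, dtype=float))[:, 1]


# ---------------------------------------------------------------------------
# standardization and table handling
# ---------------------------------------------------------------------------

def split_table(table: pd.DataFrame, label_column: str = "label"):
    x = table.drop(columns=[label_column]).to_numpy(dtype=float)
    y = (table[label_column] == POSITIVE_LABEL).astype(int).to_numpy()
    return x, y, list(table.columns.drop(label_column))


class Standardizer:
    """Column z-scoring with training-set statistics (zero std -> 1)."""

    def fit(self, x: np.ndarray) -> "Standardizer":
        self.mean = x.mean(axis=0)
        self.std = x.std(axis=0)
        self.std[self.std == 0] = 1.0
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std


# ---------------------------------------------------------------------------
# SFS and hyperparameter search
# ---------------------------------------------------------------------------

def _training_f1(clf, x: np.ndarray, y: np.ndarray) -> float:
    """Training-set F1; KNN uses leave-one-out-on-train to avoid the
    self-match degeneracy of resubstitution."""
    clf.fit(x, y)
    if isinstance(clf, _KNN):
        pred = clf.loo_train_predict(x, y)
    else:
        pred = clf.predict(x)
    return f1_score01(y, pred)


def sfs_select(x: np.ndarray, y: np.ndarray, make_clf, max_features: int = 10):
    """Greedy forward selection maximizing training F1.

    Returns ``(selected_indices, best_f1)``: the shortest prefix of the
    greedy path achieving the maximum F1 (ties resolved toward fewer
    features). Stops early once F1 = 1 is reached.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("SFS needs both classes in the training table")
    n_feat = x.shape[1]
    max_features = min(max_features, n_feat)
    selected: list[int] = []
    best_f1 = -1.0
    best_size = 0
    remaining = list(range(n_feat))
    path_f1: list[float] = []
    for _size in range(1, max_features + 1):
        scores = [(_training_f1(make_clf(), x[:, selected + [c]], y), c) for c in remaining]
        step_f1, chosen = max(scores, key=lambda t: (t[0], -t[1]))
        selected.append(chosen)
        remaining.remove(chosen)
        path_f1.append(step_f1)
        if step_f1 > best_f1:
            best_f1 = step_f1
            best_size = len(selected)
        if best_f1 >= 1.0:
            break
    return selected[:best_size], best_f1


def _sfs_select_knn(x: np.ndarray, y: np.ndarray, k: int, max_features: int = 10):
    """KNN-specialized forward selection on cached per-feature distances.

    Equivalent to :func:`sfs_select` with a KNN factory (leave-one-out
    training F1), but incremental squared distances make it O(n^2) per
    candidate instead of a classifier refit.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("SFS needs both classes in the training table")
    n, n_feat = x.shape
    max_features = min(max_features, n_feat)
    diffs = (x[:, None, :] - x[None, :, :]) ** 2  # (n, n, d)
    current = np.zeros((n, n))
    eye = np.eye(n, dtype=bool)

    def loo_f1(d2: np.ndarray) -> float:
        d2 = d2.copy()
        d2[eye] = np.inf
        idx = np.argpartition(d2, k, axis=1)[:, :k]
        pred = (y[idx].mean(axis=1) > 0.5).astype(int)
        return f1_score01(y, pred)

    selected: list[int] = []
    remaining = list(range(n_feat))
    best_f1, best_size = -1.0, 0
    for _size in range(1, max_features + 1):
        scores = [(loo_f1(current + diffs[:, :, c]), c) for c in remaining]
        step_f1, chosen = max(scores, key=lambda t: (t[0], -t[1]))
        selected.append(chosen)
        remaining.remove(chosen)
        current = current + diffs[:, :, chosen]
        if step_f1 > best_f1:
            best_f1, best_size = step_f1, len(selected)
        if best_f1 >= 1.0:
            break
    return selected[:best_size], best_f1


def grid_search_svm(x: np.ndarray, y: np.ndarray, seed: int = 0,
                    c_grid=SVM_C_GRID, gamma_grid=SVM_GAMMA_GRID) -> tuple[float, float]:
    """Exhaustive (C, gamma) search by stratified 5-fold training F1.

    Ties resolve to the smallest C, then the smallest gamma.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y, dtype=int)
    n_splits = min(5, int(np.bincount(y).min()))
    best = (-1.0, None, None)
    if n_splits < 2:  # too few samples to cross-validate; fall back to resubstitution
        for c in c_grid:
            for g in gamma_grid:
                f1 = _training_f1(_SVM(c, g), x, y)
                if f1 > best[0]:
                    best = (f1, c, g)
        return best[1], best[2]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))
    for c in c_grid:
        for g in gamma_grid:
            preds = np.empty_like(y)
            for tr, te in folds:
                clf = _SVM(c, g).fit(x[tr], y[tr])
                preds[te] = clf.predict(x[te])
            f1 = f1_score01(y, preds)
            if f1 > best[0]:
                best = (f1, c, g)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# per-fold pipeline
# ---------------------------------------------------------------------------

def _stratified_split(y: np.ndarray, test_fraction: float, rng: np.random.Generator):
    """Largest-remainder stratified index split; returns (train_idx, test_idx)."""
    y = np.asarray(y)
    n_test = int(round(len(y) * test_fraction))
    test_idx: list[int] = []
    classes = np.unique(y)
    quotas = {}
    for c in classes:
        quotas[c] = len(np.flatnonzero(y == c)) * test_fraction
    base = {c: int(np.floor(q)) for c, q in quotas.items()}
    rem = sorted(classes, key=lambda c: quotas[c] - base[c], reverse=True)
    short = n_test - sum(base.values())
    for c in rem[:short]:
        base[c] += 1
    for c in classes:
        members = np.flatnonzero(y == c)
        take = min(max(base[c], 1), len(members) - 1)  # keep both classes on both sides
        test_idx.extend(rng.choice(members, size=take, replace=False))
    test_idx = np.sort(np.asarray(test_idx))
    train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
    return train_idx, test_idx


def _fit_fold(x_tr, y_tr, x_te, spec: ClassifierSpec, seed: int):
    """Standardize, select features, tune and fit within one training fold."""
    scaler = Standardizer().fit(x_tr)
    x_tr = scaler.transform(x_tr)
    x_te = scaler.transform(x_te)
    rng = np.random.default_rng(seed)

    if spec.kind == "LDA":
        sel, _ = sfs_select(x_tr, y_tr, GaussianLDA, spec.max_features)
        clf = GaussianLDA().fit(x_tr[:, sel], y_tr)
    elif spec.kind == "KNN":
        best = (-1.0, None, None)
        for k in spec.knn_k_grid:
            sel_k, f1 = _sfs_select_knn(x_tr, y_tr, k, spec.max_features)
            if f1 > best[0]:
                best = (f1, k, sel_k)
        _, k, sel = best
        clf = _KNN(k).fit(x_tr[:, sel], y_tr)
    elif spec.kind == "SVM-RBF":
        d = x_tr.shape[1]
        sel, _ = sfs_select(x_tr, y_tr, lambda: _SVM(1.0, 1.0 / d), spec.max_features)
        if spec.svm_c is not None and spec.svm_gamma is not None:
            c, g = spec.svm_c, spec.svm_gamma
        else:
            c, g = grid_search_svm(x_tr[:, sel], y_tr, seed=seed,
                                   c_grid=spec.svm_c_grid,
                                   gamma_grid=spec.svm_gamma_grid)
        clf = _SVM(c, g).fit(x_tr[:, sel], y_tr)
    elif spec.kind == "ANN":
        # carve a stratified validation subset out of the training fold
        tr_idx, val_idx = _stratified_split(y_tr, 15.0 / 85.0, rng)
        sfs_cfg = replace(spec.ann, max_epochs=min(spec.ann.max_epochs,
                                                   spec.ann_sfs_max_epochs))
        sel, _ = sfs_select(x_tr[tr_idx], y_tr[tr_idx],
                            lambda: _ANN(sfs_cfg, seed), spec.max_features)
        clf = _ANN(spec.ann, seed)
        clf.val = (x_tr[val_idx][:, sel], y_tr[val_idx])
        clf.fit(x_tr[tr_idx][:, sel], y_tr[tr_idx])
    else:  # pragma: no cover
        raise ValueError(spec.kind)
    return clf.predict(x_te[:, sel]), clf.score(x_te[:, sel]), sel


def fit_predict(spec: ClassifierSpec, train_table: pd.DataFrame,
                test_table: pd.DataFrame, seed: int = 0):
    """Train on all features of one table and predict another.

    Returns ``(labels, scores)``; scores are posterior probability (LDA,
    ANN), positive-vote fraction (KNN) or the signed decision value
    (SVM-RBF). Standardization uses training-set statistics only. No
    feature selection is performed here; see :func:`evaluate_loocv` /
    :func:`evaluate_holdout` for the full in-fold pipeline.
    """
    x_tr, y_tr, cols_tr = split_table(train_table)
    x_te, _y_te, cols_te = split_table(test_table)
    if cols_tr != cols_te:
        raise ValueError("train and test tables have different feature columns")
    scaler = Standardizer().fit(x_tr)
    x_tr, x_te = scaler.transform(x_tr), scaler.transform(x_te)
    if spec.kind == "LDA":
        clf = GaussianLDA().fit(x_tr, y_tr)
    elif spec.kind == "KNN":
        f1s = [(_training_f1(_KNN(k), x_tr, y_tr), -k) for k in spec.knn_k_grid]
        clf = _KNN(-max(f1s)[1]).fit(x_tr, y_tr)
    elif spec.kind == "SVM-RBF":
        if spec.svm_c is not None and spec.svm_gamma is not None:
            c, g = spec.svm_c, spec.svm_gamma
        else:
            c, g = grid_search_svm(x_tr, y_tr, seed=seed)
        clf = _SVM(c, g).fit(x_tr, y_tr)
    else:
        rng = np.random.default_rng(seed)
        tr_idx, val_idx = _stratified_split(y_tr, 15.0 / 85.0, rng)
        clf = _ANN(spec.ann, seed)
        clf.val = (x_tr[val_idx], y_tr[val_idx])
        clf.fit(x_tr[tr_idx], y_tr[tr_idx])
    pred = clf.predict(x_te)
    labels = np.where(pred == 1, POSITIVE_LABEL, "benign")
    return labels, clf.score(x_te)


# ---------------------------------------------------------------------------
# validation schemes
# ---------------------------------------------------------------------------

def evaluate_loocv(table: pd.DataFrame, spec: ClassifierSpec, seed: int = 0) -> ClassificationReport:
    """Leave-one-out validation with in-fold SFS/tuning; pooled report."""
    x, y, cols = split_table(table)
    n = len(y)
    if n < 10:
        raise ValueError("LOOCV needs at least 10 observations")
    preds = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    selected = []
    for i in range(n):
        tr = np.setdiff1d(np.arange(n), [i])
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a LOOCV training fold lost one of the classes")
        p, s, sel = _fit_fold(x[tr], y[tr], x[i:i + 1], spec, seed + i)
        preds[i] = p[0]
        scores[i] = s[0]
        selected.append([cols[j] for j in sel])
    report = roc_metrics(y, scores, preds)
    report.selected_features = selected
    return report


def evaluate_holdout(table: pd.DataFrame, spec: ClassifierSpec,
                     realizations: int = 10, seed: int = 0) -> ClassificationReport:
    """Repeated stratified 70/30 hold-out, metrics averaged over realizations.

    The ANN additionally carves a validation subset from each training
    split (70/15/15 overall).
    """
    x, y, cols = split_table(table)
    if len(y) < 20:
        raise ValueError("hold-out validation needs at least 20 observations")
    test_fraction = 0.15 if spec.kind == "ANN" else 0.30
    reports = []
    selected = []
    for r in range(realizations):
        rng = np.random.default_rng(seed * 1000 + r)
        tr, te = _stratified_split(y, test_fraction, rng)
        p, s, sel = _fit_fold(x[tr], y[tr], x[te], spec, seed + r)
        reports.append(roc_metrics(y[te], s, p))
        selected.append([cols[j] for j in sel])
    mean = lambda attr: float(np.mean([getattr(rep, attr) for rep in reports]))
    out = ClassificationReport(
        sensitivity=mean("sensitivity"), specificity=mean("specificity"),
        accuracy=mean("accuracy"), auc=mean("auc"), ppv=mean("ppv"), npv=mean("npv"),
        tp=sum(r.tp for r in reports), fp=sum(r.fp for r in reports),
        tn=sum(r.tn for r in reports), fn=sum(r.fn for r in reports),
        selected_features=selected, per_realization=reports)
    return out
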