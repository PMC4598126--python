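"""Classifiers over region descriptors: HIK-SVM, SRC (via OMP), and kNN.

The primary classifier is a support vector machine with the histogram
intersection kernel K(x, y) = sum_i min(x_i, y_i), a Mercer kernel on
nonnegative vectors and the natural similarity for the histogram-style
descriptors produced by this package.  Multiclass decisions use
one-against-one voting; the penalty parameter C is chosen by an inner
patient-grouped cross-validation on the training set only.

Two comparison classifiers are provided: sparse-representation
classification (greedy orthogonal matching pursuit against the stacked
training descriptors, class decided by minimal class-wise reconstruction
residual) and a k-nearest-neighbor rule with explicit tie-breaking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.svm import SVC

from .errors import ContractError, ParameterError


class StratificationWarning(UserWarning):
    """A class has too few patients for clean inner-CV stratification."""


# ---------------------------------------------------------------------------
# Histogram intersection kernel

def hik(x: np.ndarray, y: np.ndarray) -> float:
    """K(x, y) = sum_i min(x_i, y_i) for nonnegative vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ContractError(f"shape mismatch {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ContractError("histogram intersection requires nonnegative vectors")
    return float(np.minimum(x, y).sum())


def hik_gram(X: np.ndarray, Y: np.ndarray | None = None, block: int = 256) -> np.ndarray:
    """Gram matrix K[i, j] = hik(X[i], Y[j]); Y defaults to X."""
    X = np.asarray(X, dtype=np.float64)
    Y = X if Y is None else np.asarray(Y, dtype=np.float64)
    if (X < 0).any() or (Y < 0).any():
        raise ContractError("histogram intersection requires nonnegative vectors")
    K = np.empty((X.shape[0], Y.shape[0]))
    for start in range(0, X.shape[0], block):
        stop = min(start + block, X.shape[0])
        K[start:stop] = np.minimum(X[start:stop, None, :], Y[None, :, :]).sum(axis=2)
    return K


# ---------------------------------------------------------------------------
# One-vs-one HIK SVM

@dataclass
class SvmModel:
    """One-vs-one HIK SVM: one binary machine per class pair."""

    X_train: np.ndarray
    classes: np.ndarray
    pair_list: list[tuple[int, int]]
    machines: list[SVC]
    C: float
    inner_cv_scores: dict = field(default_factory=dict)


def _fit_ovo(X: np.ndarray, y: np.ndarray, classes: np.ndarray, C: float):
    """Fit a binary SVC on the precomputed HIK gram for every class pair."""
    K = hik_gram(X)
    pair_list, machines = [], []
    for a, b in combinations(range(len(classes)), 2):
        sel = (y == classes[a]) | (y == classes[b])
        idx = np.where(sel)[0]
        svc = SVC(kernel="precomputed", C=C)
        # binary labels: +1 for class a, -1 for class b
        svc.fit(K[np.ix_(idx, idx)], np.where(y[idx] == classes[a], 1, -1))
        pair_list.append((a, b))
        machines.append((svc, idx))
    return pair_list, machines


def _predict_ovo(model: "SvmModel", X: np.ndarray) -> np.ndarray:
    K = hik_gram(X, model.X_train)
    n, nc = X.shape[0], len(model.classes)
    votes = np.zeros((n, nc))
    dec_sum = np.zeros((n, nc))
    for (a, b), (svc, idx) in zip(model.pair_list, model.machines):
        d = svc.decision_function(K[:, idx])
        votes[:, a] += d > 0
        votes[:, b] += d <= 0
        dec_sum[:, a] += d
        dec_sum[:, b] -= d
    # majority vote; ties by largest summed decision value, then lowest index
    out = np.empty(n, dtype=model.classes.dtype)
    for i in range(n):
        best = np.where(votes[i] == votes[i].max())[0]
        if len(best) > 1:
            best = best[dec_sum[i, best] == dec_sum[i, best].max()]
        out[i] = model.classes[best[0]]
    return out


def train_svm_ovo(
    X: np.ndarray,
    y: np.ndarray,
    patients: np.ndarray,
    C_grid=(1.0,),
    seed: int = 0,
    n_inner_folds: int = 5,
) -> SvmModel:
    """Select C by inner patient-grouped CV, then fit one-vs-one HIK SVMs.

    The inner split groups slices by patient (mirroring the outer
    protocol) so C is never tuned on slices of a test patient.  Ties in
    mean inner accuracy go to the smallest C.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    patients = np.asarray(patients)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ParameterError("need at least 2 classes to train an SVM")
    if len(C_grid) == 0:
        raise ParameterError("C_grid must be nonempty")

    C_grid = sorted(float(c) for c in C_grid)
    scores = {}
    if len(C_grid) == 1:
        best_C = C_grid[0]
    else:
        folds = _inner_patient_folds(y, patients, n_inner_folds, seed)
        for C in C_grid:
            accs = []
            for tr, te in folds:
                if len(np.unique(y[tr])) < 2 or len(te) == 0:
                    continue
                sub = SvmModel(X[tr], np.unique(y[tr]), *_fit_ovo(X[tr], y[tr], np.unique(y[tr]), C), C)
                accs.append(float((_predict_ovo(sub, X[te]) == y[te]).mean()))
            scores[C] = float(np.mean(accs)) if accs else 0.0
        best_C = max(C_grid, key=lambda c: (scores[c], -c))

    pair_list, machines = _fit_ovo(X, y, classes, best_C)
    return SvmModel(X.copy(), classes, pair_list, machines, best_C, scores)


def _inner_patient_folds(y, patients, n_folds, seed):
    """Patient-grouped, class-balanced folds for inner model selection."""
    from .evaluate import patient_stratified_folds  # local import: avoid cycle

    patient_labels = {}
    for pid, lab in zip(patients, y):
        patient_labels.setdefault(pid, []).append(lab)
    pl = {pid: max(set(labs), key=labs.count) for pid, labs in patient_labels.items()}
    min_per_class = min(
        sum(1 for v in pl.values() if v == c) for c in set(pl.values())
    )
    if min_per_class < n_folds:
        warnings.warn(
            f"a class has only {min_per_class} training patients for "
            f"{n_folds}-fold inner CV; folds will be unbalanced",
            StratificationWarning,
            stacklevel=3,
        )
    assign = patient_stratified_folds(pl, n_folds=n_folds, seed=seed)
    folds = []
    fold_of = np.array([assign.fold_of[p] for p in patients])
    for f in range(n_folds):
        te = np.where(fold_of == f)[0]
        tr = np.where(fold_of != f)[0]
        if len(te) > 0:
            folds.append((tr, te))
    return folds


def predict_svm(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """One-against-one voting over all pairwise machines."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.X_train.shape[1]:
        raise ContractError(
            f"descriptor length {X.shape[1]} != training length {model.X_train.shape[1]}"
        )
    return _predict_ovo(model, X)


# ---------------------------------------------------------------------------
# Sparse-representation classification

@dataclass
class SrcModel:
    """Dictionary of unit-L2-norm training descriptors with column labels."""

    dictionary: np.ndarray  # (d, n) column-stacked
    labels: np.ndarray      # (n,)
    T: int                  # sparsity level (OMP stopping rule)


def fit_src(X: np.ndarray, y: np.ndarray, T: int = 30) -> SrcModel:
    X = np.asarray(X, dtype=np.float64)
    if T < 1:
        raise ParameterError(f"sparsity level T must be >= 1, got {T}")
    A = X.T.copy()
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    return SrcModel(A / norms, np.asarray(y), T)


def omp_select(A: np.ndarray, x: np.ndarray, T: int) -> tuple[np.ndarray, np.ndarray]:
    """Greedy OMP: returns (support indices, coefficients) with |support| <= T.

    At each step the column most correlated with the residual joins the
    support, and coefficients are refit by least squares on the support.
    Stops early when the residual is (numerically) zero.
    """
    if T > A.shape[1]:
        raise ParameterError(f"T={T} exceeds dictionary size {A.shape[1]}")
    support: list[int] = []
    residual = x.astype(np.float64).copy()
    coef = np.zeros(0)
    for _ in range(T):
        if np.linalg.norm(residual) < 1e-12:
            break
        corr = np.abs(A.T @ residual)
        corr[support] = -np.inf
        j = int(np.argmax(corr))
        support.append(j)
        coef, *_ = np.linalg.lstsq(A[:, support], x, rcond=None)
        residual = x - A[:, support] @ coef
    return np.asarray(support, dtype=int), coef


def classify_src(model: SrcModel, x: np.ndarray) -> object:
    """SRC rule: minimal class-wise reconstruction residual over OMP support."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != model.dictionary.shape[0]:
        raise ContractError("descriptor dimension does not match the SRC dictionary")
    support, coef = omp_select(model.dictionary, x, model.T)
    classes = np.unique(model.labels)
    best_label, best_res = None, np.inf
    for c in classes:
        in_c = np.isin(support, np.where(model.labels == c)[0].astype(int))
        sel = support[in_c]
        approx = model.dictionary[:, sel] @ coef[in_c] if len(sel) else np.zeros_like(x)
        res = float(np.linalg.norm(x - approx))
        if res < best_res - 1e-12:
            best_label, best_res = c, res
    return best_label


# ---------------------------------------------------------------------------
# k nearest neighbors

def classify_knn(
    train_X: np.ndarray,
    train_y: np.ndarray,
    x: np.ndarray,
    k: int,
    metric: str = "euclidean",
) -> object:
    """Majority label among the k nearest training descriptors.

    Vote ties break by smallest mean distance to x, then lowest class
    order.  ``metric`` is 'euclidean' or 'hik' (HIK similarity, larger =
    closer).
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    train_y = np.asarray(train_y)
    x = np.asarray(x, dtype=np.float64)
    if k > train_X.shape[0]:
        raise ParameterError(f"k={k} exceeds training size {train_X.shape[0]}")
    if metric == "euclidean":
        d = np.linalg.norm(train_X - x, axis=1)
    elif metric == "hik":
        d = -np.minimum(train_X, x).sum(axis=1)
    else:
        raise ParameterError(f"unknown metric {metric!r}")
    nn = np.argsort(d, kind="stable")[:k]
    labels, counts = np.unique(train_y[nn], return_counts=True)
    best = labels[counts == counts.max()]
    if len(best) == 1:
        return best[0]
    mean_d = np.array([d[nn][train_y[nn] == lab].mean() for lab in best])
    winners = best[mean_d == mean_d.min()]
    return sorted(winners)[0]
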