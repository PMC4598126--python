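"""Patient-stratified cross-validation, confusion metrics, LDA projection.

Slices of one patient are strongly correlated, so folds are assigned at
the patient level: within each class, patients are shuffled and dealt
round-robin to folds, keeping per-class patient counts balanced to
within one.  All fold-dependent state — the visual dictionary, the SVM
penalty C, the classifier itself — is fit on training-fold slices only.

Accuracy is reported both as the mean of per-fold slice accuracies (the
cross-validation convention) and as the pooled accuracy
trace(pooled confusion matrix) / total slices; the two differ slightly
when folds have unequal slice counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from . import bow as bow_mod
from . import classify as clf_mod
from .config import RunConfig
from .dataset import AnnotatedSlice, DatasetManifest, load_all
from .errors import ParameterError
from .pyramid import build_descriptor


class LabelConflictWarning(UserWarning):
    """A patient carries slices with different class labels."""


class UndefinedMetricWarning(UserWarning):
    """A confusion-matrix row is empty so sensitivity is undefined."""


@dataclass
class FoldAssignment:
    fold_of: dict
    n_folds: int

    def patients_in(self, fold: int) -> list:
        return sorted(p for p, f in self.fold_of.items() if f == fold)


def patient_stratified_folds(
    patient_labels: dict, n_folds: int = 5, seed: int = 0
) -> FoldAssignment:
    """Shuffle patients within each class and deal them round-robin to folds."""
    if n_folds < 2:
        raise ParameterError(f"n_folds must be >= 2, got {n_folds}")
    rng = np.random.default_rng(seed)
    classes = sorted(set(patient_labels.values()))
    fold_of = {}
    offset = 0
    for c in classes:
        pats = sorted(p for p, lab in patient_labels.items() if lab == c)
        order = rng.permutation(len(pats))
        for rank, i in enumerate(order):
            # rotate the starting fold per class so small classes spread out
            fold_of[pats[i]] = (rank + offset) % n_folds
        offset += len(pats)
    return FoldAssignment(fold_of=fold_of, n_folds=n_folds)


def patient_label_map(slices: list[AnnotatedSlice]) -> dict:
    """Majority slice label per patient (warns on within-patient conflicts)."""
    by_patient: dict = {}
    for s in slices:
        by_patient.setdefault(s.patient_id, []).append(s.label)
    out = {}
    for pid, labs in by_patient.items():
        uniq = set(labs)
        if len(uniq) > 1:
            warnings.warn(
                f"patient {pid} has conflicting labels {sorted(uniq)}; using majority",
                LabelConflictWarning,
                stacklevel=2,
            )
        out[pid] = max(sorted(uniq), key=labs.count)
    return out


@dataclass
class EvaluationReport:
    classes: list
    fold_matrices: list
    fold_accuracies: list
    chosen_C: list
    config: dict = field(default_factory=dict)

    @property
    def pooled_matrix(self) -> np.ndarray:
        return np.sum(self.fold_matrices, axis=0)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def pooled_accuracy(self) -> float:
        cm = self.pooled_matrix
        return float(np.trace(cm) / cm.sum())

    def metrics(self) -> dict:
        return sensitivity_specificity(self.pooled_matrix)

    def to_dict(self) -> dict:
        m = self.metrics()
        return {
            "classes": list(self.classes),
            "fold_matrices": [np.asarray(f).tolist() for f in self.fold_matrices],
            "pooled_matrix": self.pooled_matrix.tolist(),
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "pooled_accuracy": self.pooled_accuracy,
            "sensitivity_pct": m["sensitivity_pct"].tolist(),
            "specificity_pct": m["specificity_pct"].tolist(),
            "chosen_C": self.chosen_C,
            "config": self.config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_markdown(self) -> str:
        m = self.metrics()
        lines = [
            f"Mean accuracy over {len(self.fold_accuracies)} folds: "
            f"{100 * self.mean_accuracy:.2f}% (pooled {100 * self.pooled_accuracy:.2f}%)",
            "",
            "| true \\ predicted | " + " | ".join(self.classes) + " | sensitivity |",
            "|---|" + "---|" * (len(self.classes) + 1),
        ]
        cm = self.pooled_matrix
        for i, c in enumerate(self.classes):
            row = " | ".join(str(int(v)) for v in cm[i])
            lines.append(f"| {c} | {row} | {m['sensitivity_pct'][i]:.1f}% |")
        spec_row = " | ".join(f"{v:.1f}%" for v in m["specificity_pct"])
        lines.append(f"| specificity | {spec_row} |  |")
        return "\n".join(lines)


def sensitivity_specificity(cm: np.ndarray) -> dict:
    """Per-class sensitivity and one-vs-rest specificity, in percent (1 dp).

    sensitivity_c = cm[c, c] / sum_j cm[c, j];
    specificity_c = 1 - (false positives for c) / (all slices not in c).
    An empty true-class row yields NaN sensitivity with a warning.
    """
    cm = np.asarray(cm, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ParameterError(f"confusion matrix must be square, got {cm.shape}")
    if (cm < 0).any():
        raise ParameterError("confusion matrix entries must be nonnegative")
    n = cm.shape[0]
    sens = np.full(n, np.nan)
    spec = np.full(n, np.nan)
    for c in range(n):
        row_sum = cm[c].sum()
        if row_sum == 0:
            warnings.warn(
                f"class {c} has no true slices; sensitivity undefined",
                UndefinedMetricWarning,
                stacklevel=2,
            )
        else:
            sens[c] = cm[c, c] / row_sum
        negatives = cm.sum() - cm[c].sum()
        if negatives > 0:
            false_pos = cm[:, c].sum() - cm[c, c]
            spec[c] = 1.0 - false_pos / negatives
    return {
        "sensitivity_pct": np.round(100 * sens, 1),
        "specificity_pct": np.round(100 * spec, 1),
    }


# ---------------------------------------------------------------------------
# Cross-validation driver

def _fit_fold(slices, config: RunConfig, fold_seed: int):
    """Fit all fold-dependent state on training slices; returns a predictor."""
    codebook = None
    if config.feature == "bow":
        from .preprocess import normalize_intensity
        from .roi import augment_roi

        pools = []
        for s in slices:
            normalized = normalize_intensity(
                s.image, config.p_low, config.p_high,
                mask=s.mask if config.norm_scope == "roi" else None,
            )
            region = augment_roi(s.mask, config.R)
            pools.append(bow_mod.extract_patches(normalized, region, config.p).descriptors)
        codebook = bow_mod.build_dictionary(
            np.vstack(pools), config.M, n_sample=config.bow_sample, seed=fold_seed
        )

    X = np.vstack([build_descriptor(s, config, codebook).vector for s in slices])
    y = np.array([s.label for s in slices])
    patients = np.array([s.patient_id for s in slices])

    if config.classifier == "svm_hik":
        model = clf_mod.train_svm_ovo(X, y, patients, C_grid=config.C_grid, seed=fold_seed)

        def predict(Xt):
            return clf_mod.predict_svm(model, Xt)

        return codebook, predict, model.C
    if config.classifier == "src":
        model = clf_mod.fit_src(X, y, T=min(config.src_T, X.shape[0]))

        def predict(Xt):
            return np.array([clf_mod.classify_src(model, x) for x in Xt])

        return codebook, predict, None
    if config.classifier == "knn":
        def predict(Xt):
            return np.array(
                [clf_mod.classify_knn(X, y, x, k=min(config.knn_k, X.shape[0])) for x in Xt]
            )

        return codebook, predict, None
    raise ParameterError(f"unknown classifier {config.classifier!r}")


def cross_validate(
    manifest: DatasetManifest,
    config: RunConfig,
    seed: int | None = None,
    folds: FoldAssignment | None = None,
    slices: list[AnnotatedSlice] | None = None,
) -> EvaluationReport:
    """Patient-stratified k-fold cross-validation of the full pipeline.

    Pass a shared ``folds`` assignment to compare configurations on
    identical splits (paired comparisons).  ``seed`` defaults to
    ``config.seed`` and drives fold shuffling, dictionary sampling and
    inner model selection through distinct substreams.
    """
    seed = config.seed if seed is None else seed
    if slices is None:
        slices = load_all(manifest)
    classes = list(manifest.classes)
    if folds is None:
        folds = patient_stratified_folds(
            patient_label_map(slices), n_folds=config.n_folds, seed=seed
        )

    fold_matrices, fold_acc, chosen_C = [], [], []
    for f in range(folds.n_folds):
        train = [s for s in slices if folds.fold_of[s.patient_id] != f]
        test = [s for s in slices if folds.fold_of[s.patient_id] == f]
        if not test:
            continue
        fold_seed = int(np.random.SeedSequence(entropy=(seed, 1000 + f)).generate_state(1)[0] % 2**31)
        codebook, predict, C = _fit_fold(train, config, fold_seed)
        Xt = np.vstack([build_descriptor(s, config, codebook).vector for s in test])
        pred = predict(Xt)
        true = np.array([s.label for s in test])
        cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(true, pred):
            cm[classes.index(t), classes.index(p)] += 1
        fold_matrices.append(cm)
        fold_acc.append(float((pred == true).mean()))
        chosen_C.append(C)
    return EvaluationReport(
        classes=classes,
        fold_matrices=fold_matrices,
        fold_accuracies=fold_acc,
        chosen_C=chosen_C,
        config=config.to_dict(),
    )


def paired_fold_ttest(report_a: EvaluationReport, report_b: EvaluationReport) -> dict:
    """Paired t-test on per-fold accuracies of two runs with shared folds."""
    from scipy import stats

    a = np.asarray(report_a.fold_accuracies)
    b = np.asarray(report_b.fold_accuracies)
    if len(a) != len(b):
        raise ParameterError("reports have different fold counts")
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "mean_diff": float((a - b).mean())}


# ---------------------------------------------------------------------------
# Regularized LDA 2D projection

def lda_project_2d(
    X: np.ndarray, y: np.ndarray, lam: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project descriptors on the top-2 directions of (Sw + lam I)^-1 Sb.

    Sw is the pooled within-class scatter and Sb the between-class
    scatter; the ridge lam (default 1e-3 * trace(Sw)/dim) keeps the
    generalized eigenproblem well posed when Sw is near singular.  With
    3 classes rank(Sb) <= 2, so two directions capture all separability.
    Returns (coords (n, 2), basis (d, 2), eigenvalues (2,)).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] < 3 or len(np.unique(y)) < 2:
        raise ParameterError("LDA projection needs >= 3 samples and >= 2 classes")
    d = X.shape[1]
    mu = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in np.unique(y):
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        Sw += (Xc - mc).T @ (Xc - mc)
        diff = (mc - mu)[:, None]
        Sb += Xc.shape[0] * (diff @ diff.T)
    if lam is None:
        lam = 1e-3 * np.trace(Sw) / d
    if lam <= 0:
        raise ParameterError(f"ridge constant must be > 0, got {lam}")
    evals, evecs = linalg.eigh(Sb, Sw + lam * np.eye(d))
    order = np.argsort(evals)[::-1][:2]
    basis = evecs[:, order]
    evals = evals[order]
    # deterministic sign: first entry of magnitude > 1e-12 made positive
    for j in range(basis.shape[1]):
        nz = np.nonzero(np.abs(basis[:, j]) > 1e-12)[0]
        if len(nz) and basis[nz[0], j] < 0:
            basis[:, j] = -basis[:, j]
    return X @ basis, basis, evals


def plot_lda_scatter(coords: np.ndarray, y: np.ndarray, classes: list, path) -> None:
    """Class-colored 2D scatter (red/green/blue) written as PNG or SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = ["red", "green", "blue", "orange", "purple"]
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, c in enumerate(classes):
        sel = np.asarray(y) == c
        ax.scatter(coords[sel, 0], coords[sel, 1], s=12, c=colors[i % len(colors)], label=str(c))
    ax.set_xlabel("LD 1")
    ax.set_ylabel("LD 2")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
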