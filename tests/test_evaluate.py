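"""Fold stratification, confusion metrics against published values, LDA, CV driver."""

import numpy as np
import pytest

from ringspm.benchmarks import AUGMENTATION_STUDY, all_benchmark_matrices
from ringspm.config import RunConfig
from ringspm.errors import ParameterError
from ringspm.evaluate import (
    UndefinedMetricWarning,
    cross_validate,
    lda_project_2d,
    paired_fold_ttest,
    patient_stratified_folds,
    sensitivity_specificity,
)


def test_folds_exact_division():
    labels = {f"p{i}": f"c{i % 3}" for i in range(15)}
    fa = patient_stratified_folds(labels, n_folds=5, seed=0)
    for f in range(5):
        pats = fa.patients_in(f)
        assert len(pats) == 3
        assert len({labels[p] for p in pats}) == 3  # one patient per class


def test_folds_233_patients_sizes():
    """233 patients in realistic class proportions split into sizes 46 or 47."""
    labels = {}
    i = 0
    for cls, n in (("meningioma", 54), ("glioma", 108), ("pituitary", 71)):
        for _ in range(n):
            labels[f"p{i}"] = cls
            i += 1
    fa = patient_stratified_folds(labels, n_folds=5, seed=3)
    sizes = sorted(len(fa.patients_in(f)) for f in range(5))
    assert sum(sizes) == 233
    assert set(sizes) <= {46, 47}
    # per-class balance within one
    for cls in ("meningioma", "glioma", "pituitary"):
        per_fold = [sum(1 for p in fa.patients_in(f) if labels[p] == cls) for f in range(5)]
        assert max(per_fold) - min(per_fold) <= 1


def test_each_patient_in_exactly_one_fold():
    labels = {f"p{i}": f"c{i % 3}" for i in range(40)}
    fa = patient_stratified_folds(labels, n_folds=5, seed=1)
    seen = [p for f in range(5) for p in fa.patients_in(f)]
    assert sorted(seen) == sorted(labels)


def test_fold_sizes_invariant_under_patient_relabeling():
    labels = {f"p{i}": f"c{i % 3}" for i in range(20)}
    renamed = {f"q{i}": labels[f"p{i}"] for i in range(20)}
    fa1 = patient_stratified_folds(labels, seed=5)
    fa2 = patient_stratified_folds(renamed, seed=5)
    for cls in ("c0", "c1", "c2"):
        s1 = sorted(
            sum(1 for p in fa1.patients_in(f) if labels[p] == cls) for f in range(5)
        )
        s2 = sorted(
            sum(1 for p in fa2.patients_in(f) if renamed[p] == cls) for f in range(5)
        )
        assert s1 == s2


def test_sensitivity_specificity_identity_matrix():
    m = sensitivity_specificity(np.eye(3) * 10)
    assert (m["sensitivity_pct"] == 100.0).all()
    assert (m["specificity_pct"] == 100.0).all()


def test_sensitivity_specificity_published_example():
    """The undilated intensity-histogram matrix reproduces its printed metrics."""
    bm = AUGMENTATION_STUDY["histogram"]["baseline"]
    m = sensitivity_specificity(bm.counts)
    assert m["sensitivity_pct"][0] == 60.5
    assert m["specificity_pct"][0] == 88.2


@pytest.mark.parametrize("bm", all_benchmark_matrices(), ids=lambda b: b.name)
def test_all_published_metrics_reproduced(bm):
    """Every printed sensitivity/specificity follows from its count matrix."""
    m = sensitivity_specificity(bm.counts)
    np.testing.assert_array_equal(m["sensitivity_pct"], bm.sensitivity_pct)
    np.testing.assert_array_equal(m["specificity_pct"], bm.specificity_pct)


def test_zero_row_sensitivity_nan_with_warning():
    cm = np.array([[0, 0], [1, 9]])
    with pytest.warns(UndefinedMetricWarning):
        m = sensitivity_specificity(cm)
    assert np.isnan(m["sensitivity_pct"][0])


def test_report_invariants(small_separable):
    _, manifest = small_separable
    cfg = RunConfig(feature="histogram", R=0, L=0, G=10, n_folds=3, C_grid=(1.0,), seed=0)
    rep = cross_validate(manifest, cfg)
    pooled = rep.pooled_matrix
    assert pooled.sum() == len(manifest)
    np.testing.assert_array_equal(pooled, np.sum(rep.fold_matrices, axis=0))
    assert rep.pooled_accuracy == pytest.approx(np.trace(pooled) / pooled.sum())
    d = rep.to_dict()
    assert set(d) >= {"pooled_matrix", "mean_accuracy", "sensitivity_pct", "config"}
    assert "true \\ predicted" in rep.to_markdown()


def test_cv_determinism_and_separability(small_separable):
    _, manifest = small_separable
    cfg = RunConfig(feature="histogram", R=0, L=0, G=10, n_folds=3, C_grid=(1.0,), seed=2)
    r1 = cross_validate(manifest, cfg)
    r2 = cross_validate(manifest, cfg)
    assert r1.to_dict() == r2.to_dict()
    assert r1.mean_accuracy == 1.0  # widely separated textures are trivial


def test_shared_folds_pair_reports(small_separable):
    from ringspm.dataset import load_all
    from ringspm.evaluate import patient_label_map

    _, manifest = small_separable
    slices = load_all(manifest)
    folds = patient_stratified_folds(patient_label_map(slices), n_folds=3, seed=0)
    cfg = RunConfig(feature="histogram", R=0, L=0, G=10, n_folds=3, C_grid=(1.0,))
    ra = cross_validate(manifest, cfg, folds=folds, slices=slices)
    rb = cross_validate(manifest, cfg.replace(R=4), folds=folds, slices=slices)
    t = paired_fold_ttest(ra, rb)
    assert set(t) == {"t", "p", "mean_diff"}
    assert len(ra.fold_accuracies) == len(rb.fold_accuracies)


def test_lda_recovers_separating_axis(rng):
    n = 300
    X = rng.normal(size=(2 * n, 5))
    X[:n, 0] += 8.0
    y = np.array(["a"] * n + ["b"] * n)
    coords, basis, evals = lda_project_2d(X, y)
    v = basis[:, 0] / np.linalg.norm(basis[:, 0])
    assert abs(v[0]) > 0.99
    assert coords.shape == (2 * n, 2)


def test_lda_rank_bound_three_classes(rng):
    X = rng.normal(size=(30, 6))
    X[:10, 0] += 4
    X[10:20, 1] += 4
    y = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
    _, _, evals = lda_project_2d(X, y)
    assert (evals > 0).sum() <= 2 and evals[0] >= evals[1]


def test_lda_matches_generalized_eig_oracle(rng):
    from scipy import linalg

    X = rng.normal(size=(24, 4))
    X[:12, 2] += 3
    y = np.array(["a"] * 12 + ["b"] * 12)
    lam = 0.5
    coords, basis, evals = lda_project_2d(X, y, lam=lam)
    d = X.shape[1]
    mu = X.mean(axis=0)
    Sw = sum((X[y == c] - X[y == c].mean(0)).T @ (X[y == c] - X[y == c].mean(0)) for c in "ab")
    Sb = sum(
        (y == c).sum() * np.outer(X[y == c].mean(0) - mu, X[y == c].mean(0) - mu) for c in "ab"
    )
    w, v = linalg.eigh(Sb, Sw + lam * np.eye(d))
    assert evals[0] == pytest.approx(w[-1])
    with pytest.raises(ParameterError):
        lda_project_2d(X, y, lam=-1.0)


def test_lda_scatter_plot_written(tmp_path, rng):
    from ringspm.evaluate import plot_lda_scatter

    coords = rng.normal(size=(30, 2))
    y = np.array(["a", "b", "c"] * 10)
    out = tmp_path / "lda.png"
    plot_lda_scatter(coords, y, ["a", "b", "c"], out)
    assert out.exists() and out.stat().st_size > 0
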