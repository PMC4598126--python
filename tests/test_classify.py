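"""Classifiers: HIK properties, one-vs-one voting, OMP/SRC and kNN oracles."""

import itertools

import numpy as np
import pytest

from ringspm.classify import (
    classify_knn,
    classify_src,
    fit_src,
    hik,
    hik_gram,
    omp_select,
    predict_svm,
    train_svm_ovo,
)
from ringspm.errors import ContractError, ParameterError


def test_hik_basic_identities(rng):
    x = rng.random(10)
    assert hik(x, x) == pytest.approx(x.sum())
    a = np.array([0.2, 0.8])
    b = np.array([0.5, 0.5])
    assert hik(a, b) == pytest.approx(0.7)
    assert hik(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
    with pytest.raises(ContractError):
        hik(np.array([-0.1, 1.0]), np.array([0.5, 0.5]))


def test_hik_bounded_by_self_similarity(rng):
    for _ in range(20):
        x, y = rng.random(8), rng.random(8)
        assert hik(x, y) <= min(hik(x, x), hik(y, y)) + 1e-12


def test_hik_gram_symmetric_psd(rng):
    X = rng.random((25, 12))
    K = hik_gram(X)
    np.testing.assert_allclose(K, K.T, atol=1e-12)
    assert np.linalg.eigvalsh(K).min() >= -1e-8


def _three_class_data(rng, n_per=15, sep=0.8):
    """Histogram-like descriptors concentrated on class-specific bins."""
    X, y, pats = [], [], []
    for c in range(3):
        base = np.full(6, (1 - sep) / 6)
        base[2 * c : 2 * c + 2] += sep / 2
        for i in range(n_per):
            v = base + rng.random(6) * 0.02
            X.append(v / v.sum())
            y.append(f"c{c}")
            pats.append(f"p{c}_{i // 3}")  # 5 patients per class
    return np.array(X), np.array(y), np.array(pats)


def test_svm_separable_training_accuracy(rng):
    X, y, pats = _three_class_data(rng)
    model = train_svm_ovo(X, y, pats, C_grid=(1.0,), seed=0)
    assert (predict_svm(model, X) == y).all()
    assert model.C in (1.0,)


def test_svm_determinism(rng):
    X, y, pats = _three_class_data(rng)
    m1 = train_svm_ovo(X, y, pats, C_grid=(0.1, 1.0, 10.0), seed=4)
    m2 = train_svm_ovo(X, y, pats, C_grid=(0.1, 1.0, 10.0), seed=4)
    assert m1.C == m2.C
    Xt = rng.random((10, 6))
    Xt /= Xt.sum(axis=1, keepdims=True)
    assert (predict_svm(m1, Xt) == predict_svm(m2, Xt)).all()


def test_svm_prediction_matches_pairwise_vote_oracle(rng):
    """Voting outcome equals brute-force evaluation of the 3 pairwise machines."""
    X, y, pats = _three_class_data(rng, sep=0.5)
    model = train_svm_ovo(X, y, pats, C_grid=(1.0,), seed=0)
    Xt = rng.random((20, 6))
    Xt /= Xt.sum(axis=1, keepdims=True)
    pred = predict_svm(model, Xt)
    for i, x in enumerate(Xt):
        votes = {c: 0 for c in model.classes}
        dec = {c: 0.0 for c in model.classes}
        for (a, b), (svc, idx) in zip(model.pair_list, model.machines):
            K = hik_gram(x[None, :], model.X_train[idx])
            d = float(svc.decision_function(K)[0])
            winner = model.classes[a] if d > 0 else model.classes[b]
            votes[winner] += 1
            dec[model.classes[a]] += d
            dec[model.classes[b]] -= d
        best = max(votes.values())
        tied = [c for c in model.classes if votes[c] == best]
        expected = max(tied, key=lambda c: (dec[c], -list(model.classes).index(c)))
        assert pred[i] == expected


def test_svm_needs_two_classes(rng):
    X = rng.random((5, 3))
    with pytest.raises(ParameterError):
        train_svm_ovo(X, np.array(["a"] * 5), np.array(["p"] * 5))


def test_src_training_column_zero_residual(rng):
    X = rng.random((12, 8))
    y = np.array(["a", "b", "c"] * 4)
    model = fit_src(X, y, T=3)
    for i in range(12):
        assert classify_src(model, X[i]) == y[i]


def test_src_T1_is_max_correlation(rng):
    X = rng.random((9, 6))
    y = np.array(["a", "b", "c"] * 3)
    model = fit_src(X, y, T=1)
    x = rng.random(6)
    corr = np.abs(model.dictionary.T @ x)
    assert classify_src(model, x) == y[int(np.argmax(corr))]


def test_omp_matches_exhaustive_search(rng):
    """On tiny dictionaries the greedy residual is near the best support's.

    OMP is greedy so it may not reach the global optimum, but its selected
    support must be one of the enumerated supports and its residual must
    match the exhaustive least-squares residual for that same support.
    """
    for _ in range(10):
        A = rng.random((6, 7))
        A /= np.linalg.norm(A, axis=0)
        x = rng.random(6)
        T = 3
        support, coef = omp_select(A, x, T)
        res = np.linalg.norm(x - A[:, support] @ coef)
        best = np.inf
        for size in range(1, T + 1):
            for comb in itertools.combinations(range(7), size):
                c, *_ = np.linalg.lstsq(A[:, comb], x, rcond=None)
                best = min(best, np.linalg.norm(x - A[:, comb] @ c))
        # residual equals the exhaustive LS residual on OMP's own support
        c_opt, *_ = np.linalg.lstsq(A[:, support], x, rcond=None)
        assert res == pytest.approx(np.linalg.norm(x - A[:, support] @ c_opt))
        assert res >= best - 1e-10  # greedy can't beat exhaustive


def test_omp_rejects_oversized_T(rng):
    A = rng.random((4, 3))
    with pytest.raises(ParameterError):
        omp_select(A, rng.random(4), T=5)


def test_knn_examples(rng):
    X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [5.0, 5.0]])
    y = np.array(["A", "A", "B", "B"])
    assert classify_knn(X, y, np.array([0.0, 0.0]), k=1) == "A"
    assert classify_knn(X, y, np.array([0.1, 0.1]), k=3) == "A"  # A, A, B -> A
    with pytest.raises(ParameterError):
        classify_knn(X, y, np.zeros(2), k=9)


def test_knn_matches_exhaustive_sort(rng):
    X = rng.random((40, 5))
    y = rng.choice(["a", "b", "c"], size=40)
    for _ in range(10):
        x = rng.random(5)
        k = int(rng.integers(1, 10))
        d = np.linalg.norm(X - x, axis=1)
        nn = np.argsort(d, kind="stable")[:k]
        labs, counts = np.unique(y[nn], return_counts=True)
        cand = labs[counts == counts.max()]
        got = classify_knn(X, y, x, k)
        assert got in cand


def test_knn_hik_metric(rng):
    X = rng.random((10, 4))
    y = np.array(list("ababababab"))
    x = X[3].copy()
    assert classify_knn(X, y, x, k=1, metric="hik") == y[3]
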