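"""Bag-of-words stages: patch extraction, k-means dictionary, coding, pooling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ringspm.bow import (
    Codebook,
    build_dictionary,
    encode_sa_k,
    encode_vq,
    extract_patches,
    normalize_vec,
    pool,
)
from ringspm.errors import EmptyRoiError, ParameterError
from ringspm.preprocess import NormalizedSlice


def _ns(arr):
    return NormalizedSlice(np.asarray(arr, dtype=float), 0.0, 1.0)


def test_single_center_patch_is_flattened_image():
    img = np.arange(25).reshape(5, 5) / 24.0
    ps = extract_patches(_ns(img), np.ones((5, 5), bool), p=5)
    assert len(ps) == 1
    np.testing.assert_allclose(ps.descriptors[0], img.ravel())
    assert tuple(ps.centers[0]) == (2, 2)


def test_patch_count_enumeration():
    """6x6 region block 2+ pixels from the border: every center valid -> 36."""
    img = np.zeros((10, 10))
    region = np.zeros((10, 10), bool)
    region[2:8, 2:8] = True
    ps = extract_patches(_ns(img), region, p=5)
    assert len(ps) == 36


def test_patch_centers_near_border_dropped():
    region = np.ones((6, 6), bool)
    ps = extract_patches(_ns(np.zeros((6, 6))), region, p=5)
    assert len(ps) == 4  # only the 2x2 central block admits full windows


def test_patch_parameter_and_empty_errors():
    with pytest.raises(ParameterError):
        extract_patches(_ns(np.zeros((8, 8))), np.ones((8, 8), bool), p=4)
    region = np.zeros((8, 8), bool)
    region[0, 0] = True  # no full window fits
    with pytest.raises(EmptyRoiError):
        extract_patches(_ns(np.zeros((8, 8))), region, p=5)


def test_dictionary_recovers_duplicated_points():
    rng = np.random.default_rng(0)
    points = rng.random((4, 9))
    pool_arr = np.repeat(points, 10, axis=0)
    cb = build_dictionary(pool_arr, M=4, seed=0)
    # zero-inertia optimum: words are the points themselves (any order)
    d = np.linalg.norm(cb.words[:, None, :] - points[None], axis=2)
    assert d.min(axis=1).max() < 1e-9


def test_dictionary_two_blobs():
    rng = np.random.default_rng(1)
    a = rng.normal(0.2, 0.02, size=(400, 4))
    b = rng.normal(0.8, 0.02, size=(400, 4))
    cb = build_dictionary(np.vstack([a, b]), M=2, seed=1)
    means = sorted(cb.words.mean(axis=1))
    se = 0.02 / np.sqrt(400)
    assert abs(means[0] - 0.2) < 3 * se * 4  # loose sampling-theory bound
    assert abs(means[1] - 0.8) < 3 * se * 4


def test_dictionary_determinism_and_pool_cap():
    rng = np.random.default_rng(2)
    pool_arr = rng.random((500, 6))
    c1 = build_dictionary(pool_arr, M=5, n_sample=200, seed=3)
    c2 = build_dictionary(pool_arr, M=5, n_sample=200, seed=3)
    np.testing.assert_array_equal(c1.words, c2.words)
    assert c1.n_sampled == 200


def test_dictionary_rejects_oversized_M():
    pool_arr = np.zeros((50, 3))  # one distinct descriptor
    with pytest.raises(ParameterError):
        build_dictionary(pool_arr, M=2, seed=0)


def test_vq_one_hot_and_tie_to_lowest_index():
    words = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    cb = Codebook(words, 0, 3)
    c = encode_vq(np.array([1.0, 1.0]), cb)
    assert c[0, 1] == 1.0 and c.sum() == 1.0
    # equidistant from words 0 and 1 -> lowest index wins
    tie = encode_vq(np.array([0.5, 0.5]), cb)
    assert tie[0, 0] == 1.0


def test_vq_matches_exhaustive_scan(rng):
    words = rng.random((7, 5))
    cb = Codebook(words, 0, 7)
    X = rng.random((30, 5))
    codes = encode_vq(X, cb)
    for x, c in zip(X, codes):
        d = np.linalg.norm(words - x, axis=1)
        assert c[np.argmin(d)] == 1.0


def test_sa1_equals_vq(rng):
    words = rng.random((6, 4))
    cb = Codebook(words, 0, 6)
    X = rng.random((10, 4))
    np.testing.assert_allclose(encode_sa_k(X, cb, k_nn=1), encode_vq(X, cb))


def test_sa2_symmetric_equidistant():
    words = np.array([[0.0, 0.0], [2.0, 0.0], [9.0, 9.0]])
    cb = Codebook(words, 0, 3)
    c = encode_sa_k(np.array([1.0, 0.0]), cb, k_nn=2)
    np.testing.assert_allclose(c[0, :2], [0.5, 0.5])
    assert c[0, 2] == 0.0


def test_sa_weight_ratio_closed_form():
    words = np.array([[0.0], [1.0], [10.0]])
    cb = Codebook(words, 0, 3)
    x = np.array([0.2])
    sigma = 0.5
    c = encode_sa_k(x, cb, k_nn=2, sigma=sigma)[0]
    d1, d2 = 0.2, 0.8
    expected_ratio = np.exp((d2**2 - d1**2) / (2 * sigma**2))
    assert c[0] / c[1] == pytest.approx(expected_ratio)
    assert c[:2].sum() == pytest.approx(1.0)


def test_pool_sum_is_word_histogram_and_max_is_presence(rng):
    words = rng.random((4, 3))
    cb = Codebook(words, 0, 4)
    X = rng.random((20, 3))
    codes = encode_vq(X, cb)
    s = pool(codes, "sum")
    assert s.sum() == 20  # mass conservation
    m = pool(codes, "max")
    assert set(np.unique(m)) <= {0.0, 1.0}
    # average pooling identity: sum + L1 = empirical word frequencies
    np.testing.assert_allclose(normalize_vec(s, "l1"), s / 20)


def test_pool_hand_computed_max():
    codes = np.array([[0.7, 0.3, 0.0], [0.0, 0.6, 0.4], [0.2, 0.0, 0.8]])
    np.testing.assert_allclose(pool(codes, "max"), [0.7, 0.6, 0.8])


def test_pool_empty_and_permutation_invariance(rng):
    assert (pool([], "sum", M=5) == 0).all()
    codes = rng.random((15, 6))
    perm = rng.permutation(15)
    np.testing.assert_allclose(pool(codes, "sum"), pool(codes[perm], "sum"))
    np.testing.assert_allclose(pool(codes, "max"), pool(codes[perm], "max"))


@given(
    st.lists(
        st.one_of(st.just(0.0), st.floats(1e-6, 10.0)), min_size=1, max_size=20
    )
)
@settings(deadline=None)
def test_normalize_vec_properties(vals):
    v = np.array(vals)
    l1 = normalize_vec(v, "l1")
    l2 = normalize_vec(v, "l2")
    if v.sum() > 0:
        assert l1.sum() == pytest.approx(1.0)
        assert np.linalg.norm(l2) == pytest.approx(1.0)
    else:
        assert (l1 == 0).all() and (l2 == 0).all()


def test_normalize_vec_examples():
    np.testing.assert_allclose(normalize_vec(np.array([2.0, 2.0]), "l1"), [0.5, 0.5])
    np.testing.assert_allclose(normalize_vec(np.array([3.0, 4.0]), "l2"), [0.6, 0.8])
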