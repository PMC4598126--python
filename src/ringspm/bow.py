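"""Raw-patch bag-of-visual-words: extraction, dictionary, coding, pooling.

Local descriptors are raw p x p patches of the normalized image, densely
sampled at every ROI pixel whose full window fits inside the image (no
padding — padded intensities would be fabricated data).  A visual
dictionary of M words is learned with k-means on descriptors sampled from
the training folds only; each descriptor is then coded against the
dictionary (hard vector quantization, or localized Gaussian soft
assignment over the k nearest words) and the codes are pooled per region.

Sum pooling followed by L1 normalization of hard VQ codes equals the
empirical word-frequency histogram ("average pooling").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin

from .errors import ContractError, EmptyRoiError, ParameterError
from .preprocess import NormalizedSlice

DEFAULT_POOL_SAMPLE = 100_000


@dataclass
class PatchSet:
    """Dense patch descriptors with their center coordinates.

    descriptors: (N, p*p) row-major flattened windows, values in [0, 1].
    centers: (N, 2) integer (row, col) of each patch center.
    """

    descriptors: np.ndarray
    centers: np.ndarray
    p: int

    def __len__(self) -> int:
        return self.descriptors.shape[0]


@dataclass
class Codebook:
    """M visual words of dimension p*p plus the provenance of the fit."""

    words: np.ndarray
    train_seed: int
    n_sampled: int

    @property
    def M(self) -> int:
        return self.words.shape[0]


def extract_patches(normalized: NormalizedSlice, region: np.ndarray, p: int) -> PatchSet:
    """One descriptor per region pixel whose full p x p window is in-bounds.

    The center must be a region pixel; the window may extend outside the
    region (context is informative) but never outside the image.
    Raises :class:`EmptyRoiError` when no valid center exists.
    """
    if p < 3 or p % 2 == 0:
        raise ParameterError(f"patch side must be odd and >= 3, got {p}")
    values = np.asarray(normalized.values, dtype=np.float64)
    region = np.asarray(region, dtype=bool)
    H, W = values.shape
    h = p // 2
    valid = np.zeros_like(region)
    if H >= p and W >= p:
        valid[h : H - h, h : W - h] = True
    centers = np.argwhere(region & valid)
    if centers.shape[0] == 0:
        raise EmptyRoiError("no region pixel admits a full patch window inside the image")
    # gather windows via broadcasting over the window offsets
    offs = np.arange(-h, h + 1)
    rows = centers[:, 0:1, None] + offs[None, :, None]
    cols = centers[:, 1:2, None] + offs[None, None, :]
    descriptors = values[rows, cols].reshape(centers.shape[0], p * p)
    return PatchSet(descriptors=descriptors, centers=centers, p=p)


def build_dictionary(
    descriptor_pool: np.ndarray,
    M: int,
    n_sample: int = DEFAULT_POOL_SAMPLE,
    seed: int = 0,
) -> Codebook:
    """k-means codebook from a random subsample of the descriptor pool.

    min(n_sample, pool size) descriptors are drawn without replacement
    with ``seed``; k-means uses k-means++ seeding from the same seed with
    a single initialization, so the result is deterministic given the
    pool order and seed.
    """
    pool = np.asarray(descriptor_pool, dtype=np.float64)
    if pool.ndim != 2 or pool.shape[0] == 0:
        raise ParameterError("descriptor pool must be a nonempty 2D array")
    rng = np.random.default_rng(seed)
    n = min(n_sample, pool.shape[0])
    idx = rng.choice(pool.shape[0], size=n, replace=False)
    sample = pool[idx]
    n_distinct = np.unique(sample, axis=0).shape[0]
    if M > n_distinct:
        raise ParameterError(
            f"dictionary size M={M} exceeds the {n_distinct} distinct sampled descriptors"
        )
    km = KMeans(
        n_clusters=M,
        init="k-means++",
        n_init=1,
        max_iter=300,
        tol=1e-6,
        random_state=int(seed) % (2**31),
    )
    km.fit(sample)
    return Codebook(words=km.cluster_centers_.copy(), train_seed=int(seed), n_sampled=n)


def encode_vq(descriptors: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Hard assignment: one-hot at the nearest word (ties -> lowest index).

    Accepts a single descriptor or an (N, d) batch; returns (N, M) codes.
    """
    X = np.atleast_2d(np.asarray(descriptors, dtype=np.float64))
    if X.shape[1] != codebook.words.shape[1]:
        raise ContractError(
            f"descriptor dim {X.shape[1]} != word dim {codebook.words.shape[1]}"
        )
    # pairwise_distances_argmin returns the smallest index among ties
    nearest = pairwise_distances_argmin(X, codebook.words)
    codes = np.zeros((X.shape[0], codebook.M))
    codes[np.arange(X.shape[0]), nearest] = 1.0
    return codes


def encode_sa_k(
    descriptors: np.ndarray,
    codebook: Codebook,
    k_nn: int,
    sigma: float = 0.5,
    bandwidth_is_beta: bool = False,
) -> np.ndarray:
    """Localized soft assignment over the k nearest words.

    Weights on the k nearest words are proportional to
    exp(-||x - w||^2 / (2 sigma^2)) and sum to 1; all other entries are
    zero.  With ``bandwidth_is_beta`` the bandwidth parameter is instead
    interpreted as beta in exp(-beta ||x - w||^2).
    """
    X = np.atleast_2d(np.asarray(descriptors, dtype=np.float64))
    M = codebook.M
    if not 1 <= k_nn <= M:
        raise ParameterError(f"k_nn must be in [1, {M}], got {k_nn}")
    d2 = ((X[:, None, :] - codebook.words[None, :, :]) ** 2).sum(axis=2)
    beta = sigma if bandwidth_is_beta else 1.0 / (2.0 * sigma**2)
    codes = np.zeros((X.shape[0], M))
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k_nn]
    rows = np.arange(X.shape[0])[:, None]
    # subtract the per-row min before exponentiating for numerical stability
    d2_nn = d2[rows, nn]
    w = np.exp(-beta * (d2_nn - d2_nn.min(axis=1, keepdims=True)))
    w /= w.sum(axis=1, keepdims=True)
    codes[rows, nn] = w
    return codes


def pool(codes: np.ndarray | list, method: str = "sum", M: int | None = None) -> np.ndarray:
    """Aggregate codes elementwise by sum or max; an empty list pools to zeros."""
    if method not in ("sum", "max"):
        raise ParameterError(f"pooling method must be 'sum' or 'max', got {method!r}")
    if isinstance(codes, list):
        if len(codes) == 0:
            if M is None:
                raise ParameterError("pooling an empty code list requires M")
            return np.zeros(M)
        codes = np.vstack([np.atleast_2d(c) for c in codes])
    codes = np.atleast_2d(np.asarray(codes, dtype=np.float64))
    if codes.shape[0] == 0:
        if M is None:
            raise ParameterError("pooling an empty code array requires M")
        return np.zeros(M)
    if M is not None and codes.shape[1] != M:
        raise ContractError(f"code dim {codes.shape[1]} != expected {M}")
    return codes.sum(axis=0) if method == "sum" else codes.max(axis=0)


def normalize_vec(v: np.ndarray, norm: str = "l1") -> np.ndarray:
    """L1 or L2 normalization; the zero vector is returned unchanged."""
    if norm not in ("l1", "l2"):
        raise ParameterError(f"norm must be 'l1' or 'l2', got {norm!r}")
    v = np.asarray(v, dtype=np.float64)
    s = np.abs(v).sum() if norm == "l1" else np.sqrt((v**2).sum())
    return v / s if s > 0 else v.copy()
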