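"""Low-level region features: intensity histograms and GLCM variants.

Two co-occurrence feature flavours are provided:

* ``glcm_element_features`` — the lower-triangular entries of the
  symmetric isotropic GLCM used directly as a histogram-style vector of
  length G(G+1)/2.  Because these are themselves histogram entries they
  combine naturally with ring-pyramid weighting, unlike scalar texture
  statistics.
* ``glcm_statistics_16`` — the classic comparison: contrast, correlation,
  energy and homogeneity from each of the four directional GLCMs,
  concatenated into 16 values.

All extractors take an explicit region mask; co-occurring pixel pairs
count only when BOTH endpoints lie inside the region, so a ring's
features never depend on pixels outside that ring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, ParameterError
from .preprocess import QuantizedSlice

# offsets (dy, dx) for directions 0°, 45°, 90°, 135° at unit distance
_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


class ZeroPairWarning(UserWarning):
    """A direction produced no co-occurring pixel pair inside the region."""


@dataclass
class GlcmMatrix:
    """A gray-level co-occurrence matrix with its construction parameters."""

    P: np.ndarray
    G: int
    D: int
    normalized: bool


@dataclass
class HaralickFeatures:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float

    def as_array(self) -> np.ndarray:
        return np.array([self.contrast, self.correlation, self.energy, self.homogeneity])


def intensity_histogram(levels: QuantizedSlice, region: np.ndarray, G: int | None = None) -> np.ndarray:
    """L1-normalized histogram of quantized levels over region pixels.

    An empty region returns the all-zero vector (no normalization), which
    downstream concatenation relies on for empty rings.
    """
    G = levels.G if G is None else G
    vals = levels.levels[np.asarray(region, dtype=bool)]
    counts = np.bincount(vals, minlength=G).astype(np.float64)
    total = counts.sum()
    return counts / total if total > 0 else counts


def _directional_counts(levels: np.ndarray, region: np.ndarray, G: int, dy: int, dx: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one (dy, dx) offset.

    Each unordered pair inside the region contributes to both (i, j) and
    (j, i), matching the usual symmetric-GLCM accounting.
    """
    H, W = levels.shape
    y0, y1 = max(0, -dy), min(H, H - dy)
    x0, x1 = max(0, -dx), min(W, W - dx)
    a = levels[y0:y1, x0:x1]
    b = levels[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
    valid = region[y0:y1, x0:x1] & region[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
    P = np.zeros((G, G), dtype=np.float64)
    np.add.at(P, (a[valid], b[valid]), 1.0)
    return P + P.T


def glcm_directional(
    levels: QuantizedSlice, region: np.ndarray, D: int = 1, normalized: bool = True
) -> list[GlcmMatrix]:
    """Symmetric GLCM for each of the four directions at distance D."""
    if levels.G < 2:
        raise ParameterError(f"G must be >= 2, got {levels.G}")
    if D < 1:
        raise ParameterError(f"co-occurrence distance must be >= 1, got {D}")
    region = np.asarray(region, dtype=bool)
    out = []
    for dy, dx in _DIRECTIONS:
        P = _directional_counts(levels.levels, region, levels.G, dy * D, dx * D)
        total = P.sum()
        if normalized and total > 0:
            out.append(GlcmMatrix(P / total, levels.G, D, True))
        else:
            out.append(GlcmMatrix(P, levels.G, D, False))
    return out


def glcm_isotropic(levels: QuantizedSlice, region: np.ndarray, D: int = 1) -> GlcmMatrix:
    """Isotropic GLCM: average of the four directional count matrices, L1-normalized.

    Averaging happens in count space before the single normalization, so
    directions with few valid pairs (common in thin rings) are weighted by
    their actual pair counts.  With zero pairs overall the zero matrix is
    returned with ``normalized=False``.
    """
    mats = glcm_directional(levels, region, D, normalized=False)
    P = sum(m.P for m in mats) / 4.0
    total = P.sum()
    if total == 0:
        return GlcmMatrix(P, levels.G, D, normalized=False)
    return GlcmMatrix(P / total, levels.G, D, normalized=True)


def glcm_element_features(glcm: GlcmMatrix) -> np.ndarray:
    """Lower-triangular elements (diagonal included) in row-major order.

    For a symmetric G x G matrix this is the full information content in
    G(G+1)/2 numbers: P(0,0), P(1,0), P(1,1), P(2,0), ...
    """
    P = glcm.P
    if not np.allclose(P, P.T, atol=1e-9):
        raise ContractError("GLCM is not symmetric")
    idx = np.tril_indices(glcm.G)
    return P[idx]


def glcm_statistics(glcm: GlcmMatrix) -> HaralickFeatures:
    """Contrast, correlation, energy and homogeneity of a normalized GLCM.

    correlation = sum (i - mu_i)(j - mu_j) P(i,j) / (sigma_i sigma_j),
    defined as 0 when either marginal standard deviation vanishes
    (constant regions) to avoid NaN propagation.
    """
    if not glcm.normalized:
        raise ContractError("glcm_statistics requires a normalized GLCM")
    P = glcm.P
    G = glcm.G
    i, j = np.meshgrid(np.arange(G), np.arange(G), indexing="ij")
    contrast = float(((i - j) ** 2 * P).sum())
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + np.abs(i - j))).sum())
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = (np.arange(G) * pi).sum()
    mu_j = (np.arange(G) * pj).sum()
    var_i = ((np.arange(G) - mu_i) ** 2 * pi).sum()
    var_j = ((np.arange(G) - mu_j) ** 2 * pj).sum()
    denom = np.sqrt(var_i * var_j)
    if denom <= 0:
        correlation = 0.0
    else:
        correlation = float(((i - mu_i) * (j - mu_j) * P).sum() / denom)
    return HaralickFeatures(contrast, correlation, energy, homogeneity)


def glcm_statistics_16(levels: QuantizedSlice, region: np.ndarray, D: int = 1) -> np.ndarray:
    """Four Haralick statistics per direction, concatenated (length 16).

    Directions are ordered 0°, 45°, 90°, 135°; a direction with zero
    co-occurring pairs contributes four zeros and a warning.
    """
    feats = []
    for m in glcm_directional(levels, region, D, normalized=True):
        if not m.normalized:
            warnings.warn(
                "direction with zero co-occurring pairs; its features set to 0",
                ZeroPairWarning,
                stacklevel=2,
            )
            feats.extend([0.0, 0.0, 0.0, 0.0])
        else:
            feats.extend(glcm_statistics(m).as_array())
    return np.asarray(feats, dtype=np.float64)
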