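"""Intensity normalization and gray-level quantization.

MR intensities are not calibrated across acquisitions, so every feature
extractor in this package works on robust min-max normalized values: the
1st and 99th percentile of the whole slice map to 0 and 1, tails are
clipped.  Histogram and co-occurrence features additionally quantize the
normalized values into G uniform bins on [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


class DegenerateSliceWarning(UserWarning):
    """Raised when a slice is (near) constant so min-max scaling collapses."""


@dataclass
class NormalizedSlice:
    """Slice values scaled to [0, 1]; keeps the percentile anchors for audit."""

    values: np.ndarray
    p_low_value: float
    p_high_value: float


@dataclass
class QuantizedSlice:
    """Integer gray levels in [0, G-1]."""

    levels: np.ndarray
    G: int


def normalize_intensity(
    image: np.ndarray,
    p_low: float = 1.0,
    p_high: float = 99.0,
    mask: np.ndarray | None = None,
) -> NormalizedSlice:
    """Robust min-max normalization: v' = clip((v - P_lo) / (P_hi - P_lo), 0, 1).

    Percentiles use linear interpolation between order statistics and are
    computed over the whole slice by default; pass ``mask`` to restrict
    them to an ROI instead.  A constant slice (P_hi == P_lo) maps to all
    zeros and emits :class:`DegenerateSliceWarning`.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ParameterError("cannot normalize an empty image")
    sample = image[mask] if mask is not None else image
    lo, hi = np.percentile(sample, [p_low, p_high])
    if hi <= lo:
        warnings.warn(
            "degenerate slice: identical low/high percentiles, output set to 0",
            DegenerateSliceWarning,
            stacklevel=2,
        )
        return NormalizedSlice(np.zeros_like(image), float(lo), float(hi))
    values = np.clip((image - lo) / (hi - lo), 0.0, 1.0)
    return NormalizedSlice(values, float(lo), float(hi))


def quantize(normalized: NormalizedSlice | np.ndarray, G: int) -> QuantizedSlice:
    """Uniform quantization of [0, 1] into G levels; the top edge is closed.

    level = min(floor(v * G), G - 1), so v = 1.0 lands in level G-1 rather
    than an out-of-range bin.
    """
    if G < 2:
        raise ParameterError(f"G must be >= 2, got {G}")
    values = normalized.values if isinstance(normalized, NormalizedSlice) else np.asarray(normalized)
    levels = np.minimum(np.floor(values * G).astype(np.int64), G - 1)
    return QuantizedSlice(levels=levels, G=G)
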