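"""Assembly of the ring-form spatial-pyramid descriptor.

For one slice the pipeline is: normalize intensities, dilate the tumor
mask by R, partition the augmented ROI into rings at levels 0..L, extract
one feature vector per ring, normalize each ring's subvector, scale it by
its level weight and concatenate in (level ascending, ring ascending)
order.  In ``single_level`` mode only the finest level L is used,
unweighted — the ablation counterpart of the full pyramid.

Level weights follow the standard spatial-pyramid kernel decomposition:
level 0 gets 1/2^L and level k >= 1 gets 1/2^(L-k+1), so that the
weighted sum of per-level histogram-intersection kernels telescopes into
the pyramid match kernel.  The weights are an argument everywhere, so a
uniform or custom weighting can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bow as bow_mod
from . import features as feat_mod
from .config import RunConfig
from .dataset import AnnotatedSlice
from .errors import ConfigError, ParameterError
from .preprocess import normalize_intensity, quantize
from .roi import augment_roi, ring_partition


@dataclass
class RegionDescriptor:
    """Final concatenated feature vector plus its block layout.

    ``layout`` maps (level, ring index) -> (offset, length) into ``vector``.
    """

    vector: np.ndarray
    layout: dict


def spm_weights(L: int) -> np.ndarray:
    """Per-level weights of the pyramid match kernel for levels 0..L."""
    if L < 0:
        raise ParameterError(f"L must be >= 0, got {L}")
    w = np.empty(L + 1)
    w[0] = 1.0 / 2**L
    for k in range(1, L + 1):
        w[k] = 1.0 / 2 ** (L - k + 1)
    return w


def feature_dim(config: RunConfig) -> int:
    """Per-ring feature dimension B for the configured feature family."""
    if config.feature == "histogram":
        return config.G
    if config.feature == "glcm_element":
        return config.G * (config.G + 1) // 2
    if config.feature == "glcm_stats16":
        return 16
    if config.feature == "bow":
        return config.M
    raise ConfigError(f"unknown feature family {config.feature!r}")


def descriptor_length(config: RunConfig) -> int:
    """Total descriptor length: (2^(L+1)-1) B in pyramid mode, 2^L B single-level."""
    B = feature_dim(config)
    if config.mode == "pyramid":
        return (2 ** (config.L + 1) - 1) * B
    return 2**config.L * B


def _ring_feature(
    config: RunConfig,
    ring: np.ndarray,
    quantized,
    patches: "bow_mod.PatchSet | None",
    codes: "np.ndarray | None",
) -> np.ndarray:
    """Raw (pre-normalization) feature vector for one ring."""
    if config.feature == "histogram":
        return feat_mod.intensity_histogram(quantized, ring)
    if config.feature == "glcm_element":
        glcm = feat_mod.glcm_isotropic(quantized, ring, D=config.D)
        return feat_mod.glcm_element_features(glcm)
    if config.feature == "glcm_stats16":
        if not ring.any():
            return np.zeros(16)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", feat_mod.ZeroPairWarning)
            return feat_mod.glcm_statistics_16(quantized, ring, D=config.D)
    if config.feature == "bow":
        in_ring = ring[patches.centers[:, 0], patches.centers[:, 1]]
        return bow_mod.pool(codes[in_ring], method=config.pooling, M=config.M)
    raise ConfigError(f"unknown feature family {config.feature!r}")


def build_descriptor(
    slice_: AnnotatedSlice,
    config: RunConfig,
    codebook: "bow_mod.Codebook | None" = None,
    weights: np.ndarray | None = None,
) -> RegionDescriptor:
    """Full per-slice pipeline producing the classifier-ready descriptor."""
    if config.feature == "bow" and codebook is None:
        raise ConfigError("feature 'bow' requires a codebook")
    normalized = normalize_intensity(
        slice_.image,
        config.p_low,
        config.p_high,
        mask=slice_.mask if config.norm_scope == "roi" else None,
    )
    region = augment_roi(slice_.mask, config.R)
    partition = ring_partition(region, config.L)

    quantized = None
    if config.feature in ("histogram", "glcm_element", "glcm_stats16"):
        quantized = quantize(normalized, config.G)

    patches = codes = None
    if config.feature == "bow":
        patches = bow_mod.extract_patches(normalized, region, config.p)
        if config.coding == "vq":
            codes = bow_mod.encode_vq(patches.descriptors, codebook)
        else:
            codes = bow_mod.encode_sa_k(patches.descriptors, codebook, config.k_nn, config.sigma)

    if config.mode == "pyramid":
        level_range = range(config.L + 1)
        w = spm_weights(config.L) if weights is None else np.asarray(weights, dtype=float)
        if len(w) != config.L + 1:
            raise ConfigError(f"expected {config.L + 1} level weights, got {len(w)}")
    else:
        level_range = [config.L]
        w = {config.L: 1.0}

    blocks = []
    layout = {}
    offset = 0
    for k in level_range:
        wk = w[k]
        for i, ring in enumerate(partition.rings(k)):
            v = _ring_feature(config, ring, quantized, patches, codes)
            v = bow_mod.normalize_vec(v, config.norm) * wk
            blocks.append(v)
            layout[(k, i)] = (offset, len(v))
            offset += len(v)
    return RegionDescriptor(vector=np.concatenate(blocks), layout=layout)
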