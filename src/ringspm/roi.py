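"""ROI augmentation by disk dilation and ring-form partition.

The tumor mask alone ignores peritumoral tissue, which carries class
information (tumor location context).  ``augment_roi`` therefore dilates
the mask with a discrete disk of radius R.  ``ring_partition`` then splits
the (augmented) ROI into concentric rings: each ROI pixel's Euclidean
distance to the nearest background pixel is linearly rescaled to [0, 1]
over the ROI, and level k bins that normalized distance into 2**k equal
subintervals.  Ring index 0 is the outermost ring (smallest distance).

Together the per-level ring sets form a spatial pyramid adapted to blob-
shaped regions, replacing the rectangular grids of classic spatial
pyramid matching which make no sense for tumors of arbitrary shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyRoiError, ParameterError


class ThinRoiWarning(UserWarning):
    """ROI too thin for a distance gradient; all pixels fall in ring 0."""


def disk_offsets(R: int) -> np.ndarray:
    """Integer (dy, dx) offsets of the discrete disk {dy^2 + dx^2 <= R^2}."""
    if R < 0:
        raise ParameterError(f"radius must be >= 0, got {R}")
    rng = np.arange(-R, R + 1)
    dy, dx = np.meshgrid(rng, rng, indexing="ij")
    keep = dy**2 + dx**2 <= R**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def disk_footprint(R: int) -> np.ndarray:
    """Boolean (2R+1) x (2R+1) structuring element for the discrete disk."""
    rng = np.arange(-R, R + 1)
    dy, dx = np.meshgrid(rng, rng, indexing="ij")
    return dy**2 + dx**2 <= R**2


def augment_roi(mask: np.ndarray, R: int) -> np.ndarray:
    """Morphological dilation of mask by a disk of radius R (R=0: identity).

    The result is clipped to the image bounds and always contains the
    input mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRoiError("cannot augment an empty mask")
    if R < 0:
        raise ParameterError(f"radius must be >= 0, got {R}")
    if R == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=disk_footprint(R))


def border_distance(mask: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance to the nearest background pixel.

    The image is treated as padded with background, so a region touching
    the border still gets distance 1 at its edge pixels.  Background
    pixels map to 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRoiError("cannot compute border distance of an empty mask")
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded)
    return dist[1:-1, 1:-1]


@dataclass
class RingPartition:
    """Disjoint ring masks per pyramid level.

    ``levels[k]`` holds 2**k boolean masks ordered outermost-first; within
    each level the rings are pairwise disjoint and their union is exactly
    the ROI.  ``distance_map`` stores the normalized border distance
    (in [0, 1] on ROI pixels, 0 elsewhere).
    """

    levels: list[list[np.ndarray]]
    L: int
    distance_map: np.ndarray

    def rings(self, k: int) -> list[np.ndarray]:
        return self.levels[k]


def ring_partition(mask: np.ndarray, L: int) -> RingPartition:
    """Split the ROI into 2**k concentric rings at each level k = 0..L.

    Normalized distance d' = (d - dmin) / (dmax - dmin) over ROI pixels;
    ring i at level k collects pixels with d' in [i/2^k, (i+1)/2^k), the
    last subinterval closed at 1.  A ROI with a flat distance map (e.g. a
    1-pixel-thin region) puts every pixel in ring 0 at every level, with a
    warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if L < 0:
        raise ParameterError(f"L must be >= 0, got {L}")
    dist = border_distance(mask)
    d_roi = dist[mask]
    dmin, dmax = d_roi.min(), d_roi.max()
    dnorm = np.zeros_like(dist)
    if dmax > dmin:
        dnorm[mask] = (dist[mask] - dmin) / (dmax - dmin)
    else:
        warnings.warn(
            "ROI has a constant border distance; all pixels assigned to ring 0",
            ThinRoiWarning,
            stacklevel=2,
        )
    levels: list[list[np.ndarray]] = []
    for k in range(L + 1):
        n = 2**k
        # bin by interval membership; the closed top edge folds d'=1 into the last ring
        idx = np.minimum(np.floor(dnorm * n).astype(np.int64), n - 1)
        rings = [mask & (idx == i) for i in range(n)]
        levels.append(rings)
    return RingPartition(levels=levels, L=L, distance_map=dnorm)
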