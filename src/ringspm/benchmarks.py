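"""Reference confusion matrices from a published CE-MRI brain-tumor benchmark.

A widely used three-class benchmark (meningioma / glioma / pituitary
tumor; 3064 T1-weighted contrast-enhanced slices from 233 patients)
reports slice-level confusion matrices for three feature families, each
in two ablation pairs: without vs with ROI dilation (radius 8), and —
at the dilated setting — without vs with ring partition.  The matrices
are reproduced here as plain count tables so that this package's
sensitivity/specificity computation can be checked against the
percentages printed alongside them, and so worked examples have
realistic inputs.

Rows are true classes, columns predicted, in the order
(meningioma, glioma, pituitary); class totals are 708 / 1426 / 930.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CLASSES = ("meningioma", "glioma", "pituitary")


@dataclass(frozen=True)
class BenchmarkMatrix:
    """One reported confusion matrix with its printed per-class metrics."""

    name: str
    counts: np.ndarray            # 3x3, true rows x predicted columns
    sensitivity_pct: tuple        # printed, 1 decimal
    specificity_pct: tuple        # printed, 1 decimal


def _bm(name, counts, sens, spec):
    return BenchmarkMatrix(name, np.array(counts, dtype=np.int64), tuple(sens), tuple(spec))


# Dilation ablation: baseline = undilated tumor mask, augmented = radius-8 dilation.
AUGMENTATION_STUDY = {
    "histogram": {
        "baseline": _bm(
            "histogram, R=0",
            [[428, 36, 244], [37, 1262, 127], [240, 192, 498]],
            (60.5, 88.5, 53.5),
            (88.2, 86.1, 82.6),
        ),
        "augmented": _bm(
            "histogram, R=8",
            [[524, 63, 121], [46, 1291, 89], [134, 91, 705]],
            (74.0, 90.5, 75.8),
            (92.4, 90.6, 90.2),
        ),
    },
    "glcm_element": {
        "baseline": _bm(
            "glcm_element, R=0",
            [[491, 46, 171], [31, 1293, 102], [173, 146, 611]],
            (69.4, 90.7, 65.7),
            (91.3, 88.3, 87.2),
        ),
        "augmented": _bm(
            "glcm_element, R=8",
            [[555, 53, 100], [51, 1306, 69], [122, 73, 735]],
            (78.4, 91.6, 79.0),
            (92.7, 92.3, 92.1),
        ),
    },
    "bow": {
        "baseline": _bm(
            "bow, R=0",
            [[532, 35, 141], [29, 1330, 67], [125, 108, 697]],
            (75.1, 93.3, 74.9),
            (93.5, 91.3, 90.3),
        ),
        "augmented": _bm(
            "bow, R=8",
            [[571, 57, 80], [44, 1326, 56], [75, 54, 801]],
            (80.6, 93.0, 86.1),
            (94.9, 93.2, 93.6),
        ),
    },
}

# Partition ablation at R=8: baseline = L=0, partitioned = best ring pyramid.
PARTITION_STUDY = {
    "histogram": {
        "baseline": _bm(
            "histogram, L=0",
            [[518, 64, 126], [48, 1292, 86], [134, 81, 715]],
            (73.2, 90.6, 76.9),
            (92.3, 91.1, 90.1),
        ),
        "partitioned": _bm(
            "histogram, ring pyramid",
            [[562, 31, 115], [38, 1363, 25], [130, 42, 758]],
            (79.4, 95.6, 81.5),
            (92.9, 95.5, 93.4),
        ),
    },
    "glcm_element": {
        "baseline": _bm(
            "glcm_element, L=0",
            [[556, 45, 107], [35, 1328, 63], [99, 73, 758]],
            (78.5, 93.1, 81.5),
            (94.3, 92.8, 92.0),
        ),
        "partitioned": _bm(
            "glcm_element, ring pyramid",
            [[582, 26, 100], [25, 1376, 25], [99, 40, 791]],
            (82.2, 96.5, 85.1),
            (94.7, 96.0, 94.1),
        ),
    },
    "bow": {
        "baseline": _bm(
            "bow, L=0",
            [[569, 62, 77], [45, 1318, 63], [75, 54, 801]],
            (80.4, 92.4, 86.1),
            (94.9, 92.9, 93.4),
        ),
        "partitioned": _bm(
            "bow, ring pyramid",
            [[609, 23, 76], [27, 1374, 25], [80, 38, 812]],
            (86.0, 96.4, 87.3),
            (95.5, 96.3, 95.3),
        ),
    },
}


def all_benchmark_matrices() -> list[BenchmarkMatrix]:
    out = []
    for study in (AUGMENTATION_STUDY, PARTITION_STUDY):
        for variants in study.values():
            out.extend(variants.values())
    return out
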