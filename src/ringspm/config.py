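"""Run configuration: one flat record of every pipeline parameter.

Defaults follow the configuration that performed best in the benchmark
study this pipeline is modeled on: disk radius R = 8, gray levels G = 20,
co-occurrence distance D = 4, patch size 5, dictionary size 300, hard VQ
coding, sum pooling, L1 normalization, histogram-intersection-kernel SVM.
The pyramid depth L is experiment-specific and defaults to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

FEATURES = ("histogram", "glcm_element", "glcm_stats16", "bow")
MODES = ("pyramid", "single_level")
CODINGS = ("vq", "sa_k")
POOLINGS = ("sum", "max")
NORMS = ("l1", "l2")
CLASSIFIERS = ("svm_hik", "src", "knn")

DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))


@dataclass
class RunConfig:
    """All pipeline and evaluation parameters for one run."""

    feature: str = "histogram"
    R: int = 8              # ROI dilation radius, pixels
    L: int = 0              # pyramid depth: 2**k rings at level k
    mode: str = "pyramid"   # 'pyramid' (levels 0..L) or 'single_level' (level L only)
    G: int = 20             # gray levels for histogram / GLCM quantization
    D: int = 4              # co-occurrence distance, pixels
    p: int = 5              # patch side for bag-of-words, odd
    M: int = 300            # dictionary size
    coding: str = "vq"
    k_nn: int = 5           # neighbors for soft assignment
    sigma: float = 0.5      # Gaussian bandwidth for soft assignment
    pooling: str = "sum"
    norm: str = "l1"
    p_low: float = 1.0      # robust min-max percentiles
    p_high: float = 99.0
    norm_scope: str = "slice"  # percentile scope: 'slice' or 'roi'
    classifier: str = "svm_hik"
    C_grid: tuple = DEFAULT_C_GRID
    src_T: int = 30         # sparsity level for sparse-representation classification
    knn_k: int = 1
    n_folds: int = 5
    bow_sample: int = 100_000  # descriptors sampled for dictionary learning
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            ("feature", self.feature, FEATURES),
            ("mode", self.mode, MODES),
            ("coding", self.coding, CODINGS),
            ("pooling", self.pooling, POOLINGS),
            ("norm", self.norm, NORMS),
            ("classifier", self.classifier, CLASSIFIERS),
            ("norm_scope", self.norm_scope, ("slice", "roi")),
        ]
        for name, value, allowed in checks:
            if value not in allowed:
                raise ConfigError(f"{name}={value!r} not in {allowed}")
        if self.R < 0:
            raise ConfigError(f"R must be >= 0, got {self.R}")
        if self.L < 0:
            raise ConfigError(f"L must be >= 0, got {self.L}")
        if self.G < 2:
            raise ConfigError(f"G must be >= 2, got {self.G}")
        if self.D < 1:
            raise ConfigError(f"D must be >= 1, got {self.D}")
        if self.p < 3 or self.p % 2 == 0:
            raise ConfigError(f"p must be odd and >= 3, got {self.p}")
        if self.M < 2:
            raise ConfigError(f"M must be >= 2, got {self.M}")
        if len(self.C_grid) == 0:
            raise ConfigError("C_grid must be nonempty")
        if self.n_folds < 2:
            raise ConfigError(f"n_folds must be >= 2, got {self.n_folds}")

    def replace(self, **kwargs) -> "RunConfig":
        d = asdict(self)
        d.update(kwargs)
        return RunConfig(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["C_grid"] = list(self.C_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "C_grid" in d:
            d["C_grid"] = tuple(float(c) for c in d["C_grid"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
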