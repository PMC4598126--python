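"""Synthetic phantom datasets with controllable class signal placement.

Real contrast-enhanced MRI slices of brain tumors are not redistributable
here, so this module generates 2D phantoms that reproduce the statistical
structure the ring-pyramid method exploits, with the class signal
injectable into three independent channels:

* **tumor texture** — mean / contrast / correlation length of the tumor
  interior (what a plain ROI histogram or GLCM sees);
* **peritumoral context** — intensity and texture of an annulus just
  outside the true tumor border (visible only after ROI dilation);
* **radial layout** — a per-shell intensity pattern inside the tumor
  whose value multiset is identical across classes, so it is invisible
  to a global histogram but visible to a ring partition.

Each phantom slice carries a common background with a bright peripheral
band: the band anchors the 99th intensity percentile and the dark
background the 1st, so slice-wise robust min-max normalization is
class-independent even when annulus intensities differ by class.

Textures are smoothed seeded white noise affine-mapped to a target mean
and standard deviation; tumor boundaries are low-order Fourier
perturbations of a circle (star-convex, so the border distance transform
stays well behaved).  All randomness derives from one integer seed via
per-patient/per-slice substreams, making datasets byte-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .dataset import DatasetManifest, SliceRecord, save_image
from .errors import GeometryError, ParameterError
from .roi import augment_roi, border_distance


@dataclass(frozen=True)
class ClassSpec:
    """Signal parameters of one tumor class across the three channels."""

    name: str
    tumor_mean: float = 0.55
    tumor_sd: float = 0.05
    tumor_corr_len: float = 2.0
    context_mean: float | None = None   # None: annulus keeps the background
    context_sd: float = 0.03
    radial_values: tuple[float, ...] | None = None  # per-shell means, outer -> core


@dataclass(frozen=True)
class PhantomConfig:
    n_patients: int = 15
    slices_per_patient: int = 4
    image_size: int = 128
    classes: tuple[ClassSpec, ...] = (
        ClassSpec("classA", tumor_mean=0.40),
        ClassSpec("classB", tumor_mean=0.55),
        ClassSpec("classC", tumor_mean=0.70),
    )
    tumor_radius_range: tuple[int, int] = (10, 16)
    shape_irregularity: float = 0.2
    annulus_width: int = 6
    margin: int = 34            # min distance of mask from image border (>= max tested R)
    background_mean: float = 0.15
    background_sd: float = 0.02
    band_width: int = 5         # bright peripheral band, anchors the 99th percentile
    band_value: float = 0.9
    noise_sd: float = 0.02
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < len(self.classes):
            raise ParameterError("need at least one patient per class")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0 <= self.shape_irregularity <= 0.5:
            raise ParameterError("shape_irregularity must be in [0, 0.5]")
        r_max = self.tumor_radius_range[1]
        if self.image_size < 2 * (r_max + self.margin) + 2:
            raise ParameterError(
                "image too small for the tumor radius range plus the dilation margin"
            )


def _smooth_texture(shape, rng, mean, sd, corr_len) -> np.ndarray:
    """Gaussian-smoothed white noise with target mean/SD and correlation length."""
    z = rng.standard_normal(shape)
    if corr_len > 0:
        z = ndimage.gaussian_filter(z, corr_len)
    s = z.std()
    if s > 0:
        z = (z - z.mean()) / s
    return mean + sd * z


def generate_tumor_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    irregularity: float,
    rng: np.random.Generator,
    n_harmonics: int = 4,
) -> np.ndarray:
    """Star-convex blob: a circle with low-order Fourier radius perturbation.

    r(theta) = radius * (1 + irregularity * s(theta)) with s a random
    combination of harmonics 2..n_harmonics+1 scaled to max |s| = 1.
    Raises :class:`GeometryError` if the blob touches the image border.
    """
    if radius < 2:
        raise ParameterError(f"radius must be >= 2, got {radius}")
    if not 0 <= irregularity <= 0.5:
        raise ParameterError(f"irregularity must be in [0, 0.5], got {irregularity}")
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    dy = yy - center[0]
    dx = xx - center[1]
    rho = np.hypot(dy, dx)
    if irregularity == 0:
        mask = rho <= radius
    else:
        theta = np.arctan2(dy, dx)
        amps = rng.normal(size=n_harmonics)
        phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
        s = np.zeros_like(theta)
        for m, (a, ph) in enumerate(zip(amps, phases), start=2):
            s += a * np.cos(m * theta + ph)
        peak = np.abs(s).max()
        if peak > 0:
            s /= peak
        mask = rho <= radius * (1.0 + irregularity * s)
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise GeometryError("tumor mask touches the image border")
    n_comp = ndimage.label(mask)[1]
    if n_comp != 1:
        raise GeometryError(f"tumor mask has {n_comp} connected components")
    return mask


def _radial_shell_index(mask: np.ndarray, n_shells: int) -> np.ndarray:
    """Equal-area shells by area-quantiles of the border distance (0 = outermost).

    Quantile binning (not distance-range binning) makes the shells hold
    the same pixel count, so permuting shell intensities across classes
    leaves the global intensity histogram unchanged.
    """
    dist = border_distance(mask)
    d = dist[mask]
    ranks = np.argsort(np.argsort(d, kind="stable"), kind="stable")
    shell = np.minimum((ranks * n_shells) // len(d), n_shells - 1)
    out = np.zeros(mask.shape, dtype=np.int64)
    out[mask] = shell
    return out


def render_slice(
    config: PhantomConfig, spec: ClassSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One phantom slice for one class: returns (image float in [0,1], mask)."""
    H = W = config.image_size
    r_lo, r_hi = config.tumor_radius_range
    radius = rng.uniform(r_lo, r_hi)
    pad = int(np.ceil(radius * (1 + config.shape_irregularity))) + config.margin
    center = (rng.uniform(pad, H - pad), rng.uniform(pad, W - pad))
    mask = generate_tumor_mask((H, W), center, radius, config.shape_irregularity, rng)

    img = _smooth_texture((H, W), rng, config.background_mean, config.background_sd, 3.0)
    # bright peripheral band (common to all classes; anchors the 99th percentile)
    b = config.band_width
    if b > 0:
        band = np.zeros((H, W), dtype=bool)
        band[:b, :] = band[-b:, :] = band[:, :b] = band[:, -b:] = True
        img[band] = config.band_value + 0.02 * rng.standard_normal(band.sum())

    # peritumoral annulus
    if spec.context_mean is not None:
        annulus = augment_roi(mask, config.annulus_width) & ~mask
        tex = _smooth_texture((H, W), rng, spec.context_mean, spec.context_sd, 1.5)
        img[annulus] = tex[annulus]

    # tumor interior
    tex = _smooth_texture((H, W), rng, spec.tumor_mean, spec.tumor_sd, spec.tumor_corr_len)
    img[mask] = tex[mask]
    if spec.radial_values is not None:
        shells = _radial_shell_index(mask, len(spec.radial_values))
        vals = np.asarray(spec.radial_values)
        img[mask] = vals[shells[mask]] + 0.01 * rng.standard_normal(int(mask.sum()))

    if config.noise_sd > 0:
        img = img + config.noise_sd * rng.standard_normal((H, W))
    return np.clip(img, 0.0, 1.0), mask


def _to_integer(img: np.ndarray, bit_depth: int) -> np.ndarray:
    if bit_depth == 8:
        return np.round(img * 255).astype(np.uint8)
    if bit_depth == 16:
        return np.round(img * 65535).astype(np.uint16)
    raise ParameterError(f"bit_depth must be 8 or 16, got {bit_depth}")


def generate_phantom_dataset(config: PhantomConfig, out_dir: str | Path) -> DatasetManifest:
    """Write a phantom dataset (images, masks, manifest.csv) and return its manifest.

    Patients are assigned to classes round-robin, so per-class patient
    counts differ by at most one.  Every random draw flows from
    ``config.seed`` through per-(patient, slice) substreams, so the same
    config yields byte-identical output anywhere.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    n_classes = len(config.classes)
    rows = []
    records = []
    for pi in range(config.n_patients):
        spec = config.classes[pi % n_classes]
        patient_id = f"p{pi:03d}"
        for si in range(config.slices_per_patient):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=(config.seed, pi, si))
            )
            for attempt in range(20):
                try:
                    img, mask = render_slice(config, spec, rng)
                    break
                except GeometryError:
                    continue
            else:
                raise GeometryError(
                    f"could not place a tumor for {patient_id} slice {si} in 20 attempts"
                )
            stem = f"{patient_id}_s{si:02d}"
            img_rel, mask_rel = f"images/{stem}.png", f"masks/{stem}.png"
            save_image(out / img_rel, _to_integer(img, config.bit_depth))
            save_image(out / mask_rel, (mask.astype(np.uint8) * 255))
            rows.append((img_rel, mask_rel, patient_id, spec.name))
            records.append(
                SliceRecord(
                    image_path=(out / img_rel).resolve(),
                    mask_path=(out / mask_rel).resolve(),
                    patient_id=patient_id,
                    label=spec.name,
                )
            )
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "mask_path", "patient_id", "label"])
        writer.writerows(rows)
    classes = sorted({spec.name for spec in config.classes})
    return DatasetManifest(records=records, classes=classes, root=out.resolve())


# ---------------------------------------------------------------------------
# Preset study conditions

def separable_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Widely separated tumor textures and no noise: a pipeline should hit 100%."""
    cfg = PhantomConfig(
        classes=(
            ClassSpec("classA", tumor_mean=0.30, tumor_sd=0.02),
            ClassSpec("classB", tumor_mean=0.55, tumor_sd=0.02),
            ClassSpec("classC", tumor_mean=0.78, tumor_sd=0.02),
        ),
        noise_sd=0.0,
        seed=seed,
    )
    return replace(cfg, **overrides)


def null_config(seed: int = 0, **overrides) -> PhantomConfig:
    """All class parameters identical: any pipeline must perform at chance."""
    spec = ClassSpec
    cfg = PhantomConfig(
        classes=(
            spec("classA", tumor_mean=0.55),
            spec("classB", tumor_mean=0.55),
            spec("classC", tumor_mean=0.55),
        ),
        seed=seed,
    )
    return replace(cfg, **overrides)


def context_signal_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Class signal ONLY in the peritumoral annulus.

    Tumor interiors are identical across classes, so a pipeline restricted
    to the undilated mask (R = 0) sees no signal; dilation with R at least
    the annulus width exposes it.
    """
    cfg = PhantomConfig(
        classes=(
            ClassSpec("classA", tumor_mean=0.50, context_mean=0.30),
            ClassSpec("classB", tumor_mean=0.50, context_mean=0.55),
            ClassSpec("classC", tumor_mean=0.50, context_mean=0.78),
        ),
        annulus_width=6,
        noise_sd=0.02,
        seed=seed,
    )
    return replace(cfg, **overrides)


def radial_signal_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Class signal ONLY in the radial layout of tumor intensities.

    Each class permutes the same four shell intensities over four
    equal-area shells, so the global tumor histogram is class-independent
    (L = 0 at chance) while ring partitions resolve the layout.
    """
    cfg = PhantomConfig(
        classes=(
            ClassSpec("classA", radial_values=(0.30, 0.45, 0.60, 0.75)),
            ClassSpec("classB", radial_values=(0.75, 0.60, 0.45, 0.30)),
            ClassSpec("classC", radial_values=(0.45, 0.75, 0.30, 0.60)),
        ),
        noise_sd=0.01,
        seed=seed,
    )
    return replace(cfg, **overrides)
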