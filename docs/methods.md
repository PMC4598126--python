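# Methods

## Problem and approach

`ringspm` classifies 2D grayscale slices, each annotated with a binary
region-of-interest (ROI) mask, into a small number of tissue classes —
the motivating application is discriminating meningioma, glioma and
pituitary tumor in T1-weighted contrast-enhanced MRI slices with
manually delineated tumor borders. Three observations drive the design:

1. **Peritumoral tissue is informative.** Tumor types correlate with
   location, so the tissue just outside the delineated border carries
   class signal. The ROI is therefore *augmented*: dilated with a
   discrete disk of radius `R` (the set of integer offsets with
   `dy² + dx² ≤ R²`), clipped to the image.
2. **Histogram-style features discard spatial layout.** The augmented
   ROI is split into concentric *rings*: every ROI pixel's Euclidean
   distance to the nearest background pixel is rescaled linearly to
   [0, 1] over the ROI, and level `k` of the pyramid bins that
   normalized distance into `2^k` equal subintervals (half-open, last
   one closed). Ring 0 is the outermost ring. Rectangular spatial
   pyramids are useless for blobs of arbitrary shape and size; the ring
   construction is invariant to the ROI's position, orientation (up to
   pixelization) and scale.
3. **Histogram features compose with the pyramid.** Per ring we extract
   one of: the `G`-bin intensity histogram; the `G(G+1)/2`
   lower-triangular elements of the symmetric isotropic gray-level
   co-occurrence matrix (GLCM) — themselves histogram entries, unlike
   scalar Haralick statistics; or a bag-of-visual-words histogram of
   raw `p×p` patches quantized against a `M`-word k-means dictionary.
   A 16-dimensional Haralick vector (contrast, correlation, energy,
   homogeneity × 4 directions) is included as the classical comparison
   feature.

Per-ring vectors are individually normalized (L1 by default), scaled by
the standard spatial-pyramid level weights — `1/2^L` for level 0,
`1/2^(L−k+1)` for level `k ≥ 1`, which makes the weighted sum of
per-level histogram-intersection kernels telescope into the pyramid
match kernel — and concatenated in (level ascending, ring ascending)
order. `single_level` mode keeps only level `L`, unweighted, as an
ablation. Empty rings contribute zero blocks so the descriptor length,
`(2^(L+1)−1)·B` in pyramid mode with per-ring dimension `B`, is
constant across slices.

Classification uses a support vector machine with the histogram
intersection kernel `K(x,y) = Σᵢ min(xᵢ, yᵢ)` (a Mercer kernel on
nonnegative vectors), one-against-one voting, and the penalty `C`
selected by an inner patient-grouped five-fold cross-validation over
the grid `{2⁻⁵, 2⁻³, …, 2¹⁵}` (ties to the smallest `C`). Sparse
representation classification (greedy orthogonal matching pursuit with
sparsity level `T`, class decided by minimal class-wise reconstruction
residual) and a k-nearest-neighbor rule are provided as comparisons.

## Parameters and defaults

| parameter | meaning | default | note |
|---|---|---|---|
| `R` | dilation radius, pixels | 8 | typical useful grid 0–32; too large admits irrelevant tissue |
| `L` | pyramid depth | 0 | `2^k` rings at level `k`; 1–3 useful |
| `G` | gray levels | 20 | GLCM-element dimension grows as `G(G+1)/2` |
| `D` | co-occurrence distance, pixels | 4 | larger `D` captures longer-range texture |
| `p` | patch side, odd | 5 | raw-patch descriptor dimension `p²` |
| `M` | dictionary size | 300 | k-means on ≤ 100 000 sampled training descriptors |
| `coding` | `vq` or `sa_k` | `vq` | soft assignment uses `k_nn` neighbors, Gaussian bandwidth `sigma = 0.5` (interpreted as σ in `exp(−d²/2σ²)`; a β-convention switch exists) |
| `pooling` / `norm` | `sum`/`max`, `l1`/`l2` | `sum`, `l1` | sum + L1 of VQ codes = word-frequency histogram |
| `p_low`, `p_high` | robust min-max percentiles | 1, 99 | computed over the whole slice by default (`norm_scope` can restrict to the ROI) |
| `C_grid` | SVM penalty grid | `2^{−5..15}` (odd exponents) | selected by inner grouped CV |
| `n_folds` | outer CV folds | 5 | patient-stratified |

## Numerical and convention choices

- **Percentile normalization** uses linear interpolation between order
  statistics and *clips* outside `[P_low, P_high]` — the standard robust
  min-max reading; extrapolation would leave [0, 1].
- **Quantization**: `level = min(floor(v·G), G−1)`, closing the top
  edge so `v = 1` is not out of range.
- **Border distance** is the Euclidean distance transform of the mask
  with the image treated as padded with background, so edge-adjacent
  ROI pixels get distance 1, never 0, and a mask touching the frame
  stays finite.
- **Distance rescaling** maps `[d_min, d_max]` over ROI pixels to
  [0, 1] (not `[0, d_max]`): ring boundaries then depend only on the
  ROI's internal geometry. A ROI with constant distance (1-pixel-thin)
  collapses into ring 0 with a warning.
- **Partition order**: dilation precedes partition; rings are computed
  on the augmented region.
- **GLCM counting**: ordered pairs with *both* endpoints inside the
  region mask, accumulated symmetrically; the four directional count
  matrices (0°, 45°, 90°, 135°) are averaged in count space and then
  normalized once. Count-space averaging weights directions by their
  actual pair counts, which matters in thin rings where directions have
  unequal numbers of valid pairs. Degenerate cases (zero pairs) return
  a zero matrix flagged unnormalized; GLCM correlation is defined as 0
  when a marginal variance vanishes.
- **Patch validity**: the full `p×p` window must lie inside the
  *image* (no padding — padded intensities would be fabricated); the
  center must lie in the region. Patches are assigned to rings by their
  center pixel. Descriptors are taken from the normalized, not
  quantized, image.
- **Dictionary learning** runs k-means (k-means++ seeding, single
  initialization, fixed seed) on a without-replacement sample of
  training-fold descriptors only — never on test-fold pixels.
- **Tie-breaking** is explicit and deterministic everywhere: VQ ties go
  to the lowest word index; one-vs-one vote ties to the largest summed
  signed decision value, then lowest class index; kNN vote ties to the
  smallest mean distance, then lexicographic label order; inner-CV
  accuracy ties to the smallest `C`.
- **LDA visualization** solves the generalized symmetric eigenproblem
  `S_b v = λ (S_w + λ_r I) v` with ridge `λ_r = 10⁻³·tr(S_w)/dim` by
  default, with a deterministic sign convention (first nonvanishing
  basis entry positive).
- **SRC**: orthogonal matching pursuit is used as literally named — a
  greedy L0 method with sparsity level `T` (default 30) as the stopping
  rule; a residual-threshold stopping rule is intentionally not the
  default because `T` makes runtime predictable.

## Evaluation protocol

Folds are assigned per patient: within each class, patients are
shuffled by the run seed and dealt round-robin to folds, with the
starting fold rotated between classes so total fold sizes stay within
one of each other (233 patients in realistic class proportions split
into folds of 46–47). A patient with conflicting slice labels is
assigned by majority label with a warning. Per fold, the codebook, the
SVM `C` and the classifier are fit on training slices only; the report
carries per-fold and pooled confusion matrices, per-class sensitivity
(`cm[c,c]/Σⱼ cm[c,j]`) and one-vs-rest specificity
(`1 − false positives / all negatives`), both rounded to one decimal in
percent, and both mean-of-fold and pooled accuracy. Sweeps over a
parameter reuse one fold assignment so comparisons are paired; a paired
t-test over per-fold accuracies is provided as a convenience statistic.

The package ships the slice-level confusion matrices reported by a
published three-class CE-MRI brain-tumor benchmark (3064 slices, 233
patients; class totals 708/1426/930) in `ringspm.benchmarks`. These are
used to validate the sensitivity/specificity conventions — every
printed percentage is reproduced exactly at one-decimal rounding — and
as realistic worked-example inputs. The benchmark's image data is not
redistributable, so its headline accuracies are not reproduction
targets; the synthetic experiments below probe the same qualitative
claims instead.

## The phantom generator

`ringspm.synthetic` generates datasets whose class signal can be placed
in exactly one of three channels: tumor-interior texture (mean /
contrast / correlation length of smoothed white noise), peritumoral
context (a textured annulus of configurable width just outside the true
border), or radial layout (per-shell intensities over equal-area
quantile shells of the border distance). Tumor boundaries are low-order
Fourier perturbations of a circle — star-convex, so the distance
transform stays well behaved — with placement margins large enough for
any tested dilation radius. Every slice also carries a common dark
background and a bright peripheral band; the band pins the 99th
intensity percentile and the background the 1st, so slice-wise
normalization cannot leak class information through the annulus tail.

Default study conditions: 15 patients (5 per class), 4 slices per
patient, 128×128 pixels, tumor radii 10–16 px, irregularity 0.2,
annulus width 6 px, additive noise SD 0.02 (0.01 for the radial preset,
where the signal contrast is smaller). These sizes keep a full
cross-validated experiment in seconds while leaving each class ≥ 20
slices for a meaningful accuracy estimate. Two constructions make the
ablations sharp:

- **Context preset**: interiors are statistically identical across
  classes, so an undilated pipeline is at chance by construction; with
  `R ≥` annulus width, the annulus enters the ROI and the signal is
  exposed.
- **Radial preset**: the three classes permute the same multiset of
  four shell intensities over four *equal-area* shells, making the
  global ROI histogram class-independent (area weights are equal) while
  ring partitions resolve the permutation. The analysis rings
  (equal-distance bins) do not coincide with the generator shells
  (equal-area bins); they only need to correlate with them, which is
  what makes the test non-circular.

What the phantoms do **not** emulate: anatomy (no brain structures,
no skull geometry beyond the percentile-anchoring band), MRI physics
(no bias field, no Rician noise), inter-scanner intensity variation
beyond a global affine, 3D continuity between slices of one patient
(slices are independent draws given the class), and segmentation error
in the masks. Passing tests therefore show the pipeline's mechanics and
its sensitivity to where the signal lives — not clinical performance.

## Reproducibility

All randomness flows from a single integer seed: the generator derives
per-(patient, slice) substreams via seed sequences, and the evaluator
derives per-fold substreams for dictionary sampling and inner model
selection. The same config and seed produce byte-identical datasets and
identical reports across runs.

## Known limitations

- The isotropic GLCM's probability- vs count-space averaging is a
  genuine convention fork; both agree except when directions have
  unequal pair counts (thin rings). Count-space is implemented.
- Greedy OMP does not generally find the optimal size-`T` support;
  tests assert it matches least squares on its own support and never
  beats exhaustive search, not global optimality.
- The HIK SVM stores the full training Gram matrix; for training sets
  beyond a few thousand slices a budgeted or approximate kernel
  evaluation would be needed.
- With very few patients per class the inner 5-fold C-selection
  degrades gracefully (folds may miss classes and are skipped, with a
  warning) but C estimates become noisy.
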