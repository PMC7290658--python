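# Methods

This note documents the models behind `myofuse`, the parameter choices that
matter, and what the synthetic benchmarks do and do not establish.

## Coordinate conventions

All modules share one frame: a 0-based pixel grid with origin at the top-left
corner, x = column, y = row. Polygon vertices and nucleus centres live in the
continuous version of this frame, and the sample point of pixel (row, col) is
its centre `(col + 0.5, row + 0.5)`. Point-in-polygon tests use the even-odd
(ray crossing) rule with the boundary counting as inside, so a centroid on a
drawn ROI edge is never silently dropped.

## Synthetic scenes

A scene is the complete ground truth for one simulated field. Myotubes are
modelled as capsules — line segments dilated by half the tube width,
discretised to a simple polygon with 10-interval semicircular caps (the
polygon is inscribed in the true capsule; chords cut inwards by < 2 % of the
half-width). A capsule's usable area scales with the number of nuclei it must
hold (2.4·sep² per nucleus, comfortably above the ~1.44·sep² jamming density
of random sequential placement with minimum separation `sep`), its length is
capped at 0.72 of the field's short side, and its width grows to compensate,
which is also what large myotubes look like. Capsules are placed largest
first by rejection sampling, rejecting overlaps (segment–segment distance
below the sum of half-widths plus a 2 px guard); failure after 400 attempts
raises a "field too crowded" error naming the parameters to relax.

Nucleus centres are rejection-sampled inside each capsule at a margin of
(nucleus radius + 1) px from the boundary, with a minimum pairwise separation
enforced across the *whole* field. The default separation is
`2·radius + 3 px`: at exactly `2·radius` two rasterised disks can touch
diagonally and merge under the 8-connected particle analyzer, so the small
guard is what actually guarantees exact count recovery, and it also keeps
mildly blurred disks separable. Mononucleated cells are placed outside every
myotube outline (cleared by their cytoplasmic radius, 2× the nucleus radius),
so the planted differentiation index is exactly recoverable; a configurable
fraction of them (default 0.2, rounded to a count) is eMHC-positive.

Default field: 512 × 512 px at 0.2 µm/px (~102 µm across; the pixel size of
a high-NA oil objective is not pinned down by any reference value, so this is
a free parameter), 6 myotubes with nuclei counts from a shifted geometric
distribution with mean 8 (support ≥ 2; its tail reaches the 15–49 class
regularly and the ≥ 50 class occasionally), 40 mono-nucleated cells, nucleus
radius 4 px. Samplers available: fixed list (cycled), shifted geometric,
shifted negative binomial.

## Rendering

DAPI gets a filled disk per nucleus; eMHC gets the filled myotube polygons
and a cytoplasmic disk per eMHC-positive mono cell. Then, in order: constant
background (default 10), isotropic Gaussian blur as a crude PSF (default
sigma 1 px), and noise — Gaussian with SD defaulting to 5 % of the DAPI peak
(visible, but far below the Otsu separation limit at the default 200/10
peak/background), or Poisson, or none. Intensities are checked against the
bit depth (8 or 16) *before* noise: the overflow error is about the
deterministic signal configuration, while noise tails are unbounded by
construction and are clipped the way a saturating/flooring sensor would.
There is no photorealism (no chromatin texture, no illumination gradients,
no 3-D), so passing benchmarks demonstrate correctness of the measurement
chain, not robustness to real-microscope artefacts.

## Nuclei detection

1. **Rolling-ball background subtraction.** The background is the grayscale
   opening of the image by a ball structuring element: footprint
   `x² + y² ≤ r²`, height profile `sqrt(r² − x² − y²) − r` (0 at the centre),
   which makes the opening anti-extensive and non-negative on non-negative
   input. Default radius 50 px, the conventional default of interactive
   tools; the widely used interactive implementation approximates the ball
   with a paraboloid, and bit-compatibility with it is a non-goal. For radii
   above 16 px the opening is computed on a 4× block-minimum downsampled copy
   and linearly upsampled, then clipped into `[0, image]` — the same
   shrink-for-large-radii strategy those tools use. Edge handling is
   nearest-pixel replication.
2. **Otsu thresholding.** 256 equal-width bins over the image's own value
   range (16-bit data is binned down accordingly); the threshold maximises
   between-class variance, ties resolved to the lowest bin; the mask is
   `image > threshold`. A constant image has no separable foreground and
   yields an empty mask with a warning.
3. **Binary cleanup.** Enclosed holes filled, then opening by a disk of
   radius 1 px (removes speckle smaller than the minimum area well before the
   area filter sees it).
4. **Particle analysis.** Connected components (default 8-connectivity, the
   particle-analyzer convention), area filter default `[20 px², ∞)` — a
   default nucleus disk covers ~49 px² — centroid = arithmetic mean of member
   pixel centres.

Touching nuclei are **not** split: there is no watershed/declumping stage.
With the simulator's separation guarantee this costs nothing; on dense real
cultures it would undercount and is the main known limitation.

## Fusion metrics

Nuclei are assigned to ROIs by centroid containment; a centroid inside
several ROIs goes to the ROI with the nearest polygon centroid (ties to the
lowest id) — inert for non-overlapping manually drawn ROIs. Density is
reported per mm² (`count / (W·H·pixel_size²)` with explicit µm²→mm²
conversion). The differentiation index counts nuclei in *all* eMHC-positive
ROIs, mono- and polynucleated alike, per its literal definition. The fusion
distribution covers eMHC-positive ROIs with ≥ 2 nuclei; the size classes are
`[2, 14]`, `[15, 49]`, `[50, ∞)` — the conventional "more than 50" phrasing
leaves exactly-50 unmapped, and assigning it to the top class makes the
partition exhaustive.

Comparisons: Student's two-sample pooled-variance t-test (Welch behind a
flag; two constant identical groups return t = 0, p = 1 rather than 0/0),
and the two-sided Wilcoxon rank-sum with midrank ties — exact by full
enumeration of all C(n, n_a) rank assignments when n = n_a + n_b ≤ 12
(at most 924 terms), otherwise a normal approximation with continuity and
tie correction. "Wilcoxon" here is the two-sample rank-sum test, since the
compared groups are independent conditions; the one-sample signed-rank test
is not implemented.

## Differential-expression stage

The DE stage consumes per-gene `(gene_id, log2fc, pvalue[, padj])` tables
from any upstream fit (the negative-binomial model fit itself is out of
scope). Benjamini–Hochberg is the textbook step-up (sort ascending, multiply
`p_(i)` by `m/i`, cumulative minimum from the top, cap at 1) applied within
each contrast separately over the **full** table, never a filtered subset,
because the correction depends on the number of tests m. The filter keeps
`|log2FC| ≥ 0.8` — equivalently a 1.74-fold linear change — and
`padj ≤ 0.05`, both boundaries inclusive; direction is "up" iff log2FC > 0
(exactly 0 can never pass a positive cutoff, so the convention is inert).
Genes significant in both contrasts are classified into the four
joint-direction quadrants; the down-in-A/up-in-B quadrant is the
opposing-regulation candidate set.

The table simulator plants, by default, 98 shared significant genes among
1,000, 46 of them opposing; the remaining 52 are distributed uniformly over
the other three quadrants. Planted |log2FC| is uniform on [0.8, 5.0]; planted
p-values are log-uniform on [1e-12, 1e-3] — the upper bound is chosen a
priori so that the worst planted gene stays BH-significant at 0.05 in a
1,000-gene table (`1e-3 · 1000/98 ≈ 0.01`), as befits strongly deregulated
genes. Null genes draw log2FC from N(0, 0.3) and p from Uniform(0, 1); at the
default thresholds the chance of a null gene passing both filters in both
contrasts is ~1e-9 per gene, so planted-truth recovery is exact in practice
and any false entry would be binomially quantifiable.

## Determinism and problem sizes

Every stochastic stage takes an explicit integer seed and uses an
independently constructed generator; sub-seeds are derived by hashing
(seed, indices) into [0, 2³¹). Scenes, rendered rasters and tables serialise
to canonical JSON/CSV, and whole-pipeline reruns are byte-identical — this is
asserted by tests. The benchmark sizes (10 noiseless fields, 3 noisy
~50-nucleus fields, 20 replicates of 100-myotube comparisons, 1,000-gene
tables) were chosen as the smallest sizes at which the checked properties are
stable across seeds; all of them, and the oracle cross-checks
(brute-force morphology, exhaustive threshold scan, flood fill, winding
number, permutation enumeration), run in seconds.

## Known limitations

* No watershed splitting of touching nuclei; no 3-D stacks; no time-lapse.
* No illumination-field correction beyond the rolling ball; no photorealistic
  noise (fixed-pattern, read noise, bleed-through are not modelled).
* Automatic myotube segmentation from the eMHC channel is out of scope: ROIs
  are an input (ground-truth outlines serve in tests).
* The rolling-ball background for radii > 16 px is a downsampled
  approximation of the exact ball opening (exact for the radii the oracle
  tests exercise).
* The DE stage classifies; it does not fit. Library-size normalisation,
  dispersion estimation and enrichment analysis belong upstream/downstream.
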