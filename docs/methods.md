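# Methods

This note documents the models and procedures implemented in `abquant`, the
defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical decisions that were genuinely open.

## Pipeline model

The pipeline treats a whole-slide image (WSI) as an 8-bit RGB raster with a
physical resolution tag (microns per pixel, mpp). Quantification proceeds in
fixed stages:

**Resolution harmonization.** All slides are brought to one working
resolution by area-average (BOX) downsampling. Area averaging preserves mean
intensity (to within one gray level) and avoids the ringing of interpolating
kernels. Upsampling is refused by default: interpolated slides have different
texture statistics from scanned ones, and silently mixing them into a cohort
would bias any texture-sensitive classifier. Default working resolution:
**0.503 µm/px** (a 20x Aperio scan).

**Reinhard color normalization.** Stain intensity varies between staining
batches and scanners. Each slide's color statistics are matched to a single
reference slide in the original Reinhard color-transfer space: RGB → LMS cone
response → log10 → the decorrelated log-opponent lαβ basis. Per channel, the
map is affine — standardize against the source mean/std, rescale to the
reference — followed by the inverse transform and clipping to [0, 255].
Consequences that are tested: self-normalization is the identity up to
quantization (±1 gray level); the re-profiled output matches the reference
profile to machine precision before clipping; the map preserves within-channel
rank order. CIELAB was deliberately not used: the method cited for this
pipeline is Reinhard's, which is defined in lαβ.

Profiles are computed on tissue only by default: pixels whose luminance
(0.299R + 0.587G + 0.114B) reaches 90% of full scale are treated as glass
background and excluded, since slides vary widely in tissue coverage and
whole-image statistics are dominated by glass. A whole-image mode is
available because either convention is defensible; the choice is recorded in
the profile.

**Tiling.** Slides are tiled into 1536×1536 px tiles on a ceil(H/ts)×ceil(W/ts)
grid, 0-based (row, col), with half-open pixel extents; edge tiles are
reflect-padded. Reflection rather than zero-fill avoids artificial dark
borders that would alias into deposit confidences. Tiling is exactly
invertible (tested bit-for-bit).

**Sliding-window inference.** Two classifiers run over the slide at a fixed
stride (default **16 px**, which must divide the patch size, default
**256 px**): f(·) produces three independent confidences in [0, 1] for cored
plaque, diffuse plaque, and CAA (multi-label, since the three heatmaps are
separate); g(·) produces three probabilities (GM, WM, background) summing
to 1. Cell (i, j) of the resulting grids corresponds to the patch *centered*
on the cell's representative pixel (j·s + s/2, i·s + s/2). Center anchoring
was chosen so that a cell's label describes the cell's own location; a
"topleft" anchor mode is provided as a config switch. Patches overhanging the
slide edge see reflect-padded context so the heatmaps cover the whole slide.
Heatmaps are assembled on a single global canvas; tiles are an implementation
detail, so no cross-tile deduplication exists or is needed.

Cells are enumerated row-major and evaluated in batches; batching cannot
change results (tested bit-for-bit). A classifier whose decision depends only
on the patch's center pixel may expose a vectorized `predict_pixels` fast
path; the engine uses it when present, and its equivalence to the
batch-of-patches path is part of the test suite.

The region map is the per-cell argmax of g's probabilities with exact ties
broken by the fixed priority background > GM > WM, so ambiguous cells fall
out of the tissue denominators rather than into them.

**Quantification.** Per class: threshold (values **≥** threshold become 1 —
"below goes to zero" puts equality on the foreground side), remove connected
components smaller than `min_blob_cells` (detection noise), and blob-label
the rest. Default per-class thresholds are 0.9 and `min_blob_cells` is 2;
with the one-hot oracle classifiers any threshold in (0, 1] behaves
identically, and for probabilistic classifiers both are explicitly tunable
per class. Blobs use 8-connectivity by default (standard for object counting
on coarse grids; 4-connectivity is a switch). Each blob is attributed by
majority vote of its cells over the region map: a strict majority of
background cells excludes the blob (a detection sitting on glass is not a
plaque); otherwise GM vs WM majority wins with ties to GM, where deposits
predominate. Counts go into the 1×6 vector ordered (GM-cored, GM-diffuse,
GM-CAA, WM-cored, WM-diffuse, WM-CAA).

Two counting modes exist because object counting and per-patch one-hot
accumulation are both defensible readings of the workflow this package
implements. **Blob mode** (default) counts connected components — the
quantity interpretable as "number of plaques" and the one reported as raw
counts. **Patch-vote mode** increments the slot (argmax class, cell region)
for every cell where any class meets its threshold; its totals are cell
votes, not objects, and all outputs carry `mode="patchvote"` so the two can
never be conflated. Lowering a class's threshold can never decrease that
class's patch-vote count (tested as a property).

**Areas and densities.** Region areas are measured on the heatmap grid:
one cell = (stride × mpp)² µm² (at the defaults, 16 × 0.503 = 8.048 µm per
cell side, 64.770304 µm² per cell). Measuring the denominator at heatmap
resolution keeps it consistent with the grid the counts are defined on.
Density = count/area per (class, region); a zero-area region with zero counts
reports a missing density, and zero area with positive counts is an error
(it indicates inconsistent inputs). Full-resolution areas would differ by a
sub-percent discretization term; the grid convention is stated in every
output table.

**Overlays.** One image per class at heatmap resolution (optionally integer-
upscaled): black background, cyan GM (0,255,255), yellow WM (255,255,0),
orange deposits (255,165,0), as either filled blob cells or centroid dots.
Rendering is a pure function; the pixel-color census equals the region/blob
cell counts (tested).

## Synthetic slides and oracle classifiers

No public WSI accompanies the workflow this package re-implements, so the
generator is a first-class module and the pipeline's primary test bed.

A synthetic slide is an elliptical "tissue" region (semi-axes 0.45·W, 0.45·H)
on a near-white background, split vertically into GM (left) and WM at the
column where the cumulative tissue fraction reaches `gm_fraction`. This
mimics the side-by-side cortical-ribbon adjacency of GM and WM, so behavior
near the GM/WM boundary is testable. Deposits are placed discs: cored = dense
brown disc with a darker core (inner 40% of the radius); diffuse = lighter,
mottled brown disc; CAA = brown annulus (outer 45% of the radius) with a
paler lumen. The whole disc, lumen included, is the deposit's footprint.

Placements are validated hard: every footprint must lie entirely inside its
intended region, and centers must be at least 2·(r_i + r_j) apart. Disjoint,
well-separated deposits make the object-count ground truth unambiguous, which
is what turns end-to-end count recovery into an exact test rather than an
approximate one. The randomized spec generator draws radii of 24–40 px: a
24 px disc covers at least two stride-16 cell centers at any grid alignment,
so every deposit survives the default minimum-blob-size cleaning. When the
generator draws the deposit count itself, it caps the draw by a
packing-feasibility bound so that rejection sampling terminates on small
slides; at the standard slide sizes (2048–4096 px) the cap is above the
drawn range and never binds.

Rendering encodes class and region in a documented color code: each deposit
class and tissue type occupies a disjoint band of the green channel (cored
~[30, 60], CAA ~[81, 98], diffuse ~[119, 140], GM tissue ~[192, 200], WM
tissue ~[216, 224], background ≥ 244), deposits additionally satisfy the
DAB-brown relation R ≥ G + 15, and WM deposits are shifted +24 on the blue
channel (a nod to myelinated background, and the bit that lets region be
decoded under a deposit). Per-pixel multiplicative shading (noise) stays
within each band. The oracle classifiers invert exactly this code from the
patch's center pixel: they are deterministic, perfect stand-ins for trained
CNNs, and they pin down the geometric semantics of a heatmap cell. Arbitrary
off-palette colors decode to "no deposit"/"background".

What the synthetic data do **not** emulate: nuclei and hematoxylin
counterstain, leptomeninges, tissue tears/folds/dust, stain gradients,
out-of-focus regions, and deposits with ambiguous or overlapping extents.
Passing tests therefore demonstrate that the *pipeline machinery* —
geometry, counting, attribution, arithmetic, statistics — is correct, not
that any particular CNN is accurate on real histology. Plugging a trained
model into the classifier registry is the intended path to real data, and
nothing in the pipeline changes when that happens.

## Cohort simulation

Real per-case densities are reported as medians with IQRs; no generative
model is published. The simulator therefore draws each case's density for a
(class, region) slot from a log-normal parameterized by its *median* m
(density = m·exp(σZ), so the group median is m by construction) with
log-space dispersion σ (default 0.5, giving a middle-half spread of roughly
×0.71–×1.40 around the median — comparable to the order-of-magnitude spreads
seen in published IQRs), plus optional zero inflation for sparse classes
such as CAA. Densities convert to integer counts over fixed region areas
(defaults 5×10⁷ µm² GM, 3×10⁷ µm² WM, the order of magnitude of a temporal-
lobe section at the working resolution); the reported density is count/area
so the table is internally exactly consistent. Any calibration of group
medians to published values (e.g. GM diffuse medians of 0, 3.75×10⁻⁷,
5.03×10⁻⁶, 7.625×10⁻⁶ across the four ADNC strata) is a convenience for
realistic magnitudes, not a claim of distributional fidelity.

## Statistics

Skewed, zero-heavy densities get nonparametric treatment: Kruskal–Wallis
omnibus (tie-corrected H, chi-square p on k−1 df) per outcome per grouping;
when the omnibus p < 0.05 and there are ≥3 groups, Dunn's pairwise z tests on
pooled ranks with the tie-corrected variance factor
N(N+1)/12 − Σ(t³−t)/(12(N−1)) and Bonferroni adjustment
(adjusted p = min(1, p·k(k−1)/2)); Wilcoxon rank-sum for two groups, exact by
enumeration when the pooled tie-free sample has ≤12 observations, otherwise
the tie-corrected normal approximation without continuity correction (the
path taken is recorded in the result). Categorical tables use chi-square
(without Yates correction by default; a switch is provided since some
software applies it for 2×2) or Fisher's exact test, chosen automatically
when any expected cell is below 5; Fisher beyond 2×2 uses a seeded
Monte-Carlo sampler of tables with the observed margins, comparing
conditional hypergeometric probabilities, with the method and seed recorded.
Demographics use means/SD and one-way ANOVA. Quartiles are linearly
interpolated (type 7), the default of the major statistical environments.

Analysis plans are explicit: each entry names a grouping variable, outcome
columns, the test ("auto" resolves to Wilcoxon for exactly two groups),
post-hoc alpha, and label exclusions — "deferred" clinical diagnoses are
excluded by default since they carry no usable category. Cases missing the
grouping or outcome value are dropped per analysis; there is no imputation
and no covariate adjustment anywhere.

Degenerate inputs are defined, not left to chance: fully tied data give
H = 0/p = 1 (KW), z = 0/p = 1 (Dunn), F = 0/p = 1 (ANOVA), statistic 0/p = 1
(chi-square on a uniform table); zero within-group variance with unequal
means reports F = ∞, p = 0; empty groups are skipped with a notice.

## Problem sizes used in the checks

The end-to-end recovery check quantifies 100 random slides of 2048–4096 px
with 3–40 deposits each; sliding-window equivalence is verified exhaustively
on 1024² slides; blob labeling is compared to an independent flood-fill
oracle exhaustively on all 65 536 4×4 masks and on 1000 random 64×64 masks
(both connectivities); the Kruskal–Wallis null size uses 1000 simulated
cohorts of 4×30 cases and the power check 200 cohorts with a 10× median
shift. These sizes give exact or tightly bounded expectations while keeping
the default test run fast.

## Known limitations

- The oracle classifiers read one pixel; they validate geometry and
  plumbing, not texture discrimination. Real-data accuracy is entirely a
  property of the plugged-in classifier.
- Blob counting merges deposits whose above-threshold cells touch; the
  generator's separation rule guarantees this cannot happen in tests, but on
  real tissue adjacent deposits can merge (and a single fragmented deposit
  can split) — an intrinsic property of threshold-and-label counting.
- Region attribution is majority-vote per blob; a deposit straddling the
  GM/WM boundary is assigned wholly to one side.
- The Fisher Monte-Carlo p-value is an estimate with seed-dependent
  simulation error of order 1/√B (B = 20 000 by default).
- Single working resolution; no pyramid/level management, no DICOM-WSI, no
  viewer integration.
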