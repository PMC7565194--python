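# Methods

This note documents the models, numerical choices and known limitations of
`cycifpipe`, stage by stage, and states what the synthetic benchmark does
and does not demonstrate about real tissue.

## Coordinate and intensity conventions

Images are 2-D `(row, col)` grids, 0-based, with the pixel-center
convention for sub-pixel quantities (centroids, transforms). Intensities
are stored as nonnegative float64 exactly as read from the source TIFF —
no rescaling on load — so ratios and intensity scatter plots remain
comparable across staining cycles regardless of the camera bit depth.
Masks are pixel sets; there is no sub-pixel geometry anywhere.

## Preprocessing

**Background subtraction** is the white top-hat `clip(I − opening(I, disk(r)), 0)`
with default radius r = 50 px, user-overridable. The opening is a
rolling-ball-equivalent estimate of the smooth background floor; any
structure wider than the disk is treated as background. The disk is applied
in its octagonal sequence decomposition, which makes the cost near-linear
in the radius instead of quadratic. The operation is monotone (output ≤
input), nonnegative, and idempotent up to floating-point error on
spot-like foregrounds.

**Autofluorescence (AF) subtraction.** Diet-derived AF (lipofuscin-like
granules) appears as one shared component across marker channels. Given a
designated AF reference channel, the leakage coefficient into a marker
channel is the least-absolute-deviation (LAD) slope *through the origin* of
marker vs AF over pixels above the AF channel's 0.75 intensity quantile.
For a through-origin line the exact LAD solution is the AF-weighted median
of the per-pixel ratios — deterministic, and robust to genuine staining
that overlaps the AF support. Fewer than 100 qualifying pixels is an error.

Inside the pipeline the fit runs on Gaussian-smoothed (σ = 3 px,
`af_estimate_smooth_px`) and median-centered copies of both channels:
smoothing suppresses shot noise in the AF *reference*, whose presence would
otherwise attenuate the slope (errors-in-variables), and centering removes
the residual noise-floor pedestal left by the top-hat, which would inflate
a through-origin fit. Subtraction then uses the above-pedestal AF
structure, so no pixel ever increases. Two bilinear resamplings (simulation
warp + alignment warp) still soften fine AF granules relative to the
unwarped reference, so pipeline-estimated coefficients sit slightly below
truth (≈ 0.13–0.2 recovered for a true 0.2 mixing in the benchmark); on
same-frame data the estimator is accurate to < 0.01 at 0.7 mixing. The
residual is a few intensity units and does not affect coverage-based
gating.

**Collagen extraction** from trichrome RGB is a fixed HSV threshold —
hue ∈ (0.50, 0.72), saturation ≥ 0.25, value ≤ 0.98 (the value ceiling
excludes near-white empty background) — mirroring the manual color-
threshold step deterministically rather than learning colors per image.
Saturation and hue are invariant to moderate uniform brightness changes, so
the mask is stable under ±20 % illumination scaling.

## Registration

Each staining cycle is re-mounted once, so one planar affine per cycle maps
its frame onto cycle 0 (the reference — first by convention, matching the
channel-1-first role of DAPI). The estimate is two-stage on the nuclear
channel:

1. global translation from the phase-correlation peak at the coarsest
   pyramid level;
2. iterative refinement of all six affine parameters minimizing
   `1 − NCC` (normalized cross-correlation) with Powell's method, over a
   multi-resolution pyramid with downsampling factors 8, 4, 2, 1 and
   Gaussian pre-smoothing (σ = factor/2 before decimation, σ = 1 at full
   resolution).

Powell was chosen over an analytic-gradient scheme because the objective
composes NCC with a bilinear resampler (piecewise-smooth); a derivative-free
direction-set method refines the same objective without the noise of
finite-difference gradients. Iterations are front-loaded where resampling
is cheap: 30 Powell iterations at the coarsest level, 4 at intermediate
levels, 1 polish pass at full resolution. The objective carries a barrier
that rejects any candidate whose linear-part |det| leaves [0.5, 2] — a
sanity range for microscope re-mounting — which keeps the coarse-level
search from wandering into degenerate scales. Translation parameters are
kept in full-resolution pixels and divided by the level factor inside the
objective, so the linear part transfers unchanged across levels.

The final NCC is reported as a similarity score; results below 0.2 are
flagged low-confidence with a warning but returned — dropping a damaged
cycle is the analyst's decision, mirroring manual QC of merged DAPI images.
On the benchmark (300 nuclei, 1024², shifts ≤ 20 px, rotations ≤ 3°,
scales 0.98–1.02, shot noise) recovered transforms displace true cell
centers by ≈ 0.03 px on average, two orders below the 1 px acceptance bar.

Warping uses bilinear interpolation for intensities (clipped at 0) and
nearest-neighbor for masks; each cycle yields one validity mask (pixels
whose pre-image lies inside the moving frame). The common crop is the
*exact* largest axis-aligned rectangle inside the intersection of all
validity masks, found with the maximal-rectangle dynamic program
(histogram-with-stack per row, O(rows·cols)).

Brightfield (trichrome) images carry no DAPI, so their alignment is a
least-squares affine over ≥ 3 user-picked landmark pairs, with the RMS
residual reported; collinear landmarks are rejected.

## Segmentation

**Pixel classification.** Features per pixel: raw intensity plus, at each
scale σ ∈ {1, 2, 4}, the Gaussian-smoothed intensity, Gaussian gradient
magnitude and Laplacian of Gaussian (3·|scales| + 1 planes). The classifier
is a random forest (50 trees, depth ≤ 12, fixed seed, single-threaded for
determinism) fitted on sparse brush labels; masks are `P(class) ≥ 0.5`
with 4-connected components under 20 px removed. Interactive brush labeling
is replaced in unattended runs by a quantile auto-labeler (background
strokes sampled below the median intensity, foreground above the 0.995
quantile), which is enough for the blob-like staining the benchmark
renders; real tissue with textured staining will still want hand labels,
which the same API accepts as an indexed label TIFF.

**Nuclei.** Foreground by global Otsu (or a classifier probability map),
holes filled, then touching nuclei split by seeding watershed growth at
distance-transform peaks (peaks closer than the minimum nucleus diameter,
7 px by default, merge into one seed). Objects outside [30, 1500] px are
dropped and labels renumbered 1..K. 4-connectivity throughout; splitting is
on by default only for the nuclear channel, since cytoplasmic markers form
sheets that must not be shattered.

**Cell assembly.** Nuclei expand by ≤ 3 px (`cell_expand_px`) into
unclaimed territory, ties to the nearest nucleus — the footprint never
crosses another cell. Per marker the mean intensity over the footprint is
recorded (for dot plots), and positivity is *coverage-based*: the marker's
binary mask must cover ≥ 30 % (`coverage_min`) of the footprint. Nuclear
markers (PCNA by default) are scored over the nucleus footprint only, since
proliferation staining is nuclear. Coverage gating on binary masks, rather
than an intensity cutoff, matches a workflow whose masks are the trained
classifier's output. The 3 px expansion is an exposed parameter because the
field does not agree on a cell-boundary definition without a membrane
stain.

## Phenotyping

Gates are ordered conjunctions of positivity signs (KC = IBA1⁺∧CLEC4F⁺,
MoMF = IBA1⁺∧CLEC4F⁻, ductular = CK19⁺), applied in priority order, first
match wins, fall-through label "other" — always a partition. Proliferation
fractions are positive-count over population-count with the counts
returned alongside; empty populations yield NaN with a zero denominator
rather than an exception, so batch runs over many images never abort.
Stained-area statistics count mask pixels inside the tissue mask, with
compound populations (A∧B, A∧¬B) built by explicit set algebra before
counting; zero-denominator ratios are NaN.

## Spatial analysis

**Density maps** place one Gaussian kernel (bandwidth in px, truncated at
4 bandwidths) per centroid on a downsampled grid and renormalize *each
kernel* to unit mass on the grid, so border truncation loses nothing and
the grid total equals the cell count to 1e-6 — making densities comparable
across images of different sizes.

**Neighbor counts** dilate each reference object by a disk of the chosen
radius and count target cells whose centroid (rasterized to its nearest
pixel) falls inside. Because the discrete disk contains exactly the integer
offsets with Euclidean norm ≤ r, this equals thresholding the distance from
the rasterized centroid to the object's pixel set — integer-exact against a
brute-force oracle. A target near several objects counts once per object
but once in the deduplicated total, which is also normalized per tissue
area. The radius is deliberately a **required** parameter with no default:
published descriptions of this analysis state both 6 px and 10 px, and the
package does not silently pick one.

**Tumor regions** operationalize "collagen-encapsulated proliferative
structures": the collagen mask is morphologically closed (disk, default
10 px) to seal capsule gaps, the holes of the closed mask (background
components not touching the image border) are candidates, and a candidate
with ≥ 500 px and ≥ 10 PCNA⁺-nucleus centroids becomes a tumor region;
everything else is one extratumoral region, so the frame is partitioned.
For thin capsule walls the closing reliably seals gaps up to about the
closing *radius* (not diameter): the dilation bridge across a wider gap is
eroded away again when the adjacent wall is only a few pixels thick.
Raising the nucleus threshold can only shrink the tumor set (monotone).
Region composition assigns each cell by its rasterized centroid and reports
counts, fractions of the region, and fractions of the region's macrophage
(KC+MoMF) compartment, conserving every cell.

## Synthetic tissue

The generator emulates what the analysis consumes, not optics: cells placed
by dart-throwing with a minimum center distance (default 14 px ≥ 2.5× the
5 px nucleus radius, so nuclei are separable) and a margin (48 px) that
keeps every cell inside the common field of view across misaligned cycles;
i.i.d. phenotypes from configured frequencies (default KC 0.3, MoMF 0.3,
ductular 0.1, other 0.3); Gaussian per-phenotype marker amplitudes
truncated at 0; isotropic Gaussian spots with σ = 0.75× the object radius
(half-max support ≈ 0.88 radius, so objects fill most of their nominal
footprint); a background plane; a shared granular AF field (Gaussian-
smoothed white noise, σ = 8 px, scaled to the AF amplitude) mixed into
marker channels; per-cycle true affines applied before noise (noise belongs
to the acquisition, not the tissue); additive Gaussian noise with sd
proportional to √intensity, clipped at 0; spots truncated at 4σ (< 0.04 %
mass loss). PCNA positivity is Bernoulli per cell — 0.3 in macrophages,
0.05 elsewhere by default; in the tumor scenario 0.6 inside vs 0.05 outside
the collagen rings. The tumor scenario draws three rings (radius 70 px,
wall 6 px, two 6° capsule gaps whose ≈ 7.5 px chord stays under the
closing radius) and is typically run at denser cellularity (800 cells per
768² in the benchmark) — tumors are hypercellular, and the density puts
≈ 25 cells in each ring so the nucleus threshold is meaningful. Every
random element draws from its own child stream of the seed (placement,
phenotypes, amplitudes, AF, tumor geometry, per-cycle noise), so outputs
are bit-identical given a config and each element can be re-drawn
independently by tests.

The trichrome renderer paints collagen in a blue HSV band (hue 0.60,
saturation 0.70), cellular tissue pink, background near-white — enough to
exercise color thresholding, not a histology simulation.

Ground-truth marker masks for scoring are defined as the half-maximum
support of the noiseless signal (pixels where it exceeds 0.5× the model
mean amplitude), the natural contour for comparing against a classifier
trained on intensity extremes.

**What passing does not show.** The simulator has no PSF, no chromatic or
stage drift within a cycle, no staining variability across rounds beyond
amplitude jitter, no nonrigid tissue deformation, no 3-D structure, and
spot-shaped staining only. Results demonstrate correctness of the
algorithms under the stated model, not segmentation or registration
performance on arbitrary real histology; in particular the auto-labeler's
perfect separability here is optimistic.

## Problem sizes and defaults used in the benchmark

Registration recovery runs at the full stated condition (5 cycles, 1024²,
300 cells). End-to-end phenotype/proliferation recovery uses 500 cells on a
768² frame, the tumor scenario 800 cells on 768², AF estimation 512², and
the oracle/conservation checks run on ≤ 256² fixtures — sizes at which each
property is already fully exercised. The unit-test suite uses 256–512 px
fixtures throughout.

## Known limitations

* The affine model cannot absorb nonrigid tissue relaxation between rounds;
  low NCC flags such cycles but nothing corrects them.
* AF coefficients estimated through the full pipeline are mildly attenuated
  (interpolation smoothing of fine granules); a dedicated same-frame AF
  acquisition avoids this.
* Coverage-based positivity with a single global `coverage_min` can
  misclassify cells whose staining is genuinely partial (e.g. polarized
  membrane markers).
* The quantile auto-labeler assumes foreground is the bright tail of one
  channel; markers with strong off-target texture need manual brush labels.
* Region delineation requires the capsule to be closed up to gaps of about
  the closing radius; heavily fragmented capsules dissolve into the
  extratumoral compartment.
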