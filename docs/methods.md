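# Methods

This note documents the models, algorithms and numerical choices behind the
package, in the spirit of a methods supplement: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## The experimental system being modelled

A metabolic-gradient chamber (MEMIC-style device) is a culture chamber whose
monolayer of cells exchanges medium with a large, well-mixed reservoir
through a single narrow opening. Consumption by the cells outpaces diffusive
resupply with distance from the opening, so stable gradients of oxygen and
nutrients form along the chamber axis. Experiments read these gradients out
by tiled fluorescence microscopy: a uniform nuclear stain (e.g. Hoechst)
plus reporter channels (hypoxia reporters such as HRE-driven GFP,
immunofluorescence markers), exported as one stitched 16-bit grayscale TIFF
per channel. All distances in this package are measured perpendicular to
the opening edge (the edge of the top coverslip), which serves as the x = 0
reference.

## Image cytometry (`memic.cytometry`)

Per-cell quantification proceeds in three steps:

1. **Nucleus detection.** The nuclear channel is Gaussian-smoothed
   (`smoothing_sigma`, default 1 µm) and thresholded. Otsu's method is the
   default because it is parameter-free and reproducible across exposure
   settings; a fixed threshold is available for dim stains. Connected
   components are filtered by area (defaults 10–500 µm², bracketing
   mammalian nuclei at 3–12 µm radius). When `split_touching` is on, merged
   blobs are divided by marker-based watershed on the Euclidean distance
   transform; seeds are h-maxima of the distance map with depth
   `h_minima_depth` (default 1 µm — deep enough to ignore pixelation bumps
   on a single convex nucleus, shallow enough to separate nuclei whose
   disks overlap by ~30% of a radius).
2. **Cell territories.** Each nucleus is grown outward by up to
   `cell_expansion_radius`, with contested pixels assigned to the nearest
   nucleus (Voronoi-constrained expansion, `skimage.segmentation.expand_labels`).
   The default radius is 0: the nucleus is the cell region. This is the
   simplest contract consistent with whole-cell intensity readout when no
   membrane marker exists; expansion never merges or drops labels.
3. **Measurement.** Per label: 0-based pixel centroid × pixel size (µm),
   pixel count × pixel size² (µm²), and the mean of raw pixel values per
   channel. Intensities stay on the raw scale; any normalization
   (e.g. GFP/Hoechst) is an explicit downstream step so provenance is
   auditable.

## Distance-resolved profiling (`memic.profiling`)

Distances are the perpendicular coordinate from the opening edge, clamped
at 0 (cells on the reservoir side are flagged `outside_chamber` and excluded
from profiles). Profiles are moving medians with 25th/75th-percentile bands
over half-open windows `[c − w/2, c + w/2)` on a 0-anchored grid. Defaults:
window 100 µm, step 25 µm, minimum 20 cells per window — chosen so
millimetre-scale gradients are resolved by ≥ 10 windows while windows keep
enough cells for a stable median; all three are configurable. Windows below
the count floor are reported absent rather than interpolated.

The **half-max position** — the summary statistic for "where the gradient
sits" — is the smallest distance at which the median profile crosses
`min + 0.5·(max − min)`, linearly interpolated between adjacent populated
window centers. The profile's own minimum (not zero) is the baseline, which
makes the statistic robust to nonzero background fluorescence and invariant
under positive rescaling of the signal. A flat profile has no half-max and
raises an error: the no-gradient condition is excluded from analysis rather
than silently assigned a position.

Binned positive fractions (e.g. fraction of phospho-H3-positive cells per
distance bin) use contiguous half-open bins anchored at 0; a cell is
positive when its marker value is strictly above the threshold.

The per-cell GFP/Hoechst normalization is per-cell (ratio column), not a
ratio of window medians; cells with a zero denominator are excluded and
counted rather than propagated as infinities.

## Comparison procedures (`memic.stats`)

- **Proximal vs distal rank-sum.** Cells are ordered by distance (never by
  table order); the `n_each` nearest and `n_each` farthest cells (default
  10,000, clamped to half the table with a warning) are compared by a
  two-sided Wilcoxon rank-sum test. The exact null distribution is used for
  tie-free groups of ≤ 10; otherwise the tie-corrected normal approximation.
- **Half-max ANOVA.** One-way fixed-effects ANOVA across groups of replicate
  half-max positions; replicates with undefined half-max (no gradient) are
  excluded and counted. Zero between-group variance reports F = 0, p = 1 by
  convention.
- **Per-bin t-tests.** Each bin's replicate fractions against the first
  (best-nurtured) bin, Student's pooled-variance t by default (a Welch flag
  exists), no multiple-testing correction by default (an optional Holm
  step-down flag exists). The first bin against itself is reported as p = 1.
- **High-expressor classification.** A cell is "high" iff its value is
  strictly greater than k × the control median (default k = 2). Strict
  inequality is the boundary convention; the classifier is invariant under
  common positive rescaling.

These are per-cell tests on spatially autocorrelated data; p-values are
calibrated under independent sampling (verified by type-I simulations) but
do not correct for spatial correlation — a deliberate, documented
limitation.

## Gradient simulator (`memic.simulate`)

The simulator commits to a minimal 1D reaction–diffusion model, written as
a reconstruction of the physics rather than a calibrated digital twin:

    ∂c/∂t = D ∂²c/∂x² − (ρq/h)·u(c),  c(0,t) = c0,  ∂c/∂x(L,t) = 0,

with u(c) = c/(c + Km), or zeroth-order u = 1 on {c > 0} when Km = 0.
Averaging over the medium column of height h puts the 1/h in the sink term:
cells sit on the floor and consume from the column above them, which is the
mechanism behind the chamber-height effect. The reservoir clamps c = c0 at
the opening edge, which is exactly why the opening width w never enters the
equations — the model's (and the device's) width-invariance prediction.
In the Km = 0 regime the steady state is the quadratic

    c(x) = c0 − (ρq/(2Dh))·x(2x* − x),  x* = min(L, √(2Dhc0/(ρq))),

with x* the anoxic front; x* ∝ √h and ∝ ρ^(−1/2) give the height and
density orderings.

Defaults are normalized: c0 = 1, D = 2×10³ µm²/s (oxygen-like), L = 5 mm,
h = 100 µm, ρ = 2×10⁻³ cells/µm² (a subconfluent monolayer), q = 50
(c0-units·µm³/cell/s), placing the front at 2 mm — mid-chamber, convenient
for exercising every regime. Only shapes and parameter orderings are
claimed; absolute calibration is out of scope.

**Numerics.** The grid is uniform (default dx = L/500 = 10 µm). The Km = 0
steady state is a linear complementarity (obstacle) problem — the free
boundary at c = 0 — solved by projected red-black SOR with the classical
near-optimal relaxation factor 2/(1 + sin(π/n)); for Km > 0 the
Michaelis–Menten uptake keeps c positive and a damped lagged-uptake
tridiagonal iteration is used. Transients default to backward Euler with
the sink evaluated explicitly; the per-step non-negativity constraint is
imposed as a small LCP solved by active-set iteration on the tridiagonal
system, because a naive solve-then-clip biases the front position by
O(dt·sink). Backward Euler was chosen over Crank–Nicolson as the default
because it is L-stable and provably monotone for this problem (CN's
undamped modes oscillate at the uptake discontinuity); CN and a
CFL-checked explicit scheme (D·dt/dx² ≤ 0.5) remain available, the latter
serving as an independent cross-check. First-order convergence in dt is
verified mid-transient in the smooth Km > 0 regime; in the Km = 0 regime
front motion is quantized to grid nodes, so refinement studies there
measure spatial, not temporal, error.

**Reporter model.** HIF-driven transcription behaves like a threshold
switch: HIF1α is degraded above an oxygen threshold and stabilized below
it. Activation is a Hill function a = 1/(1 + (c/c*)^n) (hard step at
n = ∞; default c* = 0.1·c0, n = 8 — steep but not degenerate), and the
observable signal is the activation passed through a first-order low-pass
with time constant τ (default 1 h, a fluorophore-maturation/turnover scale),
starting dark. The half-max position of the steady-state reporter profile
is the simulator-side analogue of the imaging pipeline's statistic; a
reporter whose maximum stays below 1% is reported "silent" (the
sub-threshold density regime).

## Synthetic scenes (`memic.synthetic`)

The generator emulates the statistical structure of stitched chamber
images: nuclei as hard disks (pixels whose centers fall within the radius)
with radii ~ N(5, 0.5²) µm, placed uniformly with a minimum center spacing
(default 15 µm ≥ 2.5 radii), a uniform nuclear stain at 2000 a.u. over a
100 a.u. background, reporter channels whose per-cell intensity is an
arbitrary function of the center's distance from the left border (the
opening, by convention), additive Gaussian noise (optional Poisson
resampling), and 16-bit quantization with saturation clipping. The
benchmark noise level, noise_sd = 380 a.u., sets the nuclear-stain SNR
(2000 − 100)/380 = 5. Hard disks (edge_sigma = 0) are the default so that
noiseless per-cell means inside the true masks equal the requested
intensities exactly — the ground-truth closure the measurement tests rely
on; a Gaussian-blurred edge is available for watershed realism. Touching
pairs are produced deliberately by setting the spacing below twice the
radius.

What the generator does **not** emulate: tile-stitching seams and shading,
out-of-focus light, nuclear texture, cell-shape anisotropy, density
gradients of the cells themselves, or segmentation-relevant debris. Passing
the recovery benchmarks therefore demonstrates correctness of the
algorithms under the stated noise model, not performance on arbitrary real
microscopy.

## Benchmark problem sizes

The end-to-end benchmark uses one 5 × 2 mm scene at 1 µm/px (10⁷ pixels,
5000 cells, SNR 5, logistic reporter with midpoint 2000 µm) and recovers
the midpoint within ±50 µm; segmentation recovery uses ten 1 × 1 mm seeded
scenes of 120 cells; statistical calibration uses 1000 simulated replicates
per test at α = 0.05; simulator checks run at dx = L/500. These sizes keep
every regime represented (plateaus on both sides of the midpoint, crowded
and sparse windows, exact and asymptotic test branches) at interactive
runtimes.

## Known limitations

- The detection/segmentation operators are a defensible standard pipeline
  (Otsu + distance-transform watershed + Voronoi expansion), not a
  re-implementation of any particular lab's scripts; no equivalence to
  other software is claimed.
- The simulator is single-metabolite, 1D, with no secretion terms, no
  byproduct accumulation, and no cell growth/death feedback — it cannot
  reproduce the necrotic signal collapse seen at extreme densities.
- Statistical tests ignore spatial autocorrelation (above).
- The moving-profile grid is 0-anchored, so exact shift-equivariance holds
  for translations by multiples of the step.
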