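# Methods

This note records the models behind `optofurrow`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic
validation does and does not establish about real data.

## Coordinate and unit conventions

Images are `(t, z, c, y, x)`; x is the embryo anterior–posterior (a-p)
axis, y the dorsal–ventral (d-v) axis.  Pixel coordinates are 0-based;
rectangles are half-open `[x0, x1) × [y0, y1)`.  Parameters carry
explicit unit suffixes (`_um`, `_px`, `_s`, `_min`); conversion between
μm and px happens once, where a parameter object meets an image with a
known pixel size.

## Synthetic tissue model

The generator emulates the apical surface of a blastoderm-stage
epithelium as the Euclidean Voronoi tessellation of a jittered
hexagonal lattice.  Defaults: 0.2 μm/px, 30 s frame interval, 10 × 8
cells at 30 px (6 μm) pitch on a 300 × 208 px field — the row pitch is
deliberately `≈ √3/2` of the column pitch so that the unjittered cells
are regular hexagons with moment-ratio anisotropy 1.  Jitter is ±8% of
the pitch.

### Constriction and stretching kinematics

A central rectangle of the field (70% of x, 50% of y) is the
contractile domain, standing in for the rectangular ventral-furrow
primordium.  Its dynamics are kinematic, not mechanical: no force or
vertex model is implied.  The tissue plane is deformed by an
invertible, border-pinned warp with triangular structure (a y-family
map followed by an x-family map, each monotone piecewise linear), built
so that the non-activated contractile core is locally an affine map
with scale factors

    s_x = sqrt((1 − f(t)) · a(t)),   s_y = sqrt((1 − f(t)) / a(t)),

where `f(t) = shrink_fraction · (1 − exp(−t/τ))` is the programmed area
loss and `a(t) = 1 + anisotropy_gain · (1 − exp(−t/τ))` the programmed
moment-ratio multiplier (defaults: shrink 0.5, gain 0.8, τ = 300 s —
area halves and anisotropy reaches ~1.8 over a furrow-formation
timescale of ~10–15 min).  Anisotropy growth is part of the
constriction program; `shrink_fraction = 0` freezes the geometry.

Cells whose t = 0 seed lies inside a photo-activation rectangle (after
the first pulse) are exempt from the y-compression, and the x-map gives
their columns the slope that keeps the core length constant — they are
stretched along a-p exactly by the area their constricting neighbours
give up, which is the observed phenomenology.  Seeds move with the
forward warp; the label image at time t is the t = 0 nearest-seed
assignment evaluated through the exact inverse warp.  This preserves
label identity, conserves total tissue area exactly, and makes the
programmed area and anisotropy hold exactly (up to rasterization) for
cells fully inside the core.  A plain Euclidean re-tessellation of the
displaced seeds was rejected: the Voronoi cell of a staggered lattice
saturates at moment ratio ≈ 1.1 under uniaxial lattice compression
(the staggered neighbours take over as nearest), so realistic
anisotropies (~1.7) cannot be programmed that way.

Remaining bias: pixel quantization inflates each cell dimension by
about half a pixel per side, so measured shrink is ~2–3% below and the
measured anisotropy endpoint ~4–6% below the programmed values at the
default 15–30 px cell extents.  Both sit inside the recovery
tolerances (5% and 10%).

### Photo-activation and reporter kinetics

The default protocol is a pulsed two-photon train: 2.5 s scan every
30 s over 5 z planes 1 μm apart at 950 nm and 3.0 mW.  Recruitment is
driven by *cumulative illumination time* `t_exp` (sum of completed and
partial pulses), not wall-clock time:

    R(t_exp) = R_∞ · (1 − 2^(−t_exp / t_½)),

with defaults `R_∞ = 3` (log2 pm/cyt units) and `t_½ = 9 s`, the
half-time of this pulsed two-photon regime; single-photon 488-nm
recruitment is about an order of magnitude faster (`t_½ ≈ 1 s`) and can
be set explicitly.  The plateau scales with laser power through a
saturating Michaelis-type factor `(P/(P+K)) / (3/(3+K))`, `K = 0.8 mW`,
normalized to 1 at the reference 3.0 mW — the mapping is a modeling
choice; only its monotonicity is relied on.  After an `end_s` is
reached, the log2 ratio decays with the dark-reversion half-time
(default 8.9 min, wall-clock).  Reversion during the 30-s gaps of an
ongoing pulse train is neglected (gaps are ≪ the reversion half-time).

### Rendering

Channel 1 paints the membrane band — pixels within Chebyshev distance
`membrane_halfwidth_px` (default 2) of a different label — at a fixed
amplitude (default 200) on black.  Channel 2 is the reporter: uniform
cytosol (default 100), the membrane band scaled per cell by its linear
pm/cyt ratio `2^R`, and a centered nuclear disk at 40% of the cell
equivalent radius dimmed to 0.5× (nuclei are simply darker than
cytoplasm; no chromatin texture).  Both channels are convolved with a
Gaussian PSF (default σ = 0.08 μm = 0.4 px — kept below the half-pixel
scale so that the ring and cytosol compartments remain resolvable at
the default sampling; real confocal PSFs are wider, which is one of the
gaps between this generator and real data) and then corrupted by
additive Gaussian noise (default sd 10 = 5% of the membrane amplitude)
and optional Poisson shot noise.  z planes are intensity-scaled
replicas (falloff 0.9/plane) with independent noise; there is no 3D
cell shape and no photobleaching.

## Segmentation

`segment_frame` runs, per z plane: Gaussian smoothing of the membrane
channel (σ in μm, default 1.0, interpreted as the Gaussian σ rather
than FWHM); adaptive thresholding — foreground are pixels *darker*
than their local mean minus an offset (window default 8 μm, offset 5
intensity units), because the cytoplasmic interiors are dark between
bright membranes; 4-connected component labeling with an inclusive
area threshold (≥ 10 μm² kept); and seeded propagation in which every
pixel is assigned the seed with minimal geodesic cost, step cost
`sqrt(ΔI² + λ)` between 4-neighbours on the smoothed image (λ default
1.0 in squared intensity units).  Equal costs resolve to the smaller
label id, and labels are renumbered 1..n in raster order of first
pixel, so results are bit-reproducible.  λ interpolates between a
spatial Voronoi (λ large) and pure ridge-following (λ = 0); it is a
config knob because the appropriate balance depends on membrane
contrast.

Border handling: propagation runs with *all* cytoplasm seeds so that
every internal boundary is contested from both sides; with
`border_policy="exclude"` (default) the labels whose final region
touches the field edge are then removed.  Excluding border seeds
before propagation would let interior labels flood the unclaimed
border territory and corrupt the very boundaries one wants to measure.

There is no cell tracking and no 3D stitching: features are computed
per z plane independently, and label ids are not stable across time.

## Quantification

* `cell_area`: pixel count × pixel area.
* `ap_anisotropy`: `sqrt(μ_xx/μ_yy)` of the pixel set's second central
  moments along the *fixed* image axes — not principal axes — because
  the quantity of interest is elongation relative to the embryo's a-p
  axis.  Cells with < 4 px or zero extent are flagged degenerate and
  dropped (with a logged count).  The reciprocal d-v convention is
  selectable (`anisotropy_axis="dv"`).
* `derive_region_masks`: the membrane ring is the cell's pixels within
  Chebyshev distance `membrane_halfwidth_px` (default 1) of a
  different-label or background pixel; the image border itself does
  not count as membrane.  The cytosol is the interior minus a guard
  margin (`cytosol_guard_px`, default 2, beyond the ring) minus
  nucleus pixels, defined as interior pixels darker than 0.75× the
  median interior reporter intensity.  The guard keeps PSF bleed from
  the bright ring out of the cytosol estimate; without it the pm/cyt
  ratio of strongly recruited cells is biased low by the first
  cytosol pixel layer.
* `activation_level`: `log2(mean(ring) / mean(cytosol))`, invariant
  under global gain; `depletion_ratio`: `log2(mean_t / mean_t0)` in a
  fixed mask, negative = depletion.
* `build_feature_table`: one row per (embryo, t, z, non-degenerate
  cell); a cell is inside the activation region iff its centroid is
  (partial overlaps are not subdivided).  Embryo-level summaries use a
  single configurable z plane (default index 0, the apical-most).

On ground-truth masks with noise off and PSF ≤ 0.5 px the pm/cyt
round-trip is accurate to < 1% across ratios 0.5–8.  On
*segmentation-derived* masks the ring straddles the true membrane
imperfectly and the measured plateau is attenuated (e.g. log2 ≈ 1.7
measured vs 3.0 programmed in the README example) while the fitted
half-time stays accurate — the same reason the original assay used
manually drawn membrane masks.  Activation levels from automated masks
should therefore be read as relative, not absolute.

## Kinetics fits and statistics

Half-times are fitted directly (`R_∞(1 − 2^(−t/t_½))` for recruitment,
`R_0 · 2^(−t/t_½)` for reversion) with `scipy.optimize.curve_fit`,
multi-started over a fixed geometric grid of 7 half-time guesses
spanning the data range (keeps the fit off local minima; RSS tie
tolerance 1e−8; `t_½ > 0` enforced by bounds).  Constant input is
flagged degenerate rather than fitted.  A converged fit additionally
carries `good_fit = (R² ≥ 0.8)` so a structurally wrong model (e.g. a
decay fitted to rising data) is flagged, never silently returned.
Half-time identifiability is sampling-limited: the Monte-Carlo recovery
study uses 30 points over 8 half-times (plateau well established), at
which design the median error at 5% noise is ~4%, close to the noise
floor; truncating at 2–3 half-times doubles it.

Statistics follow the experiment's conventions: the natural unit is
the embryo (one summary value per embryo); medians with Q3 − Q1 IQR
(linear-interpolation quantiles); two-sided two-sample t tests, either
pooled-variance Student's (df = n₁+n₂−2) or Welch's
(Welch–Satterthwaite df); areas are compared on log-transformed values
(any log base gives the identical t statistic; natural log is used);
Bonferroni adjustment is `min(1, m·p)`.  Two zero-variance equal
groups return t = 0, p = 1, flagged degenerate.  The built-in pipeline
`compare` stage, which sees a single synthetic embryo, groups *cells*
(activated vs non-activated) as a demonstration; for real multi-embryo
analyses, feed embryo-level summaries to `compare_groups` directly.

## Pipeline and reproducibility

`run_pipeline` executes simulate → segment → quantify → kinetics →
compare, writes TIFFs (TZCYX with a JSON description carrying axes and
calibration; 16-bit label masks), a feature CSV with a fixed column
order, fit/statistics JSON and CSV, a stage-level log including
dropped-cell counts, and `manifest.json` with the config hash, the
seed, package versions, and a SHA-256 per output file.  All randomness
derives from the single config seed, and reading a stack without pixel
size or frame interval (from metadata or an explicit override) is a
hard error.  Re-running an identical config yields byte-identical
feature tables.

Problem sizes in the shipped tests and in `scripts/acceptance.py` —
10 × 8-cell fields, movies of 4–12 frames, 200 Monte-Carlo fit
replicates, 2000 null t-test replicates — were chosen so the whole
validation runs in about two minutes on one CPU while keeping every
estimate's sampling error well inside the tolerance it is checked
against.

## What the synthetic validation does not show

The generator omits: realistic PSF widths and depth-dependent
aberrations, photobleaching, membrane-intensity heterogeneity and
gaps, cell intercalation/T1 transitions, true 3D cell shapes, myosin
or actin signal, and sub-cellular activation gradients (half-activated
cells).  Passing the recovery tests therefore demonstrates the
*correctness of the measurement chain* under the stated image model,
not segmentation robustness on arbitrary real movies; on real data the
segmentation parameters (smoothing, window, offset, λ) need tuning to
the actual contrast, and absolute activation levels need manual
membrane masks or a ring-placement check.
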