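# Methods

## The measurement

A scratch assay quantifies re-epithelialization: a uniform cell-free band
is cut into a confluent monolayer, nuclei are stained, and the same field
is imaged at fixed intervals (the canonical schedule here is 16 frames, 20
minutes apart, 0–300 min).  Rather than measuring wound area or monolayer
edge advance, the toolkit counts *cells* inside the band over time: the
count series is sigmoidal — lag, near-linear infiltration, plateau — and is
summarized by three interpretable parameters of the modified Gompertz
growth model (Zwietering parameterization):

    N(t) = A · exp(−exp( (μₘ·e/A) · (λ − t) + 1 ))

* **A** (cells) — plateau count inside the band; a proxy for final
  wound-closure status.
* **μₘ** (cells·min⁻¹) — maximum infiltration rate, the slope at the
  inflection point t\* = λ + A/(μₘ·e), where N(t\*) = A/e.
* **λ** (min) — lag time, the time-axis intercept of the inflection
  tangent; N(λ) = A·e^(−e) ≈ 0.066·A.  λ may legitimately be ≈ 0 or
  negative when migration starts before imaging; it is still required for
  an accurate fit.

Identities used as self-checks: N(λ) = A·e^(−e), N(t\*) = A/e,
N′(t\*) = μₘ, strict monotonicity, N → A as t → ∞.

## Segmentation

Per frame, independently (no tracking — counting does not require cell
identities):

1. **Illumination function**: the frame is tiled into `block_size`²
   blocks (partial blocks at the bottom/right edges are allowed); each
   block's minimum intensity estimates the local background, the block grid
   is upsampled by nearest neighbor and smoothed with a Gaussian.  The
   smoothing width is not independently specified anywhere, so σ =
   `block_size` by default (configurable): the illumination field should
   vary on the block scale, not faster.
2. **Subtraction**, clamped at zero.
3. **Otsu threshold** over a 256-bin histogram of the observed range
   (scikit-image); pixels above the threshold are foreground.  The
   between-class-variance maximizer can be a plateau when the histogram has
   empty bins between modes; any split on the plateau is an Otsu threshold,
   so tests compare attained variance, not split position.
4. **Watershed declumping** on the inverted smoothed image (σ =
   `min_diameter`/2), seeded at local maxima at least `min_diameter` apart —
   nuclei are brighter toward the interior, so intensity peaks are one-per-
   nucleus.  A foreground component that received no seed keeps its
   brightest pixel as seed so no object is silently dropped.
5. **Diameter band-pass**: components with equivalent diameter
   2·√(area/π) outside [`min_diameter`, `max_diameter`] (inclusive bounds)
   are removed; labels are renumbered consecutively.  Border-touching
   objects are retained — for counting, completeness beats shape fidelity
   of clipped objects (a deliberate divergence from segmentation tools that
   drop border objects by default).

Connectivity is 4-connected; coordinates are 0-based with row 0 at the
image top.  Features per nucleus: unweighted centroid, pixel area,
moments-based eccentricity, mean corrected intensity.

## Scratch-band detection

The band is estimated once, from the first frame, and held fixed: the
assay starts with a freshly cut, essentially empty band, and the fixed
region is what makes per-frame counts comparable.

Centroid rows are binned into `bin_height`-pixel bins (default: the well's
`min_diameter`, roughly one cell per bin scale).  The main gap is the
longest run of zero bins; among equal-length runs the one nearest the
vertical image center wins (scratches are cut mid-well), and an exact
distance tie goes to the topmost run.  Because single cells or debris may
sit inside the fresh scratch, neighboring zero runs separated from the
band by at most `merge_span_bins` bins, each holding at most
`straggler_max` cells, are absorbed; merging iterates outward above and
below until stable (a deliberate fixed point rather than a single pass).

Defaults `merge_span_bins = 6`, `straggler_max = 4` are set by the
two-regime structure of the histogram: bins inside a fresh scratch hold
0–2 stray cells, while an occupied monolayer bin holds tens (every
grid-row of a confluent monolayer crosses the full image width), so a
straggler cutoff of 4 cells separates the regimes with an order of
magnitude of headroom, and a span of 6 bins (≈ 1.5–2 nucleus diameters at
the default bin height) bridges small clumps of strays.  On simulated
plates (240 wells across 40 seeds) these defaults recovered the planted
band in every well with at most 4 px over-extension, whereas stricter
values (span 2, straggler 2) truncated the band in ~11 % of wells whenever
a clump of 3+ strays blocked the merge.  Both knobs are exposed on the
CLI (`--merge-span`, `--straggler-max`).

Counting is by centroid: a nucleus is inside iff y_low ≤ row < y_high
(half-open, so a centroid exactly on y_low is inside and on y_high is
outside).  If the detected band is narrower than 2·`max_diameter` the well
is flagged with a warning (likely detection failure), not an error.

Rotation: multiples of 90° are lossless pixel permutations; other angles
use bilinear interpolation with zero fill and an enlarged canvas.  A
plate stored with vertical scratches and `rotation_deg = 90` yields counts
identical to the horizontal original.

## Fitting

Ordinary (unweighted) least squares — counts are treated as plain
observations.  The optimizer is a Levenberg–Marquardt iteration with
Marquardt diagonal scaling: damping starts at 10⁻³, ÷10 on an accepted
step, ×10 on a rejected one; convergence when the relative RSS decrease of
an accepted step falls below 10⁻⁸, capped at 1000 iterations.
Non-convergence produces a flagged result, never an exception.  A and μₘ
are kept positive by optimizing (log A, log μₘ, λ); λ is unbounded.
Jacobians are forward differences (the model is cheap and smooth; three
parameters).

Starting values: A₀ = max count, μₘ₀ = steepest secant slope (floored at
10⁻⁶ for flat series), λ₀ = tangent intercept at the steepest point.  When
a series is sampled only during the lag phase (plateau far beyond the last
frame), max count badly underestimates A, so the fit is restarted from
A₀ × {1, 3, 10, 30} and the lowest-RSS solution kept; the plain tangent
guess is always among the starts, so the returned RSS never exceeds the
initial guess's (descent property).  In tests this multi-start recovers
noiseless parameters to ~10⁻¹⁰ relative error even for curves observed
only in their lag phase, and lands on the same minimum as an independent
optimizer (scipy's MINPACK LM) to 10 significant digits.

Goodness of fit: R² = 1 − SS_res/SS_tot (SS_tot about the observed mean)
and RMSE = √(SS_res/n).  A fit is flagged iff R² < 0.9 (strict: R² = 0.9
exactly is not flagged) or the optimizer did not converge; the threshold
is configurable (`--r2-flag-threshold`).  The flag is the adverse-effect
detector: a cytotoxic exposure produces rise-then-decline counts that the
monotone model cannot track, driving R² far below 0.9.

Degenerate inputs: fewer than 4 timepoints is a validation error (3
parameters); an all-zero or zero-variance series returns a non-converged,
flagged fit with NaN R².

Z′ factor: Z′ = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| over per-well parameter values
(e.g. μₘ or A) of positive and negative control wells, with sample
standard deviations (ddof = 1).  Z′ = 1 for zero-variance controls,
negative when the control distributions overlap.

## Synthetic plates

The generator emulates the target acquisition: 600×800 px fields, a
horizontal cell-free band at rows [220, 420) (the proportions of a 0.3 mm
scratch imaged at 4×), 16 frames 20 min apart.  The monolayer outside the
band is a jittered grid at 0.003 nuclei/px² (spacing 1.5× the 12 px
nucleus diameter, jitter bounded so centers never come closer than one
diameter) and is held fixed across frames.  Inside the band, frame k shows
the first round(N(t_k)) positions of a per-well master sequence of
non-overlapping uniform positions — infiltrated cells persist, matching
the monotone count model.  Nuclei are isotropic Gaussian spots (σ =
diameter/4, peak 3000) over a background of offset 300, a vertical ramp of
200 (to exercise illumination correction) and Gaussian pixel noise σ = 20,
written as 16-bit TIFFs with a parseable index and ground-truth tables.
Per-well truths for the default 6-well plate span A ∈ [300, 600] cells,
μₘ ∈ [2, 8] cells/min (bracketing fast gingival-cell repair rates) and
λ ∈ [10, 60] min.  Everything is deterministic per seed, byte-for-byte.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: cell motility and division outside the
band (the monolayer neither churns nor advances as a front), anisotropic
or overlapping nuclei, intensity variation between cells, photobleaching,
focus drift, debris, and non-Gaussian camera noise.  Results on real
plates depend on segmentation parameters being set sensibly per cell type.

## Known limitations and scope

* The band is one horizontal stripe; multiple or diagonal scratches are
  out of scope (rotation handles any single straight scratch).
* Area-based wound measures and collective-velocity estimates are
  deliberately not provided; the cell-count abstraction is the point.
* λ's estimation variance is intrinsically high relative to its magnitude
  when the lag is short compared to the frame interval: at the canonical
  design (truth λ = 30 min, noise 2 % of A) the linearized sd of λ̂ is
  ≈ 3.8 min, i.e. a median absolute relative error around 8 % for any
  unweighted least-squares estimator; A and μₘ come in near 2.5 %.
* Counts are fitted unweighted; Poisson weighting would change the
  estimator and is intentionally not used.
* Replicates are fitted per series; aggregation across replicates is
  reporting only, never pooled into one fit.
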