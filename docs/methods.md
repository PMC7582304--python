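# Methods

This note documents the models, algorithms and numerical choices behind
`cryoleaf`, the defaults that matter, and what the synthetic-data
validation does and does not demonstrate.

## Differential thermal analysis of leaf temperature

**Signal.** Ice nucleation in supercooled tissue releases latent heat;
on a high-frequency leaf thermocouple (nominal 0.5 s⁻¹, i.e. one sample
per 2 s) this appears as a rise of order 1 °C within seconds, followed
by a plateau just below 0 °C and a slow relaxation back to the ambient
cooling trend.

**Detector.** The lagged difference ΔT(t) = T(t) − T(t − lag) is
computed per leaf channel on a regular grid (lag 10 s by default,
rounded to the nearest whole number of samples; a lag shorter than the
sampling interval is an error).  A sample is flagged when

1. ΔT(t) ≥ `threshold_c` (default **0.5 °C** — far above sensor noise
   of ~0.05 °C, well below the ~1 °C latent-heat rise; exposed as a
   parameter since the appropriate cut-off depends on sensor noise),
2. the pre-rise temperature T(t − lag) is below 0 °C
   (`require_subzero`, default on: exotherms cannot occur above the
   melting point, and the guard suppresses sunrise warm-up false
   positives),
3. no air channel rises by ≥ threshold within ± lag of t (ambient
   artifacts warm leaf and air alike; the veto is applied only when an
   air channel exists).

Flags separated by less than `refractory_min` (default **30 min**)
merge into one event anchored at the first flagged sample — each leaf
freezes at most once per night, so plateau wobble must not be double
counted.  The nucleation temperature is T(t₀ − lag) at the anchor t₀.
ΔT is undefined (missing) across logger gaps; no event can span a gap.

Note one consequence of merging: the number of *merged events* is not
globally monotone in the threshold (a lower threshold can bridge two
flag runs into one event).  The flagged-sample criterion itself is
monotone, and so are event counts whenever events are separated by more
than the refractory window.

**Durations.** The supercooled period runs from the last downward
crossing of 0 °C before nucleation to the nucleation instant; the
frozen period from nucleation to the first subsequent upward crossing
of `thaw_threshold_c` (default 0 °C, morning warm-up).  A bound outside
the record leaves the duration missing rather than guessed.

**Regularization.** Campaign logs are put on a regular grid by
nearest-sample assignment within half a grid step — never by
interpolation or averaging, which would smear the very spikes the
detector looks for.  Grid points further than half a step from any
sample stay missing, so logger gaps survive regularization.

## Frost microclimate statistics

A *night* is the clock window 18:00 → 09:00 (configurable; it
generously brackets the span over which field freezing events were
observed).  A *frost night* for a leaf channel is a night whose
windowed minimum is strictly below 0 °C.  The frost-night rate is
aggregated as mean ± SD of the per-channel fractions — aggregating
across sensors is what gives the rate a spread.  Leaf−air depressions
are pointwise differences at matched timestamps, minimized per night;
they require synchronous sampling, which regularization provides.
Snow cover is classified per calendar day and channel by a damped
amplitude (max − min strictly below 1 °C) with a daily mean within
±1 °C of the melting point, since an insulating snowpack clamps the
sensor near 0 °C.

## Boltzmann viability curves and resampled LT50

Viability is read out as Fv/Fm (maximum quantum yield of photosystem
II), bounded by the physical range [0, 0.9].  The temperature response
is the Boltzmann sigmoid

    Fv/Fm(T) = (vmin − vmax) / (1 + exp((T − LT50)/dx)) + vmax

with lower/upper asymptotes vmin < vmax (Fv/Fm units), inflection LT50
(°C) and slope factor dx > 0 (°C).  The curve is non-decreasing in T
and evaluates to the midpoint at T = LT50.

Fits use nonlinear least squares (`scipy.optimize.curve_fit`) with dx
bounded positive and data-driven initialization: vmax from the warmest
temperature's mean yield, vmin from the coldest, LT50 from the
temperature whose mean yield is nearest the midpoint, dx from half the
median temperature step.  Degenerate data (no transition) and optimizer
failures return a `converged=False` flag instead of raising, so
resampling replicates can drop them; the number of converged fits is
always reported, making silent degradation visible.

The LT50 estimator draws 4 yield values per treatment temperature
*without replacement* (subsampling is the natural reading of "randomly
selecting" from 10 leaves; with-replacement is available as an option),
fits, and repeats 250 times; the estimate is the mean ± SD of the
converged replicate LT50 values.  Rows are canonically sorted by
(temperature, leaf id) before drawing, so a fixed seed gives the same
estimate regardless of input row order.

Gas-exchange records are normalized by dividing net assimilation A and
dark respiration R_d by the diffusive conductance to water vapour GH2O
(removing stomatal-aperture differences) and then referencing each
leaf's value to its own pre-treatment baseline, which is therefore 1 by
construction.

## Infrared differential thermal analysis

The difference stack D_t = F_t − F_{t−lag} (lag 1 frame by default; at
15 fps frames are the natural unit, with timestamps carried along for
reporting) isolates frame-to-frame warming.  Per leaf region — region
masks are inputs, not derived from the imagery — a frame is flagged
when more than `min_fraction` (default 5%) of its pixels brightened by
at least the threshold; a fractional-area trigger is robust to hot
pixels where a single-pixel trigger is not.  Flag runs within a
refractory window (default 15 frames ≈ 1 s) merge into one event
anchored at the first flagged frame, so the brindled onset and the
homogeneous fill-in count once.  The coverage curve reports, per frame,
the fraction of region pixels that have *ever* brightened past the
threshold since the event — non-decreasing by construction and a direct
readout of ice-front spread.

## Cytorrhysis morphometry

Cell outlines are simple polygons in µm traced at the middle focal
plane; the analysis is deliberately 2-D (spongy cells are too
irregular for a credible 3-D reconstruction from single sections).
Areas come from shapely with validity checking; the CA share is the
frozen area over the same cell's +20 °C baseline area.  Tissue
summaries use shares measured strictly below a cutoff (default −3 °C,
below which shrinkage has saturated).  The palisade diameter/length
split uses extents along the principal axes of the vertex set rather
than axis-aligned boxes, so outline rotation does not bias it.  The
tissue comparison is a two-sided Wilcoxon rank-sum test: exact null
distribution for combined n ≤ 30 without ties, exact permutation for
small tied samples (combined n ≤ 12), normal approximation with tie
correction otherwise — the study's sample sizes (25 vs 15) sit near the
approximation boundary, so the exact branch matters.

The cylinder model converts a diameter share d and length share l into
a volume reduction 100·(1 − d²·l); with l = 1 (diameter-only
shrinkage, as observed in palisade cells) a diameter share of 0.43
gives an 82% volume loss.  The water→ice expansion figure follows from
mass conservation with standard densities at 0 °C (999.84 and
916.7 kg m⁻³): 100·(ρ_w/ρ_i − 1) ≈ 9%.

## Synthetic data: what it emulates, and what it does not

The campaign generator is phenomenological.  Its defaults *are* the
study conditions: 4 plants × 3 leaf thermocouples, 2 s sampling,
nucleation temperatures from N(−2.6, 0.9²) truncated below 0 °C, a 62%
frost-night probability per leaf and night, a deepest leaf-below-air
depression of 9.3 °C, and 0.05 °C sensor noise.

Specific construction choices:

* The air follows a fixed diel sinusoid (trough 1 °C at 02:00, peak
  7 °C at 14:00), so air frosts are rare while leaf frosts are common,
  as observed.
* Per (leaf, night), frost status is an independent Bernoulli draw.
  Frost-night depression peaks are drawn U(6.5, 9.3) °C with per-leaf
  random peak times (00:30–03:30), giving leaf-trend minima of −5 °C or
  below: the nucleation draw is then almost surely reached, so the
  recovered nucleation-temperature mean is essentially unbiased
  (residual selection bias ≈ +0.01 °C).  The single deepest depression
  of a campaign is pinned to the configured maximum so the
  campaign-minimum contract is exact rather than asymptotic.
  Clear non-frost nights use shallow depressions U(0.1, 0.6) °C, which
  keep minima safely above 0 °C at any plausible noise extreme.
* The exotherm is a linear rise over 10 s from the nucleation
  temperature θ to a plateau max(θ + 1, −0.3) °C, then an exponential
  relaxation (time constant U(200, 600) s — leaf thermal time constants
  are free parameters of the generator) back to the cooling trend.  For
  the ~1% of draws warmer than −1.3 °C the plateau can slightly exceed
  0 °C; this keeps the injected rise ≥ 1 °C and hence detectable, at
  the cost of a marginally unphysical plateau for those rare events.
* Thaw is defined as the first upward crossing of 0 °C of the morning
  trend — the frozen-duration statistic needs an endpoint, and morning
  melt is the natural one.
* Snow nights clamp leaves and soil to ~0.15 °C from dusk to morning
  (amplitude ≪ 0.5 °C); consecutive snow nights keep the pack through
  the intervening day.
* The soil channel is a damped, lagged diel signal floored near 0 °C,
  emulating the buried shoot's thermal refuge.

The assay generator places Fv/Fm on a Boltzmann curve plus Gaussian
noise, clipped to [0, 0.9].  The outline generator shrinks palisade
rectangles in width only (so the area share equals the width share and
length is preserved) and spongy 8–14-gons isotropically, with shares
drawn from a truncated normal in (0, 1].  The IR generator cools each
region linearly to the equivalent of −14 units and injects exactly one
event per region: half the pixels jump at the nucleation frame, the
rest within the next 5 frames, with a 10-frame decay.

What passing recovery tests shows: the estimators are unbiased and
complete *under the generative assumptions* — Gaussian sensor noise,
clean single-rise exotherms, one event per leaf, well-separated IR
events, polygonal outlines without tracing error.  What it does not
show: robustness to real-world artifacts such as sensor detachment,
wind-driven temperature spikes correlated across channels, drifting IR
backgrounds, emissivity variation, or hand-tracing bias.  Those failure
modes require real campaign data and are out of scope here.

## Determinism and problem sizes

All stochastic procedures take explicit integer seeds and use
`numpy.random.default_rng`; identical seed and configuration give
bit-identical output.  The validation suite and the acceptance script
use a 20-night, 12-leaf campaign at 2 s sampling (≈ 0.9 M samples × 15
channels), 100 random detector fixtures of ≤ 2000 samples for the
brute-force equivalence check, 6 × 10 assays with 250 resampling
replicates, 25-cell outline sets, and 5-region, 150-frame IR stacks —
sizes chosen to make sampling error small relative to the tolerances
being checked while keeping a full run in the order of seconds.

## Known limitations

* The exotherm detector assumes regularized, roughly synchronous
  channels; it does not model sensor-specific lag or calibration.
* The air-coincidence veto is a formalization of "not detectable in the
  air temperature"; with very noisy air sensors it could veto true
  events (none observed at the default noise level).
* LT50 confidence comes from resampling spread only; it does not
  propagate fit-parameter covariance.
* The cylinder volume model is exact only for right cylinders with
  uniform shrinkage; spongy cells violate it and are reported as area
  shares only.
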