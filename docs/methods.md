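# Methods

This note records the models, estimators and numerical choices behind
`wingbeam`, and what the synthetic benchmarks do and do not demonstrate.

## Signal model

A transit of duration D centred at t_c is synthesised as

    V(t) = V0 − D_b · g(t) − D_w · g(t) · p(t)

where g is a unit-peak Gaussian bump with σ = D/6, truncated at ±3σ so
the transit has compact support; D_b and D_w are the peak body and wing
extinction depths in volts; and p is a non-negative pulse train at the
wingbeat frequency f_w built from n harmonics with 1/k amplitude decay,
normalised to [0, 1] so it touches zero exactly once per period. The
zero-touching instants are the between-beat moments at which the wings
present minimal extinction — the structural property the separation
stage relies on. Field descriptions of transit signals constrain only
the qualitative shape ("somewhat Gaussian" dip, harmonic-rich wing
oscillation); the specific envelope and waveform here are this package's
choices. Noise is additive white Gaussian at the sample level; the
instrument noise statistics are not published, and 5 mV on a 3 V
background (SNR ≈ 60 against a typical 0.3 V body dip) is used as the
bench condition for all recovery benchmarks. Rain droplets are wingless
dips of 2–8 ms; "light" rain schedules 3 droplets/s, "heavy" 400/s so
the dips overlap into a continuous perturbation.

Defaults follow the instrument class being modelled: 30,517 Hz sampling,
3 V background, 50.8 mm beam diameter, 36 m emitter–receiver path
(probe volume 7.30 × 10⁻² m³).

## Wing/body level convention

Published notation for the two transit levels is ambiguous: "the
voltage measured during the transit is noted Vw and VB for the wings
and body" could read as levels of the full signal or of the separated
contributions. The full-signal reading is arithmetically incompatible
with reported mosquito ratios: if Vw is the deepest level of the
complete signal then sigma_w ≥ sigma_B always and
sigma_w/(sigma_w+sigma_B) ≥ 0.5, whereas mosquito field values are
0.19 (male) and 0.27 (female). This package therefore reads both levels
off the separated contributions, consistent with figures that derive
each cross-section from the drop of its own component: VB is the mean
of the 10% lowest values of the body-envelope signal, and Vw the mean of
the 10% lowest values of the wing-contribution signal (V0 minus the
wing component). A wingless event then has Vw = V0, sigma_w = 0 and
ratio 0.

## Detection

* Baseline: decimated rolling median — block medians over quarters of
  the longest expected transit (default 0.25 s blocks), rolling median
  across ten times the longest transit, linear interpolation back to
  sample resolution. Transits occupy at most a few blocks of the
  window, so the estimate ignores them while tracking slow drift.
* Noise scale: 1.4826 · median|ΔV| / √2 — robust to transits and drift.
* Threshold: V0 − k·SD with k = 6 by default. The threshold rule is
  this package's self-contained choice; the field instrument's exact
  rule is unpublished.
* Runs below threshold are bridged across sub-threshold gaps shorter
  than 2 ms (wing oscillations can touch baseline mid-transit), then
  each bound walks outward to where the lightly smoothed signal
  re-enters the noise band (0.3 SD, Gaussian smoothing of 0.5 ms).
  Without this extension the thresholded run systematically clips the
  soft Gaussian tails and the occupancy integral — hence the density —
  is biased low by ~20%; with it the bias is below 1%. Extension can be
  disabled (`extend_tails=False`), which makes the detected run set
  exactly equal to a brute-force sub-threshold scan.
* Events shorter than 10 ms are discarded; events longer than 1 s are
  kept but labelled non-insect rather than truncated. Overlapping
  simultaneous transits merge into one run and are single-counted.

## Insect discrimination

The window's upper envelope (PCHIP through local voltage maxima, which
under noise hug the signal) is subtracted and the residual's spectrum
searched for a peak in the 10–900 Hz band. The peak is compared with
the expected noise-only bin magnitude computed from the robust sample
noise and the Hann window energy — not with the in-band median, which a
strong harmonic comb inflates. Calibration on the generator: the
envelope residual of a smooth dip under noise scores up to ~12× the
noise bin (the envelope ride-up makes the residual super-Rayleigh),
pure noise up to ~10×, while genuine wing oscillations score ≥ ~25×
down to the optical detection limit; the default acceptance ratio is
15. Windows with fewer than three envelope anchors (no resolvable
oscillation, e.g. a noise-free smooth dip) are non-insect outright.

Known limitation: two rain droplets arriving within a couple of
milliseconds can merge into one ≥ 10 ms double-dip whose two humps
mimic a 2–3-cycle oscillation in the hundreds of Hz; such coincidences
occasionally pass discrimination. They are rare at realistic droplet
rates and their contribution to density is bounded by the rain
occupancy.

## Wingbeat frequency

Estimated from the raw Hann-tapered window (8× zero-padding), not from
the envelope residual: anchor jitter in the envelope creates sideband
artefacts that corrupt peak picking, whereas on the raw spectrum the
wingbeat appears as a clean comb and the smooth body dip occupies only
the lowest frequencies. The search therefore starts above 2.5 spectral
widths of the body bump (≈ 2.4/D Hz — consistent with needing roughly
three wing cycles to resolve a wingbeat at all). Candidate peaks must
exceed 6× the noise-only bin magnitude; the fundamental is the lowest
candidate with ≥ 25% of the strongest peak's magnitude that either has
harmonic support near 2f or is itself dominant (≥ 50% of the strongest)
with no sub-harmonic near f/2. Sub-bin resolution comes from parabolic
interpolation of the log-magnitude triple. On 100 ms transits at the
bench SNR the median error is ~0.05 Hz and harmonic confusion occurs in
≲ 0.3% of events, essentially only when the wing depth is within a few
noise SDs of invisibility.

## Separation and levels

With f_w known, the between-beat maxima are located on a lightly
smoothed signal (Gaussian kernel of 1/32 wingbeat period — enough to
stop anchors riding on local noise maxima, too short to touch the
harmonics) and the envelope is the PCHIP interpolant through them; the
wing component is envelope minus raw signal, so the decomposition sums
back to the input exactly. Fewer than three anchors flags the
separation degenerate. The 10%-lowest-value means then give Vw and VB,
and the cross-sections and ratio follow from the formulas above.
Residual biases at the bench SNR are ≈ +0.004 (male) / −0.004 (female)
on mean ratios of 0.19/0.27, within the 2% separation allowance the
benchmarks grant.

## Aerial density

Events contribute to time bins by overlap duration (the estimate is the
exact discretisation of the occupancy integral), native resolution one
minute, coarser series by valid-time-weighted aggregation — an exact
identity, so resampling commutes with direct computation. Bins with no
valid time are missing, not zero. Heavy-rain invalidity is declared per
block when the two-sided perturbation occupancy |V − V0| > threshold
exceeds 50% of samples: one-sided occupancy fails to saturate under
continuous rain precisely because the baseline estimate itself is
dragged into the droplet level.

## Seasonal models and the precision experiment

Trap counts: NB2 regression of daily counts on (t, t²) with log link,
fitted by iteratively reweighted least squares (statsmodels GLM) inside
a method-of-moments dispersion update; cross-checked in the tests
against the independent full-MLE negative binomial regression. Sensor
densities: OLS on log density (zero-density days dropped by default;
an offset alternative is available), residual variance stored as the
lognormal σ². The benchmark season is 180 days peaking at 50 counts/day
mid-season (β = (−2.57, 0.144, −8 × 10⁻⁴)) with NB dispersion α = 0.1 —
a mid-latitude mosquito season with realistic trap overdispersion.

The precision experiment draws, per comparison, d baseline seasons and
d seasons with the seasonal curve multiplied by 1.05, sums annual
totals within each arm and records (S₁.₀₅ − S₁)/S₁. The baseline-arm
denominator makes the noise-free limit exactly 0.05; it also carries a
small positive Jensen bias of order CV²(S₁)/d (≈ 0.0015 at d = 1 for
the benchmark model), which the tests allow for explicitly. Spread is
summarised by the interdecile range (robust to NB skew) and scales as
1/√d as independent-replicate theory requires. Device equivalence
interpolates log-spread against log-device-count and reports the count
at which one instrument type matches another's single-device spread,
returning the nearest simulated bound rather than extrapolating.

## What the benchmarks show — and do not

The generator reproduces the *structure* of field transit signals
(Gaussian-like dip, harmonic wing train, droplet morphology, overlap
rate, seasonal trend) with exactly known ground truth. Passing the
recovery benchmarks shows the estimators are consistent and essentially
unbiased under that structure at bench SNR. Real streams add effects
the generator does not emulate: irregular wing waveforms and
inter-species variation, baseline drift from optics contamination,
wind-borne debris, temperature-dependent wingbeat shifts, and partial
beam crossings with aspect-dependent depths. Field-scale aggregate
quantities (total season counts, trap correlations, equivalence factors
of specific trap types) depend on unreleased raw data and are treated
as context, not as reproduction targets.
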