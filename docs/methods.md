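# Methods

This note documents the models, defaults and numerical choices behind
`ovigait`: what the analysis computes, what the synthetic cohort generator
emulates, and where genuinely open design decisions were resolved.

## Stance segmentation

A stance phase is a maximal run of samples strictly above the onset threshold,
closed by the first sample at or below it.  Real platforms never read exactly
0 N between steps, so "force returns to zero" is implemented as a configurable
noise gate, default **5 N** (≈1 %BW of a 55 kg sheep, far below even a severely
lame limb's peak).  Indices are 0-based, half-open `[start, end)`; the contact
time is `(end − start)/fs` on the uniform grid, so it is exact to one sample
(0.02 s at the platform's 50 Hz).  Samples exactly at the threshold close a
phase; phases touching either end of the trace are `edge_truncated` and never
valid.

Inclusion criteria: field practice discards steps walked outside the amble
speed band (2–4 km/h) by eye.  A single platform cannot measure speed, so the
package proxies this with a contact-time window, default **0.15–1.20 s**, plus
a minimum-peak gate (default **20 N**) against noise blips.  This proxy is a
deliberate, documented stand-in, not a speed measurement.

One known bias: a very sharp lame-limb curve has tiny shoulder samples that can
fall below the 5 N gate, trimming one sample per side.  This shortens measured
early post-operative contact times by up to 0.04 s and slightly raises the
measured stance mean; areas (impulses) are essentially unaffected.  This is the
same gating bias any thresholded force-plate pipeline has.

## Gait parameters

Per valid phase, with body weight BW in kg and g = 9.81 m/s²:
`grf_peak_pct = max(F)/(BW·g)·100`, `grf_mean_pct = mean(F)/(BW·g)·100`,
`t_c` from the sample count, and the impulse `A = Σ F·Δt` (rectangle rule).
Two impulse normalizations are reported: `imp_rel_pct = A/(t_c·BW·g)·100`
(decouples gait speed) and `imp_abs_pct_s = A/(BW·g)·100` (%BW·s).

The rectangle rule is chosen over the trapezoid because stance samples are
treated as midpoint readings of their Δt slab; it makes the identity
`imp_rel_pct ≡ grf_mean_pct` exact (both are the mean force), which the test
suite asserts.  The two variants deliberately coexist: the t_c-normalized
impulse tracks the stance mean by construction, while the absolute impulse
also reacts to the shortened contact of a lame limb — which is why asymmetry
analyses default to the absolute variant and trajectory summaries to the
relative one.

Daily summaries are the mean ± sample sd (n−1) over a session's valid phases,
all phases weighted equally; singleton sessions report sd = 0 with a logged
caution.

## Asymmetry index

`asymmetry(%) = 100·|X_I − X_C| / (0.5·(X_I + X_C))` on daily means.  The
pair-mean denominator (standard in the lameness literature) bounds the index
in [0, 200] and makes it symmetric and scale-free; 200 occurs exactly when one
limb bears nothing.  Zero-denominator days are emitted as flagged NaN rows.
Asymmetry is computed per animal and day first, then summarized across animals
(computing the index of cohort-mean values would conflate animals of different
severity).

## Longitudinal statistics

Simple OLS per variable pair with R² = 1 − SS_res/SS_tot and a two-sided t test
on the slope (n−2 df); constant responses are a legal null fit (slope 0, R² 0,
p 1), constant predictors an error.  The limb × parameter matrix pools
per-animal daily means with animal as replicate (a per-animal mode exists for
sensitivity); cells with fewer than 3 pairs are flagged missing; significance
at raw p < 0.01 with an optional Bonferroni switch (off by default, matching
reporting practice in this field).  R² of a simple regression is invariant to
which variable is the response, so "time" enters the matrix symmetrically.

Recovery time is the first measurement day from which the daily-mean series
stays within ±5% (configurable) of the control reference *persistently* — a
single in-band day followed by a dip does not count.  Recovery rate is the OLS
slope over the consolidation window converted with 30.44 days/month (calendar
average).  Note that for a linear trajectory reaching control at day T, the
±5% band is necessarily entered before T (for the default operated-hindlimb
trajectory, at day ≈143, i.e. the first weekly session near day 147); recovery
time is a band-entry statistic, not the trajectory endpoint.

## Synthetic gait generator

### Stance-curve family

`shape(s) = sin(πs)^q · (1 − d·sin²(πs)) · (1 + (a−1)·s)`, rescaled so the
maximum sample equals the target peak exactly.  `d` is the mid-stance valley
depth (above `q/(q+2)` the curve is double-humped — the healthy "M-shape");
`q` is hump sharpness (q ≈ 2 reproduces the spiky single-maximum curve of an
acutely lame limb making punctual ground contact); `a` tilts the second hump.
The mean/peak ratio of the family is **not** monotone in `d`: it rises from
2/π at d = 0 to ≈0.78 near d ≈ 0.5, then falls to ≈0.55 as d → 1.  Calibration
therefore inverts the ratio by bracketed root search on an explicit branch:
healthy limbs use the descending ("deep") branch, which is reliably M-shaped;
lame limbs fix d = 0 and solve for `q`.  Calibration runs on the discrete
midpoint grid actually used at the acquisition rate, so a noise-free pipeline
run returns the calibrated peak and mean to ≤1e-4 relative error and the
contact time to half a sample.

Templates are sampled at midpoint phase offsets `(k+½)/m`, `m = round(t_c·fs)`:
foot strike and lift-off fall between samples, which is both physically natural
and makes the segmented contact time exactly `m/fs`.

### Levels and trajectories

Healthy reference levels (all %BW and s): hind peak 42, hind stance mean 28,
hind t_c 0.58; fore stance mean 45, fore t_c 0.52.  The forelimb peak is not
independently reported in this animal model; it is set to 62 %BW so that the
forelimb relative impulse equals its 45% reference — the one internally
consistent choice given the family's achievable mean/peak range.

Operated-cohort defaults (piecewise-linear from the first walking day, day 7,
constant after recovery):

| limb | parameter | day-7 value | control | recovered by |
|------|-----------|------------|---------|--------------|
| IH   | peak      | 23 %BW     | 42      | day 160 |
| IH   | stance mean | 11.5 %BW (sharp hump, q≈2) | 28 | day 160 |
| IH   | t_c       | 0.28 s     | 0.58    | day 200 |
| CH   | stance mean | 38 %BW (peak scaled to keep shape) | 28 | day 160 |
| IF / CF | stance mean | +11.2 / +21.7 %BW above control | 45 | day 160 |
| CH / IF / CF | t_c | control + 0.05 s | — | day 200 |

The operated limb keeps the single-hump morphology through day 160 (its
sharpness relaxing as the mean/peak ratio recovers) and switches to the healthy
M-template afterwards; a `lame_until` field on the limb model extends the
single-hump regime indefinitely if desired.  Compensatory elevations are
applied additively in %BW to the stance mean with the healthy mean/peak ratio
preserved, because the elevated-limb curve shape is reported as essentially
unchanged.

### Noise model

* Step-to-step: independent unit-mean lognormal factors on each phase's peak
  and contact time, CV default **0.05** (positive forces; dispersion of this
  order is what repeated stance bands show).
* Between-animal: body weight ~ Normal(57.90, 9.62²) kg truncated at 30 kg,
  drawn once per animal; a unit-mean lognormal severity factor (CV **0.03**)
  scales the operated limb's post-operative force levels.  All animals recover
  to the common control norm — the %BW normalization exists precisely to remove
  body-size dependence, and per-animal healthy set-points are not separately
  reported, so they are not modeled.  The published per-animal post-operative
  spread is wider than 3%, but a wide severity spread is arithmetically
  incompatible with the cohort-level recovery rate; the mild factor keeps the
  aggregate dynamics consistent.
* Inter-phase gaps: exact zeros, uniform 0.3–0.6 s.

Cohort generation is a pure function of (config, seed): one
`numpy.random.Generator` drives every draw in a fixed order.

### What the generator does not emulate

Only the vertical force component on a single platform; no double-contact
overlap, no speed variation beyond the t_c proxy, no body-weight decline over
the study, no out-of-band (non-amble) steps, and recovery is exactly piecewise
linear.  Passing tests therefore demonstrate that the *pipeline* is correct
and internally consistent under the study's statistical structure — not that
real recordings are this clean; on real data the inclusion filters and the
supervisor's phase-to-limb attribution carry more weight.

## Default study conditions used in tests and `scripts/acceptance.py`

Control cohort: 3 animals × 10 weekly sessions × 8 phases/limb, noise CV 0.05.
Operated cohort: 8 animals, weekly sessions days 7–210 with 7–10 phases/limb;
day-7 asymmetry uses only the first session; recovery statistics use the
cohort grand daily mean of the operated hindlimb's peak force, a ±5% control
band, and the day 7–160 consolidation window.  These sizes run in seconds and
match the reference study design.
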