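# Methods

## Signal model and simulator

A recording is modelled as

```
cp(t) = cp_start − r·t + osc(t) + ε(t)
```

with deflation rate `r` drawn uniformly from 2–3 mmHg/s between 180 and
40 mmHg, sensor noise `ε` white Gaussian (default SD 0.05 mmHg), and one
raised-cosine oscillometric pulse per cardiac cycle. Each beat's pulse is
mean-removed (`−½·A·cos(2πφ)` over the beat phase φ), so the deflation
baseline is unbiased by pulse rectification; its peak-to-trough height `A`
is the envelope evaluated at the beat's cuff pressure. R-peaks are emitted
as ground-truth annotations (a toy ECG trace is optional); beats are evenly
spaced at the drawn heart rate (60–95 bpm) with no beat-to-beat
variability.

The envelope is a two-sided generalized Gaussian over cuff pressure,

```
A(cp) = MA · exp(−|(cp − MAP)/w|^p),   w = w_high (cp ≥ MAP), w_low (cp < MAP)
```

with exponent `p = 2`. Per recording, SBP and DBP are drawn as truncated
normals (SBP 107 ± 13 mmHg in [70, 133]; DBP 62 ± 9 mmHg bounded so pulse
pressure stays in 20–70 mmHg), matching the reported cohort summary rather
than flat draws over the ranges, and MAP is fixed at DBP + (SBP − DBP)/3.
The characteristic ratios follow a linear link on a latent asymmetry draw
`a ~ U(−1, 1)`:

```
SBPR = 0.55 + 0.12·a + N(0, σ_link)      DBPR = 0.72 − 0.08·a + N(0, σ_link)
```

(σ_link default 0.02, clipped into physiological bands). The widths are
then *solved* from the consistency constraints `A(SBP) = SBPR·MA` and
`A(DBP) = DBPR·MA`, so the envelope exactly encodes the drawn ratios and
the realized width asymmetry is `w_high/w_low = 2·√(ln DBPR / ln SBPR)` — a
function of the ratios alone (the MAP formula cancels pulse pressure). This
is what makes the area-asymmetry features carry recoverable regression
signal, as the cohort generator is required to do.

Movement artifacts come in four signal-level archetypes — pressure-bump
(smooth transient rise, default 8 mmHg over 3 s), amplitude-spike (one
beat's pulse multiplied by 1 + magnitude), burst-oscillation (1–8 Hz noise,
Tukey-windowed), and cuff-release (transient collapse) — all additive in
their magnitude so magnitude 0 is a strict no-op, and all strictly local to
their declared interval. The 3 s bump default keeps the bump's energy below
the 0.3 Hz baseline low-pass so the pressure-rise detector can see it;
sub-second bumps are largely erased by that filter and are not a detectable
signature at the baseline level.

What the simulator does *not* emulate: beat-to-beat and respiratory
variability, pulse-morphology changes with transmural pressure, Korotkoff
sounds, hemodynamics (no Windkessel model), or any coupling between heart
rate and blood pressure. Passing tests therefore demonstrate correctness of
the algorithms under the stated signal model, not clinical performance.

## Pre-processing

The oscillometric waveform is the forward–backward application of a
first-order 0.5–5 Hz Butterworth band-pass (zero phase; the effective gain
is the squared one-pass magnitude). Edge transients are handled with
odd-reflection padding spanning three time constants of the low corner
(≈ 0.95 s at 1 kHz); signals shorter than the padding are rejected. The
deflation baseline — used for the envelope's pressure axis (`cp_at_peak`)
and the pressure-rise rule — is a second-order 0.3 Hz zero-phase low-pass.
Reading `cp_at_peak` from the baseline rather than the raw signal keeps
pulse oscillation off the envelope's pressure axis; a raw mode exists.

Beats are segmented between consecutive R-peaks; within each span the OMW
maximum and minimum give the peak and bottom, and the peak height above the
preceding and following troughs gives the two peak-to-trough amplitudes.

## Outlier rules

Defaults: `max_abs_variation = 0.4` (relative deviation from the neighbour
median, ε = 10⁻⁶ guards division; a raw-mmHg mode exists),
`neighbour_tolerance = 0.5` (±50% band), `neighbour_halfwidth = 2` pulses
each side with median aggregation (robust to adjacent double artifacts),
`rise_slope_threshold = +1 mmHg/s` sustained for ≥ 0.2 s (nominal deflation
runs at −2…−3 mmHg/s, so noise never triggers it), evaluated on the
low-passed baseline after the initial inflation maximum. Pulses whose every
relevant height is below `min_height = 0.1 mmHg` are exempt from the
relative comparisons: near-zero tail oscillations are noise-dominated and
carry no envelope information. Both rules apply to all four height series;
a pulse flagged on any series, or peaking inside a rise interval, is
removed (never repaired) before envelope fitting, which requires at least
four survivors.

## Envelope

One knot per clean pulse at `(cp_at_peak, amplitude, t_peak)`; the knot
amplitude defaults to the mean of the two peak-to-trough heights (robust to
residual baseline; a raw-peak mode exists), and coincident pressures merge
by averaging. The envelope is then delimited at its start and end points of
detectable oscillation: leading/trailing knots below a common threshold are
dropped and exact boundary knots are interpolated at the threshold
crossing. The threshold is the highest of (5% of the maximum amplitude, the
first observed amplitude, the last observed amplitude) — a *common level on
both limbs*. For unimodal envelopes the area split at the maximum is
insensitive to the chosen level as long as it is the same on both sides, so
this makes duration/area features comparable across recordings even when
deflation stops before the diastolic limb has died out (common when MAP is
within ~30 mmHg of the 40 mmHg deflation floor). Delimiting can be disabled
(`min_amplitude_frac = 0`).

A natural interpolating cubic spline over cuff pressure fits the knots
(interpolation, not smoothing; a smoothing variant was deliberately not
adopted because outlier removal precedes the fit). MAP/MA come from a
0.1 mmHg grid scan refined by bounded maximization to 0.01 mmHg; among
equal maxima the higher cuff pressure wins; a maximum within two grid steps
of a domain endpoint flags the envelope as truncated and emits a warning.
Evaluating the spline outside its domain is an error, never extrapolation.

## Features and reference ratios

Durations and areas are measured on the time axis (deflation is near-linear
so the pressure axis is proportional; a pressure-domain mode exists). The
time of the maximum is interpolated at the refined MAP between bracketing
knots. Areas integrate the piecewise-linear knot envelope by the trapezoid
rule, split exactly at that time, so `Area₁ = Area₂ + Area₃` and
`Ratio₂ + Ratio₃ = 1` hold to rounding. Reference ratios divide the spline
amplitude at the reference SBP/DBP by MA and require
DBP < MAP ≤ SBP inside the spline domain; recordings violating this (e.g.
reference DBP below the delimited envelope) yield no training target and
are excluded from scoring with a logged reason — analogous to the source
study losing reference readings on a fifth of its measurements.

## Estimation models

All models predict the *ratios*; pressures come from inverting the
predicted ratio on the envelope (grid bracket + Brent root-finding to
0.01 mmHg, crossing nearest MAP on the appropriate limb; a missing crossing
raises an error naming the failing side). Predicted ratios are clipped into
(0.05, 1] with clipping logged. Separate models are fitted for SBPR and
DBPR.

* **Fixed-ratio MAA** — component-wise training means.
* **MLR** — ordinary least squares, solved by a stable least-squares
  routine that matches the normal equations `(XᵀX)⁻¹XᵀY` to 10⁻⁸ on
  well-conditioned input; rank deficiency raises an error naming the
  collinear columns (QR with column pivoting).
* **Linear ν-SVR** — libsvm's ν-parameterization with the identity feature
  map; features are standardized internally (areas in mmHg·s would
  otherwise dominate dimensionless ratios) and the primal `(w, b)` is
  returned in original units. Defaults C = 2^14.49 ≈ 2.3·10⁴ and
  ν = 2^−1.89 ≈ 0.27: the printed tuning values are read as base-2
  exponents of their stated search ranges, since ν must lie in (0, 1].
  Solver tolerance 10⁻⁴ with a 2·10⁶-iteration cap — at such large C the
  dual converges slowly and tighter tolerances buy nothing measurable.

## Selection and cross-validation

Folds default to 4, grouped by subject (four recordings per simulated
subject) so repeated measurements never straddle a train/test split; groups
are shuffled by seed and dealt round-robin. The selection criterion is the
cross-validated n−1 SD of (reference − estimated) SBP, pooled over folds
(mean absolute error is available). Exhaustive search scores all
10 + C(10,2) = 55 one- and two-feature subsets; ties break by fewer
features then lexicographic names. SFFS starts from the best pair, adds the
best improving feature, and conditionally removes features while removal
beats the best criterion recorded at the smaller size. An addition must
improve the criterion by at least 2% (relative) to be accepted: the
criterion is itself a cross-validated estimate, and measured chance
"improvements" from adding pure-noise features reach a few percent at
cohort sizes of order 10², so a near-zero tolerance would accept noise
almost always. The tolerance is an argument for callers who want the
classical behaviour.

## Evaluation

Differences are `reference − estimate`; SD uses n−1. BHS grades compare the
cumulative percentages within 5/10/15 mmHg (boundaries inclusive) against
the A/B/C rows; AAMI requires |mean| ≤ 5 mmHg and SD below the tabulated
limit at the absolute mean rounded *up* to the next 0.5 mmHg step (the
table states no interpolation rule; rounding up is conservative).

## Problem sizes

The test suite and the acceptance script run at desk scale: 50 recordings
(≈ 3 500 pulses) for the artifact experiment, 200 for the fixed- versus
variable-ratio comparison, 120-recording planted-signal cohorts (20 of
them) for selection. The source study's absolute error tables came from 25
subjects with expert auscultatory references and are not reproducible
without that data; the experiments here reproduce the *directions* — error
SD shrinking several-fold upon outlier removal, and variable ratios beating
fixed ones when the ratio truly varies — with magnitudes native to the
simulator's conditions.

## Known limitations

* The simulator's envelope family is unimodal and noise-free in shape;
  bimodal envelopes (arrhythmia, calcified vessels) are out of scope.
* Constant heart rate within a recording means the band-pass gain is a
  single scale factor per recording; with strong heart-rate variability the
  knot amplitudes would be modulated by the filter response.
* The amplitude-relative envelope delimiting assumes the oscillation
  maximum is well inside the deflation window; severely truncated
  envelopes are flagged but their features are unreliable.
* The ν-SVR at the default (very large) C is effectively an L1-insensitive
  least-squares fit; its advantage over MLR on clean synthetic cohorts is
  negligible, consistent with the source study's conclusion that MLR is
  competitive.
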