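# Methods

## The measurement and the two parameters

Flow Mediated Skin Fluorescence with post-occlusive reactive hyperemia
(FMSF–PORH) records NADH fluorescence from forearm skin through a protocol
of resting baseline, a 3-minute brachial-artery occlusion, and several
minutes of reperfusion.  Microvascular flowmotion appears as small
oscillations riding on the signal, conventionally split into endothelial
(≤0.021 Hz), neurogenic (0.021–0.052 Hz), myogenic (0.052–0.15 Hz),
respiratory (0.15–0.6 Hz) and cardiac (≈1 Hz) bands.  The package computes
the two myogenic parameters of the method:

* **VM** — the mean-squared amplitude of myogenic oscillations of the
  normalized baseline signal, × 10⁶;
* **HS** (hypoxia sensitivity) — the same statistic on the reperfusion
  segment, where transient hypoxia activates myogenic vasomotion roughly
  tenfold.

"Mean-squared amplitude" is realized as the one-sided rectangular-window
periodogram integrated over the myogenic band.  By Parseval's theorem this
equals the mean square of the band-limited signal, which is the only
reading that makes the parameters unit-consistent power-spectral-density
quantities; the identity `∑ PSD·Δf = mean square` is enforced to machine
precision and tested.  Both parameters are analyzed as base-10 logarithms
(fixed by the reference value pairs 11.6→1.06, 150.6→2.18, 38.3→1.58,
246→2.39): the linear values are close to lognormal across subjects, the
logs close to normal.

## Trace pipeline

1. **Normalization** divides by the baseline-phase mean, making the signal
   dimensionless with baseline level 1.  Every downstream quantity is then
   invariant under rescaling of the raw fluorescence (tested as a
   property).
2. **Segmentation** uses half-open `[start, end)` windows cut at the
   occlusion markers.  Reperfusion starts a guard interval (default 30 s,
   configurable) after cuff release so the hyperemic dip/transient is not
   counted as oscillation; a reperfusion window shorter than 60 s is an
   error.
3. **Detrending** subtracts a centered moving average with *triangular*
   weights of half-width `1/cutoff` seconds (equivalently two cascaded
   flat averages).  Its subtraction transfer is `1 − sinc²(f/cutoff)`: a
   flat window's `1 − sinc(f/cutoff)` has ±8 % amplitude ripple in the
   myogenic band at the default 0.03 Hz cutoff (≈17 % in power), while the
   triangular kernel keeps band power within ≈3 %.  Segment edges are
   extended by antisymmetric (odd) reflection before convolving: linear
   trends are then removed exactly up to the endpoints and band tones are
   not tapered at the edges (symmetric window-shrinking, the obvious
   alternative, collapses the trend onto the data at the endpoints and
   costs ≈8 % of band power on a 180 s segment).  The exact detrending
   algorithm of the FMSF device software is not public; this choice is a
   documented stand-in.
4. **Spectrum and band powers** come from `scipy.signal.periodogram` with
   a rectangular window (Hann available as an option).  Band membership is
   half-open `(lower, upper]`; the DC bin is never included, so the lowest
   resolvable endothelial bin is `1/duration`.  The 5 % tolerance quoted
   for all sinusoid tests is the rectangular-window leakage allowance.

For full five-band share analysis a lower detrend cutoff is needed so the
endothelial band survives; the requested 0.005 Hz is clamped to
`2/segment_duration` (0.011 Hz on the default 180 s baseline), since the
trend window cannot exceed the segment.  Endothelial shares on short
baselines are therefore attenuated estimates — a protocol limitation, not
a numerical one.

`IR_max` is the peak rise of the normalized signal during occlusion (in
percent), `HR_max` the peak drop in the guard interval after release.  No
published operational definition exists; the definitions here round-trip
exactly with the generator envelope, which is the internal truth the tests
use.

## Synthetic trace generator

Traces are a deterministic PORH envelope plus one representative sinusoid
per band plus white noise.  The envelope is 1 during baseline, a logistic
rise normalized to reach exactly `1 + IR_max/100` at the end of occlusion
(τ = 30 s), a 5 s cosine release transient down to `1 − HR_max/100`, and
exponential recovery toward 1 with τ = 60 s — pure modeling choices,
recorded in the configuration.  Defaults emulate the reference control
group: IR_max 16.3 %, HR_max 19.8 %, low-frequency tone amplitudes of
order 0.5 % of the signal level, cardiac orders of magnitude weaker, and a
reperfusion myogenic gain of 3.6 (HS/VM ≈ 13, the "over tenfold"
activation).  Tones are silent during occlusion (no flow, no flowmotion)
and restart at release with the myogenic gain applied, constant over the
reperfusion window; real reperfusion oscillations ring and decay, which
the generator deliberately does not model — the constant gain keeps the HS
target analytic (HS/VM = gain²).  Band frequencies default to one tone per
band (0.01, 0.035, 0.1, 0.25, 1.0 Hz).  Sampling rate defaults to 10 Hz
and baseline duration to 180 s (device values are unpublished; 180 s gives
Δf ≈ 0.0056 Hz, enough to resolve the myogenic band), with a hard floor of
4 Hz and an explicit error naming the band whenever a tone would exceed
Nyquist.

## Cohort generator and calibration

Per group, `log₁₀(VM) ~ N(μ, σ²)` and `log₁₀(HS) = a·log₁₀(VM) + b + ε`,
`ε ~ N(0, σ_res²)`.  The groups are calibrated from the published
reference cohorts: control (n = 153) μ = 1.23, σ = 0.50, a = 0.56,
b = 1.11; CVD+DM2 patients (n = 910) μ = 0.53, σ = 0.58, a = 0.62,
b = 0.81.  The residual SD is *derived*, not set: `calibrate_residual_sd`
solves `σ_y² = (a·σ)² + σ_res²` for the published marginal SDs of log(HS)
(0.44 and 0.56), giving σ_res = 0.3394 (control) and 0.4293 (patient).
This single identity ties the group moments, the regression slopes and the
generator together: the implied population correlations are 0.636 and
0.642, against published sample values 0.639 and 0.636.  The ≈0.006
discrepancy on the patient side is irreducible — the published moments and
slope are rounded — and is covered by the stated ±0.02 tolerance.

Ages are uniform over a configurable range (off by default: every subject
gets the group reference age, 32.6 or 67.6 years).  When age effects are
enabled, log(VM) gets the published slope (−0.017/yr control, −0.012/yr
patient) and log(HS) a direct term sized so its *marginal* age slope
matches the published value (−0.012, −0.013/yr) after the indirect path
through log(VM).  Pooled analyses weight the groups 153:910.

What the generator does **not** emulate: measurement error in VM/HS,
non-Gaussian tails, the ceiling effects visible in the real scatter (no
control below log(VM) = 0, no patient above log(HS) = 2.5), chirped or
decaying oscillations, or motion artifacts.  Passing calibration tests
therefore shows that the pipeline recovers the generative parameters and
that the published moments/regressions are mutually consistent — not that
real FMSF traces would yield these exact numbers.

## Statistics and diagnostics

Cohort statistics go through scipy: OLS with coefficient standard errors
(`linregress`), Pearson r with the t-transform p-value, two-sided t tests
(paired for before/after designs such as the exertion comparison — the
published analysis does not say whether it paired; both variants are
exposed), Shapiro–Wilk (3 ≤ n ≤ 5000).  No multiple-testing correction is
applied, matching the reference analysis (α = 0.05).  p-values below
1e-300 are reported as the bound `"<1e-300"` at the serialization layer
only.

Classification uses two log-scale cut-offs per scheme; boundaries are
lower-inclusive for "acceptable" (`cut ≤ log(x) < upper`).  The original
and revised VM schemes and the HS scheme are defined by their linear
cut-offs (2/12, 2.5/8, 10/30) with logs derived, so the printed boundary
cases (VM = 2.5 → acceptable) hold exactly; the Youden scheme is defined
on the log scale (0.53/0.83) as it comes from ROC analysis there.

ROC curves sweep every distinct score (sklearn `roc_curve`,
`drop_intermediate=False`) so the trapezoid AUC equals the pairwise rank
statistic `P(score⁺ > score⁻) + ½P(tie)` — verified against a brute-force
oracle.  The Youden optimum maximizes J = TPR − FPR with ties broken
toward the smallest threshold, and is invariant under monotone transforms
of the score (log vs linear VM give the same partition).  The published
operating points print "FPR" values (e.g. TPR = 0.75, FPR = 0.80) that
would imply negative J; these are almost certainly specificities (TNR).
The package reports TPR, FPR and TNR explicitly and does not validate
against the ambiguous printed values.

Discordance rates use strict inequalities on the VM side (records exactly
at the cut count in neither fraction), mirroring the published "below
0.3 … above 0.3" phrasing.

## Problem sizes and tolerances

Calibration simulations use n = 10⁵ subjects (sampling error on r ≈ 0.002,
comfortably inside the ±0.01/±0.02 acceptance bands) and run in ~1 s; the
mixture ROC in the analysis scripts uses n = 10⁵, the unit-test variant
n = 2×10⁴.  Spectral tests use the default 180 s/10 Hz protocol (1800
samples, exact-bin 0.1 Hz tone).  The measured mixture AUC (≈0.83 for the
proper-response label) is reported alongside the published real-data 0.849
but not asserted against it: a two-lognormal mixture calibrated only to
moments and regressions has no reason to reproduce the empirical ROC shape
exactly.

## Known limitations

* Single-tone bands: real flowmotion is broadband; band-share estimates on
  real traces would need the Hann option and longer baselines.
* Constant reperfusion gain ignores the decay of hypoxia-driven
  oscillations; whether real HS oscillations are stationary over the
  analysis window is unquantified.
* IR/HR definitions are generator-internal conventions.
* The generator's group models are Gaussian on the log scale with no
  truncation, so extreme tails slightly exceed the ranges observed in the
  reference cohorts.
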