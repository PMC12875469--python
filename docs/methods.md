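# Methods

`modsense` is a desk-scale re-implementation of the measurement and
analysis machinery used to relate suprathreshold auditory function to early
language skills in young children: stimulus synthesis for temporal and
spectral modulation detection, the adaptive threshold procedure with its
attention quality controls, transfer-function summarization, and the
correlational inference stage — driven entirely by simulated observers and
a synthetic cohort, since the underlying child data are not published.

## Stimuli

**Temporal modulation.** The carrier is broadband Gaussian noise band-limited
to 0.05–8.0 kHz by a frequency-domain brick wall (the simplest spectrally
exact realization of a flat band). Targets are sinusoidally amplitude
modulated at 8 or 64 Hz by `1 + m·sin(2πft + φ)`; depth is expressed as
`20·log10(m)` dB, so 0 dB is full modulation and harder trials are more
negative. `m = 0` has no dB representation; standards are flagged
explicitly rather than routed through the conversion.

**Spectral modulation.** The complex is 800 sinewave components log-spaced on
0.1–5.0 kHz with fresh random phases every trial. Targets impose a
sinusoidal spectral envelope at 0.5 cycles/octave whose size is the
peak-to-trough range in dB (sinusoid amplitude = depth/2); standards are
flat. Two fixed shapings follow: raised-cosine edge tapers (40 dB over the
outermost half-octave at each band edge) so component amplitudes grow in
and fade out gradually, and a long-term-average speech-spectrum weighting
(flat to 500 Hz, −9 dB/octave above). The exact speech weighting used in
the original testing software is not published; the LTASS approximation
here is a conventional stand-in and is swappable via the `speech_shape`
argument.

All intervals are 500 ms at 44.1 kHz (configurable; the source procedure
does not state a rate), with 20-ms cosine-squared onset/offset ramps and
RMS equalization to a digital reference that stands for 68 dB SPL — only
relative levels are meaningful in simulation. The spectral task roves each
interval's level uniformly on ±3 dB; the temporal task does not rove
(the rove is described only for the spectral stimuli).

A note on verification: the 800 components are closer in frequency than the
2-Hz resolution of a 500-ms analysis window below ~1 kHz, so per-component
amplitudes cannot be read back from the waveform. The synthesis test
instead smooths component-bin power across ~1/8 octave (negligible
attenuation of a 2-octave-period ripple) and fits the 0.5-cpo sinusoid,
recovering the half-depth within ~1 dB and the envelope phase within
0.05 rad.

## Adaptive procedure

A three-alternative forced-choice, two-down/one-up transformed staircase:
two consecutive correct responses step toward shallower modulation, any
error steps toward deeper; this converges on the 70.71%-correct point
(P(two correct) = 1/2). Step size is 4 dB until the second reversal, then
1 dB (temporal) or 2 dB (spectral) for eight more; the threshold is the
mean of the last eight reversal depths. Both tasks share one depth axis
convention (larger dB = deeper = easier), with a 0-dB ceiling for temporal
depth and a 0-dB floor for spectral depth (a ripple cannot have negative
peak-to-trough range).

Bookkeeping choices, made where the protocol description is silent:

* A reversal is logged at the depth of the trial where the realized step
  direction changes; the small step takes effect on the first step after
  the second reversal (the conventional transformed up-down bookkeeping).
* A step that cannot move because the track sits at a clamp changes
  neither the depth nor the direction state, so oscillation against the
  ceiling does not fabricate reversals.
* Easy trials (maximum depth, scheduled every 4–6 adaptive trials with a
  uniformly redrawn gap) probe attention only; they never enter the
  staircase state, because catch trials that drove the track would bias it.
  More than two easy-trial errors invalidates the run.
* Practice gate: 9 of 10 consecutive correct at maximum depth within 30
  trials; a failed practice substitutes the maximum depth as that run's
  threshold. Each task's measure is the mean of two runs.
* Tracks are capped at 150 adaptive trials; a track that has not logged
  10 reversals by then is flagged incomplete rather than silently
  substituted.

Two stability statistics are computed over the last eight reversals: their
sample SD and the mean length of excursion (MLE), the mean absolute
difference between consecutive reversals.

**Convergence and the truncation transient.** With stationary lapse-free
observers the track's mean threshold approaches the 70.71% point. An
important property of the *truncated* 10-reversal protocol, reproduced and
verified here against an independent minimal reimplementation: when the
observer's psychometric spread is large relative to the 1-dB step (e.g.,
logistic slope 0.6/dB), the track is still descending from the 0-dB start
when the tenth reversal arrives, and the mean threshold overestimates
(sits easier than) the convergence point — about +0.6 dB (≈5 percentage
points) at slope 0.6, shrinking to near zero either for steep observers or
for longer tracks (the same shallow observer measured with 30 reversals
converges at ~70%). Convergence-point measurements in the acceptance
script therefore use a steep observer (slope 2.0/dB, midpoint −16 dB),
for which the protocol reaches its stationary region and the percent
correct at the grand-mean threshold is ~71%. The transient bias is a real
property of the protocol that would also affect shallow-sloped listeners.

## TMTF summary

Thresholds across modulation rates are summarized by a first-order low-pass
characteristic in dB, `T(f) = S + 10·log10(1 + (f/fc)²)`, fit by least
squares with `fc` parameterized on a log scale. `S` is the low-rate
sensitivity plateau and `fc` is analytically the 3-dB-down point
(`T(fc) = S + 3.01 dB`). Flat data return the common threshold with the
cutoff flagged undefined; if the parametric fit fails, a monotone
piecewise-linear interpolation in log-frequency supplies the 3-dB crossing.
The main study design measures only 8 and 64 Hz — both below typical
cutoffs — so the pipeline treats the two rates as separate variables and
the fit serves validation and background characterization.

## Simulated observers

A listener is a logistic (optionally Weibull) psychometric function on the
depth axis: `P = guess + (1 − guess − lapse)·F(slope·(depth − midpoint))`
with guess 1/3. `psychometric_inverse` supplies the exact percent-correct
points used as ground truth for staircase validation. Defaults used in
end-to-end simulations: slope 0.6/dB, lapse 0.02 — a deliberately
imperfect, child-like observer; convergence measurements use lapse 0 and
slope 2.0 as explained above.

## Synthetic cohort

The generator encodes the causal structure the inference stage is designed
to detect. On z scales:

    A     = a1·zSES + a2·zGA + ε_A                 Var(A) = 1
    thr_k = −λ·A + sqrt(1 − λ²)·ε_k                k = temporal 8, temporal 64, spectral
    y_j   = b1·A + b2·zSES + ε_j                   j = four language outcomes

`A` is a latent "central auditory maturation" variable. Gestational age is
**fully mediated** (no direct GA→y path; `ga_direct` exposes one for
alternative structures) and SES is **partially mediated** (`b2 > 0` is a
direct path standing for environmental language exposure). Demographic
satellites hang off the risk factors at their observed correlations
(maternal education ↔ SES .82; birthweight ↔ GA .82; NICU days ↔ GA −.78).
The SES–GA correlation defaults to 0 (the two risk arms were recruited
separately) and is configurable.

Defaults `a1 = .30, a2 = .45, λ = √.72, b1 = .55, b2 = .25` were derived
analytically from the published correlation pattern before any simulation:
they imply cross-threshold r = λ² ≈ .72, r(SES, thr) ≈ −.25, r(GA, thr) ≈
−.38, r(thr, y) ≈ −.53, r(SES, y) ≈ .42, r(GA, y) ≈ .25 — all inside the
printed ranges. Because the thresholds measure `A` with error, partials of
GA controlling the three thresholds do not vanish exactly; at these
defaults they sit near .01 at n = 10,000, far below the .05 detection
bound, while threshold partials controlling GA stay near −.48.

Observed variables are affine maps of the z-scores onto configured
means/SDs. Bounded variables (percent scores on [0,100], gestational weeks
on [23,42], the SES index on [1,64], threshold sign constraints) use a
**moment-compensated clipped normal**: the pre-clip parameters are solved
from the analytic clipped-normal moments so the post-clip mean and SD hit
the targets. Known unrealisms, accepted deliberately:

* The percent-correct calibration targets (ICC mean 44, SD 33.8) force
  ~26% boundary mass after compensation — mostly floor scores, which the
  real task also produces in this age range, but as exact zeros rather
  than a smooth floor. Clipping (not truncation) is used for simplicity;
  it mildly attenuates correlations involving the percent scores.
* NICU days are generated as an unclipped Gaussian satellite so the
  published moments are met; the real variable is zero-inflated (median 0)
  and right-skewed. Analyses using NICU days as anything other than a
  linear covariate should not trust this column's shape.
* All structural relations are linear-Gaussian before clipping; the
  generator makes no attempt to reproduce individual children or any
  nonlinearity in the real data. Passing tests show the *pipeline* detects
  the structure it was built to detect, not that the real data contain it.

`observer_from_latent` closes the loop for end-to-end runs: a child's
psychometric midpoint moves linearly with `A` (5 dB/SD temporal, 7 dB/SD
spectral around population midpoints −16/−14/+16 dB), so a full simulated
study — cohort → observers → two staircase runs per task → thresholds →
inference — can be run from one seed. Measured thresholds correlate ~.98
with the observers' true 70.71% points over 200 simulated children.

## Inference stage

* **Correlations**: product-moment r with t-reference p, star convention
  (.05/.01/.001), no family-wise correction (none was applied in the
  original analysis).
* **Stepwise regression**: forward entry at p < .05, backward removal at
  p > .10 (classic SPSS defaults; the original analysis names the package
  but not the criteria), standardized coefficients and cumulative R² per
  step.
* **Partial correlation**: residual-regression implementation with
  df = n − 2 − k; an independent closed-form recursive implementation is
  kept for cross-checking (they agree to 1e−10, and both match pingouin).
  Note the published tables print df = 102 for both one- and two-control
  analyses at n = 104; the standard formula gives 101 when k = 2. This
  package reports the standard df.
* **Dependent-correlation bootstrap**: whole subjects are resampled with
  replacement (preserving dependence among outcomes); the statistic is the
  original-sample correlation difference divided by the bootstrap SE.
  Three p-values are emitted: the one-sided tail probability that a
  replicate difference falls on the null side of zero (the convention the
  published test statistics follow — e.g., a statistic of 1.71 pairs with
  p ≈ .043 = Φ(−1.71)); its two-sided doubling; and the one-sided normal
  reference. The one-sided observed-direction p rejects at 2α under the
  null by construction, so type-I calibration is asserted on the two-sided
  p (measured 4.7% at α = .05 over 1,000 null cohorts of n = 104).
* **Driver** (`analyze_cohort`): produces the six table shapes of the
  analysis — thresholds × outcomes correlations; per-outcome stepwise; the
  twelve lexicosyntactic-vs-phonological bootstrap comparisons; risk
  factors × (outcomes + thresholds) correlations; and the two
  partial-correlation tables, in which the thresholds controlled for each
  outcome are the stepwise winners for that outcome.

## Problem sizes and numerical choices

Simulation sizes were chosen to keep Monte-Carlo error well below the
assertion tolerances: 1,000 tracks for convergence checks (the acceptance
script uses 4,000 to shrink the ~1-percentage-point seed-to-seed jitter of
the steep observer), n = 10,000 cohorts for calibration and mediation
patterns, 1,000 × 500-replicate bootstraps for type-I calibration, and
100,000 Bernoulli draws for psychometric verification. The moment
calibration is asserted at 3% of each variable's scale, max(|mean|, SD) —
NICU days has a mean (7.6) far smaller than its SD (24.8), and 3% of the
mean is below the sampling error of the mean at n = 10,000. All randomness
flows through `numpy.random.Generator` seeds; every stochastic component
is bit-reproducible under a fixed seed. Degenerate inputs (silent
waveforms, zero-variance vectors, collinear controls, < 8 reversals,
incomplete tracks) raise typed errors rather than propagating NaNs.

## Limitations

The package simulates the measurement chain, not children: psychometric
forms, lapse behavior, attention dynamics, and the true effect sizes
linking auditory maturation to thresholds are all stipulated, with
defaults tuned only to match the published correlation magnitudes
approximately. Formal causal mediation estimation is out of scope by
design (the partial-correlation probe mirrors the original analysis);
language-task administration is not modeled — language scores enter only
as numeric columns.
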