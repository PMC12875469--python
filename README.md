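# modsense

Psychophysics and statistics for studying how the maturation of
suprathreshold auditory function relates to early language skills.

Sensitivity to *temporal* amplitude modulation (envelope fluctuations of a
broadband noise at 8 or 64 Hz) and *spectral* modulation (a 0.5
cycles-per-octave ripple imposed on an otherwise flat 800-component
spectrum) develops across childhood and is thought to support the
emergence of phonological sensitivity. Measuring it in five- to
seven-year-olds requires a carefully instrumented protocol: a
three-alternative forced-choice, two-down/one-up adaptive staircase
(converging on the 70.7%-correct point), a practice gate, interleaved
easy trials probing attention, and track-stability statistics. Relating
the resulting thresholds to language outcomes and demographic risk factors
(socioeconomic status, gestational age at birth) then takes a correlational
toolkit: correlation tables, forward stepwise regression, bootstrap
comparisons of dependent correlations, and partial correlations used as a
mediation-style probe.

`modsense` implements that entire chain for simulation work: since child
data of this kind are not public, a latent-mediation cohort generator and
simulated 3AFC observers stand in for the sample, letting the pipeline be
validated end to end — from waveform synthesis through staircases to the
final partial-correlation tables.

## The core model

A simulated listener answers 3AFC trials with

    P(correct | depth) = 1/3 + (2/3 − lapse) · F(slope · (depth − midpoint)),

and the staircase steps 4 dB until the second reversal, then 1 dB
(temporal) or 2 dB (spectral) for eight more; the threshold is the mean of
the last eight reversal depths. The synthetic cohort encodes a latent
central-auditory-maturation variable `A`:

    A     = a1·zSES + a2·zGA + ε           (Var A = 1)
    thr_k = −λ·A + √(1−λ²)·ε_k             (lower threshold = better)
    y_j   = b1·A + b2·zSES + ε_j           (language outcomes)

with gestational age fully mediated by `A` and SES partially mediated (a
direct path `b2` remains). Temporal modulation transfer functions are
summarized by `T(f) = S + 10·log10(1 + (f/fc)²)` — intercept `S` and
3-dB-down cutoff `fc`.

See `docs/methods.md` for assumptions, parameter defaults, and known
limitations.

## Worked example

```python
import numpy as np
from modsense.observers import ObserverParams
from modsense.staircase import TrackConfig, run_track
from modsense.cohort import CohortParams, generate_cohort
from modsense.inference import analyze_cohort

# one adaptive run against a child-like observer
obs = ObserverParams(midpoint_dB=-16.0, slope=0.6, lapse=0.02)
res = run_track(obs, TrackConfig.preset("temporal8"), np.random.default_rng(11))
print(res.threshold_dB, res.sd_last8_dB, res.easy_errors, res.valid)
# -15.25 1.3887301496588271 0 True

# a synthetic 104-child cohort through the full inference stage
cohort = generate_cohort(CohortParams(n=104), seed=42)
report = analyze_cohort(cohort, n_boot=2000, seed=3)
cell = report.modulation_language_corr.loc["spectral_dB", "icc_pct"]
print(round(cell["r"], 3), cell["stars"])
# -0.466 ***
print({k: (round(v.r_partial, 3), v.df) for k, v in report.ga_partials["icc_pct"].items()})
# {'gestational_age_weeks': (-0.074, 101), 'spectral_dB': (-0.461, 101)}
```

The run's threshold (−15.25 dB) is the mean of its last eight reversals;
the SD of those reversals (1.39 dB) and zero easy-trial errors mark a
stable, attentive track. In the cohort analysis, the spectral threshold
correlates −.47 with initial-consonant-choice scores, and the
partial-correlation probe shows the built-in mediation structure:
controlling the threshold leaves gestational age no significant unique
variance (r = −.07, n.s.) while the threshold keeps its association
(r = −.46) when gestational age is controlled.

The same stages are scriptable from a shell:

```sh
modsense cohort-sim --n 104 --seed 42 --out cohort.csv
modsense analyze --cohort cohort.csv --seed 3 --out report.md
modsense synth --kind spectral --depth 30 --seed 7 --out stim/
modsense track-sim --task spectral --observer midpoint=14,slope=0.4,lapse=0.02 --seed 11
```

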