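# Methods

This note documents the models, numerical choices and limitations behind
`pulsevar`. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design the pipeline assumes

One visit yields two sequential ~7-minute continuous arterial-pressure
recordings (100 Hz) from the same device and posture; the analysis question
is whether per-recording summaries — mean SBP/DBP, heart rate, and the BPV
metrics — agree between the two recordings (intrasession test-retest
reliability), overall and within antihypertensive-use strata. Participants
missing either session are dropped pairwise per metric.

## Waveform generator

Per-beat systolic amplitude is

```
SBP_i = sbp_mean + subject_offset
        + lf_amplitude·sin(2π·lf_frequency·t_i + φ_lf)
        + resp_amplitude·sin(2π·resp_frequency·t_i + φ_resp)
        + e_i,           e_i = ar·e_{i−1} + N(0, innovation_sd²)
```

with DBP built the same way around `dbp_mean` (independent AR(1) stream)
and clipped to keep a ≥10 mmHg pulse pressure. Inter-beat intervals come
from a per-beat heart rate `N(hr_mean, hr_sd)`. The stationary per-beat SBP
SD is therefore `√(innovation_sd²/(1−ar²) + lf²/2 + resp²/2)`, which the
suite verifies to 3% on long simulations. The AR(1) term models true
beat-to-beat changes (what ARV sees); the 0.1 Hz term models Mayer-wave
oscillations (what dominates SD/CV/VIM); separating the two is the point of
the generator.

Defaults (420 s, 100 Hz, HR 60.65±3 bpm, SBP/DBP 132.65/77.42 mmHg,
innovation 1.5 mmHg with ar 0.4, LF 6.5 mmHg at 0.1 Hz, respiratory
1.5 mmHg at 0.25 Hz) describe a resting older adult measured by a
noninvasive finger-cuff monitor and give a per-beat SBP SD of ~5 mmHg.
Oscillation phases are randomised per session, so repeated sessions of one
subject share the subject offset but differ through phases and
innovations — the within-subject variance source of the waveform-level
cohort model.

**Pulse morphology.** Each cycle is a piecewise template: half-cosine
systolic decay from the peak to a shoulder at `dbp + 0.25·PP`, an optional
dicrotic bump of height `notch_depth·PP` riding on the shoulder, a slow
half-cosine decay to the trough (exactly `dbp` at 85% of the cycle), and
the next upstroke. Every segment has zero slope at its ends, so the sampled
extrema match the analytic SBP/DBP to well under 0.5 mmHg at 100 Hz. The
notch timing tracks systolic ejection time: it scales with the cycle length
only up to 1 s and saturates beyond, keeping the notch ~300 ms after the
peak at slow heart rates (as in real pulses, where ejection time does not
stretch with long diastole). This is a stylised template, not a Windkessel
or wave-propagation model; it exists to exercise the delineator, in
particular the dicrotic-notch misdetection failure mode.

**Motion artifacts** are Poisson events (`artifact_rate` per minute),
0.5–3 s long, adding a smooth `sin²` excursion of `artifact_magnitude`
mmHg. The spectral shape of real motion artifacts on finger-cuff devices is
not documented; this placeholder is amplitude-realistic but
morphology-naive, so QC conclusions transfer to real data only insofar as
real artifacts also violate the amplitude/slope rules.

**Metric-level cohort model.** For recovery tests of the reliability
estimators, per-metric session values are drawn directly as
`subject_i + noise`, `subject_i ~ N(mean, between²)`,
`noise ~ N(0, within²)`, giving true ICC `between²/(between²+within²)`.
Default components per metric reproduce a realistic older-adult cohort
(HR ~60 bpm with ICC .98, SBP ARV ~1.7 mmHg with ICC .87, ΔSBP ~34 mmHg
with ICC .53, etc.); strata can override components to emulate
medication-dependent reliability. This mode is exact and fast; the
waveform-level mode exercises the full pipeline instead.

**What the generator does not emulate:** real slow BP power is spread over
a band (very-low-frequency drift plus ~0.1 Hz), not a single sine, so the
waveform-level ARV/SD ratio runs somewhat higher than in real cohorts;
there is no baroreflex coupling between HR and BP, no calibration drift,
and no device-specific noise floor. Waveform-level tests therefore validate
the *pipeline* (delineation and metric arithmetic against known truth), not
physiological realism.

## Delineation

Artifact samples are those outside `artifact_bounds` (default 20–250 mmHg)
or with |first difference| > `max_abs_slope` (default 20 mmHg/sample at
100 Hz; a genuine systolic upstroke moves ~3–4 mmHg/sample). Flagged runs
are dilated outward to the nearest local pressure minimum (searched up to
1.5 s) so whole beats, never partial pulses, are removed. These
deterministic rules replace interactive visual screening; the
>10%-exclusion rule (`max_excluded_fraction = 0.10`) then decides
acceptance. Rejection is a QC outcome, not an error.

Systolic peaks are local maxima above `min_height` (default 80 mmHg),
retained greedily in descending prominence — earliest index on ties —
subject to a pairwise refractory separation (default 400 ms). Candidate
maxima come from `scipy.signal.find_peaks`; the refractory selection is
implemented here so its semantics (prominence-greedy, deterministic) are
explicit. The default separation is deliberately 400 ms: the dicrotic notch
sits roughly 300 ms after the peak, so a 40 ms separation — a plausible
misreading when the parameter is quoted in samples at 100 Hz (40 samples =
400 ms) — admits every notch as a spurious beat. Both behaviours are
reproduced in the tests. Diastolic troughs are the minimum sample strictly
between consecutive peaks (earliest index on ties). Heart rate is
60/mean(inter-peak interval), with intervals spanning masked gaps excluded.

## Metrics

SD uses the sample (n−1) denominator — the convention for cohort summary
statistics; at ~400 beats per session the choice is negligible. ARV
excludes pairs spanning artifact-masked gaps rather than bridging them: a
bridged pair is not a true consecutive beat pair. ΔSBP is max−min over the
analysed window.

**VIM.** The exponent `x` is estimated by nonlinear least squares on
`sd = a·mean^x` across participants (`scipy.optimize.least_squares`,
initialised at `a = median(sd)/median(mean)`, `x = 1`, `x` bounded to
[−5, 5], tolerances 1e−10); VIM is then `sd/mean^x · M^x` with `M` the
grand mean of the per-participant means, and no further rescaling. By
default the fit is done per session across participants (each session is a
sample in its own right); a pooled fit over both sessions is available via
configuration — with two sessions of the same cohort the two scopes differ
little, and neither is canonical. On an exact power-law cohort VIM is
constant, so its correlation with mean BP is degenerate; the acceptance
computation reports it as 0 when the relative VIM spread is below 1e−9
(pure floating-point noise).

## Reliability statistics

The paired t is `mean(d)/(sd(d)/√n)` with d = session2 − session1 and a
two-sided p from t(n−1). Degenerate inputs: all differences zero → t=0,
p=1 by convention; zero difference variance with nonzero mean → ±∞ flagged.

**ICC.** Default form is ICC(2,1) — two-way random effects, absolute
agreement, single measurement — the standard choice for test-retest with a
fixed device, computed from the two-way ANOVA of the n×2 table:

```
ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E))
```

with the Satterthwaite/F-based 95% CI (McGraw & Wong). ICC(3,1)
(consistency) and ICC(1,1) (one-way) are available via `icc_form` and the
choice is recorded in the output metadata. The implementation is
independent of `pingouin`, which the test suite uses as an oracle (point
estimates agree to 1e−9, CIs to its printed precision). Zero-variance
tables yield a flagged undefined result; pathological tables with no
between-subject variance collapse the Satterthwaite degrees of freedom and
the CI falls back to the uninformative [−1, 1]. Simulation tests at n=111
show mean absolute bias ≤0.03 and CI coverage within 95%±4% across true
ICC ∈ {.5, .7, .87, .95}.

**SEM and SRD.** `SEM = sd(d)/√n`. The default `SRD = SEM·√2` is the SD of
the paired differences rescaled to single-measurement scale; the
conventional smallest real difference `1.96·√2·SEM` is available via
`srd_factor="conventional"`. The √2 default matches the internal
arithmetic of published beat-to-beat BPV reliability tables, which is the
convention this pipeline mirrors; users wanting the 95%-confidence
interpretation of SRD should switch the flag. SEM% and SRD% divide by the
grand mean of the two session means, using the unrounded SRD.

**Bland–Altman** bias is `mean(d)` with limits `bias ± 1.96·sd(d)`.
Report tables round to 2 decimals (round-half-even) at serialization only.

## Pipeline conventions

Sessions longer than the analysis `window` (default 420 s) are truncated to
the first `window` seconds of samples before masking; shorter sessions are
analysed whole with a logged warning. Participants with a missing or
QC-rejected session are dropped from the paired analysis and logged, and
the run aborts if more than `max_rejected_fraction` (default 50%) of
sessions fail QC. Strata with fewer than 3 complete pairs produce a
flagged, statistics-free row. All outputs (metrics table, session-means
table, overall and stratified reliability reports, QC sidecars, run
metadata with config and seed) are byte-identical under identical
config+seed.

## Problem sizes used in tests and the acceptance script

Statistical calibration uses 200 replicates of n=111 metric-level cohorts
(ICC grid) and 1000 replicates for the paired-t type-I error; closed-form
convergence checks use 1e5-beat sequences; waveform round trips use one
420 s recording per parameterisation and 60 s recordings elsewhere; the QC
accounting batch uses 121 recordings of 30 s with 10 corrupted past the
10% rule. These sizes make every check sharp at the stated tolerances
while keeping the default suite fast.

## Known limitations

- The delineator assumes an already-calibrated pressure signal; no
  recalibration, pulse-wave analysis, or notch-timing estimation.
- Artifact rules are amplitude/slope heuristics; subtle artifacts
  (calibration steps inside physiologic bounds, slow drifts) pass QC.
- The HR computation is interval-based; device-reported HR channels, if
  present, are ignored.
- VIM depends on the cohort used for the exponent fit; values are not
  comparable across cohorts fitted separately.
- Frequency-domain, time-weighted and circadian BPV indices are out of
  scope.
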