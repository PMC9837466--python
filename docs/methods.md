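# Methods

`simonstop` simulates and analyzes a combined Simon / stop-signal experiment:
a letter (A or B) presented left or right of fixation maps to a left- or
right-hand key press irrespective of its side (congruent when side and
response hand coincide), and on 23% of trials the letter turns red after an
adaptively tracked stop-signal delay (SSD), requiring the response to be
withheld. The package provides the task design, a generative behavioral and
EEG model with known ground truth, the preprocessing chain, a residue
iteration decomposition (RIDE) of single-trial ERPs, and the within-subject
statistical battery. This note documents the models, the defaults and why
they were chosen, and what the synthetic experiments can and cannot show.

## Task design and staircase

A session is 9 blocks of 80 go + 24 stop trials (936 trials; 720 go / 216
stop), with congruent and incongruent trials balanced within each trial type
— also within each block, which the session-level counts do not forbid and
which stabilizes per-block condition estimates. The SSD staircase starts at
250 ms and moves one 50 ms step per stop trial (up after a correct rejection,
down after a failure to stop), clamped to [50, 1000] ms; this one-up/one-down
rule tracks the SSD at which stopping succeeds on half of the stop trials.
A speed-up prompt fires when the mean RT of the last 50 responded trials is
strictly below 450 ms; only responded trials enter the window (misses have no
RT), and the prompt is a logged event with no behavioral consequence in the
model. There is a single global staircase, not one per congruency.

## Race model

Behavior follows the independent horse-race model: an ex-Gaussian go
finishing time races a Gaussian stop-process latency that starts at the SSD;
the response escapes iff the go process finishes first. Defaults are
calibrated to a healthy adult cohort on this task:

| parameter | congruent | incongruent | unit |
|---|---|---|---|
| go RT mean (mu + tau) | 507 | 532 | ms |
| go RT SD (sqrt(sigma² + tau²)) | 169 | 162 | ms |
| ex-Gaussian tau | 60 | 60 | ms |
| stop latency mean | 266 | 277 | ms |
| stop latency SD (per trial) | 30 | 30 | ms |
| choice-error probability | 0.028 | 0.063 | — |
| miss probability | 0.005 | 0.005 | — |
| trigger-failure probability | 0 | 0 | — |

The exponential share tau = 60 ms keeps the RT distribution's skew modest.
This matters because the mean-method SSRT estimator (mean correct go RT minus
mean realized SSD) inherits a positive bias roughly equal to the go
distribution's mean-median gap: the staircase equilibrates near the median of
(go RT − stop latency), while the estimator uses the mean. Heavier tails
(tau well above ~100 ms) would make the estimator overshoot the implanted
stop latencies by tens of milliseconds. Per-trial stop-latency variability
(SD 30 ms) is a free parameter; the data constrain only its mean.

One structural caveat the simulation makes explicit: with a single global
staircase, the realized SSDs on congruent and incongruent stop trials are
identically distributed, so per-congruency mean-method SSRT estimates differ
by the full go-RT congruency cost (~25 ms) rather than by the implanted
stop-latency difference (11 ms). Group means still land within ±10 ms of the
implanted 266/277 ms values, and the ordering (incongruent slower) is stable,
but the split between the two conditions is partly an estimator artifact.

## Synthetic EEG

Epochs span −2000..2000 ms around target onset at 256 Hz, on a 10-channel
montage (Fz, FCz, Cz, C3, C4, Pz, P7, P8, O1, O2) that includes all
quantification electrodes. Only correct go responses and correct rejections
receive epochs. Each epoch is a sum of Hann-lobe components:

- P1 (80–140 ms, +3 μV) and N1 (140–200 ms, −4 μV) over P7/P8 with
  occipital spread;
- N2 (260–350 ms, −3 μV) frontocentral;
- C (390–790 ms, +5 μV peak) with frontocentral-plus-parietal topography,
  shifted per trial by a Gaussian latency offset (SD 50 ms, clipped at 3 SD,
  rounded to samples).

Condition multipliers scale each component per (response, congruency) cell;
the default map boosts C by 20% (+1 μV at the peak channel FCz) on
incongruent stop trials only — an implanted congruency × response
interaction specific to stopping. White Gaussian sensor noise at 5 μV SD is
added last (1/f-shaped noise is available). Ground truth (per-trial C
latencies and amplitudes) is returned on a separate object that the analysis
path never reads.

What the generator does **not** emulate: ocular/muscle artifacts, volume
conduction from realistic sources, autocorrelated background EEG (unless the
1/f option is chosen), latency variability of the S-family, trial-to-trial
amplitude variability, or any response-locked (R) component stream separate
from C. Passing recovery tests therefore demonstrate correctness of the
algorithms under the stated generative model, not performance on real
recordings.

## Preprocessing

Canonical order: band-pass filter → resample → average reference → epoch →
artifact rejection → baseline. Filtering is a zero-phase (forward-backward)
Butterworth band-pass of design order 8 (0.5–40 Hz) plus a 50 Hz notch
(Q = 30); zero-phase application avoids latency distortion of ERP components.
Resampling is polyphase with anti-aliasing (500 → 256 Hz exactly 64/125);
upsampling is refused. Rejection flags (never deletes) trials in which any
channel, within −200..200 ms, has a sample strictly exceeding ±100 μV or a
contiguous stretch of ≥100 ms with peak-to-peak amplitude strictly below
0.5 μV ("activity" in the flatline rule is read as peak-to-peak within the
stretch). Baseline subtracts the −200..0 ms mean per trial and channel. An
independent-component artifact-removal step and bad-channel interpolation
would precede rejection for real recordings; the synthetic generator
produces neither artifact class, so both are extension points for the
BrainVision/EDF entry paths rather than implemented stages.

## RIDE decomposition

Each subject × (response × congruency) cell (at least 10 kept trials) is
decomposed into a stimulus-locked S-cluster (window −200..600 ms) and a
latency-variable C-cluster (window 200..800 ms); the R-cluster is not
modeled, so response-locked variance is absorbed by C. The iteration:

1. initialize per-trial C latencies by cross-correlating each trial with the
   stimulus-locked average restricted to the C window (shift search
   ±300 ms, channel-summed scores, ties broken toward zero shift; the
   template's window edges carry a 10% cosine taper);
2. S-step: S = pointwise median over trials of (trial − C shifted by the
   trial's latency), on the S window;
3. C-step: C = pointwise median over trials of (trial − S) back-aligned by
   the trial's latency, on the C window;
4. re-estimate latencies against the updated C; re-center them to median 0;
   repeat until no latency moves by more than 1 sample or 10 outer
   iterations.

Numerical choices: steps 2–3 are alternated up to 4 times per latency
update. Inside the S/C window overlap (200..600 ms) the split between the
two clusters relaxes geometrically (each pass transfers a latency-smeared
residue between clusters), and the relaxation continues across outer
iterations through the warm-started waveforms, so roughly 40 cumulative
passes reach a stationary split at far lower cost than running each outer
step to convergence. Waveform extraction uses hard (rectangular) windows so
that in the degenerate noiseless, zero-jitter case S + C reproduces the
stimulus-locked average exactly; the taper is applied only to the
cross-correlation template. Shifting zero-pads outside the epoch. The
iteration runs in float32 (the residual identity is always reported in
float64; set `RideConfig(dtype="float64")` for strict reproducibility
checks). Non-convergence within 10 iterations returns the last iterate with
`converged=False` and a warning — with hundreds of noisy trials a handful of
latencies keep oscillating by ±2 samples without affecting the waveforms.

Known limitations: single-trial alignment overfits noise (a Woody-filter
effect), inflating the recovered C peak by ~10–15% at the default SNR, and
small cells (a few dozen trials) give noticeably noisier latency estimates.
Because stop cells hold roughly four times fewer trials than go cells,
alignment noise and cross-cluster leak differ between response levels, which
can surface as a spurious "response" main effect on quantified C amplitudes;
the congruency and interaction contrasts compare cells of matched size and
are unaffected. The decomposition does not attempt to reproduce any
particular toolbox's numerics.

## Quantification and statistics

Components are mean amplitudes in fixed windows at fixed electrodes: P1
(100–120 ms) and N1 (160–180 ms) at P7/P8 on the S-cluster, N2 (290–320 ms)
at FCz on the S-cluster, P3 (530–650 ms) at FCz and at Pz (analyzed
separately, not as an electrode factor) on the C-cluster.

The 2×2 within-subject ANOVA decomposes sums of squares per effect against
its own subject-by-effect error term (df = 1, n−1); with two levels per
factor sphericity is trivial (Greenhouse–Geisser epsilon ≡ 1) and each F
equals the squared paired t on the corresponding contrast, which the tests
verify. Partial eta squared is SS_effect / (SS_effect + SS_error).

The interaction is validated with the BIC approximation to the posterior
null probability: ΔBIC = n·ln(SSE1/SSE0) + k·ln(n) with SSE0 = SS_error +
SS_effect, SSE1 = SS_error, k = 1 extra parameter; BF01 = exp(ΔBIC/2) and
P(H0|D) = BF01/(1+BF01). `n` is the number of subjects (the within-subject
contrast convention); because conventions differ on whether n should count
observations, the choice is a parameter and is recorded in the result.
Interpretation bands: <0.5 favors the alternative; 0.5–0.75 weak, 0.75–0.95
positive, 0.95–0.99 strong evidence for the null.

Post hocs are paired t tests when a Kolmogorov–Smirnov check on the paired
differences is compatible with normality, Wilcoxon signed-rank otherwise
(exact null when feasible). Sensor-level sign-flip permutation tests (2500
permutations, statistic = mean paired difference; a t option exists) give
per-channel p = (#{|perm| ≥ |obs|}+1)/(n_perm+1); no across-channel
multiple-comparison correction is applied, and no source localization is
attempted.

## Problem sizes in the test suite

The statistical recovery experiments choose sizes that keep the default
suite fast while preserving the effects under test: behavioral criteria use
24 replicate cohorts of 27 subjects with full 936-trial sessions; RIDE
recovery uses one full-session subject's largest cell (~350 trials); the
end-to-end interaction-recovery experiment uses 25 replicate cohorts of 27
subjects with 3-block (312-trial) sessions, since the implanted 1 μV boost
is detected at the subject level long before trial counts matter; null
calibration of the interaction test uses 200 replicate cohort tables at the
stage that feeds the ANOVA, where the pipeline's randomness has been reduced
to per-cell amplitudes. Subject-level amplitudes and F/p/η² values from the
human study are not reproducible from a simulation and are deliberately not
targeted; the recovery and calibration properties stand in for them.
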