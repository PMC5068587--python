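# Methods

This package implements a goal-conflict EEG biomarker pipeline around the
stop-signal task (SST), together with a synthetic-data generator that stands
in for human recordings so that every stage can be tested end to end.  This
note documents the models, the parameters that matter, the numerical
choices, and what the synthetic results do and do not show.

## The task model

The SST presents a left/right arrow on every trial; on one trial in four an
auditory stop signal follows the arrow at a stop-signal delay (SSD) and the
participant must withhold the response.  Three staircases deliver the SSDs:

* **short** = 20% and **long** = 80% of the mean Go reaction time over the
  previous 16 Go trials (all available Go RTs during warm-up; the pretest
  Go RT before any have accrued);
* **medium** starts at 45% of the pretest (pure-Go) reaction time and moves
  +30 ms after each successful stop and −30 ms after each failure, clamped
  so it never comes within 50 ms of either other staircase.

The medium staircase therefore tracks the ~50% inhibition point, where
stopping and going are in maximal conflict.  Schedule construction places
exactly one stop trial, at a seeded uniformly random position, in each
consecutive non-overlapping window of four trials; arrows are balanced
left/right per block; staircase labels cycle through a per-session random
permutation of (short, medium, long) that rotates across blocks, giving
exactly 32 stop trials per staircase over a 3 × 128-trial session and
within-block counts differing by at most one.

Two points in the staircase implementation deserve note.  First, when a
±30 ms step would violate the 50 ms separation, the SSD moves to the nearest
admissible value exactly 50 ms from the conflicting staircase on the side
where the proposal fell; the admissibility comparison carries a 1e-9 ms
tolerance because the boundary candidate is *exactly* 50 ms away and must
not be rejected by floating-point rounding.  Second, a one-up/one-down
staircase with a reflecting lower boundary has mean success rate strictly
below ½ — summing the detailed-balance relations gives
S = ½ − π(bottom)(1 − p(bottom))/2, where π(bottom) is the stationary
occupancy of the boundary state.  With the separation clamp ~50 ms below
the tracking point, the designed operating point is ~48–49% inhibition, not
exactly 50%, which matches the published behavioural tables.

## The responder model

Behaviour is generated by an independent horse-race: an ex-Gaussian Go
process (mu, sigma, tau; truncated at 150 ms) races a Gaussian stop process
(truncated at 50 ms) started at the SSD; the stop wins iff
SSD + SSRT < Go RT.  On a small fraction of stop trials the stop process
fails to launch entirely (a *trigger failure*) and the response is emitted
regardless of delay.

Defaults — go 395/92/30 ms (mean 425 ms), SSRT 227 (45) ms, trigger-failure
rate 0.08, choice-error rate 0.02 — were calibrated jointly to the
behavioural summaries the task is known to produce: mean Go RT ~425 ms,
SSRT estimate (median Go RT − mean medium SSD) ~230–240 ms, and inhibition
rates of ~79% / ~49% / ~9% on the short/medium/long staircases.  The
trigger-failure component is not optional ornamentation: a pure race that
fails 21% of the time at the short delay (0.2 × RT) is so noisy that it
would succeed far more than 9% of the time at the long delay.  A ~8%
trigger-failure rate with a steeper core race is the only configuration in
this family consistent with all three staircase operating points, and it is
the standard account of such data in the stop-signal literature.
A simulated 100-participant cohort reproduces 78/48/8% inhibition, Go RT
425 ms and SSRT estimate ~231 ms.

## The EEG signal model

Continuous EEG (128 Hz; Fp1, F7, F3, Fz, F4, F8; µV) is synthesized as

    pink noise (20 µV RMS, 1/f amplitude)
  + 50 Hz mains sinusoid (2 µV, random phase per channel)
  + eye blinks (Poisson, 8/min; fixed 300 ms biphasic template, 120 µV peak
    at Fp1, propagated at fixed per-channel scales 0.30–0.45)
  + conflict injection (below)

band-passed 1–36 Hz (4th-order Butterworth, zero-phase).  The blink
template is a large positive lobe followed by a smaller negative rebound;
its exact shape is arbitrary but fixed, so template-recovery tests have
ground truth.

The conflict injection is the carrier of the biomarker: on *medium-SSD stop
trials only*, a 4–12 Hz band-limited noise burst is added at F8 during the
1 s analysis window (0.25 s before the stop signal to 0.75 s after), with a
Hanning temporal envelope so the injected power concentrates where the
analysis taper is most sensitive.  Within the band the amplitude spectrum
follows a Hann profile (zero at 4 and 12 Hz, maximal mid-band), giving the
injected rhythmicity an inverted-U spectral signature rather than a flat
plateau; a flat profile would be invisible to the zero-sum frequency
contrasts used downstream.  The burst amplitude (default 8 µV RMS before
enveloping) is multiplied by a per-block profile (default 1, 0, 1 —
mirroring the observation that the conflict signature appears in blocks 1
and 3 but not 2; the disappearance itself is not modelled), a per-group
drug multiplier (default 1.0 placebo, 0.3 for each anxiolytic), and an
optional linear coupling to the participant's simulated neuroticism
z-score.  Nothing about this injection is a neural model: it is a
phenomenological construction whose sole purpose is to give downstream
stages a known ground truth with roughly realistic single-trial SNR.  The
published record does not constrain single-trial amplitude, so the
noise/injection scales are package choices, fixed once: at these defaults a
single participant's block-1 conflict contrast is detectable but noisy, and
cohorts of ~8–10 per group separate placebo from a 0.3-multiplier drug
group in the majority of runs.

Traits (neuroticism 9 (6), trait anxiety 38 (8), BIS 21 (8)) are Gaussian,
rounded and clipped to instrument ranges.  All randomness descends from one
master seed through named substreams (numpy `SeedSequence.spawn`), so any
participant regenerates independently and identical configs are
bit-identical.

## Preprocessing

1. **Three-point running mean** y[n] = (x[n−1]+x[n]+x[n+1])/3, endpoints
   replicated.  Response (1 + 2cos(2πf/fs))/3; first null at fs/3 ≈ 43 Hz,
   suppressing residual mains leakage.
2. **Blink removal.**  Blinks are detected on Fp1 by a threshold-plus-peak
   detector (50 µV, minimum half-template separation; overlapping windows
   merged); a template is built by peak-aligned averaging of the detected
   Fp1 segments, peak-normalized; then for every blink window and channel
   the closed-form least-squares scale b* = ⟨ch, t⟩/⟨t, t⟩ is subtracted.
   Channels orthogonal to the template are untouched; exact template
   multiples are removed completely.  In the noise-free fixture >99% of
   propagated blink power is removed at F8.
3. **Artifact rejection.**  Samples exceeding ±150 µV, padded by 0.1 s, are
   set to missing (NaN) with the mask retained.  This automates what was
   historically a manual pass; thresholds sit in the run config.

Missingness propagates: any epoch containing a missing sample is excluded
whole rather than imputed.

## Spectral extraction and the conflict contrast

Each stop trial yields a 1 s, 128-sample epoch starting 0.25 s before the
stop signal, and a matched go epoch taken from the nearest preceding go
trial (nearest following if the block has none before), positioned at that
go trial's arrow onset + the stop trial's SSD − 0.25 s.  Epochs are
Hanning-tapered and Fourier transformed; power at the 1 Hz bins 4–12 Hz is
|X(f)|² · 2/N², floored at 1e-12 before the natural log (the constants and
the log base cancel in every contrast; they are fixed for
reproducibility).  Log power — log first, then averaged across trials —
is averaged into cells keyed by (participant, block, channel, trial type,
SSD level, frequency); empty cells are explicitly missing, never zero.

The biomarker is the quadratic-SSD contrast of stop-specific power:

    D_level(f)  =  StopPower − GoPower          (per SSD level)
    GCSR(f)     =  D_medium(f) − (D_short(f) + D_long(f)) / 2

computed only where all six contributing cells exist.  The (−½, 1, −½)
weighting makes one GCSR unit equal one log-power unit of conflict-specific
excess; the integer-weight (−1, 2, −1) version used inside test statistics
differs only by a factor of 2.

## Inference

Orthogonal polynomial contrast weights are generated by exact Gram–Schmidt
over the rationals and scaled to the smallest integer vectors (reproducing
the classical tables).  A participant/block/channel composite score is the
triple product contrast Σ cells · w_stop−go · w_SSD-quadratic · w_frequency
with the frequency polynomial of order 1–3.  On these single-df scores:

* within-group: one-sample t reported as F = t² with df (1, n−1);
* between groups: one-way ANOVA, df (k−1, N−k);
* personality: Pearson r per block × frequency, uncorrected two-sided p;
* frequency selectivity: forward stepwise regression of the trait on the
  nine per-frequency GCSR values, entering the largest-F-change predictor
  while its nested-model p < 0.05, no removal step.

All p-values are uncorrected by design; the stepwise entry operates at the
familywise rate of nine uncorrected tests (~37% under the null), which the
tests document rather than correct.  The omnibus multi-way
repeated-measures machinery behind the original analyses is deliberately
reduced to these single-df contrasts — that is the level at which such
results are actually reported — and the five-channel topography is provided
descriptively (per-channel GCSR means and the F8-minus-others gradient),
not as a five-way interaction F.

## Problem sizes and test design

The package's own test suite runs everything at sizes a laptop handles:
staircase-convergence and null-recovery checks use 100 simulated
participants; amplitude-ladder and channel-specificity checks use cohorts
of 10–12 with single-block sessions; the type-I calibration of the
one-sample contrast test uses 10,000 null cohorts of n = 34 with white-noise
epochs pushed through the real spectral path at reduced per-cell epoch
counts (two per cell), with the vectorized score contraction verified
in-test against the module's own `contrast_score`.  Measured calibration is
~0.05 at α = 0.05.

## What passing tests do and do not show

The generator reproduces the *structure* of the study conditions — trial
counts, staircase dynamics, behavioural operating points, channel/block/
frequency signatures, group layout (8/9/9/8) and trait distributions — but
not human EEG: no cortical dynamics, no RT autocorrelation or fatigue, no
pharmacokinetics (drugs are a pure amplitude multiplier), no mechanism for
the block-2 disappearance, and blink timing independent of task events.
Passing tests therefore certify that the pipeline recovers what was
injected under realistic noise, is calibrated under the null, and is
faithful to the documented analysis conventions — not that the biomarker
itself would behave this way in new human data.

## Known limitations

* The matched-go window requires an adjacent go trial; stop trials without
  one (impossible under the default schedule, possible under custom ones)
  are excluded and logged.
* The EDF writer covers only this pipeline's needs (continuous recording,
  common integer sampling rate, 16-bit samples, 1 s records); files are
  read back with an independent EDF implementation in tests.
* `race_outcome` is deterministic given its three latencies; all
  stochasticity lives in the samplers, which keeps the race auditable.
* With very short blocks (tests use down to 32 trials) some SSD levels can
  end up with no retained epochs, in which case the conflict contrast for
  that participant/block is missing by construction.
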