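# Methods

This note documents the models and procedures implemented in `photopipe`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic verification studies do and do not demonstrate.

## The measurement model

Dual-wavelength fiber photometry records two demodulated fluorescence
channels from one fiber: a 465 nm "signal" channel that excites the
sensor's activity-dependent fluorescence (GCaMP calcium indicators, GRAB
neurotransmitter sensors), and a 405 nm "isosbestic" channel at which the
sensor fluoresces independently of ligand binding. Motion of the fiber or
tissue, photobleaching, and hemodynamic absorption affect both channels;
sensor activity affects only the 465 nm channel. The synthetic generator
(`photopipe.simulate`) encodes exactly this structure:

    F465(t) = B465 · (1 + Σᵢ aᵢ e^(−t/τᵢ)) + Σₑ Aₑ k(t − tₑ) + g465 m(t) + ε465(t)
    F405(t) = B405 · (1 + Σᵢ a'ᵢ e^(−t/τ'ᵢ))                + g405 m(t) + ε405(t)

with per-channel double-exponential bleaching trends, Gaussian-bump
motion `m(t)` shared across channels with per-channel gains near one,
sensor transients only in the 465 channel, and independent additive
noise. Each channel's noise has a white component and, optionally, a slow
Ornstein–Uhlenbeck component (`noise_slow_sd_*`, correlation time
`noise_slow_tau_s`, default off) representing physiological state
fluctuations — arousal, locomotion, hemodynamics — whose timescale
(tens of seconds) sits between shot noise and bleaching.

The transient kernel is a unit-peak difference of exponentials,
`k(t) = (1 − e^(−t/τ_r)) e^(−t/τ_d)` rescaled to max 1, with defaults
τ_r = 0.2 s, τ_d = 1.5 s for calcium-indicator dynamics and τ_r = 0.5 s,
τ_d = 4 s for the slower neurotransmitter sensors. Its analytic peak time
τ_r·ln(1 + τ_d/τ_r) is exposed (`kernel_peak_time`) and used as an
oracle in tests. Transient amplitude is a tabulated monotone
non-decreasing function of stimulus intensity (`AmplitudeMap`), linearly
interpolated; tone intensities (dB) and shock intensities (mA) live on
different scales, so maps are per-event-label. The default tables
saturate with intensity, as sensor responses do; their absolute scale
(peak raw amplitudes of roughly 0.5–6 units on a baseline of 100, i.e.
0.5–6% dF/F) is typical of fiber-photometry bulk signals.

Every injected transient (time, amplitude, analytic peak time) and every
motion event is returned as `GroundTruth`, which is what makes the
downstream stages verifiable.

## Behavioral protocols

`photopipe.protocols` renders the standard session designs of a
trace-fear-conditioning (TFC) study into event schedules: a 180 s
pre-exposure followed by trials of a 20 s tone, a 20 s stimulus-free
trace interval, and a 2 s shock, with 120 or 180 s inter-trial intervals
and a 180 s post-period (3 trials for pharmacology-scale sessions, 10 for
photometry); tone-test (10 × 20 s tones, 140 s ITI) and extinction
(20 tones, 90 s ITI) sessions; a shock response curve of three blocks of
seven 1 s shocks at {0, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8} mA with 30 s ITIs;
a tone response curve of 25 tones at {55…95} dB; a signaled/unsignaled
variant in which a pseudorandom half of the shocks arrive without a
preceding tone (the silent 40 s replaces tone + trace, so trial length is
unchanged); and an hour-long chemogenetic session with the injection
marker at 600 s. Pseudorandom intensity orders are rejection-sampled,
seeded, under the stated constraints (no ascending or descending block;
no two blocks alike). ITI structure within a session is a parameter
(scalar or per-trial sequence) rather than a guess, since protocols vary
on this point.

## Normalization

Two methods, deliberately kept apart by a method tag so percent dF/F and
z-units are never pooled:

**Isosbestic regression.** An ordinary least-squares fit over the whole
recording predicts F465 from F405; dF/F(t) = 100 × (F465 − pred)/pred.
Fitting the entire session (rather than per trial) is required for the
artifact-screening step, which compares each trial against session-wide
robust statistics. The fit uses centered normal equations; a constant
405 channel raises a singular-fit error naming the channel. A safety
floor (default 1% of the mean prediction) refuses the division when the
prediction approaches zero on deeply bleached tails, rather than
silently emitting huge values.

The correction removes exactly those disturbances that are
channel-proportional: if bleaching and motion enter both channels in the
ratio of their baselines, the background satisfies F465 = c·F405 and the
residual is pure sensor signal. Differential bleaching (different time
constants per channel) breaks this premise — which is why hour-long
sessions use the second method instead.

**Baseline z-scoring.** For long pharmacology sessions,
dF/F(t) = (F465(t) − μ_base)/σ_base with moments taken over a baseline
window, by default the final 5 min before the injection. The 405 channel
is ignored. The window must be ≥ 10 s and inside the recording;
zero baseline SD is an error.

`bin_timecourse` averages a trace into consecutive half-open bins,
dropping (and recording) a final partial bin.

## Trial segmentation and the peak statistic

Trials are extracted on half-open sample windows [t−pre, t+post) around
each alignment event, with event times snapped to the nearest sample at
or after the nominal time. Each row is re-baselined by subtracting its
mean over a per-trial baseline window: 20 s pre-tone for conditioning
sessions, 2 s pre-event for stimulus-curve sessions (selected by protocol
name, overridable). Trials whose window leaves the recording are flagged,
never silently dropped.

Artifact screening excludes a trial iff some sample in its window has
robust z-scores (median/MAD over the whole session) above threshold in
**both** raw channels with matching sign — the signature of a shared
motion deflection, which a genuine 465-only transient cannot produce. The
threshold defaults to z = 8; it is a judgment call (what counts as a
"major" artifact is not standardized), so it is configurable and recorded
in output provenance. The operating-point study
(`artifact_detector_operating_point`) characterizes the rule on
trend-free sessions; on strongly trending raw channels the session MAD is
inflated by the trend and the rule becomes conservative — a known
limitation; detrend or restrict the session span if that regime matters.

The scalar response statistic is the signed maximum of the re-baselined
dF/F in the first 2 s of the stimulus period ("peak"), paired with the
same statistic over the 2 s before the event for pre/post comparisons.
Signed maximum, not maximum absolute value: the responses of interest are
increases. Both the normalized (primary) and raw peaks can be computed;
excluded trials contribute no rows to any response table.

Freezing enters only as a pre-scored long table (subject, trial, phase,
percent freezing); `phase_freezing_scores` averages it across trials per
subject and phase and refuses tables with missing phases.

## Statistics

Subjects are always the error stratum: trial-level values are averaged to
one score per subject and condition before testing. All tests are
two-sided at α = 0.05.

- Paired/unpaired t-tests with classical formulas; zero-variance
  differences raise an error rather than returning ±∞.
- One-way repeated-measures ANOVA by the standard partition
  (SS_condition, SS_subject, SS_error) with F = MS_cond/MS_error and
  df (k−1, (k−1)(n−1)). No sphericity correction by default — the
  uncorrected df are what small-cohort photometry studies convention-
  ally report — with Greenhouse–Geisser available as an option.
- Two-way mixed (split-plot) ANOVA, one between-subjects and one
  within-subjects factor: the between effect is tested against
  subjects-within-groups (df N−a), the within and interaction effects
  against the within-subject residual (df (b−1)(N−a)). Unequal group
  sizes are handled by the classical weighted-means partition, which
  coincides with Type III sums of squares for balanced groups and
  matches the reference implementation (pingouin) exactly in both cases;
  the canonical cohort layouts give df (4,12) for 5 levels × 4 subjects
  and interaction df (2,14) for {4,5} subjects × 3 days.
- Bonferroni post hocs over an explicitly enumerated family —
  p_adj = min(1, m·p_raw) — with no silent all-pairs default, because
  the family is an analysis decision, not a data property.
- Dose-response summaries report per-intensity mean ± SEM across
  subjects (subject means first); SEM is emitted as missing for n = 1.

The ANOVA cores operate on subject × level matrices (~100 µs per call),
which is what makes the 10,000-replicate calibration studies cheap; the
long-table front ends validate completeness and aggregate trials.

## Verification studies and problem sizes

`photopipe.experiments` packages the simulation studies; the acceptance
script and test suite run them at these sizes, chosen to give tight
Monte-Carlo error at interactive runtimes on one CPU:

- **OLS oracle**: 1,000 random small recordings against a from-scratch
  normal-equations solve (agreement ~1e-9 relative).
- **Amplitude recovery**: noiseless sessions with channel-proportional
  bleach and motion, injected amplitudes 0.05–5.0 (two orders of
  magnitude); recovered peak dF/F vs. the symbolic oracle
  100·A·k(t)/pred(t), observed error < 1%, tolerance 5% to cover the
  small whole-session regression bias a transient induces.
- **Detector operating point**: 100 sessions × 8 trials, two trials with
  10-robust-SD shared bumps, two with equally large 465-only transients,
  four clean, on trend-free backgrounds at 60 Hz.
- **Type-I calibration**: 10,000 Gaussian-null replicates per statistic
  with cohort sizes drawn from 4–11 subjects (3–7 within levels),
  rejection rates within 0.05 ± 0.01.
- **Chemogenetic power study**: cohorts of 5 vehicle + 5 CNO subjects,
  3600 s sessions, injection at 600 s, z-scored to the last 5 baseline
  minutes, five 600 s post-injection bins, mixed ANOVA on the
  treatment × time interaction. 100 replicates for power (≈1.0 at the
  default effect size, a sustained 10%-of-baseline elevation ramping in
  ~10 min after injection), 500–1,000 for the null rate with the slow
  CNO component disabled (≈0.04).

The hour-session study conditions deserve a note. Long recordings are
made at low LED power, so their bleaching is mild, and their bin-scale
variability is dominated by slow physiological fluctuations; the cohort
study therefore uses gentle bleach plus an OU component (SD 3% of
baseline, τ = 30 s), under which 10-min bin means are nearly independent
and the split-plot F is well calibrated. The regime matters: with strong
bleaching and white noise only, the *estimated* baseline SD (a 5-min
window) scales a large deterministic trend differently per subject,
producing rank-one subject × time errors that inflate the uncorrected
interaction F well above its nominal level. That sensitivity is a real
property of baseline z-scoring on trending signals, not an artifact of
the simulation — with strongly bleaching sessions, use the
Greenhouse–Geisser option or a longer baseline.

Sessions are simulated at 10 Hz in the hour-long studies and 60–120 Hz
elsewhere; the sampling rate is a generator parameter and none of the
statistics depend on it beyond Monte-Carlo precision.

## What the synthetic studies do not show

The generator emulates the structure of real recordings, not their full
messiness: no hemodynamic absorption spectra, no lock-in demodulation
artifacts, no spike-level dynamics beneath the kernel, no receptor
pharmacology beyond an onset-latency ramp, no video-based freezing
(freezing is consumed pre-scored). Passing tests demonstrate that the
pipeline computes its definitions correctly and behaves as designed under
the stated noise models; they do not certify performance on any
particular real dataset, where kernel shapes, artifact morphology and
bleaching kinetics must be expected to differ.

## Determinism

Every stochastic component flows from integer seeds through
`numpy.random.SeedSequence`; identical configuration (including seed)
reproduces bit-identical recordings, and a pipeline manifest re-run
reproduces byte-identical output files (verified by SHA-256 in the
manifest). No stage reads a clock or an unseeded generator.
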