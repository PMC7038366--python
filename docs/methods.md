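# Methods

This note documents the models, parameters and numerical choices behind
`canegait`: the event semantics the detectors implement, the synthetic
signal model and its parameter draws, and the statistical stage. Everything
stated here is computed by the test suite or by `scripts/acceptance.py`;
nothing is asserted from data the package does not generate itself.

## 1. Sensing model and event semantics

A cane-mounted strain-gauge bridge measures axial load in raw ADC counts at
a nominal 231 Hz; a 9-axis IMU on the same cane supplies angular velocity,
of which the mediolateral (x) axis — the anteroposterior (AP) velocity —
carries the gait signal. A shank-mounted IMU sampling its AP velocity at
100 Hz serves as an independent reference stream.

Gait cycle events:

| event | cane signature | shank signature |
|---|---|---|
| IC (initial contact) | positive strain zero-crossing | AP-velocity valley after PS |
| TC (terminal contact) | negative strain zero-crossing | valley before PS |
| PS (peak swing) | AP-velocity maximum in swing | AP-velocity maximum |
| EC (end of contact) | next positive strain crossing | next valley (= next IC) |

During continuous walking the EC of one cycle *is* the IC of the next; the
segmenters preserve this identity exactly (equal float timestamps).

### Preprocessing

Both streams are low-passed with 6th-order Butterworth filters — 4 Hz for
strain, 8 Hz for gyroscope channels — applied forward-backward
(`scipy.signal.filtfilt`). Zero-phase filtering is a deliberate choice: a
causal filter would delay events by a condition-dependent group lag and
corrupt the IC-difference feature, whereas the zero-phase magnitude
response (the squared Butterworth, −6 dB at the cutoff) moves a locally
symmetric extremum by nothing and a locally odd zero-crossing by very
little. Event-timing fidelity under this filter dominates most of the
design decisions below.

Raw strain counts are unsigned with an arbitrary bridge offset.
`baseline_correct` estimates the unloaded-phase level as the median of the
densest low-value cluster (a histogram mode inside the lowest 60% of
samples — robust against both the loading bumps above and the brief
load-transfer undershoots below) and subtracts that level *plus a rest
offset of 2 counts*, so the unloaded phase sits slightly below zero and
loading onset/offset produce clean positive/negative zero-crossings. The
operation is a pure shift and is idempotent. The rest offset is a stated
assumption: zero-crossing detection is undefined if the unloaded phase sits
exactly at zero.

### Zero-crossing detection

Crossings use asymmetric hysteresis: a positive crossing requires the
signal to travel from below −h_lo (the unloaded band, h_lo = max(1 count,
3× the unloaded-phase noise spread)) to above +h_hi (clearly loaded,
h_hi = max(4 counts, 3·h_lo)); the crossing time is the zero crossing of
that rising segment, linearly interpolated for sub-sample resolution. The
asymmetry matters: the filter ripple that flanks large loading bumps can
reach ≈1–2 counts and would chatter through a symmetric ±1-count detector,
but never reaches the +4-count firing level, while the arming level stays
below the −2-count unloaded baseline.

### MSMF

The template is the duration-normalized, unit-energy average of the first
five loading bumps found by a conservative scan (runs above half the global
maximum, relaxed geometrically when per-stride amplitudes vary too much for
a single level, each run extended to its zero-crossings). The similarity
trace is a Pearson-normalized sliding correlation, indexed at the alignment
*start* so that a similarity peak sits near the bump onset — this keeps the
±0.5 s IC search window valid even when stance durations vary several-fold
within a trial. For every trace peak above 0.5: IC = nearest positive
crossing within ±0.5 s; TC = first negative crossing after IC; PS = AP
velocity argmax between TC and the next candidate IC (bounded by a 3 s
stride ceiling); EC = first positive crossing after PS. Cycles violating
IC < TC < PS < EC or the 0.4–3.0 s stride-duration bounds are dropped with
a reason.

### GPD

PS events are the maxima of contiguous excursions above a threshold;
maxima closer than 0.4 s keep only the larger. The default threshold is
half the 95th percentile of the positive samples (the published procedure
selected thresholds manually per participant; a manual value always wins
when supplied). TC/IC are the nearest bracketing local minima, restricted
to *impact valleys*: prominence ≥ 5 deg/s **and** depth below −15 deg/s.
Contacts decelerate the limb, so the true landmarks are pronounced negative
valleys; the depth requirement rejects shallow inflections on the positive
swing profile. The first cycle additionally searches for a valley before
its TC so the opening stride is recoverable. Maxima and minima are refined
to sub-sample precision by parabolic interpolation.

### Synchronization

Both streams open with quiet standing. The cane's first positive strain
crossing and the shank's first prominent valley mark the same instant (the
first plant), so their clock difference is the stream offset; recovery on
synthetic trials is accurate to a few milliseconds.

## 2. Features

Per valid stride: `max_pv_swing` = max AP velocity on (TC, EC];
`max_pv_stance` = max on [IC, TC] (an apex exactly at TC counts once, in
stance); `max_pv_time_wrt_tc` and `max_strain_time_wrt_ic` in ms;
`swing_stance_ratio` = (EC−TC)/(TC−IC); `max_strain` on [IC, TC];
`stride_length` from the pendulum chord 2·L·sin(θ/2) with θ the trapezoidal
swing integral of the AP velocity (partial-sample window edges are
interpolated; negative sweeps clamp to zero). The pendulum model is this
package's definition — how stride length is derived from cane signals is
otherwise unspecified — and the generator uses the identical form, so
recovery is well-posed by construction.

`diff_ic` pairs the IC lists of the two algorithms greedily by smallest
absolute gap within ±0.2 s (half the minimum plausible stride duration).
A wide window — say half the *maximum* stride duration — lets an IC missed
by one algorithm steal its neighbour's partner and produce kilosecond-scale
outliers; 0.2 s is far above any plausible detection lag yet immune to
that. Unpaired ICs are reported, never imputed. The shank feature subset
re-uses the pendulum form with a configurable effective limb length
(default 0.9 m) — a validation convenience, not a biomechanical claim.

## 3. The synthetic-data generator

### Condition profiles

The default profiles transcribe the published per-condition mean ± sd of
swing/stance peak AP velocity, PS timing, swing/stance ratio, peak strain,
strain-apex timing, stride length and the MSMF−GPD IC difference (the
generator lag is its negation). Eleven conditions; the long/short-cane
profiles change cane length by ±2 inches (±0.0508 m) around 0.90 m.

Quantities the condition tables do not print take documented defaults:

* **Durations.** Stance mean = 2 × strain-apex offset (0.724 s for the
  control's 361.9 ms; conditions with printed apex offsets scale
  accordingly), swing = printed ratio × stance. This makes the loading bump
  symmetric about its apex, which the zero-phase filter then cannot move —
  the prototype measured a −6 ms apex bias for asymmetric bumps, most of
  the ±10 ms budget for the apex-timing feature. It also gives the swing
  phase enough room for the pendulum sweep at the printed stride-length
  spread. Duration sds derive from the printed ratio sd (split evenly,
  capped at 25% of the mean).
* **PS timing** for conditions without a printed value: the control's
  258 ± 58 ms scaled by the condition's swing duration.
* Per-stride strain-apex offsets equal half the drawn stance plus a small
  jitter (sd 20 ms, bounded ±45 ms). Freely drawn offsets produced strides
  with rise/fall asymmetry up to 3:1, whose filtered TC crossings shifted
  by 10–15 ms; the measured apex-offset mean still equals the printed value
  while the printed apex-offset sd is only partially reproduced (≈40 ms
  effective) — a known limitation.

### Waveform model

All pieces are raised-cosine segments (C¹ everywhere), designed so that
every landmark a detector reads is **locally even (extrema) or locally odd
(crossings)** under the preprocessing filters:

* **Strain**: unloaded level −2 counts; per stance a bump that undershoots
  to −max(0.12·peak, 2.5) counts on both sides so the IC/TC crossings sit
  mid-slope near an inflection, with 0.14 s recovery ramps back to the
  baseline; apex = drawn peak at IC + apex offset. Crossing positions are
  placed analytically so the continuous-time signal crosses zero exactly at
  the truth times.
* **Cane AP velocity**: a stance half-lobe peaking at `v_stance`; in swing
  a rise of at least 0.16 s (starting before TC, riding additively on the
  stance lobe, when the drawn PS offset is short — fast rises ring through
  the 8 Hz filter and displaced the apex by tens of ms), a symmetric apex
  cap (half-width ≤ 0.1 s) peaking at `v_swing` exactly at PS, a plateau
  whose level c is solved so the swing integral equals the pendulum sweep
  angle, and a post-swing valley of depth −40 deg/s whose minimum sits at
  EC + lag — the landmark GPD reads as IC. The valley descent and ascent
  are curvature-matched at the minimum (locally even), the ascent tops out
  at min(c, 0.85·v_stance) so the next stance window's maximum is
  untouched, and two slope bounds (900 deg/s² for the post-cap ramp,
  1500 deg/s² for the valley descent, widening the valley when needed)
  keep every segment inside the filter passband.
* **Shank AP velocity**: additive wide cosine lobes (stance lobe at 22% of
  the swing amplitude; swing lobe peaking mid-swing) plus narrow symmetric
  contact notches of −45 deg/s at IC and TC. Wide lobes pass the 8 Hz
  filter essentially unchanged; symmetric notches cannot move.

The swing-integral solver is exact: the integral is linear in the cap-edge
level and the plateau level, with the rise-shape exponent p ∈ {1..4} as a
discrete fallback for very short strides; it raises a parameter error when
no admissible shape reaches the target angle.

Measured consequences (noise-free, all 11 profiles, fixed seed): every
true stride is recovered by both algorithms, with worst-case event errors
of 3.3 ms (MSMF, < 1 sample at 231 Hz) and 1.8 ms (GPD on the shank,
< 1 sample at 100 Hz). Filtered swing-peak amplitudes read ≈1% low for the
narrow-cap conditions (short PS offsets); all other amplitude and timing
biases are below 2 ms / 1%.

### Parameter draws

Per-stride parameters are truncated-normal draws. Two structural choices:

* **A shared "vigor" factor.** `v_swing`, `v_stance`, `stride_length` and
  the shank swing amplitude share one standard-normal factor per stride
  (and one per participant): faster swings go with longer strides.
  Independent draws at the printed sds are jointly infeasible — the
  printed stride-length spread (e.g. 1.1 ± 0.4 m against a 1.8 m pendulum
  chord) demands sweep angles that a slow swing cannot produce. The factor
  is truncated **symmetrically** at the per-stride feasibility bound of the
  sweep constraint (found by bisection), so every drawn mean stays exactly
  at the profile mean while the realized spread contracts for conditions
  near their feasibility ceiling (notably stride length upstairs). Draws
  infeasible even at the factor's centre fall back to the nearest feasible
  stride length and are counted in the truth (`n_clamped`).
* **Centered participant shifts.** Between/within variance is split
  β = 0.5 (configurable); each participant receives one standardized shift
  per field, shared across all their conditions (the repeated-measures
  structure), and the cohort's shifts are centered to sum to zero. With
  30 participants an uncentered between-participant component would leave
  the study grand mean with a sampling sd of several percent — larger than
  the recovery tolerances — while centering leaves the within-stride
  component (≈0.1% of the mean at 1200 strides) as the only noise.

Physical bounds (positive durations, PS offset inside swing, apex inside
stance, lag in (4, 180) ms, stance > previous lag + valley span, peak
strain ≥ 15 counts, `v_stance` ≤ 0.92·`v_swing`) are enforced by symmetric
truncation wherever possible, so means are preserved.

Trials prepend/append ≥ 2 s of quiet standing, sample the cane at 231 Hz
and the shank at 100 Hz with a random 0.3–1.0 s stream-start offset
(recorded in the truth), and add white noise (defaults: 1 count strain,
1 deg/s gyro). Fixing the seed fixes every output byte.

### What the generator does and does not emulate

It reproduces: per-condition stride statistics, the event geometry of both
sensing modalities, the strain/gyro timing relationship behind the
IC-difference feature, between/within-participant variance structure,
stream asynchrony, and white measurement noise. It does **not** emulate:
baseline drift, temperature effects on the bridge, motion artifacts,
turns/pauses, accelerometer content (zeros), correlated or impulsive noise,
within-trial fatigue trends, or deviations from the pendulum stride-length
relation. Passing recovery tests therefore demonstrates the correctness
and internal consistency of the pipeline — not its robustness to every
artifact of field recordings.

## 4. Statistics

The experimental unit is the participant: each analysis cell is a
participant's mean feature over the valid strides of one condition
(stride-level analysis is available by pivoting the tidy feature table
differently). The one-way repeated-measures ANOVA uses the standard
decomposition SS_total = SS_condition + SS_subject + SS_error with
F = MS_condition/MS_error on (k−1, (k−1)(n−1)) df; no sphericity
correction is applied (matching the published analysis; for k = 2 the two
are identical and F equals the squared paired t). Pairwise contrasts are
two-sided paired t tests with Bonferroni-adjusted p values at α = 0.05;
zero-variance difference vectors are flagged degenerate rather than
declared significant. The engine is cross-checked against
`statsmodels.stats.anova.AnovaRM` in the unit tests. Reports render one
row per feature with "(mean ± sd)" cells, `*` for significant contrasts
against the control and `**` for the non-control contrast, plus
normalized-to-control ratio tables per source stream.

Study-scale checks use deliberately scaled problem sizes: the recovery
studies run 30 participants × 40 strides (20 upstairs, matching a
20-step flight); the power check (control vs dorsiflexed stance velocity,
flagged in ≥ 90% of 100 replicates) runs on drawn subject-level parameter
means — the Bonferroni flag is a function of the subject-mean matrix only,
so waveform synthesis adds nothing but runtime — and the type-I calibration
(1000 null replicates, rejection rate within [0.03, 0.07]) simulates
subject-mean matrices directly from the generator's variance split.

## 5. Known limitations

* The printed sds of PS timing, apex timing and (for feasibility-limited
  conditions) stride length are only partially realized; all printed means
  are. The published F ratios depend on the unavailable raw recordings and
  are not reproduction targets.
* The swing-peak amplitude reads ≈1% low through the 8 Hz filter for
  short-swing conditions (narrow apex caps).
* GPD applied to the *cane* stream sees stance lobes above the automatic
  threshold; the resulting spurious cycles are harmless for the
  IC-difference feature (nearest-gap pairing) but cane-GPD TC/EC events are
  not meaningful — the shank is GPD's reference stream.
* The generator's self-consistency is defined on the raw waveforms
  (drawn parameters are recovered exactly before filtering); filtered
  amplitudes inherit the small passband losses quantified above.
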