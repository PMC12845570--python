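# Methods

## The training system being modelled

Four 9-axis inertial sensors (gyroscope, accelerometer, magnetometer;
nominal 26 Hz) are strapped to an infant's wrists and ankles. During an
*active* session the infant's limb movement drives graded audiovisual
playback on a tablet; during a *passive* (catch-trial) session the stimulus
plays regardless of movement and serves as the within-infant baseline.
Training days consist of five consecutive three-minute sessions whose modes
are drawn at random (active with probability 0.68 by default).

## Activity signal and adaptive threshold

The controller's input is the angular-velocity magnitude of each limb,
`s(t) = ||gyro(t)||` in deg/s. Each controlling limb keeps its own
threshold over the trailing five-second window:

    tau(t0) = w_max * max{ s(t) : t in [t0-5, t0] }
            + w_mean * mean{ s(t) : t in [t0-5, t0] }
            + epsilon

* `w_max = w_mean = 0.5` by default — the equally weighted sum of window
  maximum and average. The window average discretizes the integral term of
  the continuous-time definition as the sample mean (for a full, uniformly
  sampled 5-s window the two coincide); both weights are configurable, so a
  reading that weights the mean fully (`w_mean = 1`) is also reachable.
* `epsilon` (default 0.8 deg/s) is the background offset: the magnitude a
  still sensor reports. The default is a placeholder for a per-device
  still-sensor calibration and should be measured per sensor in deployment.
* Warm-up: during the first five seconds the window is simply all samples
  so far (minimum one); no padding or interpolation.
* Window membership uses `t >= t0 - window_s` inclusive, and the drive
  comparison uses `>=` (activity exactly at threshold drives playback).

Two implementations exist: the streaming `SlidingWindowThreshold`
(monotonic deque for the maximum, running sum for the mean; O(1) amortised
per sample) and a brute-force full-window recomputation
(`threshold_trace_reference`). They apply the identical window predicate,
so they may differ only by float summation order; the suite requires
agreement to 1e-9 relative tolerance on 100 three-minute streams and
observes ~1e-14.

## Playback controller

Playback level is a scalar in [0, 1] (an abstraction of video
start/stop/opacity). If any controlling limb satisfies
`activity - tau >= 0`, the level rises by `dt / ramp_up_s`, otherwise it
falls by `dt / ramp_down_s`, then is clamped. Defaults `ramp_up_s = 1 s`,
`ramp_down_s = 2 s` give the gradual onset/offset the protocol calls for
while favouring stimulus retention (slower decay than rise); "any limb
drives" is the most permissive multi-limb aggregation, chosen so a
unilaterally impaired infant can always reach the stimulus. Both ramps and
the controlling-limb set are configurable.

## Session quality rules

Timestamps are seconds from session start; each sample covers one nominal
interval, so n samples at 26 Hz span n/26 s (4680 samples = 180 s).

* **Complete session** (used by every analysis): not interrupted, and every
  limb stream contains a gap-free run — no inter-sample gap above
  `max_gap_s` (default 1.0 s) — of at least the planned duration, with
  overall coverage ≥ `min_coverage` (default 0.95) of the expected sample
  count. A mid-recording dropout breaks the run; a dropout after three
  clean minutes does not.
* **Connectivity** (additionally required by the side-difference analysis):
  per limb, coverage ≥ `min_coverage` over the planned duration and no gap
  (including the lead-in from t = 0) above `max_gap_s`. The asymmetry
  comparison is between sides, so a single dropped sensor biases it and the
  whole session is excluded there, while the pooled activity median is
  robust enough to keep such sessions.

The numeric gap/coverage rule is a package choice: "consecutive data" needs
an operational definition, and 1 s / 95% keeps ordinary Bluetooth jitter
while rejecting real dropouts.

## Offline analyses

* **Session activity**: the median of all `|gyro|` samples of all four
  sensors pooled into one collection — order-free and robust to bursts.
* **Daily ratio**: mean active activity / mean passive activity per
  training day; days lacking a mode (or with zero passive mean) are
  reported with a note rather than dropped.
* **Active/passive test**: classical paired t-test on per-infant mean
  active vs. mean passive activity (one pair per infant). Zero-variance
  differences are flagged degenerate with p at the float minimum rather
  than silently propagated.
* **Side asymmetry**: L pools every left-hand and left-foot sample of the
  included sessions and takes the median; R likewise. The index
  `(R - L) / (R + L)` lies in [-1, 1]; positive = right-dominant.
  Pooled-sample medians per side (rather than averaging per-session
  indices) keep the side measure consistent with the session activity
  measure; aggregation order is otherwise a free choice.
* **Clinical correlation**: ordinary least squares (scipy), reported as
  slope, intercept, r², two-sided p. A constant response returns r² = 0
  with p = 1; a constant predictor is an error. r² is orientation-
  invariant, so either variable may be the predictor.
* **Compliance**: minutes/day = 60·hours/days per infant with ≥ 1 trained
  day; recommended dose 104 days (4 days/week × 26 weeks, configurable);
  "meeting" means ≥ 50% of recommended days, with every participant in the
  percentage denominator. Group mean and SD cover the meeting infants; the
  SD is the descriptive population SD (ddof = 0) over that group. Reported
  rounding: one decimal for min/day, integer percent. No multiple-testing
  correction is applied anywhere; each statistic is reported raw.

On the bundled twelve-infant journal this yields 13.3 (±1.8) min/day over
the seven infants meeting the criterion, and 7/12 = 58% meeting.

## Synthetic infant movement

No public infant angular-velocity corpus exists, so all movement-level
validation runs on a seeded generator. Per limb, bursts arrive as a
homogeneous Poisson process and superpose raised-cosine envelopes with
gamma-distributed peak amplitude and duration along a random fixed rotation
axis; 3-axis Gaussian sensor noise is added. Accelerometer and magnetometer
channels carry plausible correlated noise only — no analysis consumes them.

Defaults (per limb): 60 bursts/min, mean duration 2.0 s, mean peak
amplitude 60 deg/s, baseline noise SD 2 deg/s per axis. These keep a limb
in motion for most of an engaged session, so the pooled session median
(~34 deg/s) sits firmly in the burst-amplitude range — well above the
0.8 deg/s background offset and far from the controller's saturation —
which both exercises the threshold's dynamic range and keeps the median a
well-conditioned statistic (a median on the noise/burst mixture boundary is
noisy because the density there is low). The burst-process values are
invented, declared as such, and exposed in configuration; no quantitative
distribution of real infant angular velocity was available to fit.

Effects are injected at session level:

* `asymmetry_rho` scales right-side burst amplitudes (rho > 1 means
  right-dominant movement);
* `responsiveness_gain` g scales burst amplitudes in active sessions — the
  contingency effect is modelled as a session-level amplitude gain, because
  session-level activity contrasts are the testable construct; no
  closed-loop learning dynamics are modelled.

What the generator does **not** reproduce: postural/gravity structure in
the accelerometer, circadian or developmental drift, attention dynamics
within a session, sensor-specific noise spectra, or any coupling between
limbs. Passing tests therefore demonstrate that the pipeline recovers the
effects it is designed to measure from data with the right summary
statistics, not that it would behave identically on real recordings.

## Monte-Carlo study sizes and the pooled fast path

The power/calibration studies need ~1,200 cohort replicates of
7 infants × 40 days × 5 sessions. Simulating every session's waveform
would be pointless duplication: sessions are i.i.d. given a profile, and
the analyses consume only each session's pooled median. The studies
therefore draw session activities from pools of 1,200 waveform-simulated
sessions per mode (`build_activity_pool` runs the full generator and keeps
the summary statistic). A dedicated test confirms the pooled route
reproduces the full route's active/passive ratio within 10%. Under g = 1
active and passive sessions are identically distributed, so a single
shared pool serves both modes, making the null hypothesis exactly
exchangeable — the honest way to check that the paired t-test rejects at
its nominal 5%.

Study sizes used by the suite and the acceptance script: 100 streams for
threshold equivalence; 100 runs of 3 sessions per asymmetry level
(rho ∈ {0.5, 1, 2}); 200 replicates for power at g = 1.3 and 1,000 for
type-I calibration at g = 1.

## Numerical and degenerate-input choices

* Strictly increasing timestamps are enforced at ingest; the offending row
  is named.
* CSV writing uses `repr` floats and the session log uses JSON floats, so
  write→read round-trips are bit-exact.
* The streaming threshold's running sum can drift from the brute-force
  value only at the 1e-13 relative level over a 3-minute session; the 1e-9
  test tolerance leaves two orders of margin.
* `(R - L)/(R + L)` with both medians zero is an error, not a NaN.
* Empty windows, empty streams, empty journals: explicit typed errors.

## Known limitations

* The generator's realism claims are distributional, not biomechanical.
* The bundled cohort tables support the compliance analytics only; the
  hand-assessment laterality regression cannot be reproduced from published
  data (per-hand sum scores are not available) and is validated by
  property tests on synthetic cohorts instead.
* The feedback engine replays recorded or simulated streams; it makes no
  real-time latency guarantees and does not bind to sensor hardware.
* The JSON-lines session-log schema is this package's own; it is not
  claimed compatible with any tablet app's internal storage.
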