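# infantfeedback

Movement-contingent sensory-feedback training for infants at high risk of
cerebral palsy — the feedback engine, session data model, and offline
analysis, plus a seeded synthetic-movement generator so the whole pipeline
is testable without clinical recordings.

Infants who receive immediate, movement-contingent reinforcement tend to
move more, and early self-initiated movement is believed to matter for
sensorimotor development. The system modelled here straps a 9-axis IMU
(26 Hz) to each of an infant's four limbs; during *active* sessions the
limbs' angular-velocity magnitude `s(t) = ‖gyro(t)‖` drives graded
audiovisual playback on a tablet, while randomly interleaved *passive*
catch-trial sessions play the stimulus regardless of movement and provide
the within-infant baseline. The playback criterion is an adaptive
threshold per controlling limb over the trailing five seconds,

    τ(t₀) = ½·max{s(t) : t ∈ [t₀−5, t₀]} + ½·mean{s(t) : t ∈ [t₀−5, t₀]} + ε,

an equally weighted sum of window maximum and average plus a still-sensor
background offset ε, so the bar adapts to each infant's current activity
level. Playback ramps up linearly while any controlling limb satisfies
`s ≥ τ` and ramps down otherwise, clamped to [0, 1].

The offline analysis quantifies, per session, activity as the median
angular-velocity magnitude pooled over all four sensors (complete sessions
only: three minutes of consecutive data); per day, the active/passive
activity ratio; per infant, a paired t-test of mean active vs. passive
activity; movement laterality as the index `(R − L)/(R + L)` of pooled
side medians (positive = right-dominant; sessions with sensor-connectivity
problems excluded); and training compliance in minutes per trained day
against a recommended dose of 104 days. A twelve-infant pilot cohort's
training journal and clinical scores are bundled for the compliance
analytics.

## Worked example

The bundled cohort journal:

```
$ infantfeedback compliance --recommended-days 104
7/12 infants (58%) met the 50% criterion; mean 13.3 (±1.8) min/day
```

Seven of twelve infants reached at least half of the recommended 104
training days, and those seven trained 13.3 minutes per training day on
average.

A synthetic four-day intervention for a right-dominant (ρ = 1.4),
feedback-responsive (g = 1.3) infant, analysed end to end:

```python
from infantfeedback import (InfantProfile, InterventionPlan,
                            simulate_intervention, run_feedback_session)
from infantfeedback.analysis import (activity_table, daily_ratios,
                                     side_asymmetry_index)

profile = InfantProfile(asymmetry_rho=1.4, responsiveness_gain=1.3)
result = simulate_intervention(profile, InterventionPlan(n_days=4, seed=7),
                               infant_id="demo")
table, decisions = activity_table(result.sessions)
print(daily_ratios(table)[["day", "n_active", "n_passive", "ratio"]]
      .to_string(index=False))
asym = side_asymmetry_index(result.sessions)
print(f"asymmetry index {asym.index:+.3f} "
      f"(L={asym.left:.1f}, R={asym.right:.1f} deg/s)")
replay = run_feedback_session(result.sessions[0].streams, "active")
print(f"mean playback level {replay.playback_trace.level.mean():.3f}")
```

prints

```
 day  n_active  n_passive    ratio
   1         4          1 1.263807
   2         4          1 1.231376
   3         2          3 1.337580
   4         4          1 1.250109
asymmetry index +0.167 (L=40.7, R=57.1 deg/s)
mean playback level 0.765
```

Every daily ratio is above 1 — the infant moved more when its movement
controlled the stimulus, the direction the contingency gain injects — and
the recovered laterality index is positive, matching the simulated right
dominance. Replaying a session through the controller shows the stimulus
playing about 77% of the time for this activity level.

The CLI exposes the same pipeline as `simulate`, `run-session`, `analyze`,
`asymmetry`, `compliance` and `demo` subcommands; run
`infantfeedback --help` for options.

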