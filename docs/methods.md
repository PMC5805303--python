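# Methods

## Paradigm and coordinate conventions

All positions are planar, in cm, with the home position at the origin, x
rightward and y away from the body. Angles are degrees, CCW-positive from
+x; rotations are applied about home, with clockwise encoded negative. Five
targets sit at 60°, 75°, 90°, 105° and 120°, 12 cm from home (target
diameter 1.5 cm, cursor 1.0 cm, home 1.6 cm). Sampling is 50 Hz throughout.

Three designs are built by `paradigm.build_session`:

- `SINGLE_REACH`: 50 aligned reaches, 30 no-cursor reaches, 180 rotated
  (−30°) reaches, 30 no-cursor reaches.
- `SINGLE_TRACK`: the same reach baseline, then 65 aligned tracking trials,
  30 no-cursor reaches, 180 rotated (+30°) tracking trials, 30 no-cursor
  reaches.
- `DUAL`: both baselines, a mixed aligned block (25 reaches + 25 tracking
  trials), then 360 rotated trials (180 reaches at −30° interleaved with
  180 tracking trials at +30°), and 30 no-cursor reaches.

Target order is pseudo-random in permutation blocks: each target appears
once per 5 same-type trials before any repeats. Aligned tracking durations
ramp from 1800 ms down by 20 ms per trial to a 1500 ms steady state (trial
16 onward; 12 cm at 1500 ms = 8 cm/s); all rotated tracking trials use
1500 ms. Feedback color bands classify cursor-target separation (green on
overlap, yellow to 4 cm, orange to 8 cm, red beyond); "overlap" is
center-to-center distance within the sum of the radii (1.25 cm).

Design choices where the protocol is underdetermined: the mixed aligned
block alternates strictly starting with a reach; dual-training interleaving
shuffles paired 10-trial blocks (5 of each type) with no more than 2
consecutive trials of one type; the 30 no-cursor trials are target-balanced
(30 is divisible by 5); only the outward stroke of each reach is generated
and analyzed; no-cursor trials carry no schedule-level timeout.

## The synthetic participant

The paradigm under study *measures* adaptation but does not commit to a
learning model; the generator's learner is this package's design choice, in
the spirit of multi-compartment state-space accounts of context-dependent
adaptation. States (deg): `z_shared` (expressed in both movement types) and
`z_reach`, `z_track` (context-specific). On each cursor-visible trial with
signed error `e`:

```
z_shared  ← A·z_shared  − B_s·e
z_context ← A·z_context − B_c·e      (trained context)
z_other   ← A·z_other                (untrained context)
```

No-cursor trials neither update nor decay states, which keeps the first
aftereffect block stationary. The error signal is the angular error at peak
velocity on reaches, and on tracking trials the mean signed cursor-target
angle from cursor-motion onset to target halt, scaled by
`track_error_weight`. A closed-form check used by the tests: for a single
context trained alone without noise, total compensation converges to
`−rotation·B/(1−A+B)`, `B = B_s+B_c` (to `−rotation` exactly when A = 1).

Movement generation:

- **Reach**: minimum-jerk radial stroke, 12 cm in `reach_duration_ms`
  (default 1000 ms), aimed at `target direction + compensation + ε`,
  ε ~ N(0, `aim_sd_deg`²) drawn once per trial (default SD 3.5°).
- **Tracking**: first-order proportional pursuit — hand velocity =
  `pursuit_gain` × (goal − hand) with gain 6 s⁻¹, where the goal is the
  target `pursuit_lag_ms` (400 ms) earlier, rotated about home by the
  compensation (+ per-trial aiming noise). The trial continues past target
  halt until the cursor overlaps the target or a 3 s cap. Because target
  paths are radial and the controller chases a point on a fixed ray, the
  cursor's angular misalignment is exactly `rotation + compensation`, which
  makes the noiseless learning dynamics analytically checkable.
- The cursor is always the hand rotated by the trial's rotation about home
  (absent on no-cursor trials).

The tracking target is interpreted as "semi-predictable" in the sense of a
random target choice with a deterministic straight constant-speed path.

### Default calibration

Defaults were fixed once by a least-squares sweep of
(`rate_shared`, `rate_context`, `track_error_weight`) at retention 0.97
over the full noiseless simulator, targeting the qualitative pattern the
paradigm is known for: reach-only compensation ≈ 19° of 30°, about half of
it transferring from tracking training (≈ 9°, opposite sign), and a
residual dual aftereffect ≈ 7° in the reach direction. The frozen values —
`retention = 0.97`, `rate_shared = 0.0238`, `rate_context = 0.0202`,
`track_error_weight = 1.0` (the weight pinned at its upper bound; the three
targets are not exactly attainable simultaneously in this architecture) —
give noiseless aftereffects of +17.8° (reach), −9.6° (tracking transfer)
and +8.0° (dual). Signs are reported as CCW-positive hand deviations, so a
CW-trained group shows a *positive* aftereffect; bar-plot conventions that
plot CW-training aftereffects negative are mirror images of these values.

## Kinematic measures

Positions are filtered with a first-order Butterworth low-pass, 2.5 Hz
cutoff at 50 Hz, applied zero-phase (forward–backward) by default so that
group delay cannot shift the peak-velocity sample; a causal single-pass
mode (initialized at DC steady state) is available as a config switch.
Positions are filtered before differentiation; speed is the magnitude of
central-difference velocities (one-sided at the ends).

- **Onset**: scanning back from the (earliest) global speed peak, the first
  sample at or above 10 % (reach) / 33 % (tracking) of peak speed.
- **Offset**: the last sample at or above 33 % of peak after the peak;
  flagged when speed never falls below threshold.
- **Angular error at peak velocity**: cursor direction minus target
  direction, both from home, wrapped to (−180°, 180°]; computed on the hand
  for no-cursor trials. Undefined (error) if the cursor is at home at peak.
- **Tracking RMSE**: root-mean-square *Euclidean* cursor-target distance
  (the per-sample subtraction of Cartesian positions is read as a 2-D
  distance), evaluated from target-motion onset through target halt.
- **Pursuit descriptors**: latency (target-motion start → cursor onset at
  the 33 % criterion), cursor-to-target distance at onset, and movement
  time (onset → offset).

## Learning analysis

Training measures are averaged in 5-trial blocks. Milestones are the raw
first trial, the mean of trials 6–10, and the mean of the final block.
Aftereffects are per-participant: mean of the first no-cursor block after
rotated training minus the mean of the *final* aligned no-cursor block
(using the last aligned no-cursor phase preceding rotated training); a
first-block baseline variant is available as a config switch. Exponential
fits use bounded least squares (`a ∈ [0, 5]`, `b`, `c` free; analytic
Jacobian; parameter tolerance 1e-10) initialized at
`a = 0.1, b = y₁ − y_N, c = y_N`, computed on group-mean block series by
default (per-participant optional), on raw (not baseline-subtracted)
values. Degenerate constant series fit cleanly (b → 0).

The statistics battery uses scipy for t-tests (pooled-variance independent,
paired, one-sample), pingouin for the 3 × 2 mixed ANOVA, statsmodels for
the one-way repeated-measures ANOVA, and a one-way between-groups ANOVA
for aftereffects, with Bonferroni-corrected post-hocs (multiply by the
comparison count, cap at 1; α = .05). Paired tests on identical data (0/0)
report t = 0, p = 1. No sphericity corrections are applied.

## Problem sizes, tolerances, determinism

Group-level property checks simulate 16 participants per design with
deterministic per-participant seeds spawned from a single group seed; a
full 3 × 16-session simulation plus analysis runs in well under a minute.
Schedules, simulations, and CLI outputs are byte-reproducible from their
seeds; trajectory CSVs round-trip losslessly (floats re-read with
round-trip precision). Fit-recovery checks on noiseless 36-block series
recover planted parameters to ≤ 1e-4.

## Known limitations

- The first-order pursuit controller cannot simultaneously reproduce a
  ~0.5 s (~4 cm) trailing distance *and* cursor movement times above 2 s:
  with the default gain (6 s⁻¹) and lag (400 ms), onset-to-offset times on
  converged tracking trials come out near 1.4–1.6 s. Real participants make
  corrective sub-movements that stretch the 33 %-criterion window; the
  model trades that fidelity for analytic transparency. Pursuit latency at
  the 33 % criterion also exceeds the programmed lag by the controller rise
  time (~80 ms at default gain); the lag is recovered exactly only with a
  fast controller.
- Aiming noise is a single per-trial direction draw: there is no
  within-trial motor noise, no reaction-time variability, no feedback
  corrections on reaches, and no eye-movement or explicit-strategy
  component. Passing tests therefore validate the pipeline's arithmetic and
  the qualitative learning structure, not biological realism of individual
  trajectories.
- The learner is single-rate per state; savings, spontaneous recovery and
  other two-rate phenomena are out of scope.
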