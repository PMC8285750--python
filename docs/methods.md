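# Methods

## Difficulty engine

The engine encodes a 15-level table. Level parameters are generated from
the level-1 values plus `(level − 1)` applications of the per-level change,
not by interpolating between the level-1 and level-15 endpoint columns.
Delta generation reproduces the level-6 reference values exactly (speed
13.8 °/s, lifetime 11.07 s, thresholds 77.1% / 67.1%); the level-15 column
then differs from the conventionally printed endpoints only by display
rounding (e.g. speed 35.04 vs 35), which the test suite tolerates at
relative 2×10⁻³.

Threshold comparisons are strict: percent found strictly above the
level-up threshold promotes, strictly below the level-down threshold
demotes, equality holds the level. Percentages are compared as exact
floats with no pre-rounding — rounding is display-only — which avoids
boundary artifacts (e.g. 83.33…% vs a 83.3% display value). Promotion at
level 15 and demotion at level 1 clamp: there is no level 0 or 16.

## Task simulation

Time is continuous and event-based; there is no frame loop. Targets spawn
uniformly over the ±60° × ±50° rectangle in (azimuth, elevation) — the
spawn distribution is a modeling choice, as is everything else not fixed
by the task description. The motion direction is ±1 with probability ½.
The next target spawns a fixed 2 s after the previous one resolves
(tagged or expired). The 1 s alerting cue is folded into the agent's base
latency rather than modelled separately.

The agent response model is deliberately minimal: search time is the sum
of a base latency, an azimuth-proportional scan term and an aiming term,
multiplied by the left-hemispace penalty `1 + bias_gain · λ` and by
lognormal noise with median 1 (so the no-noise closed form is the median
behavior, and symmetry/penalty identities hold exactly when noise is off).
Consequences of this choice:

- Search restarts from a neutral center each trial; no gaze carry-over.
- Elevation is recorded but does not enter search time (azimuth-dominant
  search).
- Target speed does not change detectability directly; difficulty pressure
  comes through the lifetime, which shrinks with level. The spawn azimuth
  is the azimuth used for search time.
- There is no aiming-error model; misses happen only by lifetime expiry.

The patient variant's speed floor replaces the level-1 speed with
0.1 °/s and keeps the same per-level increment thereafter, so only the
easiest levels are slowed.

Hemispace assignment: azimuth < 0 is left; exactly 0 counts as right
(probability zero under continuous sampling; the tie-break is fixed for
reproducibility).

### Hand traces

For each found target the simulated controller moves from its current
position toward the reach point at 0.5 m arm radius in the target's
azimuth direction, sampled at 10 Hz with 1 cm Gaussian jitter; left-side
reach points are pulled toward the midline by the factor `1 − λ`,
emulating restricted contralesional exploration. Missed targets produce
drift in place. Samples are clamped to the 2 m × 2 m workspace. This is a
qualitative emulation — good enough for symmetry and rightward-shift
summaries, not a kinematic model of reaching.

### Cohort defaults

Per-participant seeds are drawn from the master generator, so any session
is reproducible from its recorded seed. Defaults define the simulated
study conditions:

| cohort | n | start level | base latency (s) | scan speed (°/s) | aim (s) | noise σ | λ |
|---|---|---|---|---|---|---|---|
| young | 21 | 8 | 0.40 | 40 | 0.30 | 0.25 | 0 |
| elderly | 23 | 8 | 0.50 | 28 | 0.35 | 0.45 | 0 |
| neglect | 11 | 2 | 0.60 | 25 | 0.40 | 0.35 | U(0.1, 0.9) |

Young parameters were set so the deterministic mean search time over the
spawn area (~1.45 s, ~1.5 s with noise) lands near typical healthy adult
performance; elderly agents scan slower and noisier; neglect agents add
the lateralized penalty (gain 2) and the patient-variant config (speed
floor, gentle start). These were chosen once as realistic study
conditions and are not tuning knobs.

## Center of Cancellation

Each target on the sheet gets a normalized horizontal coordinate
`(x − center) / span`, where `center` is the sheet midline and `span` the
larger of the distances from the midline to the leftmost/rightmost target
column — linear, 0 at the sheet center, ±1 at the extreme column of a
symmetric sheet. The CoC is the mean coordinate over marked targets; the
raw (millimeter) mean deviation is exposed alongside. Classification uses
the inclusive cutoff CoC ≥ 0.081. An empty mark set raises rather than
returning 0, because 0 means "no bias", not "no data". The default sheet
is a synthetic stand-in: 40 targets on an 8×5 grid among 240 distractors
on a 24×10 grid, left-right symmetric; agreement with any published
cancellation-scoring software is not claimed, only the range and cutoff
semantics.

The cancellation simulator links the agent bias λ to sheet behavior: each
target is marked with probability `clip(1 − λ(1 − x̃)/2, 0, 1)`, omitting
leftward targets increasingly as λ grows, with the rightmost target forced
if every draw fails. This provides the severity-recovery property: across
simulated patients, sheet CoC correlates strongly with left-hemispace
search time and weakly with right.

## Analysis layer

Level-difference trajectories subtract each session's starting level and
pool per round across sessions, tolerating unequal round counts
(patient protocols): round r reports mean, SE = sd/√n and the n of
sessions that reached round r.

Plateau (balance-point) detection returns the earliest round r such that
the levels from r to the end span at most the tolerance (default 1 level,
minimum window 3 rounds) *and* the round-r level equals the plateau level
(the window mean rounded half-up). The second condition makes the plateau
start where the trajectory first sits at its settled level rather than on
the monotone approach to it; half-up rounding keeps the result equivariant
under shifting all levels by a constant.

Questionnaire scoring: SUS (3 items, 1–5) and SSQ (7 items, 1–4) return
the item mean; IPQ (1–5) and PGTQ (1–7) are scored per item. Group
statistics are Welch's unequal-variance t test and Pearson correlation
(scipy-backed; cross-checked in the tests against independently coded
textbook formulas). p-values are reported but never drive automated
decisions inside the package; no multiple-testing correction is applied.

## Serialization

Configs and session headers are JSON; events and hand traces are CSV.
Floats are written with the shortest round-trip representation, so logs
are byte-identical under a fixed seed and parse back exactly. Run
manifests embed the package version, a SHA-256 config hash and the master
seed. Config loading validates against the known key set and rejects
unknown keys by name.

## Problem sizes and numerical choices

Stochastic properties are checked at fixed seeds with modest sizes chosen
for tight confidence: ≥2000 targets for hemispace symmetry (3 SE
criterion), 20 simulated patients for severity recovery, 30-round
sessions for plateau convergence, 10⁴ replicates for the CoC Monte-Carlo
null. Exact identities (penalty scaling, closed-form search times,
table resolution) are tested with noise off, where the model is
deterministic.

## Limitations

- The agent model has no learning/practice effect, so healthy trajectories
  plateau at a stationary balance point; with the simple reach-time model
  and long sessions, unbiased skilled agents sit at the level ceiling.
  Real elderly players plateau below young ones for reasons (fatigue,
  strategy, aiming difficulty at speed) this model does not capture.
- Passing tests demonstrate the engine's and metrics' correctness on the
  synthetic behavior model, not fidelity to any human dataset: the
  simulator reproduces qualitative patterns (lateralized slowing,
  rightward hand-trace shift, balance-point plateaus), not human effect
  sizes.
- No 3D rendering, audio, hardware interfacing, aiming-error model, or
  scoring of other neglect instruments.
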