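# Methods

## The detection model

The detector formalizes how sleep myoclonus presents to an overhead
video tracker: a mouse that has been immobile for a long stretch produces a
single short burst of center-point velocity, far faster than anything it
does while resting but bounded above (unlike a startled dash across the
cage). All numeric thresholds live in `DetectionConfig`; the movement,
multi-condition and mobility thresholds are the published analysis-profile
settings of the commercial tracker this pipeline emulates, and the
remaining parameters operationalize its qualitative criteria:

| parameter | default | role |
|---|---|---|
| `move_start_cms` / `move_stop_cms` | 3.20 / 2.25 cm/s | Movement hysteresis (enter above start, exit below stop; initial state not-moving). The two published numbers are interpreted as start/stop thresholds, matching the emulated software's documented semantics. |
| `mc1_avg_window_samples`, `mc1_avg_vel_max_cms` | 100 samples, 0.45 cm/s | MC1's quiescence test: mean velocity over 4 s (at 25 Hz) nearly zero. The apparent contradiction with Movement=true is deliberate and preserved: it selects an isolated spike inside a quiet window — the jerk signature. |
| `mc1_elong_max_pct`, `mc1_angle_max_deg` | 75 %, 20° | curled, straight-bodied resting posture. |
| `mc2_accel_max_cms2`, `mc2_move_*` | 180 cm/s², 2.00/1.75 cm/s | MC2: bounded center acceleration while center, nose and tail-base all move — the whole body twitches coherently. |
| `mobility_window_samples`, `mobility_high_pct`, `mobility_immobile_pct` | 15, 60 %, 5 % | three-level mobility state (average first, then threshold). |
| `burst_vel_min/max_cms` | 20 / 60 cm/s | the velocity band of a jerk burst. The lower bound is strict (a burst must exceed 20 cm/s); the source material's "~20" tilde is noted but not given slack. |
| `burst_max_dur_s` | 1.5 s | operationalizes "short (~1 s)" with margin for smoothing spread. |
| `pre_immobile_min_s`, `pre_immobile_gap_max_s` | 10 s, 1 s | operationalizes "preceded by a long immobile state"; the 1-s gap absorbs the smoothing-induced early break of the immobile label. |
| `merge_gap_s` | 1 s | velocity runs closer than this merge into one candidate, so one jerk fragmented by a mid-burst dip is not double-counted (a single jerk's burst is ≤ ~1 s). |
| `mc_pad_s` | 0.2 s | tolerance when requiring an MC1/MC2 hit near the burst. |
| `pair_min/max_gap_s` | 1 / 20 s | consecutive-event pairing window; paired events still count as two. |
| `analysis_start_s`, `analysis_end_s` | 3600 / 14400 s | first hour (active cage exploration) discarded; last three hours scored. |
| `start_latency_s` | 3 s | recording-start rule: lead-in before the animal is continuously tracked for 3 s can be trimmed (`apply_start_latency`, CLI `--start-latency`). |

Candidates satisfy, inside the analysis window: (a) run duration ≤
`burst_max_dur_s`; (b) peak in the burst band; (c) an Immobile run of ≥
`pre_immobile_min_s` ending ≤ `pre_immobile_gap_max_s` before onset; (d)
MC1 **or** MC2 true at ≥ 1 sample in the padded burst ("and/or" is taken
literally — either condition suffices).

Merging precedes the criteria: raw above-threshold runs are first merged
over `merge_gap_s`, then (a)–(d) are applied to the merged runs, so a
fragmented burst is judged as one event. The brute-force oracle in the test
suite applies the identical order with literal loops.

### Automated stand-in for visual confirmation

In the emulated workflow every flagged event was confirmed by eye and
events where the animal was "clearly walking" were discarded. Here that
review is replaced by explicit rules with logged rejection reasons:
(i) *walking-in* — Mobile/HighlyMobile for > 50 % of the 5 s before onset;
(ii) *sustained locomotion* — net displacement > 10 cm during the burst
with no in-burst sample exceeding 1.5× the preceding 10-s velocity maximum;
(iii) *invalid gap* — the burst overlaps an unresolvable tracking gap.
Post-event locomotion never rejects. Note that rule (i) is logically
subsumed by candidate criterion (c) (ten seconds of immobility ending ≤ 1 s
before onset leaves at most ~20 % of the preceding 5 s mobile); it is kept
as an independent, configurable guard because both rules are stand-ins whose
parameters users may relax separately. All rejected events are exported
with their reasons so the automated decisions remain auditable.

### Numerical conventions

* Sample-count windows are rate-relative; the default 25 Hz makes
  100 samples = 4 s. The acquisition rate of the original recordings is not
  public, so the rate is a config field, inferable from the time column.
* All sliding means are **centered** boxcars truncated at the edges
  (centered minimizes event-onset bias; the emulated software does not
  document its alignment). Missing samples are excluded from the mean; an
  all-missing window stays missing.
* First-sample derivatives are 0 (not missing) so state machines have
  defined input from t = 0. Acceleration is a magnitude, because the MC2
  condition bounds a magnitude.
* Missing data: gaps ≤ `max_gap_s` (default 1 s) are linearly interpolated
  before state logic; longer gaps stay missing, state machines hold state
  across them, and candidates overlapping them are rejected, not scored.
* The commercial outlier filter is undocumented; "averaging interval
  1 sample" is read as raw velocity, and an optional 3-sample median
  despike (`despike`, off by default) is provided as a declared stand-in,
  not a claim of equivalence.
* Ordering and tie-breaks are deterministic throughout: candidates sorted
  by onset, greedy left-to-right pairing, onset-proximity-ordered one-to-one
  event matching. Identical input and config give bit-identical output.

### Mobility without pixels

The emulated mobility measure is pixel-change based. From trajectories
alone we use the documented surrogate
`100·min(1, 0.3·d_center + 0.3·d_nose + 0.3·d_tail + 0.1·|Δelongation|/100)`
with `d_p` the per-sample displacement of point `p` over a 7-cm body-length
scale. It is a displacement proxy, not a pixel count: slow locomotion can
sit near the Immobile boundary. That is sufficient here because the
detector only requires Immobile to mean "genuinely at rest" (criterion (c))
and the voluntary-movement rules use velocity as well. When video is
available the tracker supplies the pixel-faithful alternative
(`100·|mask XOR prev| / |mask OR prev|`), and every consumer accepts either
source.

## The simulator

`simulate_session` emulates the study conditions: 4-h single-mouse sessions
in a 30 × 30 cm arena at 25 Hz, a first hour dominated by cage exploration,
then mostly sleep. Behavior is a semi-Markov chain of explore / sleep /
groom bouts with exponential holding times (means 60 / 600 / 30 s); the
first hour biases transitions toward exploration. Exploration is a
correlated random walk at 5–15 cm/s with stretched posture; sleep is a
stationary curled posture; grooming is in-place oscillation.

Jerks are Poisson events within sleep bouts (default 4/h for the
mutant-like condition, 0.2/h for wild-type-like "physiological twitches"),
injected as half-cosine displacement pulses whose magnitude is chosen so
the peak velocity hits a target sampled from 25–55 cm/s over 0.2–0.8 s —
inside the 20–60 cm/s detection band, since no quantitative jerk kinematics
are published. A jerk spawns a partner event 1–20 s later with probability
0.15 (the consecutive-event phenomenon). Jerks start ≥ 15 s after sleep
onset (sleep-onset latency) and ≥ 25 s apart; directions are wall-aware,
and a wall-clamped pulse is shortened in duration so its peak velocity (and
the ground-truth annotation) is preserved.

Tracking imperfections: AR(1)-correlated jitter (ρ = 0.9, stationary SD
0.05 cm) on every coordinate channel plus random dropout samples (10⁻³ per
sample). The correlation matters: white jitter of the same amplitude at
25 Hz would alias into ~1.8 cm/s velocity noise, which no real blob tracker
produces and which would swamp the 2.25 cm/s immobility threshold;
correlated jitter reproduces both the centimeter-scale positional error and
the quiet velocity floor of real tracking. Behavior and noise draw from
independent seeded streams, so a noise-free re-simulation of the same seed
has identical ground truth.

Body geometry for rendering and the two extra points: a constant-area
(13.7 cm²) ellipse whose axis ratio encodes elongation
(`r = 1 − e/100`, semi-major `a = √(A/πr)`, capped at 5 cm — a stretched
mouse stays ~10 cm long); nose and tail-base sit at 85 % of the semi-major
axis, the nose rotated off the trunk axis by the bend angle. The walk keeps
the center ≥ 5 cm from the walls so the whole body always lies inside the
arena; rendered blobs are therefore never truncated at the frame edge. A
consequence is that the simulated mouse never hugs the walls the way real
mice do — wall-following and thigmotaxis are not modeled.

### What passing the benchmarks does and does not show

The benchmarks demonstrate that the vectorized decision logic and an
independent literal reimplementation agree exactly, that the full chain
recovers known injected events at high recall/precision under realistic
noise, bout structure and dropouts, and that the statistics are calibrated.
They cannot certify performance on real recordings: real mice produce
postural shifts, slow-wave twitching, bedding occlusion and lighting
artifacts the simulator does not model, and the simulator's jerks are by
construction inside the detection band the detector looks for. Threshold
recalibration — particularly the elongation/body-angle bounds, whose
commercial definitions are unpublished and need not match this package's
mask-derived definitions (`100·(1 − minor/major)`; deviation of the
nose–center–tail triplet from collinearity) — should be expected on real
data; all thresholds are config-exposed for exactly that reason.

## The tracker

Background: per-pixel median over ≤ 200 uniformly subsampled frames
(valid while the animal occupies any pixel in a minority of frames).
Segmentation: Otsu threshold on |frame − background| (fixed-threshold
override for degenerate illumination), largest 8-connected component.
The nose is marked in rendered frames by a brighter terminal lobe; body
geometry is measured on the body pixels with the lobe excluded so the
marker does not bias the centroid or rotate the principal axis. Head/tail
identity comes from the lobe; frames without a distinguishable lobe fall
back to nearest-neighbor continuity with the previous frame. Failed frames
become missing samples and are handled by the standard gap policy.

## Statistics

Event counts are compared with a two-way genotype × age ANOVA — Type II
sums of squares, the conventional default for the mild imbalance of real
cohorts — followed by planned per-age genotype contrasts on the pooled
residual variance with Šídák adjustment `p_adj = 1 − (1 − p)^m` (m = number
of planned contrasts, recorded in the output). A repeated-measures variant
(mixed ANOVA: genotype between, age within) is provided for designs where
every animal is measured at every age; which variant a given study used is
often ambiguous, so both are exposed. Counts are analyzed untransformed by
default, mirroring common practice; a `log1p` option exists. Null
calibration uses Poisson-distributed counts (λ = 12, the scale of a
high-rate group over 3 h) at equal rates in both genotypes: the F test's
empirical type-I error stays within [0.03, 0.07] at α = 0.05.

## Problem sizes of the shipped benchmarks

The trajectory benchmark runs 24 four-hour sessions (12 at 4 jerks/h, 12 at
0.2/h; ~360 000 samples each); the video benchmark renders a 10-min
sleep-dominated session at 5 px/cm (15 000 frames of 150 × 150 px) with a
60/h jerk rate so the short window still contains a handful of events; the
brute-force cross-check uses randomized series of 1 500–5 000 samples; the
null calibration uses 500–1 000 replicates of a 2 × 3 × 8 design. These
sizes were chosen so the entire suite runs in a few minutes on one CPU
while keeping every check statistically meaningful.

## Known limitations

* Wakeful/action myoclonus is out of scope by design: events during
  locomotion are deliberately rejected, so the count is a sleep-myoclonus
  count.
* The voluntary-movement rules are declared stand-ins for human review; on
  real data their parameters (and the posture thresholds) may need
  recalibration, and rejected events should be spot-checked via the
  exported rejection reasons.
* A candidate-count monotonicity caveat: widening the burst band by
  *raising the upper* bound, or shortening the required pre-immobility,
  can only add candidates; *lowering the lower* bound also lengthens and
  merges velocity runs and can therefore push a run past the duration
  limit — the count is not monotone in that direction.
* The pixel-change and surrogate mobility measures agree on
  Immobile-vs-not at rest but are not numerically interchangeable mid-range.
* The simulator does not model wall-hugging, bedding occlusion, multi-animal
  cages, or circadian structure beyond the explore→sleep transition.
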