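# Methods

This note documents the models, conventions and numerical choices behind
`phenocage`, and what the synthetic-data generator does and does not
emulate.

## Traces, frames and event layers

A `TrackingTrace` is a uniformly sampled 2-D position track. Sample *i*
owns the frame `[i/rate, (i+1)/rate)`, so *n* samples cover `n/rate`
seconds and the per-layer events tile the trace exactly: shelter time +
movement time + arrest time = trace duration. Per-sample speed is the
forward-difference displacement times the sample rate; the last sample
inherits the previous step. Steps that cross the shelter boundary are
assigned zero locomotor speed, so movement events live strictly outside
the shelter and a teleport-style shelter entry/exit (as rendered by the
generator) cannot masquerade as a movement.

Segmentation thresholds (all exposed in `SegmentationConfig`):

| parameter | default | meaning |
|---|---|---|
| `v_move` | 2 cm/s | speed above which a frame counts as moving |
| `min_move_dur` | 0.5 s | shortest retained movement |
| `merge_gap` | 0.5 s | sub-threshold gap bridged inside one movement |
| `activity_merge_gap` | 5 s | gap bridged when merging movements into activity bouts |
| `v_freeze` | 1 cm/s | speed below which a frame counts as frozen |
| `min_freeze_dur` | 1 s | shortest retained freezing interval |
| `proximity_radius` | 2 cm | interaction margin beyond an object boundary |
| `min_conf` | 0.6 | keypoint confidence cutoff |
| `max_gap` | 1 s | longest tracking gap repaired by linear interpolation |
| `max_missing` | 20% | lost-frame fraction above which QC fails |

Commercial tracking software does not publish its internal thresholds;
these defaults are conventional for mouse tracking, and every derived
metric takes the configuration explicitly rather than relying on them.
Tracking gaps longer than `max_gap` are left missing and act as event
barriers (they split events); a trace with more than `max_missing` lost
frames is rejected with the offending spans listed.

Zone membership is decided on the point position with closed boundaries;
the four compass quadrants of a circular arena use a half-open convention
on the centre lines so they partition the disc exactly, which is what
makes per-quadrant relative distances sum to one identically. Distance of
step *i* is attributed to the zone of sample *i*. The body centre is the
shoulders/back centroid when keypoints are available, else the trace
point. Arena coordinates are arena-local: origin at the lower-left corner
for rectangles, at the centre for discs.

## Mixture thresholds

Shelter-visit durations (log2 seconds, 3 components) and movement
distances (log2 cm, 2 components) are fitted per animal by
expectation-maximisation on the raw log2 values — not by least squares on
a histogram; the fitted curves, and hence their intersections, are
equivalent, and EM is the statistically standard estimator. Ten seeded
restarts (k-distinct-points initialisation) are run and the best
likelihood kept; convergence is a relative log-likelihood change below
1e-8, with a standard-deviation floor of 1e-3 log2 units against
component collapse. Components are reported in ascending order of mean —
the only ordering consistent with "short" versus "long" events. Fewer
than 30 values, or constant input, yields a missing-flagged fit rather
than an error.

The long thresholds are the crossing point of two weighted component
densities, obtained in closed form from the quadratic
`A x² + B x + C = 0` that equates the weighted log-densities; the root
inside `(μ₁, μ₂)` is taken. If no crossing exists there (one component
dominates throughout), the weight-averaged midpoint
`(w₁μ₁ + w₂μ₂)/(w₁ + w₂)` is returned with a fallback flag. The
short-visit threshold is the Gaussian quantile `μ₁ + z₀.₉σ₁`. Arrest
durations are thresholded on the raw seconds scale with the nearest-rank
empirical 90th percentile (`sorted[ceil(0.9 n)] − 1`), which is
deterministic and scale-equivariant; the log2 transform is reserved for
visits and movements, matching the phenotyping scheme's usage.

Mixtures are fitted on all recorded days pooled per animal (more points
for EM); `PhenotypeConfig(mixtures_day_only=True)` restricts them to the
scoped day instead. Day-scoped quantities (totals, counts, cumulative
durations) use day 3 by default, the day least affected by novelty of the
cage.

## The activity profile and switch deltas

Recordings start at dark onset (default cycle: lights on 07:00–19:00,
trace time 0 at 19:00), so a 3-day recording contains dark phases 1–3
interleaved with light phases 1–3. Activity-bout seconds are accumulated
per clock hour; hour 1 is the first hour of a phase. The habituation
index is total dark-3 over total dark-1 activity (1 = no habituation;
below 1 = less activity on the third dark phase). Switch deltas compare
the mean hourly activity of a 2-h window — the last two hours of the
phase before a switch (anticipation) or the first two hours after it
(response) — against a baseline defined as the mean of hours 8–10 of the
phase before the switch, in s/h. Both windows of a switch share that
baseline.

## The 20-parameter registry

The registry emits exactly 20 named parameters per animal (see
`phenocage.REGISTRY`): activity totals and mean bout duration, the
habituation and dark–light indices, the four switch deltas, shelter visit
counts, the three mixture thresholds, cumulative short- and long-visit
durations, shelter time fraction, fraction of long movements, and
long-arrest statistics. Fourteen of these are named directly by the
published phenotyping scheme the registry follows; the remaining six
(flagged `registry_completed` in the output) complete the documented
cardinality of 20 with the scheme's natural companions, since the full
list lives in a reference we do not reproduce. Parameters whose inputs
are insufficient (too few events for a mixture, missing phases) are
flagged missing while the rest are still computed; strict mode requires
three full dark phases.

## Task metrics

Cognition-wall entries are classified against the current day's target:
correct, perseverative (the previous day's target, when it differs from
the current one), or neutral (the remaining hole). On the first day no
previous target exists, so all errors are neutral. Learning curves are
class fractions over consecutive, non-overlapping bins of 50 entries,
restarting at each daily switch by default; the trailing partial bin is
reported with its size. Group-average curves record how many animals
contribute per bin and flag bins with more than 3 contributors for
display, the usual plotting cutoff. The reward replay dispenses one
pellet per five cumulative correct entries (non-consecutive allowed); the
counter resets at each daily target switch by default because the rule is
tied to the day's target entrance — `reset_daily=False` carries it over.

Interaction scoring counts frames whose nose keypoint lies within
`proximity_radius` of a target boundary; frames below the confidence
cutoff are excluded from numerator and denominator alike, and a session
with fewer than 20% confident frames is rejected.

## Group statistics

The ladder mirrors standard multi-model phenotyping practice: Shapiro–
Wilk per group at α = 0.05; if any group fails, a single log10 transform
is attempted (positive data only); if all groups are then normal, one-way
ANOVA with Tukey HSD, otherwise Kruskal–Wallis with pairwise Mann–Whitney
tests run only when the omnibus is significant. Pairwise comparisons
follow the pooled-control convention: every model against the pooled
control always, model-versus-model only when at least one model differs
from the control. Mann–Whitney pairwise p-values are reported unadjusted
by default (Benjamini–Hochberg over the pairwise set is available as an
option). Chance-level tests use a one-sample t-test on normal data and
the Wilcoxon signed-rank test otherwise; samples exactly at chance are
reported as degenerate with p = 1. The FDR correction over the registry
is Benjamini–Hochberg step-up. Constant data anywhere yields a degenerate
flag with p = 1 rather than an error. The gate only selects the test
path; it never transforms the data used by the nonparametric branch.

The pooled-control consistency filter takes a tidy table in which control
animals carry the label of the model line they are littermates of. Per
parameter it asks: do the control subgroups differ among themselves
(two-group gate or Kruskal–Wallis for three or more subgroups)? is any
model significant against the pooled control? is any such model also
significant against its own littermate controls? A parameter is excluded
exactly when the subgroups differ, the pooled comparison is significant,
and no pooled-significant model confirms against its own controls — the
signature of a pooling artifact.

Time-course comparisons (linear mixed models) are deliberately not
implemented; the tidy per-bin tables the pipeline exports are the
intended input for a dedicated mixed-model backend.

## The synthetic-behavior generator

The generator produces the statistical structure the analysis assumes,
with exact frame-aligned ground truth; it makes no claim of
biomechanical realism (no body kinematics, no video). The true
distributions of mouse behavior are unknown; the families below are a
documented modeling choice.

Timeline: the animal alternates outside-shelter segments and shelter
visits. Visit durations are drawn from the 3-component log2 mixture
(defaults w = 0.3/0.4/0.3, μ = 4/7/11 log2-s, σ = 0.5 — i.e. modes near
16 s, 2 min and 34 min); entries occur with per-phase exponential waiting
times (defaults 2/h dark, 5/h light of outside time). Within outside
segments, activity bouts arrive as a thinned Poisson process with
per-phase rates (defaults 20/h dark, 4/h light) and lognormal durations
(median 40 s), multiplicatively modulated in the 2-h windows around light
switches (defaults: ×1.5 anticipation and ×1.8 response to dark, ×1.2 and
×0.6 around lights-on — an anticipating, dark-active animal). Bouts are
filled with movements whose distances come from the 2-component log2
mixture (defaults μ = 2/5 log2-cm, σ = 0.5), separated by lognormal
within-bout arrest gaps clipped to lie strictly between the merge gap and
the activity merge gap, so segmentation boundaries are unambiguous.
Movement speed along the path is 8 cm/s with a duration floor that keeps
every movement above both the speed and minimum-duration thresholds
(distances are clipped to the minimum detectable, ≈1.2 cm at 20
samples/s, a negligible tail of the mixture). All event boundaries are
snapped to the frame grid.

Rendering: positions follow a bounded random walk of equal-length steps
during movements (total step length equals the drawn movement distance
exactly), constant position during arrests and visits (shelter centre
while inside, previous outside position restored on exit). Optional
Gaussian position jitter is available and defaults to zero so that
segmentation can be validated exactly.

Because the generator quantises to frames and renders rest as perfectly
still, passing the reconstruction tests shows the segmentation logic is
exact on clean input — it does not show robustness to tracker noise,
reflections, body-size effects or missing frames beyond the interpolation
rule, none of which the generator emulates.

The cognition-wall agent makes Poisson entries with an hourly rate
profile; each entry is correct with probability `p_correct`, and errors
go to the previous day's target with probability `perseveration_weight`
when a distinct previous target exists. Probe trials for chance-level
studies use a fresh-direction isotropic random walk in the circular arena
with a radial-fold reflective boundary and a swim-like default speed of
20 cm/s; by symmetry each quadrant's expected share of path length is
0.25. The per-trial share has a standard deviation near 0.29 because the
angular coordinate of such a walk mixes slowly, so the 500-trial mean
carries a Monte-Carlo s.e. of about 0.013 — the scale against which the
chance-level study should be read.

Cohorts spawn per-animal seeds deterministically from the cohort seed
(`numpy` `SeedSequence`); group effects are additive offsets on named
generator knobs and are recorded as ground truth. All simulation takes
explicit seeds; no global random state is used or mutated.

## Problem sizes and numerical conventions

The bundled fixture cohort is 4 groups × 4 animals, one simulated day at
2 samples/s — small enough to rebuild from scratch in seconds while
exercising every reader and the full pipeline. Estimator studies sample
visit durations directly from the mixture (1,000 visits ≈ 8 recording
days) rather than rendering traces; simulation-based tests use 1–3 day
event-level simulations at 5 samples/s. Ties in zone membership go to
the zone (closed boundaries); quadrant partitions use half-open centre
lines; empirical percentiles are nearest-rank; EM restarts, tolerances
and floors are as above; p-values are reported untruncated and the FDR
adjustment is capped at 1.

## Known limitations

* The generator's outside/shelter alternation is a renewal process;
  phase changes during a single waiting interval use the rate of the
  phase at the interval's start.
* At high bout rates the sequential thinning saturates (bout plus guard
  gap consume timeline), compressing nominal rate ratios; rate parameters
  are calibrated conditions, not guarantees of realized event counts.
* Tukey HSD cross-checks against other backends are limited by the
  reference's studentized-range approximation (~1e-3), not by this
  package's computation.
* The consistency filter operates per parameter with two-group gates; it
  does not model correlation between parameters.
* No circadian modeling beyond the defined parameters (no periodograms or
  actograms), no pose estimation, no multi-animal tracking, no mixed
  models.
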