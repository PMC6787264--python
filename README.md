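# walkmem

Scoring and statistics for **wearable-camera (lifelog) autobiographical-memory
experiments**, with a calibrated synthetic cohort generator.

In this paradigm a participant lives a controlled real-world event — a ~1-hour
guided city walk photographed automatically every 10 s — and returns a week
later to have their memory of it probed: they segment a replay slideshow of
their own pictures into events, chronologically reorder picture series and
five-card story sequences, and freely recall the walk, with narratives coded
into experience units and components. The package is for researchers analysing
such cohorts (e.g. patient vs control comparisons in computational psychiatry):
it implements the task scores, the group-comparison battery, and a generative
model of the whole data set so every stage is testable without access to raw
participant data.

## The scores

**Event segmentation.** Each participant's boundary presses (picture indices on
their own slideshow of `N_i` pictures) are normalized to a common timeline,
`x = index / N_i ∈ [0, 1)`. Pooled presses of a separate reference group
(n = 12) are agglomerated — sweeping the sorted positions, a press joins the
current cluster while it lies within a window `w` (default 0.02) of the running
cluster mean — into *prototypical boundaries* with position = member mean and
frequency `f_k` = number of distinct contributing reference participants.
For a participant with presses `x_1 … x_B` matched to prototypes (nearest
within ±`w`, one press per prototype):

- **typicality** = `(1/B) Σ_j f(x_j)`, where `f(x_j)` is the matched
  prototype's frequency (top-20 prototypes; unmatched presses score 0);
  range [0, 12], higher = segmentation agrees with the majority;
- **temporal accuracy** = `100 · mean_j |x_j − p(x_j)|` over matched presses
  (top-30 prototypes), in percentage points of the timeline; higher = worse.

**Chronological organisation.** For three series of 12 pictures:
chronological score = mean number of fixed points (`response[i] = i`) per
series; deviation score = mean absolute displacement `|placed − correct|` per
picture. For 8 behavioural and 8 theory-of-mind five-card stories: error
score = total number of incorrectly placed cards (Hamming).

**Free recall.** Items = `|recalled ∩ checklist|` against a reference-group
checklist; experience-unit component *prevalence* = % of units containing ≥1
component of each of eight categories (person, object, thought, action with
interaction, spatial movement, perceptual detail, spatial detail, comment).

**Statistics.** Pooled (Student) two-sample t from raw scores or printed
summary cells; standardized effect size with explicit direction and
denominator flags (default Glass's Δ = Δmean / SD_control); 2×2 mixed ANOVA
(group × boundary category); Pearson correlations with Bonferroni; Cohen's κ
and ICC(2,1) for rater agreement.

**Synthetic cohorts.** A ground-truth walk schema (≥30 transitions with
saliences and perceptual/action labels) plus per-group noise parameters:
transition detection `P = rate · salience`, Gaussian press jitter, Poisson
spurious presses; Mallows permutation noise
`P(π) ∝ exp(−θ·Kendall(π, id))` for ordering; negative-binomial counts and
per-unit component presence for recall; binomial TOJ errors. Defaults are
calibrated once against the published group summary cells
(`src/walkmem/data/calibration.json`).

## Worked example

```python
from walkmem import simulate_cohort, run_pipeline

sim = simulate_cohort(seed=1)          # 27 patients, 27 controls, 12 reference
result = run_pipeline(sim.cohort, seed=1)
print(result.comparisons.set_index("label").loc[
    ["n_items", "pct_action_with_interaction", "typicality",
     "temporal_accuracy", "chronological_score"],
    ["patient_mean", "control_mean", "t", "p", "d"]].round(3))
```

prints

```
                             patient_mean  control_mean      t      p      d
label
n_items                            24.185        32.333 -5.199  0.000 -1.625
pct_action_with_interaction        16.905        31.570 -5.890  0.000 -1.624
typicality                          4.979         5.089 -0.680  0.500 -0.161
temporal_accuracy                   0.818         0.822 -0.112  0.911 -0.025
chronological_score                 7.679         7.222  1.159  0.252  0.288
```

— the paradigm's characteristic dissociation: large, significant patient
deficits in recall *content* (fewer checklist items; about half the
action-with-interaction prevalence), while event segmentation (typicality,
temporal accuracy) and chronological ordering show null group differences.
The accompanying 2×2 ANOVA finds a strong boundary-category main effect
(more perceptual than action boundaries) with no group or interaction effect,
and the dual-rater category labels give κ ≈ 0.77.

More narrative walk-throughs live in `examples/` (one script per capability:
prototype scoring by hand, Mallows ordering noise, recomputing published
statistics, jitter parameter recovery).

A thin CLI wraps the same machinery for shell use:

```bash
walkmem simulate --seed 7 --out cohort/
walkmem score --in cohort/ --out results/
walkmem recompute --out results/        # packaged summary cells
```

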