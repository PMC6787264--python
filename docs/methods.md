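# Methods

This note documents the models, conventions and numerical choices behind
`walkmem`, in the order data flow through the pipeline.

## Data model and normalization

Slideshows are unique per participant (walk durations varied), so boundary
presses are only comparable after normalization. A press at picture index
`i` (0-based) on a slideshow of `N` pictures maps to `x = i / N` on the
half-open timeline `[0, 1)`. Pictures are the only recorded clock, so
normalization divides by picture count, not wall-clock duration. All
cross-participant machinery (prototypes, matching, scores) operates on this
timeline.

Validation is total: records violating an invariant (non-permutation
ordering responses, out-of-range picture indices, duplicate presses, TOJ
errors exceeding trials, unknown category labels) cannot enter a `Cohort`,
and file loaders report the offending CSV row.

## Prototypical boundaries

Reference-group presses are pooled, sorted, and agglomerated by a
single-linkage sweep: a press joins the current cluster while it lies within
`w` of the running cluster mean, else it opens a new cluster. The window
comparison carries an absolute slack of 1e-12 so positions exactly `w` apart
are inside the window regardless of float representation; a cluster of
identical positions reports exactly that position as its mean. For ≤6 pooled
presses the sweep provably equals exhaustive enumeration of feasible
contiguous partitions with lexicographically maximal block lengths (every
prefix of a feasible block is feasible, so greedy extension is maximal);
the test suite enforces this equivalence on random cases.

A prototype's *frequency* counts distinct contributing participants —
two presses by one participant inside a cluster count once — and prototypes
are ranked by descending frequency, ties broken by earlier position.

**Matching.** Candidate (press, prototype) pairs within ±`w` are accepted
greedily in order of increasing distance; distances are snapped to 1e-9
before sorting so exact ties (up to representation noise) resolve toward the
more frequent prototype. Each press matches at most one prototype and each
prototype accepts at most one press per participant (nearest wins, the loser
becomes unmatched).

**Scores.** Typicality uses the top-20 prototypes: the press score is the
matched prototype's raw frequency (0–12 for a 12-person reference) and
unmatched presses contribute 0 to the participant mean. Including unmatched
presses is a deliberate choice: it makes typicality decrease strictly when
spurious presses are appended, which reproduces the negative association
between number of boundaries and typicality expected when extra presses are
random. Temporal accuracy uses the top-30 prototypes and is the mean
absolute press-to-prototype deviation over *matched* presses only, reported
×100 (percentage points of the timeline); a participant whose presses match
nothing gets a missing value, excluded from group statistics. Rater 1's
category labels are authoritative for the perceptual/action counts; rater 2
exists for the κ audit.

The window default `w = 0.02` (±2% of the timeline ≈ ±7 pictures ≈ ±72 s of
walk) keeps top-30 prototypes of a 12-person reference group well separated
for realistic transition spacing; it is configurable in `StudyConfig`.

## Ordering scores

The *deviation score* is the mean absolute positional displacement per
picture. A literal "number of pictures out of place" reading would be
redundant with (12 − chronological score) and inconsistent with the
magnitudes the tasks produce, whereas mean displacement is a proper
resolution-preserving distance; this interpretation is flagged as such.
Story sequencing uses Hamming error (count of positions whose card is
wrong), summed over the eight stories of a type, and the combined story
score is the mean of the two type totals.

## Recall scores

Component percentages are *per-unit presence rates*: the share of a
participant's experience units containing at least one component of a
category. Categories are non-exclusive, so prevalences need not sum to 100;
a presence rate is also the only reading guaranteed ≤ 100 when units hold
several components. An experience unit carries at least one component by
construction (a unit describes at least one piece of information), which
also makes the long-CSV representation lossless. Checklist items are opaque
identifiers matched exactly; the reference checklist defaults to the union
of the reference group's recalled items, and a cohort without a reference
group degrades to counting items as recorded, with a warning.

## Statistical battery

- Student (pooled-variance) t, not Welch: the design is balanced and the
  summary-cell recomputation mode must reproduce pooled-t arithmetic.
  `pooled_t` on raw data equals `pooled_t` on that data's exact summaries to
  1e-10 by construction (the raw path computes the summaries first).
- Effect sizes take explicit `direction` and `d_denominator` flags,
  defaulting to Glass's Δ with the control-group SD, patient minus control:
  recomputation of the published full-sample cells matches that convention
  (e.g. (25.17 − 31.11)/5.33 = −1.11), with per-row sign flags because the
  published d column is deficit-negative while the t column is consistently
  patient-minus-control. Rows whose printed effect sizes match no
  identifiable convention (the verbal-fluency pair, and the verbatim-subset
  rows with unreported subgroup sizes) are transcribed but not treated as
  reproducible.
- The 2×2 mixed ANOVA delegates to `pingouin.mixed_anova`; with two
  within-subject levels the category F equals the squared paired t on the
  condition difference after removing the group effect (enforced to 1e-8 in
  tests). A fully constant input returns all-zero F rather than 0/0.
- κ delegates to scikit-learn with the degenerate both-raters-constant case
  defined as 1; ICC is the two-way random-effects, absolute-agreement,
  single-rater form ICC(2,1) (configurable to the consistency form
  ICC(3,1)), validated against a mean-squares hand computation. The ICC is
  an error only when the ratings table is fully constant (denominator 0);
  zero between-subject variance with residual variance yields a legitimate
  negative ICC.
- Correlations are pairwise-deleted Pearson with two-sided p; Bonferroni
  multiplies by the number of pairs tested (capped at 1) unless an explicit
  m is supplied. p-values are two-sided throughout.

## Synthetic cohort generator

The generator emulates the study conditions — a 360-picture walk (1 h at
10-s intervals, per-participant length varying ±8%), a 12-person reference
group and two 27-person comparison groups — with one master seed spawning
independent sub-streams per task, so identical seeds give byte-identical
cohorts.

- **Walk schema**: 32 transitions on a jittered grid (neighbours ≥ 0.019
  apart, keeping prototype windows mostly disjoint at w = 0.02), saliences
  Beta(5, 2), 60% perceptual labels (the direction of the observed
  boundary-category main effect).
- **Segmentation**: transition `i` is marked with probability
  `detection_rate · salience_i` (default 0.75), press position jittered with
  SD 0.010 on the timeline, plus Poisson(2) spurious presses labelled
  perceptual (fine segmentation is sensory-driven). Rater 2 flips each
  category label with probability 0.11, which yields κ ≈ 0.77 at the
  simulated label margins. Patients and controls share these parameters:
  the study found no group differences on any segmentation score.
- **Ordering**: Mallows noise sampled by repeated insertion — the simplest
  one-parameter family over permutations with the right limits (uniform at
  θ = 0, identity as θ → ∞). θ = 1.5 for picture series in both groups
  (≈7.4/12 correct); story θ per type and group chosen so story error totals
  sit at the published group means (a single θ cannot simultaneously match
  the published chronological and deviation means — real responses evidently
  mix near-correct placement with occasional long-range dislocations the
  one-parameter family does not capture; the chronological scale was
  matched).
- **Recall**: counts are negative binomial (overdispersed where the
  published SDs demand it; the control item-count cell is *under*dispersed
  relative to Poisson, so the Poisson limit is used there and the simulated
  SD is ~5.6 against the published 5.33), capped at the 40-item checklist.
  Unit components are independent per-category presence draws, redrawn
  conditional on at least one component; action-with-interaction presence
  is group-dependent (0.171 vs 0.294), the driver of the content deficit.
- **TOJ**: binomial errors over 160 trials at 100 ms SOA and 20 trials at
  500 ms, rates 0.07/0.06 (patients) and 0.03/0.02 (controls).

Calibration targets and values live in `data/calibration.json`; they were
fixed once against the published summary cells and are not free test knobs.

**What the generator does not model** — and hence what passing tests do not
show about real data: response latencies and backward scrubbing during
segmentation; which pictures compose the ordering series; any
encoding/retrieval distinction or drift-diffusion-style process realism;
correlations between tasks within a participant beyond those induced by
group membership (latent cross-task traits are absent, so simulated
correlation matrices are null beyond group structure); and higher moments of
the count distributions, which the published summaries do not constrain.

## Problem sizes

Defaults mirror the study (27 + 27 + 12 participants; 3×12 series; 8+8
stories; 160/20 TOJ trials). The heavier diagnostics run at sizes chosen for
stable statistics: calibration mean checks at n = 2000/group, the uniform
fixed-point limit at 20 000 draws, the headline dissociation over 100
simulated cohorts with a majority criterion, and jitter recovery over 50
participants against a low-noise reference consensus (press jitter 0.003,
participant jitter uniform on [0.001, 0.010] — inside the matching window so
deviations are observed rather than truncated).

## Known limitations

- The exact frequency-to-score mapping for typicality and the study's
  press-to-prototype matching rule are not documented anywhere public; raw
  frequency and nearest-within-window matching are assumptions, flagged
  above, and the absolute typicality/temporal-accuracy levels produced by
  the generator (≈5.0 and ≈0.8) accordingly sit below the published ≈6.1 and
  ≈1.6 while all directional and dissociation properties reproduce.
- `run_pipeline` reports κ for the dual category labels; an ICC cannot be
  computed from the cohort schema (it carries no dual continuous ratings),
  so `icc_agreement` is exposed at the library level instead.
- Printed t values reproduce the published ones only to the rounding of the
  printed means/SDs (±0.01–0.07 for most rows; worse where the underlying
  values are small, e.g. TOJ proportions printed to 2 decimals); one
  published deviation-score t (−0.34) is inconsistent with its own summary
  cells and p-value and recomputes to −0.04.
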