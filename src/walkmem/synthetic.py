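"""Synthetic cohort generator.

Emulates the data-generating conditions of a wearable-camera memory
protocol so the whole pipeline is testable without raw data: a ~1-h walk
discretized into ~360 pictures (one per 10 s) with a fixed ground-truth
event structure; a 12-person reference group plus two 27-person
comparison groups; boundary presses clustered around true transitions
with group-dependent detection, jitter and spurious presses; Mallows
permutation noise for the ordering tasks; negative-binomial counts and
per-unit component presence for free recall; and Bernoulli trial errors
for the TOJ task.

Default parameters live in ``data/calibration.json`` together with the
published group summary cells they were calibrated against.  One master
seed drives every sub-stream (via ``numpy.random.SeedSequence``):
identical seeds give byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    BoundaryCategory,
    BoundaryRecord,
    Cohort,
    ExperienceUnit,
    Group,
    OrderingResponse,
    ParticipantRecord,
    RecallCoding,
    StudyConfig,
    Task,
    TOJRecord,
    ValidationError,
)


@dataclass(frozen=True)
class Transition:
    """A true event transition of the walk."""

    position: float  # normalized [0, 1)
    salience: float  # (0, 1]; scales detection probability
    category: BoundaryCategory


@dataclass(frozen=True)
class WalkSchema:
    """Ground-truth event structure of the circuit."""

    transitions: tuple[Transition, ...]
    n_pictures: int

    def __post_init__(self) -> None:
        pos = [t.position for t in self.transitions]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValidationError("transition positions must be strictly increasing")
        if any(not (0 <= p < 1) for p in pos):
            raise ValidationError("transition positions must lie in [0, 1)")


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one participant group."""

    detection_rate: float = 0.75  # base P(transition marked), scaled by salience
    jitter_sd: float = 0.010  # SD of Gaussian press-position noise (timeline fraction)
    extra_press_rate: float = 2.0  # Poisson mean of spurious presses
    rater_disagreement: float = 0.11  # P(rater 2 flips the category label)
    mallows_theta: float = 1.5  # picture-series ordering concentration
    story_theta_behavioral: float = 2.45
    story_theta_tom: float = 1.65
    recall_mean: float = 28.0
    recall_dispersion: float = 20.0  # NB size parameter; large => Poisson limit
    units_mean: float = 25.0
    units_dispersion: float = 20.0
    component_probs: Mapping[str, float] = field(default_factory=dict)
    toj_error_rate_100: float = 0.05
    toj_error_rate_500: float = 0.04

    def __post_init__(self) -> None:
        for name in (
            "detection_rate",
            "rater_disagreement",
            "toj_error_rate_100",
            "toj_error_rate_500",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("jitter_sd", "extra_press_rate", "mallows_theta",
                     "story_theta_behavioral", "story_theta_tom"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for cat, p in self.component_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"component_probs[{cat}] must lie in [0, 1]")
        if self.recall_mean <= 0 or self.recall_dispersion <= 0:
            raise ValidationError("recall_mean and recall_dispersion must be > 0")
        if self.units_mean <= 0 or self.units_dispersion <= 0:
            raise ValidationError("units_mean and units_dispersion must be > 0")


def load_calibration() -> dict:
    """The versioned default-parameter file shipped with the package."""
    with resources.files("walkmem.data").joinpath("calibration.json").open() as fh:
        return json.load(fh)


def default_group_params() -> dict[Group, GroupParams]:
    cal = load_calibration()
    return {
        Group(name): GroupParams(**params) for name, params in cal["groups"].items()
    }


def make_walk_schema(
    k_transitions: int = 32,
    seed: int | np.random.SeedSequence = 0,
    perceptual_fraction: float = 0.6,
    n_pictures: int = 360,
    salience_beta: tuple[float, float] = (5.0, 2.0),
    min_k: int = 30,
) -> WalkSchema:
    """Draw a ground-truth walk: jittered-grid transition positions
    (strictly increasing, well separated), Beta-distributed saliences,
    and categories with a perceptual majority (the study direction:
    more fine/perceptual than coarse/action boundaries)."""
    if k_transitions < min_k:
        raise ValidationError(
            f"k_transitions must be >= {min_k} (top-k prototype scoring), "
            f"got {k_transitions}"
        )
    rng = np.random.default_rng(seed)
    # one transition per grid cell keeps neighbours >= 0.6/k apart
    positions = (np.arange(k_transitions) + rng.uniform(0.3, 0.7, k_transitions)) / k_transitions
    saliences = rng.beta(*salience_beta, size=k_transitions)
    saliences = np.clip(saliences, 0.05, 1.0)
    is_perc = rng.random(k_transitions) < perceptual_fraction
    return WalkSchema(
        transitions=tuple(
            Transition(
                position=float(p),
                salience=float(s),
                category=BoundaryCategory.PERCEPTUAL if f else BoundaryCategory.ACTION,
            )
            for p, s, f in zip(positions, saliences, is_perc)
        ),
        n_pictures=n_pictures,
    )


def simulate_participant_boundaries(
    schema: WalkSchema,
    params: GroupParams,
    total_pictures: int,
    rng: np.random.Generator,
    participant_id: str,
) -> list[BoundaryRecord]:
    """One participant's boundary presses on their own slideshow.

    Transition i is marked with probability detection_rate * salience_i;
    the press lands at the transition position plus Gaussian jitter
    (clipped to [0, 1)) and inherits the transition's category.  A
    Poisson number of spurious presses fall uniformly on the timeline,
    labeled perceptual (sensory-driven fine segmentation).  Presses
    colliding on the same picture index are merged; rater 2 relabels
    each press independently with probability ``rater_disagreement``.
    """
    presses: dict[int, BoundaryCategory] = {}
    for tr in schema.transitions:
        if rng.random() < params.detection_rate * tr.salience:
            pos = tr.position + rng.normal(0.0, params.jitter_sd)
            pos = min(max(pos, 0.0), 1.0 - 1.0 / total_pictures)
            idx = min(int(pos * total_pictures), total_pictures - 1)
            presses.setdefault(idx, tr.category)
    for _ in range(rng.poisson(params.extra_press_rate)):
        idx = int(rng.integers(0, total_pictures))
        presses.setdefault(idx, BoundaryCategory.PERCEPTUAL)
    records = []
    for idx in sorted(presses):
        cat1 = presses[idx]
        if rng.random() < params.rater_disagreement:
            cat2 = (
                BoundaryCategory.ACTION
                if cat1 == BoundaryCategory.PERCEPTUAL
                else BoundaryCategory.PERCEPTUAL
            )
        else:
            cat2 = cat1
        records.append(
            BoundaryRecord(
                participant_id=participant_id,
                picture_index=idx,
                category_rater1=cat1,
                category_rater2=cat2,
            )
        )
    return records


def simulate_segmentation_cohort(
    schema: WalkSchema,
    group_specs: Mapping[Group, tuple[GroupParams, int]],
    seed: int | np.random.SeedSequence = 0,
    length_jitter: float = 0.08,
) -> tuple[dict[str, ParticipantRecord], dict[str, list[BoundaryRecord]]]:
    """Boundary presses for every participant of every group.

    Slideshow lengths vary per participant by ±``length_jitter`` around
    the schema's nominal picture count (walk durations differed).
    """
    rng = np.random.default_rng(seed)
    participants: dict[str, ParticipantRecord] = {}
    boundaries: dict[str, list[BoundaryRecord]] = {}
    prefixes = {Group.PATIENT: "pat", Group.CONTROL: "ctl", Group.REFERENCE: "ref"}
    for group in sorted(group_specs, key=lambda g: g.value):
        params, n = group_specs[group]
        for i in range(1, n + 1):
            pid = f"{prefixes[group]}_{i:02d}"
            total = int(round(schema.n_pictures * rng.uniform(1 - length_jitter, 1 + length_jitter)))
            participants[pid] = ParticipantRecord(
                participant_id=pid, group=group, total_pictures=total
            )
            boundaries[pid] = simulate_participant_boundaries(
                schema, params, total, rng, pid
            )
    return participants, boundaries


def sample_mallows(
    rng: np.random.Generator, length: int, theta: float
) -> tuple[int, ...]:
    """Draw a permutation from the Mallows distribution,
    P(pi) ∝ exp(-theta * Kendall(pi, identity)), by repeated insertion.

    Item i (1-based) is inserted at position j of the partial sequence
    with probability proportional to exp(-theta * (i - j)); theta = 0
    is the uniform distribution, large theta concentrates on the
    identity.
    """
    perm: list[int] = []
    for i in range(1, length + 1):
        # j ranges over insertion slots 1..i; slot i (the end) costs 0 inversions
        costs = np.arange(i - 1, -1, -1, dtype=float)  # inversions for slots 1..i
        w = np.exp(-theta * costs)
        j = int(rng.choice(i, p=w / w.sum()))
        perm.insert(j, i)
    return tuple(perm)


def simulate_ordering_cohort(
    params_by_pid: Mapping[str, GroupParams],
    seed: int | np.random.SeedSequence = 0,
    config: Optional[StudyConfig] = None,
) -> list[OrderingResponse]:
    """Mallows-noise responses for the picture series and both story
    types, for each participant (keyed by participant id)."""
    cfg = config or StudyConfig()
    rng = np.random.default_rng(seed)
    responses = []
    for pid in sorted(params_by_pid):
        params = params_by_pid[pid]
        for s in range(1, cfg.n_series + 1):
            responses.append(
                OrderingResponse(
                    participant_id=pid,
                    task=Task.PICTURE_SERIES,
                    series_id=f"series_{s}",
                    response_order=sample_mallows(
                        rng, cfg.series_length, params.mallows_theta
                    ),
                )
            )
        for task, theta in (
            (Task.BEHAVIORAL_STORY, params.story_theta_behavioral),
            (Task.TOM_STORY, params.story_theta_tom),
        ):
            for s in range(1, cfg.n_stories + 1):
                responses.append(
                    OrderingResponse(
                        participant_id=pid,
                        task=task,
                        series_id=f"{task.value}_{s}",
                        response_order=sample_mallows(rng, cfg.story_length, theta),
                    )
                )
    return responses


def _neg_binomial(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """NB(mean, size) draw; size -> inf recovers Poisson."""
    if dispersion > 1e5:
        return int(rng.poisson(mean))
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_recall_cohort(
    params_by_pid: Mapping[str, GroupParams],
    seed: int | np.random.SeedSequence = 0,
    checklist_size: int = 40,
) -> dict[str, RecallCoding]:
    """Checklist items and coded experience units per participant.

    Item counts are negative binomial (capped at the checklist size),
    items drawn without replacement from the canonical item universe;
    unit counts likewise; each unit's components are independent
    per-category presence draws.
    """
    rng = np.random.default_rng(seed)
    universe = [f"item_{i:03d}" for i in range(checklist_size)]
    recalls = {}
    for pid in sorted(params_by_pid):
        params = params_by_pid[pid]
        n_items = min(
            _neg_binomial(rng, params.recall_mean, params.recall_dispersion),
            checklist_size,
        )
        items = frozenset(
            str(x) for x in rng.choice(universe, size=n_items, replace=False)
        )
        n_units = max(_neg_binomial(rng, params.units_mean, params.units_dispersion), 1)
        units = []
        for u in range(1, n_units + 1):
            # a coded unit holds >= 1 component: redraw conditional on non-empty
            comps: tuple[str, ...] = ()
            while not comps:
                comps = tuple(
                    cat
                    for cat, prob in params.component_probs.items()
                    if rng.random() < prob
                )
            units.append(ExperienceUnit(unit_id=f"{pid}_u{u:03d}", components=comps))
        recalls[pid] = RecallCoding(
            participant_id=pid, checklist_items=items, units=tuple(units)
        )
    return recalls


def simulate_toj_cohort(
    params_by_pid: Mapping[str, GroupParams],
    seed: int | np.random.SeedSequence = 0,
    n_trials_100: int = 160,
    n_trials_500: int = 20,
) -> list[TOJRecord]:
    """Binomial error counts at both stimulus onset asynchronies."""
    rng = np.random.default_rng(seed)
    records = []
    for pid in sorted(params_by_pid):
        params = params_by_pid[pid]
        records.append(
            TOJRecord(
                participant_id=pid,
                soa_ms=100,
                n_trials=n_trials_100,
                n_errors=int(rng.binomial(n_trials_100, params.toj_error_rate_100)),
            )
        )
        records.append(
            TOJRecord(
                participant_id=pid,
                soa_ms=500,
                n_trials=n_trials_500,
                n_errors=int(rng.binomial(n_trials_500, params.toj_error_rate_500)),
            )
        )
    return records


def jitter_recovery_experiment(
    n_participants: int = 50,
    seed: int = 0,
    jitter_range: tuple[float, float] = (0.001, 0.010),
    w: float = 0.02,
) -> pd.DataFrame:
    """Parameter-recovery experiment for the temporal-accuracy score.

    Builds a low-noise 12-person reference consensus (press jitter
    0.003, so the prototypes sit close to the true transitions), then
    simulates ``n_participants`` whose press jitter SD is drawn
    uniformly from ``jitter_range`` — chosen inside the matching window
    so deviations are observable rather than truncated — and scores
    each against the consensus.  Returns a frame with the true
    ``jitter_sd`` and measured ``temporal_accuracy`` per participant;
    the rank correlation between the two is the recovery diagnostic.
    """
    from .segmentation import (
        build_prototypes,
        normalize_boundaries,
        temporal_accuracy_score,
    )

    rng = np.random.default_rng(seed)
    schema = make_walk_schema(32, seed=np.random.SeedSequence(seed).spawn(1)[0])
    ref_params = GroupParams(
        jitter_sd=0.003, extra_press_rate=0.5, detection_rate=0.9
    )
    reference = {
        f"ref_{i:02d}": normalize_boundaries(
            simulate_participant_boundaries(
                schema, ref_params, schema.n_pictures, rng, f"ref_{i:02d}"
            ),
            schema.n_pictures,
        )
        for i in range(12)
    }
    prototypes = build_prototypes(reference, w, 30)
    rows = []
    for i in range(n_participants):
        jitter = float(rng.uniform(*jitter_range))
        params = GroupParams(
            jitter_sd=jitter, extra_press_rate=1.0, detection_rate=0.9
        )
        pid = f"sub_{i:02d}"
        normalized = normalize_boundaries(
            simulate_participant_boundaries(
                schema, params, schema.n_pictures, rng, pid
            ),
            schema.n_pictures,
        )
        rows.append(
            {
                "participant_id": pid,
                "jitter_sd": jitter,
                "temporal_accuracy": temporal_accuracy_score(
                    normalized, prototypes, w
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SimulatedCohort:
    """A generated cohort plus its ground truth (for recovery tests)."""

    cohort: Cohort
    schema: WalkSchema
    latents: pd.DataFrame  # per-participant true generator parameters


def simulate_cohort(
    seed: int = 0,
    config: Optional[StudyConfig] = None,
    group_params: Optional[Mapping[Group, GroupParams]] = None,
    n_patients: int = 27,
    n_controls: int = 27,
    n_reference: int = 12,
) -> SimulatedCohort:
    """Generate a complete study cohort under the default (calibrated)
    conditions: 27 patients, 27 controls, a 12-person reference group.

    Deterministic: a single master seed spawns independent sub-streams
    for the walk schema, segmentation, ordering, recall and TOJ data.
    """
    cfg = config or StudyConfig(rng_seed=seed)
    params = dict(group_params or default_group_params())
    cal = load_calibration()
    master = np.random.SeedSequence(seed)
    ss_walk, ss_seg, ss_ord, ss_rec, ss_toj = master.spawn(5)

    walk = cal["walk"]
    schema = make_walk_schema(
        k_transitions=max(walk["k_transitions"], cfg.top_k_accuracy),
        seed=ss_walk,
        perceptual_fraction=walk["perceptual_fraction"],
        n_pictures=cfg.n_pictures,
        salience_beta=(walk["salience_beta_a"], walk["salience_beta_b"]),
        min_k=cfg.top_k_accuracy,
    )
    specs = {
        Group.PATIENT: (params[Group.PATIENT], n_patients),
        Group.CONTROL: (params[Group.CONTROL], n_controls),
        Group.REFERENCE: (params[Group.REFERENCE], n_reference),
    }
    participants, boundaries = simulate_segmentation_cohort(
        schema, specs, seed=ss_seg, length_jitter=walk["length_jitter"]
    )
    by_pid = {
        pid: params[part.group] for pid, part in participants.items()
    }
    orderings = simulate_ordering_cohort(by_pid, seed=ss_ord, config=cfg)
    recalls = simulate_recall_cohort(
        by_pid, seed=ss_rec, checklist_size=cal["checklist_size"]
    )
    toj = simulate_toj_cohort(by_pid, seed=ss_toj)
    cohort = Cohort(
        participants=participants,
        boundaries=boundaries,
        orderings=orderings,
        recalls=recalls,
        toj=toj,
        config=cfg,
    )
    latents = pd.DataFrame(
        [
            {
                "participant_id": pid,
                "group": part.group.value,
                "total_pictures": part.total_pictures,
                "jitter_sd": by_pid[pid].jitter_sd,
                "detection_rate": by_pid[pid].detection_rate,
                "extra_press_rate": by_pid[pid].extra_press_rate,
                "mallows_theta": by_pid[pid].mallows_theta,
            }
            for pid, part in participants.items()
        ]
    )
    return SimulatedCohort(cohort=cohort, schema=schema, latents=latents)
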