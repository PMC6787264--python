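"""Domain types for wearable-camera memory experiments.

The data model covers the four behavioural artifacts produced by a
lifelog memory protocol: event-boundary presses on a picture slideshow,
chronological-ordering responses (picture series and five-card story
sequences), coded free-recall narratives, and temporal-order-judgment
(TOJ) trial counts.  Records are plain frozen dataclasses; validation is
total — a record violating an invariant cannot be constructed, and a
:class:`Cohort` additionally enforces cross-record invariants.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence


class ValidationError(ValueError):
    """A record or file violated the documented schema.

    ``row`` is the 1-based data-row number in the offending CSV when the
    error was raised during file loading.
    """

    def __init__(self, message: str, row: Optional[int] = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


class Group(str, enum.Enum):
    PATIENT = "patient"
    CONTROL = "control"
    REFERENCE = "reference"


class BoundaryCategory(str, enum.Enum):
    """Fine (perceptual-change driven) vs coarse (action driven) segmentation."""

    PERCEPTUAL = "perceptual"
    ACTION = "action"


class Task(str, enum.Enum):
    PICTURE_SERIES = "picture_series"
    BEHAVIORAL_STORY = "behavioral_story"
    TOM_STORY = "tom_story"


#: The eight experience-unit component categories, in canonical order.
COMPONENT_CATEGORIES: tuple[str, ...] = (
    "person",
    "object",
    "thought",
    "action_with_interaction",
    "spatial_movement",
    "perceptual_detail",
    "spatial_detail",
    "comment",
)


@dataclass(frozen=True)
class StudyConfig:
    """Fixed parameters of the study design.

    Parameters
    ----------
    n_pictures
        Nominal slideshow length: a one-hour walk photographed every 10 s
        gives ~360 pictures.  Individual slideshows may differ (walk
        durations varied); this is the generator's centre value.
    slideshow_rate
        Seconds per picture at replay (0.75 s).
    match_window_w
        Half-width of the boundary-matching window on the normalized
        [0, 1) timeline.  0.02 is ±2% of the walk (~7 pictures).
    top_k_typicality, top_k_accuracy
        Number of most-frequent reference-group prototypes used for the
        typicality score (20) and the temporal-accuracy score (30).
    n_series, series_length
        Picture-ordering task: 3 series of 12 pictures.
    n_stories, story_length
        Story-sequencing task: 8 stories per type, 5 cards each.
    """

    n_pictures: int = 360
    slideshow_rate: float = 0.75
    match_window_w: float = 0.02
    top_k_typicality: int = 20
    top_k_accuracy: int = 30
    n_series: int = 3
    series_length: int = 12
    n_stories: int = 8
    story_length: int = 5
    rng_seed: int = 0
    effect_size_convention: str = "patient_minus_control"

    def __post_init__(self) -> None:
        if not (0.0 < self.match_window_w < 0.5):
            raise ValidationError(
                f"match_window_w must lie in (0, 0.5), got {self.match_window_w}"
            )
        if self.top_k_typicality > self.top_k_accuracy:
            raise ValidationError(
                "top_k_typicality must not exceed top_k_accuracy "
                f"({self.top_k_typicality} > {self.top_k_accuracy})"
            )
        for name in (
            "n_pictures",
            "top_k_typicality",
            "top_k_accuracy",
            "n_series",
            "series_length",
            "n_stories",
            "story_length",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.slideshow_rate <= 0:
            raise ValidationError("slideshow_rate must be positive")
        if self.effect_size_convention not in (
            "patient_minus_control",
            "control_minus_patient",
        ):
            raise ValidationError(
                f"unknown effect_size_convention {self.effect_size_convention!r}"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        """Load a config from JSON; missing keys take the defaults."""
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    group: Group
    total_pictures: int

    def __post_init__(self) -> None:
        if self.total_pictures <= 0:
            raise ValidationError(
                f"participant {self.participant_id}: total_pictures must be > 0"
            )


@dataclass(frozen=True)
class BoundaryRecord:
    """One boundary press on the participant's own slideshow."""

    participant_id: str
    picture_index: int
    category_rater1: BoundaryCategory
    category_rater2: Optional[BoundaryCategory] = None

    def __post_init__(self) -> None:
        if self.picture_index < 0:
            raise ValidationError(
                f"participant {self.participant_id}: negative picture_index"
            )


@dataclass(frozen=True)
class OrderingResponse:
    """A permutation response to an ordering task.

    ``response_order[i]`` is the true (chronological) rank, 1-based, of
    the item the participant placed at position ``i``.  ``true_order`` is
    always the identity, kept explicit so responses are self-describing.
    """

    participant_id: str
    task: Task
    series_id: str
    response_order: tuple[int, ...]
    true_order: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        L = len(self.response_order)
        if not self.true_order:
            object.__setattr__(self, "true_order", tuple(range(1, L + 1)))
        if sorted(self.response_order) != list(range(1, L + 1)):
            raise ValidationError(
                f"participant {self.participant_id}, series {self.series_id}: "
                f"response_order {self.response_order} is not a permutation of 1..{L}"
            )
        if self.true_order != tuple(range(1, L + 1)):
            raise ValidationError(
                f"series {self.series_id}: true_order must be the identity 1..{L}"
            )


@dataclass(frozen=True)
class ExperienceUnit:
    """One narrative moment of experience and its coded components."""

    unit_id: str
    components: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError(
                f"unit {self.unit_id}: a unit carries at least one component"
            )
        bad = [c for c in self.components if c not in COMPONENT_CATEGORIES]
        if bad:
            raise ValidationError(
                f"unit {self.unit_id}: unknown component categories {bad}"
            )


@dataclass(frozen=True)
class RecallCoding:
    """Free-recall scoring inputs for one participant."""

    participant_id: str
    checklist_items: frozenset[str] = frozenset()
    units: tuple[ExperienceUnit, ...] = ()


@dataclass(frozen=True)
class TOJRecord:
    """Temporal-order-judgment error count at one stimulus onset asynchrony."""

    participant_id: str
    soa_ms: int
    n_trials: int
    n_errors: int

    def __post_init__(self) -> None:
        if self.soa_ms not in (100, 500):
            raise ValidationError(
                f"participant {self.participant_id}: soa_ms must be 100 or 500"
            )
        if not (0 <= self.n_errors <= self.n_trials):
            raise ValidationError(
                f"participant {self.participant_id}: "
                f"n_errors {self.n_errors} outside [0, {self.n_trials}]"
            )


@dataclass
class Cohort:
    """A validated study cohort: all typed records plus the config."""

    participants: dict[str, ParticipantRecord]
    boundaries: dict[str, list[BoundaryRecord]] = field(default_factory=dict)
    orderings: list[OrderingResponse] = field(default_factory=list)
    recalls: dict[str, RecallCoding] = field(default_factory=dict)
    toj: list[TOJRecord] = field(default_factory=list)
    config: StudyConfig = field(default_factory=StudyConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Enforce cross-record invariants (referential integrity etc.)."""
        for pid, recs in self.boundaries.items():
            part = self._require_participant(pid, "boundaries")
            last = -1
            for r in recs:
                if r.picture_index >= part.total_pictures:
                    raise ValidationError(
                        f"participant {pid}: picture_index {r.picture_index} "
                        f">= total_pictures {part.total_pictures}"
                    )
                if r.picture_index == last:
                    raise ValidationError(
                        f"participant {pid}: duplicate picture_index {r.picture_index}"
                    )
                if r.picture_index < last:
                    raise ValidationError(
                        f"participant {pid}: picture indices not strictly increasing"
                    )
                last = r.picture_index
        for resp in self.orderings:
            self._require_participant(resp.participant_id, "orderings")
        for pid in self.recalls:
            self._require_participant(pid, "recalls")
        for rec in self.toj:
            self._require_participant(rec.participant_id, "toj")

    def _require_participant(self, pid: str, what: str) -> ParticipantRecord:
        try:
            return self.participants[pid]
        except KeyError:
            raise ValidationError(
                f"{what}: participant_id {pid!r} not in participant table"
            ) from None

    def ids_in_group(self, group: Group) -> list[str]:
        return [p.participant_id for p in self.participants.values() if p.group == group]

    def orderings_for(
        self, pid: str, task: Optional[Task] = None
    ) -> list[OrderingResponse]:
        return [
            r
            for r in self.orderings
            if r.participant_id == pid and (task is None or r.task == task)
        ]


def as_group(label: str) -> Group:
    try:
        return Group(label)
    except ValueError:
        raise ValidationError(f"unknown group label {label!r}") from None


def as_category(label: str) -> BoundaryCategory:
    try:
        return BoundaryCategory(label)
    except ValueError:
        raise ValidationError(f"unknown boundary category {label!r}") from None
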