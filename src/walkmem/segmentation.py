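"""Event-segmentation scoring against reference-group prototypical boundaries.

Each participant watches their own slideshow (slideshows differ in
length because walk durations varied), so boundary presses are first
normalized to a common [0, 1) timeline.  Pooled presses from a separate
reference group are clustered into *prototypical boundaries* — consensus
boundary locations ranked by how many distinct reference participants
marked them.  Two individual scores follow:

- *typicality*: mean reference frequency of the prototypes a
  participant's boundaries match (top-20 prototypes; unmatched presses
  score 0), range [0, n_reference].  Higher = segmentation agrees with
  the majority.
- *temporal accuracy*: mean absolute deviation between matched presses
  and their prototype positions (top-30 prototypes), in percentage
  points of the timeline.  Higher = worse temporal precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .types import BoundaryCategory, BoundaryRecord, Cohort, Group, ValidationError

logger = logging.getLogger(__name__)

# absolute slack on window comparisons so that positions exactly w apart
# (up to float rounding) still count as inside the window
_EPS = 1e-12


def _mean_position(values: Sequence[float]) -> float:
    # identical members must yield exactly their common value
    if min(values) == max(values):
        return values[0]
    return sum(values) / len(values)


@dataclass(frozen=True)
class NormalizedBoundary:
    participant_id: str
    position: float  # fraction of timeline, in [0, 1)
    category: BoundaryCategory

    def __post_init__(self) -> None:
        if not (0.0 <= self.position < 1.0):
            raise ValidationError(
                f"normalized position {self.position} outside [0, 1)"
            )


@dataclass(frozen=True)
class PrototypicalBoundary:
    prototype_id: str
    position: float  # mean normalized position of member presses
    frequency: int  # distinct contributing reference participants
    rank: int  # 1-based, by descending frequency


@dataclass(frozen=True)
class SegmentationScores:
    participant_id: str
    n_boundaries: int
    n_perceptual: int
    n_action: int
    typicality: float
    temporal_accuracy: float  # NaN when no press matches a top-30 prototype


def normalize_boundaries(
    records: Sequence[BoundaryRecord], total_pictures: int
) -> list[NormalizedBoundary]:
    """Map picture indices onto the common [0, 1) timeline.

    position = picture_index / total_pictures; order is preserved.
    """
    out = []
    for rec in records:
        if rec.picture_index >= total_pictures:
            raise ValidationError(
                f"participant {rec.participant_id}: picture_index "
                f"{rec.picture_index} >= total_pictures {total_pictures}"
            )
        out.append(
            NormalizedBoundary(
                participant_id=rec.participant_id,
                position=rec.picture_index / total_pictures,
                category=rec.category_rater1,
            )
        )
    return out


def build_prototypes(
    reference_boundaries: Mapping[str, Sequence[NormalizedBoundary]],
    w: float,
    top_k: int,
) -> list[PrototypicalBoundary]:
    """Cluster pooled reference-group presses into ranked prototypes.

    Single-linkage agglomeration over the pooled, position-sorted
    presses: a press joins the current cluster while it lies within
    ``w`` of the running cluster mean, otherwise it opens a new cluster.
    A prototype's position is the mean of its member presses and its
    frequency counts *distinct* participants (two presses by the same
    participant inside one cluster count once).  Output is ranked by
    descending frequency, ties broken by earlier position, truncated to
    ``top_k``.  Deterministic and invariant to the order in which
    participants are supplied.
    """
    if len(reference_boundaries) < 2:
        raise ValidationError(
            "building prototypes requires at least 2 reference participants"
        )
    pooled = sorted(
        ((b.position, pid) for pid, bs in reference_boundaries.items() for b in bs),
        key=lambda t: t[0],
    )
    clusters: list[list[tuple[float, str]]] = []
    mean = None
    for pos, pid in pooled:
        if clusters and abs(pos - mean) <= w + _EPS:
            clusters[-1].append((pos, pid))
            mean = _mean_position([p for p, _ in clusters[-1]])
        else:
            clusters.append([(pos, pid)])
            mean = pos
    protos = [
        (
            _mean_position([p for p, _ in members]),
            len({pid for _, pid in members}),
        )
        for members in clusters
    ]
    protos.sort(key=lambda t: (-t[1], t[0]))
    return [
        PrototypicalBoundary(
            prototype_id=f"proto_{rank:02d}", position=pos, frequency=freq, rank=rank
        )
        for rank, (pos, freq) in enumerate(protos[:top_k], start=1)
    ]


def match_boundaries(
    boundaries: Sequence[NormalizedBoundary],
    prototypes: Sequence[PrototypicalBoundary],
    w: float,
) -> dict[int, Optional[PrototypicalBoundary]]:
    """Assign each press to at most one prototype within ±w.

    Greedy nearest-pair assignment: candidate (press, prototype) pairs
    are taken in order of increasing distance (ties resolved toward the
    lower-rank, i.e. more frequent, prototype), and a pair is accepted
    only while both the press and the prototype are still free.  Hence
    each press matches at most one prototype and each prototype takes at
    most one of the participant's presses (the nearest wins; the loser
    becomes unmatched).  Returns a map from press index to its prototype
    or ``None``.
    """
    # distances are snapped to 1e-9 so that exact ties up to float
    # rounding resolve by prototype rank, not by representation noise
    candidates = sorted(
        (
            (round(abs(b.position - p.position), 9), p.rank, i, p)
            for i, b in enumerate(boundaries)
            for p in prototypes
            if abs(b.position - p.position) <= w + _EPS
        ),
        key=lambda t: (t[0], t[1], t[2]),
    )
    assignment: dict[int, Optional[PrototypicalBoundary]] = {
        i: None for i in range(len(boundaries))
    }
    taken: set[int] = set()
    for _, rank, i, proto in candidates:
        if assignment[i] is None and rank not in taken:
            assignment[i] = proto
            taken.add(rank)
    return assignment


def typicality_score(
    boundaries: Sequence[NormalizedBoundary],
    prototypes: Sequence[PrototypicalBoundary],
    w: float,
) -> float:
    """Mean prototype frequency over all of a participant's presses.

    Each press scores the frequency of its matched prototype; unmatched
    presses score 0 (they dilute the mean — pressing more, atypically,
    lowers the score).  Undefined for a participant with no presses.
    """
    if not boundaries:
        raise ValidationError("typicality undefined for zero boundaries")
    assignment = match_boundaries(boundaries, prototypes, w)
    return sum(p.frequency for p in assignment.values() if p is not None) / len(
        boundaries
    )


def temporal_accuracy_score(
    boundaries: Sequence[NormalizedBoundary],
    prototypes: Sequence[PrototypicalBoundary],
    w: float,
) -> float:
    """Mean |press − prototype| over matched presses, in percentage
    points of the timeline.  Unmatched presses are excluded; returns NaN
    (missing) when nothing matches."""
    assignment = match_boundaries(boundaries, prototypes, w)
    devs = [
        abs(boundaries[i].position - p.position)
        for i, p in assignment.items()
        if p is not None
    ]
    if not devs:
        return math.nan
    return 100.0 * sum(devs) / len(devs)


def category_counts(
    records: Sequence[BoundaryRecord], which_rater: int = 1
) -> tuple[int, int]:
    """Count (perceptual, action) boundary labels for the chosen rater."""
    n_perc = n_act = 0
    for rec in records:
        label = rec.category_rater1 if which_rater == 1 else rec.category_rater2
        if label is None:
            raise ValidationError(
                f"participant {rec.participant_id}, picture {rec.picture_index}: "
                f"missing rater-{which_rater} category label"
            )
        if label == BoundaryCategory.PERCEPTUAL:
            n_perc += 1
        else:
            n_act += 1
    return n_perc, n_act


def score_segmentation(cohort: Cohort) -> pd.DataFrame:
    """Segmentation scores for every patient/control participant.

    Prototypes are built from the cohort's reference group; typicality
    uses the ``top_k_typicality`` most frequent prototypes, temporal
    accuracy the ``top_k_accuracy`` most frequent.  Participants without
    presses, or whose presses match no top-30 prototype, get missing
    scores (NaN), which downstream group statistics exclude.
    """
    cfg = cohort.config
    ref_ids = cohort.ids_in_group(Group.REFERENCE)
    if len(ref_ids) < 2:
        raise ValidationError(
            "segmentation scoring requires a reference group with >= 2 participants"
        )
    reference = {
        pid: normalize_boundaries(
            cohort.boundaries.get(pid, []), cohort.participants[pid].total_pictures
        )
        for pid in ref_ids
    }
    protos_acc = build_prototypes(reference, cfg.match_window_w, cfg.top_k_accuracy)
    protos_typ = protos_acc[: cfg.top_k_typicality]

    rows = []
    for pid, part in cohort.participants.items():
        if part.group == Group.REFERENCE:
            continue
        records = cohort.boundaries.get(pid, [])
        normalized = normalize_boundaries(records, part.total_pictures)
        n_perc, n_act = category_counts(records) if records else (0, 0)
        if normalized:
            typ = typicality_score(normalized, protos_typ, cfg.match_window_w)
            acc = temporal_accuracy_score(normalized, protos_acc, cfg.match_window_w)
        else:
            logger.info("participant %s: no boundary presses, scores missing", pid)
            typ, acc = math.nan, math.nan
        if math.isnan(acc) and normalized:
            logger.info(
                "participant %s: no press within w of a prototype, "
                "temporal accuracy missing",
                pid,
            )
        rows.append(
            {
                "participant_id": pid,
                "group": part.group.value,
                "n_boundaries": len(records),
                "n_perceptual": n_perc,
                "n_action": n_act,
                "typicality": typ,
                "temporal_accuracy": acc,
            }
        )
    return pd.DataFrame(rows)


def prototypes_table(prototypes: Sequence[PrototypicalBoundary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "prototype_id": p.prototype_id,
                "position": p.position,
                "frequency": p.frequency,
                "rank": p.rank,
            }
            for p in prototypes
        ]
    )
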