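"""Scores for chronological-ordering tasks.

Picture series (three series of twelve personal pictures) yield two
scores: the *chronological score* — mean number of pictures placed at
their correct position per series — and the *deviation score* — mean
absolute displacement of each picture from its correct position.  The
five-card story-sequencing task (behavioural and theory-of-mind
stories, eight each) yields an *error score*: the total number of
incorrectly placed cards over the eight stories of a type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .types import Cohort, Group, OrderingResponse, Task, ValidationError


@dataclass(frozen=True)
class OrderingScores:
    participant_id: str
    chronological_score: float  # mean correct placements per series, 0..L
    deviation_score: float  # mean |placed - correct| per picture
    behavioral_error_score: Optional[int]  # total wrong positions, 8 stories
    tom_error_score: Optional[int]
    mean_error_score: Optional[float]  # mean of the two story totals


def _check(responses: Sequence[OrderingResponse], n: int, length: int, what: str):
    if len(responses) != n:
        raise ValidationError(
            f"{what}: expected {n} responses, got {len(responses)}"
        )
    for r in responses:
        if len(r.response_order) != length:
            raise ValidationError(
                f"{what}: series {r.series_id} has length "
                f"{len(r.response_order)}, expected {length}"
            )


def chronological_score(
    responses: Sequence[OrderingResponse], n_series: int = 3, series_length: int = 12
) -> float:
    """Mean count of correctly placed pictures per series."""
    _check(responses, n_series, series_length, "picture series")
    fixed = [
        sum(1 for i, item in enumerate(r.response_order, start=1) if item == i)
        for r in responses
    ]
    return sum(fixed) / len(fixed)


def deviation_score(
    responses: Sequence[OrderingResponse], n_series: int = 3, series_length: int = 12
) -> float:
    """Mean absolute positional displacement per picture, averaged over
    series.  0 iff every picture is correctly placed."""
    _check(responses, n_series, series_length, "picture series")
    per_series = [
        sum(abs(item - i) for i, item in enumerate(r.response_order, start=1))
        / len(r.response_order)
        for r in responses
    ]
    return sum(per_series) / len(per_series)


def sequencing_error_score(
    responses: Sequence[OrderingResponse], n_stories: int = 8, story_length: int = 5
) -> int:
    """Total number of incorrectly positioned cards over the stories of
    one type (Hamming distance to the true order, summed)."""
    _check(responses, n_stories, story_length, "story sequencing")
    return sum(
        sum(1 for i, item in enumerate(r.response_order, start=1) if item != i)
        for r in responses
    )


def score_ordering(cohort: Cohort) -> pd.DataFrame:
    """Ordering scores for every patient/control participant.

    Story scores are missing (None/NaN) for participants without story
    responses; picture-series scores are required.
    """
    cfg = cohort.config
    rows = []
    for pid, part in cohort.participants.items():
        if part.group == Group.REFERENCE:
            continue
        series = cohort.orderings_for(pid, Task.PICTURE_SERIES)
        if not series:
            continue
        chrono = chronological_score(series, cfg.n_series, cfg.series_length)
        dev = deviation_score(series, cfg.n_series, cfg.series_length)
        behav = cohort.orderings_for(pid, Task.BEHAVIORAL_STORY)
        tom = cohort.orderings_for(pid, Task.TOM_STORY)
        b = (
            sequencing_error_score(behav, cfg.n_stories, cfg.story_length)
            if behav
            else None
        )
        t = (
            sequencing_error_score(tom, cfg.n_stories, cfg.story_length)
            if tom
            else None
        )
        rows.append(
            {
                "participant_id": pid,
                "group": part.group.value,
                "chronological_score": chrono,
                "deviation_score": dev,
                "behavioral_error_score": b,
                "tom_error_score": t,
                "mean_error_score": (b + t) / 2 if b is not None and t is not None else None,
            }
        )
    return pd.DataFrame(rows)
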