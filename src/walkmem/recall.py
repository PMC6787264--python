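"""Free-recall content scoring.

Two layers: (1) a checklist count — how many items from a reference
list (compiled from the reference group's own recalls) the participant
correctly reported; (2) experience-unit coding — narratives are divided
into units (one particular moment of experience), each unit carrying
one or more coded components from eight categories.  Component
*prevalence* is the percentage of a participant's units containing at
least one component of a category; categories are non-exclusive, so
prevalences need not sum to 100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import COMPONENT_CATEGORIES, Cohort, ExperienceUnit, Group, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecallScores:
    participant_id: str
    n_items: int
    n_units: int
    prevalence: Mapping[str, float]  # category -> percent of units


def checklist_item_count(
    recalled: Iterable[str], reference_checklist: Iterable[str]
) -> int:
    """Number of distinct recalled items present on the reference
    checklist; duplicates count once."""
    checklist = set(reference_checklist)
    if not checklist:
        raise ValidationError("reference checklist is empty")
    return len(set(recalled) & checklist)


def component_prevalence(units: Sequence[ExperienceUnit]) -> dict[str, float]:
    """Percent of units containing >=1 component of each category.

    All eight categories are present in the output (0 when absent); a
    unit holding several components of one category counts once.
    Returns NaN for every category when there are no units.
    """
    if not units:
        return {c: math.nan for c in COMPONENT_CATEGORIES}
    n = len(units)
    return {
        c: 100.0 * sum(1 for u in units if c in u.components) / n
        for c in COMPONENT_CATEGORIES
    }


def reference_checklist(cohort: Cohort) -> frozenset[str]:
    """The item checklist: union of the reference group's recalled items."""
    items: set[str] = set()
    for pid in cohort.ids_in_group(Group.REFERENCE):
        coding = cohort.recalls.get(pid)
        if coding is not None:
            items |= coding.checklist_items
    return frozenset(items)


def score_recall(
    cohort: Cohort, checklist: Iterable[str] | None = None
) -> pd.DataFrame:
    """Recall scores for every patient/control participant.

    ``checklist`` defaults to the union of reference-group items.  The
    eight prevalence columns appear in canonical category order as
    ``pct_<category>``.
    """
    checklist = (
        frozenset(checklist) if checklist is not None else reference_checklist(cohort)
    )
    if not checklist:
        logger.warning(
            "no reference checklist available: item counts are taken as recorded"
        )
    rows = []
    for pid, part in cohort.participants.items():
        if part.group == Group.REFERENCE:
            continue
        coding = cohort.recalls.get(pid)
        if coding is None:
            continue
        prev = component_prevalence(coding.units)
        row = {
            "participant_id": pid,
            "group": part.group.value,
            "n_items": (
                checklist_item_count(coding.checklist_items, checklist)
                if checklist
                else len(coding.checklist_items)
            ),
            "n_units": len(coding.units) if coding.units else math.nan,
        }
        row.update({f"pct_{c}": prev[c] for c in COMPONENT_CATEGORIES})
        rows.append(row)
    return pd.DataFrame(rows)
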