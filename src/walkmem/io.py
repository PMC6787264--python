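"""CSV/JSON readers and writers for study artifacts.

All files are comma-separated UTF-8 with a header row and "." decimal
separator.  Schemas (one row per record unless noted):

- ``boundaries.csv``: participant_id, group, total_pictures,
  picture_index, category_rater1, category_rater2.  This file doubles as
  the participant table; a participant with no boundary presses appears
  once with the index and category fields left blank.
- ``orderings.csv`` (long): participant_id, task, series_id, position,
  response_item — one row per position within a series.
- ``recall.csv`` (long): participant_id, unit_id, component.
- ``checklist.csv``: participant_id, item_id.
- ``toj.csv``: participant_id, soa_ms, n_trials, n_errors.
- ``config.json``: StudyConfig fields; missing fields take defaults.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .types import (
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
    as_category,
    as_group,
)

# fixed rendering precision by column name; everything else is written
# with repr-level precision
_COLUMN_FORMATS = {
    "t": "{:.2f}",
    "d": "{:.2f}",
    "F": "{:.2f}",
    "p": "{:.3f}",
    "p_adj": "{:.3f}",
    "p_group": "{:.3f}",
    "p_category": "{:.3f}",
    "p_interaction": "{:.3f}",
}


def _read_rows(path: str | Path, required: list[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file (missing header)")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ValidationError(f"{path}: missing columns {missing}")
        return [dict(row) for row in reader]


def _to_int(value: str, what: str, row: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{what}: not an integer ({value!r})", row=row)


def read_boundaries(
    path: str | Path,
) -> tuple[dict[str, ParticipantRecord], dict[str, list[BoundaryRecord]]]:
    """Read the boundary-press file, which also defines the participant table."""
    cols = [
        "participant_id",
        "group",
        "total_pictures",
        "picture_index",
        "category_rater1",
        "category_rater2",
    ]
    participants: dict[str, ParticipantRecord] = {}
    boundaries: dict[str, list[BoundaryRecord]] = {}
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(_read_rows(path, cols[:5]), start=1):
        pid = row["participant_id"]
        try:
            part = ParticipantRecord(
                participant_id=pid,
                group=as_group(row["group"]),
                total_pictures=_to_int(row["total_pictures"], "total_pictures", i),
            )
        except ValidationError as err:
            raise ValidationError(str(err), row=i) from None
        if pid in participants:
            if participants[pid] != part:
                raise ValidationError(
                    f"participant {pid}: inconsistent group/total_pictures", row=i
                )
        else:
            participants[pid] = part
            boundaries[pid] = []
        if not row["picture_index"]:  # participant row without a press
            continue
        idx = _to_int(row["picture_index"], "picture_index", i)
        if not (0 <= idx < part.total_pictures):
            raise ValidationError(
                f"picture_index {idx} outside [0, {part.total_pictures})", row=i
            )
        if (pid, idx) in seen:
            raise ValidationError(
                f"duplicate (participant {pid}, picture_index {idx})", row=i
            )
        seen.add((pid, idx))
        rater2 = row.get("category_rater2") or None
        try:
            rec = BoundaryRecord(
                participant_id=pid,
                picture_index=idx,
                category_rater1=as_category(row["category_rater1"]),
                category_rater2=as_category(rater2) if rater2 else None,
            )
        except ValidationError as err:
            raise ValidationError(str(err), row=i) from None
        boundaries[pid].append(rec)
    for pid in boundaries:
        boundaries[pid].sort(key=lambda r: r.picture_index)
    return participants, boundaries


def read_orderings(path: str | Path) -> list[OrderingResponse]:
    cols = ["participant_id", "task", "series_id", "position", "response_item"]
    by_series: dict[tuple[str, str, str], dict[int, int]] = {}
    first_row: dict[tuple[str, str, str], int] = {}
    for i, row in enumerate(_read_rows(path, cols), start=1):
        try:
            task = Task(row["task"])
        except ValueError:
            raise ValidationError(f"unknown task {row['task']!r}", row=i) from None
        key = (row["participant_id"], task.value, row["series_id"])
        pos = _to_int(row["position"], "position", i)
        item = _to_int(row["response_item"], "response_item", i)
        slot = by_series.setdefault(key, {})
        first_row.setdefault(key, i)
        if pos in slot:
            raise ValidationError(f"duplicate position {pos} in series {key[2]}", row=i)
        slot[pos] = item
    responses = []
    for (pid, task, series_id), slots in by_series.items():
        L = len(slots)
        if sorted(slots) != list(range(1, L + 1)):
            raise ValidationError(
                f"participant {pid}, series {series_id}: positions must be 1..{L}",
                row=first_row[(pid, task, series_id)],
            )
        try:
            responses.append(
                OrderingResponse(
                    participant_id=pid,
                    task=Task(task),
                    series_id=series_id,
                    response_order=tuple(slots[p] for p in range(1, L + 1)),
                )
            )
        except ValidationError as err:
            raise ValidationError(str(err), row=first_row[(pid, task, series_id)]) from None
    return responses


def read_recall(
    recall_path: str | Path, checklist_path: Optional[str | Path] = None
) -> dict[str, RecallCoding]:
    units_by_pid: dict[str, dict[str, list[str]]] = {}
    for i, row in enumerate(
        _read_rows(recall_path, ["participant_id", "unit_id", "component"]), start=1
    ):
        units_by_pid.setdefault(row["participant_id"], {}).setdefault(
            row["unit_id"], []
        ).append(row["component"])
    items_by_pid: dict[str, set[str]] = {}
    if checklist_path is not None:
        for row in _read_rows(checklist_path, ["participant_id", "item_id"]):
            items_by_pid.setdefault(row["participant_id"], set()).add(row["item_id"])
    recalls = {}
    for pid in set(units_by_pid) | set(items_by_pid):
        units = tuple(
            ExperienceUnit(unit_id=uid, components=tuple(comps))
            for uid, comps in sorted(units_by_pid.get(pid, {}).items())
        )
        recalls[pid] = RecallCoding(
            participant_id=pid,
            checklist_items=frozenset(items_by_pid.get(pid, set())),
            units=units,
        )
    return recalls


def read_toj(path: str | Path) -> list[TOJRecord]:
    records = []
    for i, row in enumerate(
        _read_rows(path, ["participant_id", "soa_ms", "n_trials", "n_errors"]), start=1
    ):
        try:
            records.append(
                TOJRecord(
                    participant_id=row["participant_id"],
                    soa_ms=_to_int(row["soa_ms"], "soa_ms", i),
                    n_trials=_to_int(row["n_trials"], "n_trials", i),
                    n_errors=_to_int(row["n_errors"], "n_errors", i),
                )
            )
        except ValidationError as err:
            raise ValidationError(str(err), row=i) from None
    return records


def load_cohort(
    boundaries_csv: str | Path,
    orderings_csv: Optional[str | Path] = None,
    recall_csv: Optional[str | Path] = None,
    toj_csv: Optional[str | Path] = None,
    config_json: Optional[str | Path] = None,
    checklist_csv: Optional[str | Path] = None,
) -> Cohort:
    """Load and validate a full cohort from its CSV/JSON artifacts.

    ``boundaries_csv`` is mandatory (it carries the participant table);
    the other files are optional so partial cohorts can be scored.
    Raises :class:`ValidationError` naming the offending row on any
    schema violation.
    """
    participants, boundaries = read_boundaries(boundaries_csv)
    config = StudyConfig.from_json(config_json) if config_json else StudyConfig()
    return Cohort(
        participants=participants,
        boundaries=boundaries,
        orderings=read_orderings(orderings_csv) if orderings_csv else [],
        recalls=read_recall(recall_csv, checklist_csv) if recall_csv else {},
        toj=read_toj(toj_csv) if toj_csv else [],
        config=config,
    )


def save_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort back to its CSV artifacts (inverse of load_cohort)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = []
    for pid, part in cohort.participants.items():
        recs = cohort.boundaries.get(pid, [])
        if not recs:
            rows.append(
                [pid, part.group.value, part.total_pictures, "", "", ""]
            )
        for r in recs:
            rows.append(
                [
                    pid,
                    part.group.value,
                    part.total_pictures,
                    r.picture_index,
                    r.category_rater1.value,
                    r.category_rater2.value if r.category_rater2 else "",
                ]
            )
    paths["boundaries"] = _write_csv(
        out / "boundaries.csv",
        [
            "participant_id",
            "group",
            "total_pictures",
            "picture_index",
            "category_rater1",
            "category_rater2",
        ],
        rows,
    )

    rows = []
    for resp in cohort.orderings:
        for pos, item in enumerate(resp.response_order, start=1):
            rows.append(
                [resp.participant_id, resp.task.value, resp.series_id, pos, item]
            )
    paths["orderings"] = _write_csv(
        out / "orderings.csv",
        ["participant_id", "task", "series_id", "position", "response_item"],
        rows,
    )

    unit_rows, item_rows = [], []
    for pid, coding in cohort.recalls.items():
        for unit in coding.units:
            for comp in unit.components:
                unit_rows.append([pid, unit.unit_id, comp])
        for item in sorted(coding.checklist_items):
            item_rows.append([pid, item])
    paths["recall"] = _write_csv(
        out / "recall.csv", ["participant_id", "unit_id", "component"], unit_rows
    )
    paths["checklist"] = _write_csv(
        out / "checklist.csv", ["participant_id", "item_id"], item_rows
    )

    paths["toj"] = _write_csv(
        out / "toj.csv",
        ["participant_id", "soa_ms", "n_trials", "n_errors"],
        [[r.participant_id, r.soa_ms, r.n_trials, r.n_errors] for r in cohort.toj],
    )
    cohort.config.to_json(out / "config.json")
    paths["config"] = out / "config.json"
    return paths


def _write_csv(path: Path, header: list[str], rows: list[list]) -> Path:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)
    return path


def format_table(table: pd.DataFrame) -> pd.DataFrame:
    """Render result-table floats at the documented fixed precision.

    t, d and F columns get 2 decimals; p-value columns get 3.  Columns
    without a rule are left untouched.  Returns a copy with formatted
    columns as strings.
    """
    out = table.copy()
    for col, fmt in _COLUMN_FORMATS.items():
        if col in out.columns:
            out[col] = [
                "" if pd.isna(v) else fmt.format(v) for v in out[col]
            ]
    return out


def write_results(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> dict[str, Path]:
    """Write result tables as CSV with deterministic column order and
    fixed float precision (2 decimals for t/d/F, 3 for p-values)."""
    if not tables:
        raise ValueError("no result tables to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, table in tables.items():
        path = out / f"{name}.csv"
        format_table(table).to_csv(path, index=False)
        written[name] = path
    return written
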