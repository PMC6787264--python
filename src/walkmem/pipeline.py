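"""End-to-end orchestration: cohort in, score tables and statistics out.

``run_pipeline`` turns a validated cohort into per-participant score
tables, the patient-vs-control comparison table (mean, SD, n, t, df, p,
Glass's delta), the 2x2 mixed ANOVA on boundary-category counts,
within-group Pearson correlation matrices with Bonferroni adjustment,
the boundary-category rater agreement (Cohen's kappa), and a run
manifest.  ``recompute_from_summaries`` reruns the t/d battery straight
from printed summary cells, so published tables can be checked without
raw data.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .ordering import score_ordering
from .recall import score_recall
from .segmentation import score_segmentation
from .stats import (
    PATIENT_MINUS_CONTROL,
    GroupSummary,
    cohens_kappa,
    compare_groups,
    correlation_matrix,
    effect_size_d,
    mixed_anova_2x2,
    pooled_t,
)
from .types import Cohort, Group, ValidationError

logger = logging.getLogger(__name__)

#: measures carried into the within-group correlation matrices
CORRELATION_MEASURES = [
    "chronological_score",
    "deviation_score",
    "n_boundaries",
    "temporal_accuracy",
    "typicality",
    "n_items",
    "n_units",
    "toj_100ms_error_proportion",
    "toj_500ms_error_proportion",
    "mean_error_score",
]


@dataclass
class PipelineResult:
    segmentation_scores: Optional[pd.DataFrame]
    ordering_scores: Optional[pd.DataFrame]
    recall_scores: Optional[pd.DataFrame]
    toj_scores: Optional[pd.DataFrame]
    comparisons: pd.DataFrame
    anova: Optional[pd.DataFrame]
    correlations: pd.DataFrame
    agreement: Optional[pd.DataFrame]
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        """All non-empty result tables, for :func:`walkmem.io.write_results`."""
        named = {
            "segmentation_scores": self.segmentation_scores,
            "ordering_scores": self.ordering_scores,
            "recall_scores": self.recall_scores,
            "toj_scores": self.toj_scores,
            "comparisons": self.comparisons,
            "anova": self.anova,
            "correlations": self.correlations,
            "agreement": self.agreement,
        }
        return {k: v for k, v in named.items() if v is not None and not v.empty}


def score_toj(cohort: Cohort) -> pd.DataFrame:
    """Per-participant TOJ error proportions at both SOAs."""
    rows: dict[str, dict] = {}
    for rec in cohort.toj:
        part = cohort.participants[rec.participant_id]
        if part.group == Group.REFERENCE:
            continue
        row = rows.setdefault(
            rec.participant_id,
            {"participant_id": rec.participant_id, "group": part.group.value},
        )
        row[f"toj_{rec.soa_ms}ms_error_proportion"] = rec.n_errors / rec.n_trials
    return pd.DataFrame(list(rows.values()))


def _comparison_rows(
    merged: pd.DataFrame, measures: list[str]
) -> list[dict]:
    rows = []
    pat = merged[merged["group"] == Group.PATIENT.value]
    ctl = merged[merged["group"] == Group.CONTROL.value]
    for m in measures:
        x = pat[m].dropna()
        y = ctl[m].dropna()
        if len(x) < 2 or len(y) < 2:
            logger.warning("comparison %s skipped: insufficient data", m)
            continue
        cmp = compare_groups(x, y)
        rows.append(
            {
                "label": m,
                "patient_mean": x.mean(),
                "patient_sd": x.std(ddof=1),
                "patient_n": len(x),
                "control_mean": y.mean(),
                "control_sd": y.std(ddof=1),
                "control_n": len(y),
                "t": cmp.t,
                "df": cmp.df,
                "p": cmp.p,
                "d": cmp.d,
            }
        )
    return rows


def run_pipeline(
    cohort: Cohort,
    input_digests: Optional[Mapping[str, str]] = None,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run the full scoring and statistics battery on a cohort.

    If the reference group is absent the segmentation scores are
    skipped with a warning; the remaining tables are still produced.
    Missing scores propagate as missing and each comparison reports its
    per-group n.
    """
    for group in (Group.PATIENT, Group.CONTROL):
        if len(cohort.ids_in_group(group)) < 2:
            raise ValidationError(
                f"pipeline requires >= 2 participants in group {group.value}"
            )

    seg = None
    if len(cohort.ids_in_group(Group.REFERENCE)) >= 2:
        seg = score_segmentation(cohort)
    else:
        logger.warning(
            "no reference group in cohort: segmentation scores skipped"
        )
    orde = score_ordering(cohort) if cohort.orderings else None
    rec = score_recall(cohort) if cohort.recalls else None
    toj = score_toj(cohort) if cohort.toj else None

    frames = [f for f in (seg, orde, rec, toj) if f is not None and not f.empty]
    merged: Optional[pd.DataFrame] = None
    for f in frames:
        merged = (
            f
            if merged is None
            else merged.merge(f, on=["participant_id", "group"], how="outer")
        )
    if merged is None:
        raise ValidationError("cohort holds no scorable data")

    measures = [
        c for c in merged.columns if c not in ("participant_id", "group")
    ]
    comparisons = pd.DataFrame(_comparison_rows(merged, measures))

    anova = None
    if seg is not None and not seg.empty:
        res = mixed_anova_2x2(
            seg.rename(columns={"n_perceptual": "perceptual", "n_action": "action"}),
            value_cols=("perceptual", "action"),
        )
        anova = pd.DataFrame(
            [
                {"effect": "group", "F": res.F_group, "df1": res.df1,
                 "df2": res.df2, "p": res.p_group},
                {"effect": "category", "F": res.F_category, "df1": res.df1,
                 "df2": res.df2, "p": res.p_category},
                {"effect": "interaction", "F": res.F_interaction, "df1": res.df1,
                 "df2": res.df2, "p": res.p_interaction},
            ]
        )

    corr_cols = [m for m in CORRELATION_MEASURES if m in merged.columns]
    corr_frames = []
    for group in (Group.PATIENT, Group.CONTROL):
        sub = merged[merged["group"] == group.value]
        if sub.empty or len(corr_cols) < 2:
            continue
        cm = correlation_matrix(sub[corr_cols])
        cm.insert(0, "group", group.value)
        corr_frames.append(cm)
    correlations = (
        pd.concat(corr_frames, ignore_index=True) if corr_frames else pd.DataFrame()
    )

    agreement = None
    labels1, labels2 = [], []
    for pid in cohort.ids_in_group(Group.PATIENT) + cohort.ids_in_group(Group.CONTROL):
        for b in cohort.boundaries.get(pid, []):
            if b.category_rater2 is not None:
                labels1.append(b.category_rater1.value)
                labels2.append(b.category_rater2.value)
    if labels1:
        agreement = pd.DataFrame(
            [
                {
                    "statistic": "category_kappa",
                    "value": cohens_kappa(labels1, labels2),
                    "n": len(labels1),
                }
            ]
        )

    manifest = {
        "software_version": __version__,
        "config": dataclasses.asdict(cohort.config),
        "input_digests": dict(input_digests or {}),
        "seed": seed,
        "n_participants": {
            g.value: len(cohort.ids_in_group(g)) for g in Group
        },
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return PipelineResult(
        segmentation_scores=seg,
        ordering_scores=orde,
        recall_scores=rec,
        toj_scores=toj,
        comparisons=comparisons,
        anova=anova,
        correlations=correlations,
        agreement=agreement,
        manifest=manifest,
    )


def file_digests(paths: Mapping[str, str | Path]) -> dict[str, str]:
    """SHA-256 digests of the input files, recorded before computation."""
    out = {}
    for name, path in paths.items():
        h = hashlib.sha256()
        h.update(Path(path).read_bytes())
        out[name] = h.hexdigest()
    return out


def load_published_summaries() -> pd.DataFrame:
    """The transcribed published group-summary cells shipped as package
    data (label, per-group mean/SD/n, direction and denominator flags)."""
    with resources.files("walkmem.data").joinpath("group_summaries.csv").open() as fh:
        return pd.read_csv(fh)


def recompute_from_summaries(summaries: pd.DataFrame) -> pd.DataFrame:
    """Recompute t, df, p and d from printed summary cells.

    Expects the columns of :func:`load_published_summaries`.  The
    ``t_rendered``/``d_rendered`` columns round to the printed precision
    (t to 2 decimals; d to the row's ``d_decimals``, default 2).
    """
    rows = []
    for rec in summaries.to_dict("records"):
        s_pat = GroupSummary(
            mean=rec["patient_mean"], sd=rec["patient_sd"], n=int(rec["patient_n"])
        )
        s_ctl = GroupSummary(
            mean=rec["control_mean"], sd=rec["control_sd"], n=int(rec["control_n"])
        )
        t, df, p, _ = pooled_t(
            s_pat, s_ctl, rec.get("t_direction", PATIENT_MINUS_CONTROL)
        )
        d = effect_size_d(
            s_pat,
            s_ctl,
            rec.get("d_direction", PATIENT_MINUS_CONTROL),
            rec.get("d_denominator", "control_sd"),
        )
        dd = int(rec.get("d_decimals", 2) or 2)
        rows.append(
            {
                "label": rec["label"],
                "t": t,
                "df": df,
                "p": p,
                "d": d,
                "t_rendered": f"{t:.2f}",
                "d_rendered": f"{d:.{dd}f}",
            }
        )
    return pd.DataFrame(rows)
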