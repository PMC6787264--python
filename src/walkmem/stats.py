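"""The group-comparison battery.

Pooled-variance (Student) two-sample t-tests computed either from raw
scores or from printed summary cells (mean, SD, n); standardized effect
sizes with an explicit direction and denominator convention (default
Glass's delta over the control-group SD, patient minus control); a 2x2
mixed ANOVA (group between, boundary category within); Pearson
correlation matrices with Bonferroni adjustment; and the rater-agreement
statistics Cohen's kappa and the intraclass correlation (two-way
random effects, absolute agreement, single rater — ICC(2,1) — by
default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

PATIENT_MINUS_CONTROL = "patient_minus_control"
CONTROL_MINUS_PATIENT = "control_minus_patient"


@dataclass(frozen=True)
class GroupSummary:
    """Printed-table cell: mean, SD and group size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def of(cls, values: Sequence[float]) -> "GroupSummary":
        x = np.asarray(values, dtype=float)
        x = x[~np.isnan(x)]
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


@dataclass(frozen=True)
class GroupComparison:
    t: float
    df: int
    p: float
    d: float
    direction: str
    d_denominator: str
    degenerate: bool = False


@dataclass(frozen=True)
class AnovaResult:
    F_group: float
    p_group: float
    F_category: float
    p_category: float
    F_interaction: float
    p_interaction: float
    df1: int
    df2: int


def _signed(delta: float, direction: str) -> float:
    if direction == PATIENT_MINUS_CONTROL:
        return delta
    if direction == CONTROL_MINUS_PATIENT:
        return -delta
    raise ValueError(f"unknown direction {direction!r}")


def pooled_t(
    patients: GroupSummary,
    controls: GroupSummary,
    direction: str = PATIENT_MINUS_CONTROL,
) -> tuple[float, int, float, bool]:
    """Student t-test from summary statistics.

    t = (m1 - m2) / (s_p * sqrt(1/n1 + 1/n2)) with the pooled SD
    s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2); two-sided p on
    n1+n2-2 df.  Returns (t, df, p, degenerate).  With zero pooled
    variance and a nonzero mean difference the result is a signed
    infinite t with p = 0, flagged degenerate; with both zero the test
    is undefined.
    """
    df = patients.n + controls.n - 2
    delta = _signed(patients.mean - controls.mean, direction)
    if patients.sd == 0 and controls.sd == 0:
        if delta == 0:
            raise ValueError("t undefined: zero variance and zero mean difference")
        return math.copysign(math.inf, delta), df, 0.0, True
    t, p = sps.ttest_ind_from_stats(
        patients.mean,
        patients.sd,
        patients.n,
        controls.mean,
        controls.sd,
        controls.n,
        equal_var=True,
    )
    return _signed(float(t), direction), df, float(p), False


def effect_size_d(
    patients: GroupSummary,
    controls: GroupSummary,
    direction: str = PATIENT_MINUS_CONTROL,
    d_denominator: str = "control_sd",
) -> float:
    """Standardized mean difference.

    ``control_sd`` gives Glass's delta (the control group's SD as
    denominator); ``pooled_sd`` gives Cohen's d with the pooled SD.
    """
    if d_denominator == "control_sd":
        denom = controls.sd
    elif d_denominator == "pooled_sd":
        denom = math.sqrt(
            (
                (patients.n - 1) * patients.sd**2
                + (controls.n - 1) * controls.sd**2
            )
            / (patients.n + controls.n - 2)
        )
    else:
        raise ValueError(f"unknown d_denominator {d_denominator!r}")
    if denom == 0:
        raise ValueError("effect size undefined: zero denominator SD")
    return _signed(patients.mean - controls.mean, direction) / denom


def compare_groups(
    patient_values: Sequence[float],
    control_values: Sequence[float],
    direction: str = PATIENT_MINUS_CONTROL,
    d_denominator: str = "control_sd",
) -> GroupComparison:
    """Full comparison from raw scores (NaN values are dropped).

    Identical, to floating precision, to running :func:`pooled_t` and
    :func:`effect_size_d` on the exact summaries of the same data.
    """
    s1 = GroupSummary.of(patient_values)
    s2 = GroupSummary.of(control_values)
    t, df, p, degenerate = pooled_t(s1, s2, direction)
    d = effect_size_d(s1, s2, direction, d_denominator)
    return GroupComparison(
        t=t,
        df=df,
        p=p,
        d=d,
        direction=direction,
        d_denominator=d_denominator,
        degenerate=degenerate,
    )


def mixed_anova_2x2(
    data: pd.DataFrame,
    value_cols: tuple[str, str] = ("perceptual", "action"),
    group_col: str = "group",
    id_col: str = "participant_id",
) -> AnovaResult:
    """2x2 mixed ANOVA: group between subjects, condition within.

    ``data`` holds one row per participant with both within-condition
    values.  Participants missing either value are dropped with a
    logged warning.  With two within-subject levels the condition F
    equals the squared paired t on the condition difference after
    removing the group effect.
    """
    import pingouin as pg

    keep = data.dropna(subset=list(value_cols))
    dropped = set(data[id_col]) - set(keep[id_col])
    if dropped:
        logger.warning(
            "mixed ANOVA: dropped %d participant(s) with missing condition "
            "values: %s",
            len(dropped),
            sorted(dropped),
        )
    if keep[group_col].nunique() != 2 or (keep.groupby(group_col).size() < 2).any():
        raise ValueError("mixed ANOVA requires two groups with >= 2 participants each")
    values = keep[list(value_cols)].to_numpy(dtype=float)
    if np.allclose(values, values.flat[0]):
        # no variance at all: every sum of squares is 0, all F are 0
        n0 = keep.shape[0]
        return AnovaResult(0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1, n0 - 2)
    long = keep.melt(
        id_vars=[id_col, group_col],
        value_vars=list(value_cols),
        var_name="condition",
        value_name="value",
    )
    aov = pg.mixed_anova(
        long,
        dv="value",
        within="condition",
        between=group_col,
        subject=id_col,
    ).set_index("Source")

    def _f(source: str) -> tuple[float, float]:
        F = aov.loc[source, "F"]
        p = aov.loc[source, "p_unc"]
        if math.isnan(F) and aov.loc[source, "SS"] == 0:
            return 0.0, 1.0  # no effect and no error variance
        return float(F), float(p)

    fg, pg_ = _f(group_col)
    fc, pc = _f("condition")
    fi, pi = _f("Interaction")
    n = keep.shape[0]
    return AnovaResult(
        F_group=fg,
        p_group=pg_,
        F_category=fc,
        p_category=pc,
        F_interaction=fi,
        p_interaction=pi,
        df1=1,
        df2=n - 2,
    )


def correlation_matrix(
    measures: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    bonferroni_m: Optional[int] = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlations with two-sided p-values.

    Missing values are pairwise-deleted; pairs with fewer than 3
    complete observations, or a zero-variance column, yield missing r
    (logged).  ``bonferroni_m`` multiplies p by m (capped at 1); when
    None it defaults to the number of pairs tested.  Returns a long
    table (var1, var2, n, r, p, p_adj).
    """
    cols = list(columns) if columns is not None else list(measures.columns)
    pairs = list(combinations(cols, 2))
    m = bonferroni_m if bonferroni_m is not None else len(pairs)
    rows = []
    for a, b in pairs:
        sub = measures[[a, b]].dropna()
        n = len(sub)
        if n < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            logger.warning("correlation %s vs %s: insufficient data (n=%d)", a, b, n)
            r = p = p_adj = math.nan
        else:
            r, p = sps.pearsonr(sub[a], sub[b])
            p_adj = min(1.0, m * p)
        rows.append(
            {"var1": a, "var2": b, "n": n, "r": r, "p": p, "p_adj": p_adj}
        )
    return pd.DataFrame(rows)


def cohens_kappa(labels1: Sequence, labels2: Sequence) -> float:
    """Cohen's kappa for two raters: (p_o - p_e) / (1 - p_e), with
    chance agreement p_e from the marginal products.  Symmetric in
    rater exchange.  Two identical constant raters (p_e = 1) agree
    perfectly by convention (kappa = 1)."""
    from sklearn.metrics import cohen_kappa_score

    l1, l2 = list(labels1), list(labels2)
    if len(l1) != len(l2):
        raise ValueError("rater label vectors must have equal length")
    if not l1:
        raise ValueError("kappa undefined for empty label vectors")
    if len(set(l1)) == 1 and l1 == l2:
        return 1.0
    return float(cohen_kappa_score(l1, l2))


def icc_agreement(ratings: np.ndarray | pd.DataFrame, form: str = "icc2") -> float:
    """Single-rater intraclass correlation for a subjects x 2-raters table.

    ``icc2``: two-way random effects, absolute agreement (the default;
    a constant offset between raters lowers the ICC).  ``icc3``:
    two-way mixed, consistency.  Requires >= 3 subjects, no missing
    cells, and nonzero between-subject variance.
    """
    import pingouin as pg

    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("ratings must be a (subjects x 2 raters) table")
    if arr.shape[0] < 3:
        raise ValueError("ICC requires at least 3 subjects")
    if np.isnan(arr).any():
        raise ValueError("ICC requires complete ratings (no missing cells)")
    if np.allclose(arr, arr.flat[0]):
        raise ValueError("ICC undefined: no variance anywhere in the ratings")
    n = arr.shape[0]
    long = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), 2),
            "rater": np.tile(["r1", "r2"], n),
            "score": arr.ravel(),
        }
    )
    table = pg.intraclass_corr(
        long, targets="target", raters="rater", ratings="score"
    ).set_index("Type")
    key = {"icc2": "ICC(A,1)", "icc3": "ICC(C,1)"}[form]
    return float(table.loc[key, "ICC"])
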