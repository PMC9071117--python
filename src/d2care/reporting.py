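"""Descriptive comparison tables and enrollment-flow accounting.

Categorical comparisons use Pearson's chi-squared test (no continuity
correction); continuous comparisons use the two-sided Student's t test with
pooled variance (Welch available via flag).  Column percentages are always
recomputed from counts and rounded half-up to one decimal, the convention
of the printed tables.  Flow accounting re-derives every stage count of an
enrollment cycle and hard-fails on any broken conservation identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rounding import pct, round_half_up
from .types import Disposition

__all__ = [
    "ComparisonTable",
    "categorical_table",
    "ContinuousComparison",
    "continuous_compare",
    "flow_accounting",
    "ConservationError",
]


@dataclass
class ComparisonTable:
    counts: pd.DataFrame        # rows x groups, integer counts
    percents: pd.DataFrame      # column percentages, half-up to 1 decimal
    test_name: str
    statistic: float | None
    dof: int | None
    p_value: float | None

    def to_markdown(self) -> str:
        cells = self.counts.astype(str) + " (" + self.percents.astype(str) + ")"
        lines = cells.to_markdown()
        if self.p_value is not None:
            lines += (
                f"\n\n{self.test_name}: statistic={self.statistic:.4f}, "
                f"df={self.dof}, p={self.p_value:.3g}"
            )
        else:
            lines += f"\n\n{self.test_name}"
        return lines


def categorical_table(
    rows: pd.Series | None = None,
    groups: pd.Series | None = None,
    *,
    counts: pd.DataFrame | None = None,
) -> ComparisonTable:
    """Counts, column percents and Pearson chi-square for rows x groups.

    Either supply two aligned factor Series, or a ready-made contingency
    table (*counts*, rows x groups).  A group with zero total still yields
    the table, but the test is marked not applicable.
    """
    if counts is None:
        if rows is None or groups is None:
            raise ValueError("supply either (rows, groups) or counts")
        counts = pd.crosstab(rows, groups)
    counts = counts.astype(int)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 row levels and 2 groups")
    col_totals = counts.sum(axis=0)
    percents = counts.apply(
        lambda col: col.map(lambda c: pct(c, col.sum()) if col.sum() else np.nan)
    )
    if (col_totals == 0).any() or (counts.sum(axis=1) == 0).any():
        return ComparisonTable(
            counts, percents, "chi-square not applicable (empty margin)",
            None, None, None,
        )
    chi2, p, dof, _ = stats.chi2_contingency(counts.to_numpy(), correction=False)
    return ComparisonTable(counts, percents, "Pearson chi-square",
                           float(chi2), int(dof), float(p))


@dataclass
class ContinuousComparison:
    means: dict[str, float]     # group -> mean, half-up to 1 decimal
    t_statistic: float
    p_value: float
    test_name: str


def continuous_compare(
    values: pd.Series, groups: pd.Series, *, welch: bool = False
) -> ContinuousComparison:
    """Two-group comparison of a continuous variable (Student's t by default)."""
    levels = pd.unique(groups.dropna())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    a = values[groups == levels[0]].dropna().to_numpy(dtype=float)
    b = values[groups == levels[1]].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    means = {
        str(levels[0]): round_half_up(a.mean(), 1),
        str(levels[1]): round_half_up(b.mean(), 1),
    }
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return ContinuousComparison(
            means, 0.0, 1.0, "Student t (degenerate: zero variance)"
        )
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return ContinuousComparison(
        means, float(t), float(p), "Welch t" if welch else "Student t (pooled)"
    )


class ConservationError(AssertionError):
    """A stage-count identity failed; the message names the identity."""


def flow_accounting(
    boxes: pd.DataFrame,
    conference: pd.DataFrame,
    watchlist_counts: dict[str, int],
    assignments: pd.DataFrame,
) -> dict:
    """Enrollment-flow report with every conservation identity asserted.

    Takes the outputs of classify_cohort, run_case_conference,
    WatchlistResolution.counts and randomize; returns a flat dict of stage
    counts.  Raises :class:`ConservationError` naming the first identity
    that fails.
    """
    n_cohort = len(boxes)
    box_counts = boxes["box"].value_counts().to_dict()
    per_box = {b: int(box_counts.get(b, 0)) for b in ("A", "B", "C", "D")}
    n_not_in_care = int((~boxes["in_care"].astype(bool)).sum()) if len(boxes) else 0
    potentially_ooc = per_box["B"] + per_box["C"] + per_box["D"]

    disp_counts = conference["disposition"].value_counts().to_dict() if len(conference) else {}
    per_disposition = {d.value: int(disp_counts.get(d.value, 0)) for d in Disposition}
    initially_randomizable = per_disposition[Disposition.RANDOMIZABLE.value]
    watchlist = per_disposition[Disposition.UPCOMING_VISIT.value]
    missed = int(watchlist_counts.get("watchlist_missed", 0))
    kept = int(watchlist_counts.get("watchlist_kept", 0))
    pending = int(watchlist_counts.get("watchlist_pending", 0))
    final_randomizable = initially_randomizable + missed
    arm_counts = assignments["arm"].value_counts().to_dict() if len(assignments) else {}
    n_dis = int(arm_counts.get("DIS", 0))
    n_soc = int(arm_counts.get("SOC", 0))

    def _check(name: str, lhs: int, rhs: int) -> None:
        if lhs != rhs:
            raise ConservationError(f"{name}: {lhs} != {rhs}")

    _check("boxes partition classified cohort (A+B+C+D+not_in_care = cohort)",
           sum(per_box.values()) + n_not_in_care, n_cohort)
    _check("dispositions cover potentially OOC", len(conference), potentially_ooc)
    _check("disposition counts sum to potentially OOC",
           sum(per_disposition.values()), potentially_ooc)
    _check("watchlist resolution conserves the watchlist",
           missed + kept + pending, watchlist)
    if len(assignments):
        _check("initially randomizable + watchlist missed = randomized",
               final_randomizable, len(assignments))
        _check("arms partition the randomized set", n_dis + n_soc, len(assignments))

    report = {
        "cohort": n_cohort,
        "not_in_care": n_not_in_care,
        "potentially_ooc": potentially_ooc,
        **{f"box_{b}": v for b, v in per_box.items()},
        **{f"disposition_{k}": v for k, v in per_disposition.items()},
        "initially_randomizable": initially_randomizable,
        "watchlist": watchlist,
        "watchlist_missed": missed,
        "watchlist_kept": kept,
        "watchlist_pending": pending,
        "final_randomizable": final_randomizable,
        "randomized": int(len(assignments)),
        "arm_DIS": n_dis,
        "arm_SOC": n_soc,
    }
    if potentially_ooc:
        report["randomized_pct_of_potentially_ooc"] = pct(
            len(assignments), potentially_ooc
        )
        report["nonrandomized_pct_of_potentially_ooc"] = pct(
            potentially_ooc - len(assignments), potentially_ooc
        )
    return report
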