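"""Descriptive error-rate analytics: marginal tables, median/IQR, cross-tabs.

Missing answers are excluded from every denominator: an error rate is
``n_errors / n_answered`` for the group.  Rates are kept unrounded
internally; :func:`round_half_up` implements the 2-decimal presentation
rounding used in the published tables (half away from zero, so
26/81 = 0.3209... displays as 0.32 and 0.125 as 0.13).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CATEGORY_LABELS,
    GROUPINGS,
    GroupErrorTable,
    ResponseItem,
    StudyDesign,
    ValidationError,
    items_to_frame,
)

__all__ = [
    "SummaryStats",
    "error_table",
    "all_error_tables",
    "median_iqr",
    "cross_error_rates",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (presentation rounding for rate columns)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SummaryStats:
    """Median and interquartile range of a set of group-level rates."""

    median: float
    q1: float
    q3: float
    n_groups: int

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValidationError("quartiles must be ordered q1 <= median <= q3")

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round_half_up(self.median, ndigits),
            round_half_up(self.q1, ndigits),
            round_half_up(self.q3, ndigits),
        )


_GROUP_COLUMN = {
    "pathologist": "participant",
    "level": "level",
    "category": "category",
    "specimen": "specimen",
    "subspecialty": "subspecialty",
}


def _answered_frame(items: Sequence[ResponseItem], design: StudyDesign) -> pd.DataFrame:
    frame = items_to_frame(items, design)
    frame = frame[frame["outcome"] != "missing"].copy()
    frame["is_error"] = (frame["outcome"] == "error").astype(int)
    return frame


def error_table(
    items: Sequence[ResponseItem], design: StudyDesign, grouping: str
) -> GroupErrorTable:
    """Marginal (n_tasks, n_errors) per group for one grouping.

    ``n_tasks`` counts answered items only.  Group labels for the category
    grouping are the question texts; every group observed in the design's
    items appears, in design order.
    """
    if grouping not in GROUPINGS:
        raise ValidationError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    frame = _answered_frame(items, design)
    if frame.empty:
        raise ValidationError("no answered items to tabulate")
    col = _GROUP_COLUMN[grouping]
    agg = frame.groupby(col, sort=False)["is_error"].agg(["count", "sum"])
    rows: dict[str, tuple[int, int]] = {}
    for key, rec in agg.iterrows():
        label = CATEGORY_LABELS[int(key)] if grouping == "category" else str(key)
        rows[label] = (int(rec["count"]), int(rec["sum"]))
    ordered = _design_order(grouping, design)
    if ordered is not None:
        rows = {k: rows[k] for k in ordered if k in rows}
    return GroupErrorTable(grouping=grouping, rows=rows)


def _design_order(grouping: str, design: StudyDesign) -> list[str] | None:
    if grouping == "pathologist":
        return list(design.participant_ids)
    if grouping == "level":
        seen: list[str] = []
        for p in design.participants:
            if p.career_level not in seen:
                seen.append(p.career_level)
        # canonical published order
        from .data_model import LEVELS

        return [lvl for lvl in LEVELS if lvl in seen]
    if grouping == "category":
        return [CATEGORY_LABELS[q] for q in sorted(CATEGORY_LABELS)]
    return None


def all_error_tables(
    items: Sequence[ResponseItem], design: StudyDesign
) -> dict[str, GroupErrorTable]:
    """All five grouping tables plus the shared totals row."""
    tables = {g: error_table(items, design, g) for g in GROUPINGS}
    n, e = tables["pathologist"].totals
    tables["total"] = GroupErrorTable(grouping="total", rows={"total": (n, e)})
    return tables


def median_iqr(rates: Sequence[float]) -> SummaryStats:
    """Median and quartiles of group rates by linear interpolation.

    Quantile convention: position ``1 + (n-1)p`` on the sorted values
    (the default of numpy and of R's ``quantile`` type 7).  Input rates must
    be unrounded; presentation rounding is a separate concern.
    """
    arr = np.asarray(list(rates), dtype=float)
    if arr.size == 0:
        raise ValidationError("median_iqr needs at least one rate")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return SummaryStats(median=float(med), q1=float(q1), q3=float(q3), n_groups=arr.size)


def cross_error_rates(
    items: Sequence[ResponseItem],
    design: StudyDesign,
    task_categories: Sequence[int],
    by: str,
) -> pd.DataFrame:
    """Raw error proportion per (diagnostic task, group) cell.

    Returns a long DataFrame with columns
    ``category, <by>, n_tasks, n_errors, rate``; a cell with no answered
    items keeps its row with ``n_tasks = 0`` and ``rate = NaN`` (undefined,
    never zero).
    """
    if by not in ("level", "specimen"):
        raise ValidationError(f"'by' must be 'level' or 'specimen', got {by!r}")
    cats = sorted(set(int(c) for c in task_categories))
    if not cats or not set(cats) <= set(CATEGORY_LABELS):
        raise ValidationError(f"task categories must be a nonempty subset of 1-5, got {cats}")
    frame = _answered_frame(items, design)
    frame = frame[frame["category"].isin(cats)]
    groups = _design_order(by if by == "level" else "specimen", design) or sorted(
        frame[by].unique()
    )
    if by == "specimen":
        from .data_model import SPECIMENS

        groups = [s for s in SPECIMENS if s in set(c.specimen for c in design.cases)]
    recs = []
    for cat in cats:
        for grp in groups:
            cell = frame[(frame["category"] == cat) & (frame[by] == grp)]
            n = int(len(cell))
            e = int(cell["is_error"].sum())
            recs.append(
                {
                    "category": cat,
                    by: grp,
                    "n_tasks": n,
                    "n_errors": e,
                    "rate": (e / n) if n else float("nan"),
                }
            )
    return pd.DataFrame(recs)
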