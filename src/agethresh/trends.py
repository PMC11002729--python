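"""Descriptive cross-census comparisons: percent changes, per-1000 rates, extrema.

Summarizes how the old-age population shifted between two censuses,
stratum by stratum — the material behind statements like "the 90-plus
population rose 84% nationally" or "Nevada saw the greatest state-level
increase".  Exports flat ``state,value`` tables ready for choropleth
mapping; rendering maps is out of scope.

All reported reals are rounded half-up to one decimal place, the
precision at which such figures are conventionally presented.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Union

from .census import CensusTable, StratumKey, WILDCARD, tail_count
from .errors import AgethreshError


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percent_change(old: float, new: float) -> float:
    """100 * (new - old) / old, rounded to one decimal.  Requires old > 0."""
    if old <= 0:
        raise AgethreshError(
            f"percent change undefined for non-positive old count {old}"
        )
    return _round1(100.0 * (new - old) / old)


def per_capita_rate(
    subgroup_count: int, total_count: int, per: int = 1000
) -> float:
    """Subgroup size per ``per`` of total population, rounded to one decimal."""
    if total_count <= 0:
        raise AgethreshError(
            f"per-capita rate undefined for non-positive total {total_count}"
        )
    return _round1(per * subgroup_count / total_count)


@dataclass(frozen=True)
class TrendRow:
    """Old/new tail counts and derived statistics for one stratum.

    A stratum present in only one of the two tables yields a gap row:
    the missing side's count is None and the derived statistics are None.
    """

    stratum: StratumKey
    old_count: Optional[int]
    new_count: Optional[int]
    percent_change: Optional[float]
    per_1000_old: Optional[float]
    per_1000_new: Optional[float]

    @property
    def is_gap(self) -> bool:
        return self.old_count is None or self.new_count is None


@dataclass(frozen=True)
class TrendReport:
    """Per-stratum change rows plus the extremum strata they imply."""

    rows: tuple[TrendRow, ...]
    min_age: int
    max_increase: Optional[StratumKey] = None
    min_increase: Optional[StratumKey] = None
    min_count_old: Optional[StratumKey] = None
    min_count_new: Optional[StratumKey] = None


def _stratum_sort_key(s: StratumKey) -> tuple:
    return (s.state, s.sex)


def build_trend_report(
    old_table: CensusTable,
    new_table: CensusTable,
    min_age: int,
    group_by: set[str] = frozenset({"state"}),
) -> TrendReport:
    """Compare tail counts at ``min_age`` between two censuses, by stratum.

    One row per combination of the grouped dimensions (rows ordered by
    state code then sex, so output is deterministic).  Rates are per 1000
    of the stratum's own total population in each year.  Extrema consider
    only complete rows; ties break by ascending state code, then sex.
    """
    group_by = set(group_by)
    extra = group_by - {"state", "sex"}
    if extra:
        raise ValueError(f"unknown grouping dimensions: {sorted(extra)}")

    def values(dim: str) -> list[str]:
        if dim not in group_by:
            return [WILDCARD]
        old_vals = old_table.states() if dim == "state" else old_table.sexes()
        new_vals = new_table.states() if dim == "state" else new_table.sexes()
        return sorted(set(old_vals) | set(new_vals))

    strata = [
        StratumKey(state=st, sex=sx) for st in values("state") for sx in values("sex")
    ]
    strata.sort(key=_stratum_sort_key)

    rows: list[TrendRow] = []
    for s in strata:
        in_old = bool(old_table.cells_in(s))
        in_new = bool(new_table.cells_in(s))
        old_n = tail_count(old_table, min_age, s) if in_old else None
        new_n = tail_count(new_table, min_age, s) if in_new else None
        pc = p_old = p_new = None
        if in_old:
            total_old = tail_count(old_table, 0, s)
            p_old = per_capita_rate(old_n, total_old) if total_old > 0 else None
        if in_new:
            total_new = tail_count(new_table, 0, s)
            p_new = per_capita_rate(new_n, total_new) if total_new > 0 else None
        if in_old and in_new and old_n > 0:
            pc = percent_change(old_n, new_n)
        rows.append(TrendRow(s, old_n, new_n, pc, p_old, p_new))

    complete = [r for r in rows if not r.is_gap and r.percent_change is not None]
    max_inc = min_inc = None
    if complete:
        max_inc = sorted(
            complete,
            key=lambda r: (-r.percent_change, _stratum_sort_key(r.stratum)),
        )[0].stratum
        min_inc = sorted(
            complete,
            key=lambda r: (r.percent_change, _stratum_sort_key(r.stratum)),
        )[0].stratum
    with_old = [r for r in rows if r.old_count is not None]
    with_new = [r for r in rows if r.new_count is not None]
    min_old = (
        min(with_old, key=lambda r: (r.old_count, _stratum_sort_key(r.stratum))).stratum
        if with_old
        else None
    )
    min_new = (
        min(with_new, key=lambda r: (r.new_count, _stratum_sort_key(r.stratum))).stratum
        if with_new
        else None
    )
    return TrendReport(
        rows=tuple(rows),
        min_age=min_age,
        max_increase=max_inc,
        min_increase=min_inc,
        min_count_old=min_old,
        min_count_new=min_new,
    )


_METRICS = (
    "old_count",
    "new_count",
    "percent_change",
    "per_1000_old",
    "per_1000_new",
)


def export_choropleth_table(
    report: TrendReport, metric: str, path: Union[str, Path]
) -> None:
    """Write a flat ``state,value`` CSV of one report metric, one row per state.

    The report must be grouped by state only (each state appearing once);
    gap rows are written with an empty value.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    state_rows = [r for r in report.rows if r.stratum.state != WILDCARD]
    seen = [r.stratum.state for r in state_rows]
    if len(seen) != len(set(seen)):
        raise ValueError(
            "choropleth export needs one row per state; regroup the report by state only"
        )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["state", "value"])
        for r in state_rows:
            value = getattr(r, metric)
            writer.writerow([r.stratum.state, "" if value is None else value])
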