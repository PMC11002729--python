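"""Census-style count tables and tail (at-or-above-age) counts.

The elementary object of the whole analysis is an aggregate count table
shaped like the decennial census single-year-of-age tabulations: one
non-negative integer count per (year, state, sex, age-bin) cell.  Ages
are completed years at census day; bins are closed integer ranges
``[lower, upper]``, with an open-ended terminal bin ``[lower, inf)``
housing top-coded groups such as a "90 years or older" aggregate.

The quantity everything else is built on is the *tail count*
``N(age >= t)`` within a stratum — the equivalence-class size of a
"t years or older" age group.  Tail counts are only computed at bin
boundaries; a query falling strictly inside a bin raises
:class:`~agethresh.errors.AlignmentError` rather than prorating, because
interpolation would fabricate group sizes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from ._states import STATE_CODES
from .errors import AggregationError, AlignmentError, ParseError

#: Sentinel for a wildcard stratum dimension ("aggregate over all values").
WILDCARD = "*"

SEXES = ("male", "female", "all")

CSV_HEADER = ["year", "state", "sex", "age_lo", "age_hi", "count"]


@dataclass(frozen=True)
class AgeBin:
    """A closed integer age range ``[lower, upper]``; ``upper=None`` is open-ended."""

    lower: int
    upper: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValueError(f"age bin lower bound must be >= 0, got {self.lower}")
        if self.upper is not None and self.upper < self.lower:
            raise ValueError(f"age bin upper {self.upper} < lower {self.lower}")

    @property
    def is_open(self) -> bool:
        return self.upper is None

    def overlaps(self, other: "AgeBin") -> bool:
        lo = max(self.lower, other.lower)
        if self.is_open and other.is_open:
            return True
        if self.is_open:
            return other.upper >= self.lower
        if other.is_open:
            return self.upper >= other.lower
        return lo <= min(self.upper, other.upper)

    def straddles(self, age: int) -> bool:
        """True if ``age`` splits this bin (part below, part at-or-above)."""
        return self.lower < age and (self.upper is None or self.upper >= age)

    def __str__(self) -> str:
        return f"{self.lower}+" if self.is_open else f"{self.lower}-{self.upper}"


def _bin_sort_key(b: AgeBin) -> tuple:
    return (b.lower, float("inf") if b.upper is None else b.upper)


@dataclass(frozen=True)
class CensusCell:
    """One aggregate count: persons of one sex, in one state, in one age bin."""

    year: int
    state: str
    sex: str
    age_bin: AgeBin
    count: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not isinstance(self.count, int) or isinstance(self.count, bool):
            raise ValueError(f"count must be an integer, got {self.count!r}")
        if self.count < 0:
            raise ValueError(f"count must be non-negative, got {self.count}")


@dataclass(frozen=True)
class StratumKey:
    """Selects a (state, sex) stratum; a WILDCARD dimension sums over all values."""

    state: str = WILDCARD
    sex: str = WILDCARD

    def matches(self, cell: CensusCell) -> bool:
        return (self.state == WILDCARD or cell.state == self.state) and (
            self.sex == WILDCARD or cell.sex == self.sex
        )

    def __str__(self) -> str:
        return f"(state={self.state}, sex={self.sex})"


@dataclass(frozen=True)
class CensusTable:
    """A collection of cells sharing one census year, plus provenance text."""

    cells: tuple[CensusCell, ...]
    metadata: str = ""

    def __init__(self, cells: Iterable[CensusCell], metadata: str = ""):
        object.__setattr__(self, "cells", tuple(cells))
        object.__setattr__(self, "metadata", metadata)

    @property
    def year(self) -> Optional[int]:
        return self.cells[0].year if self.cells else None

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.cells)

    def strata(self) -> list[tuple[str, str]]:
        return sorted({(c.state, c.sex) for c in self.cells})

    def states(self) -> list[str]:
        return sorted({c.state for c in self.cells})

    def sexes(self) -> list[str]:
        return sorted({c.sex for c in self.cells})

    def cells_in(self, stratum: StratumKey) -> list[CensusCell]:
        return [c for c in self.cells if stratum.matches(c)]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per cell (age_hi is NA for the open bin)."""
        return pd.DataFrame(
            {
                "year": [c.year for c in self.cells],
                "state": [c.state for c in self.cells],
                "sex": [c.sex for c in self.cells],
                "age_lo": [c.age_bin.lower for c in self.cells],
                "age_hi": [c.age_bin.upper for c in self.cells],
                "count": [c.count for c in self.cells],
            }
        ).astype({"age_hi": "Int64"})

    def __len__(self) -> int:
        return len(self.cells)


def validate_table(table: CensusTable) -> list[str]:
    """Check table-level invariants; return one description per violation.

    Violations are returned, never raised, so callers can report them all.
    Checked: single census year; known state codes; no overlapping bins
    within a (state, sex) stratum; at most one open-ended bin per stratum,
    with its lower bound above every closed bin; no mixing of "all"-sex
    rows with per-sex rows in one state (double counting).
    """
    violations: list[str] = []

    years = {c.year for c in table.cells}
    if len(years) > 1:
        violations.append(f"cells span multiple census years: {sorted(years)}")

    bad_states = sorted({c.state for c in table.cells} - STATE_CODES)
    if bad_states:
        violations.append(f"unknown state codes: {bad_states}")

    by_stratum: dict[tuple[str, str], list[AgeBin]] = {}
    for c in table.cells:
        by_stratum.setdefault((c.state, c.sex), []).append(c.age_bin)

    for (state, sex), bins in sorted(by_stratum.items()):
        bins_sorted = sorted(bins, key=_bin_sort_key)
        for a, b in zip(bins_sorted, bins_sorted[1:]):
            if a.overlaps(b):
                violations.append(
                    f"stratum (state={state}, sex={sex}): "
                    f"overlapping age bins {a} and {b}"
                )
        open_bins = [b for b in bins if b.is_open]
        if len(open_bins) > 1:
            violations.append(
                f"stratum (state={state}, sex={sex}): "
                f"{len(open_bins)} open-ended bins (at most 1 allowed)"
            )
        # a closed bin reaching the open bin's range is already reported as an
        # overlap, so "open bin must top the stratum" needs no separate check

    per_state_sexes: dict[str, set[str]] = {}
    for c in table.cells:
        per_state_sexes.setdefault(c.state, set()).add(c.sex)
    for state, sexes in sorted(per_state_sexes.items()):
        if "all" in sexes and ({"male", "female"} & sexes):
            violations.append(
                f"state {state}: 'all'-sex rows coexist with per-sex rows "
                f"(double counting)"
            )

    return violations


def _require_valid(table: CensusTable) -> None:
    violations = validate_table(table)
    if violations:
        raise ValueError("invalid census table: " + "; ".join(violations))


def read_census_table(path: Union[str, Path]) -> CensusTable:
    """Read a census table from the package's CSV dialect.

    The dialect is UTF-8 CSV with header exactly
    ``year,state,sex,age_lo,age_hi,count``; an empty ``age_hi`` encodes the
    open-ended bin; counts must be non-negative integers; one census year
    per file.  Any malformed row raises :class:`ParseError` naming the row.
    """
    path = Path(path)
    cells: list[CensusCell] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (missing header)") from None
        if header != CSV_HEADER:
            raise ParseError(
                f"{path}: bad header {header!r}, expected {CSV_HEADER!r}"
            )
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 6:
                raise ParseError(f"{path} row {i}: expected 6 fields, got {len(row)}")
            year_s, state, sex, lo_s, hi_s, count_s = (f.strip() for f in row)
            try:
                year = int(year_s)
                lo = int(lo_s)
                hi = None if hi_s == "" else int(hi_s)
                count = int(count_s)  # rejects fractional counts like "5.5"
                cell = CensusCell(year, state, sex, AgeBin(lo, hi), count)
            except ValueError as exc:
                raise ParseError(f"{path} row {i}: {exc}") from None
            cells.append(cell)
    table = CensusTable(cells, metadata=f"read from {path.name}")
    violations = validate_table(table)
    if violations:
        raise ParseError(f"{path}: " + "; ".join(violations))
    return table


def write_census_table(table: CensusTable, path: Union[str, Path]) -> None:
    """Write a table in the CSV dialect read by :func:`read_census_table`.

    The round trip is bit-exact: counts are plain integers and the open
    bin's upper bound serializes as the empty string.
    """
    _require_valid(table)
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_HEADER)
        for c in sorted(
            table.cells, key=lambda c: (c.state, c.sex, _bin_sort_key(c.age_bin))
        ):
            hi = "" if c.age_bin.is_open else c.age_bin.upper
            writer.writerow([c.year, c.state, c.sex, c.age_bin.lower, hi, c.count])


def aggregate(table: CensusTable, collapse: set[str]) -> CensusTable:
    """Sum counts over collapsed dimensions (subset of {"state", "sex"}).

    A collapsed state becomes "US", a collapsed sex becomes "all"; counts
    are summed within identical age bins, so the total population is
    conserved exactly.  If strata bring mutually incompatible bins (e.g.
    one state top-codes at 90 and another at 100), the summed bins overlap
    and an :class:`AggregationError` names the contributing strata.
    """
    extra = collapse - {"state", "sex"}
    if extra:
        raise ValueError(f"unknown collapse dimensions: {sorted(extra)}")
    _require_valid(table)

    sums: dict[tuple[str, str, AgeBin], int] = {}
    contributors: dict[tuple[str, str, AgeBin], set[tuple[str, str]]] = {}
    for c in table.cells:
        state = "US" if "state" in collapse else c.state
        sex = "all" if "sex" in collapse else c.sex
        key = (state, sex, c.age_bin)
        sums[key] = sums.get(key, 0) + c.count
        contributors.setdefault(key, set()).add((c.state, c.sex))

    year = table.year
    cells = [
        CensusCell(year, state, sex, age_bin, count)
        for (state, sex, age_bin), count in sums.items()
    ]
    result = CensusTable(
        sorted(cells, key=lambda c: (c.state, c.sex, _bin_sort_key(c.age_bin))),
        metadata=f"{table.metadata} [aggregated over {sorted(collapse)}]".strip(),
    )

    # detect incompatible binning surfaced by the merge
    by_stratum: dict[tuple[str, str], list[AgeBin]] = {}
    for c in result.cells:
        by_stratum.setdefault((c.state, c.sex), []).append(c.age_bin)
    for (state, sex), bins in by_stratum.items():
        bins_sorted = sorted(bins, key=_bin_sort_key)
        for a, b in zip(bins_sorted, bins_sorted[1:]):
            if a.overlaps(b):
                src_a = sorted(contributors[(state, sex, a)])
                src_b = sorted(contributors[(state, sex, b)])
                raise AggregationError(
                    f"cannot aggregate: bins {a} (from strata {src_a}) and "
                    f"{b} (from strata {src_b}) overlap in stratum "
                    f"(state={state}, sex={sex})"
                )
    return result


def is_aligned(table: CensusTable, age: int, stratum: StratumKey) -> bool:
    """True if ``age`` is a clean cut point: no contributing bin straddles it."""
    return not any(c.age_bin.straddles(age) for c in table.cells_in(stratum))


def tail_count(table: CensusTable, min_age: int, stratum: StratumKey) -> int:
    """Exact count of persons aged ``min_age`` or older within the stratum.

    This is the equivalence-class size of a ">= min_age" age group.  Every
    contributing bin must lie entirely at-or-above or entirely below
    ``min_age``; an open-ended bin with lower bound >= ``min_age``
    contributes fully.  WILDCARD dimensions of the stratum are summed over.

    Raises
    ------
    AlignmentError
        If ``min_age`` falls strictly inside a contributing bin.  There is
        deliberately no proration.
    """
    if min_age < 0:
        raise ValueError(f"min_age must be >= 0, got {min_age}")
    total = 0
    for c in table.cells_in(stratum):
        b = c.age_bin
        if b.lower >= min_age:
            total += c.count
        elif b.straddles(min_age):
            raise AlignmentError(
                f"age {min_age} falls inside bin {b} of stratum "
                f"(state={c.state}, sex={c.sex}); tail counts are only "
                f"defined at bin boundaries"
            )
    return total
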