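"""Derive updated maximum-age generalization thresholds.

The recipe: the group of people aged 90+ at the time an age cap of 90 was
adopted defines a baseline equivalence-class size B.  Against a newer
census table, the updated cap t* is the highest age whose tail count
still reaches B,

    t* = max { t : N_current(age >= t) >= B },

so a "t* or older" group today is at least as large — hence at least as
anonymous under a group-size (k-anonymity) reading — as the "90 or older"
group was then.  Because tail counts step down as age rises, t* is unique.

Also here: the generic minimum-group-size admissibility check used for
geographic units (strictly greater than a population floor), and the
longitudinal deduction that defeats an age cap when linked records show a
person below the cap in an earlier year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

from .census import CensusTable, StratumKey, WILDCARD, is_aligned, tail_count
from .errors import InferenceNotApplicableError, NoAdmissibleThresholdError


@dataclass(frozen=True)
class BaselineSpec:
    """The historical reference group: its census year, age cutoff, and size."""

    baseline_year: Optional[int]
    baseline_age: int
    stratum: StratumKey
    group_size: int

    def __post_init__(self) -> None:
        if self.group_size < 0:
            raise ValueError("baseline group size must be >= 0")


@dataclass(frozen=True)
class ThresholdRecommendation:
    """A derived maximum-age cutoff t* with its achieved and baseline group sizes.

    ``capped_by_top_code`` is set when t* sits at the table's open-ended
    (top-coded) bin, where finer age resolution is unavailable — the true
    admissible cutoff may be higher.  ``decreased_below_baseline_age``
    flags a recommendation below the original cutoff, which would require
    data sources to re-bin rather than merely relax.
    """

    stratum: StratumKey
    recommended_age: int
    achieved_group_size: int
    baseline: BaselineSpec
    capped_by_top_code: bool = False
    decreased_below_baseline_age: bool = False


def baseline_group_size(
    baseline_table: CensusTable, baseline_age: int, stratum: StratumKey
) -> BaselineSpec:
    """Measure the historical reference group size B = N(age >= baseline_age)."""
    size = tail_count(baseline_table, baseline_age, stratum)
    return BaselineSpec(
        baseline_year=baseline_table.year,
        baseline_age=baseline_age,
        stratum=stratum,
        group_size=size,
    )


def _default_age_range(
    table: CensusTable, stratum: StratumKey
) -> tuple[int, int, list[int]]:
    """Default search floor/ceiling plus the open-bin lower bounds in the stratum.

    Ceiling = lower bound of the open-ended bin (finest resolvable cutoff)
    or, absent one, the highest closed bin's upper bound.
    """
    cells = table.cells_in(stratum)
    if not cells:
        raise ValueError(f"no cells in stratum {stratum}")
    open_lowers = [c.age_bin.lower for c in cells if c.age_bin.is_open]
    if open_lowers:
        ceiling = max(open_lowers)
    else:
        ceiling = max(c.age_bin.upper for c in cells)
    return 0, ceiling, open_lowers


def derive_threshold(
    current_table: CensusTable,
    baseline: BaselineSpec,
    stratum: StratumKey,
    age_floor: Optional[int] = None,
    age_ceiling: Optional[int] = None,
) -> ThresholdRecommendation:
    """Find the highest age whose tail count still meets the baseline size.

    Scans aligned ages in ``[age_floor, age_ceiling]`` from the top down
    and returns the first (hence maximum) age t with
    ``tail_count(current_table, t, stratum) >= baseline.group_size``.
    Ages falling inside a bin are not queried.  Defaults: floor 0, ceiling
    the stratum's open-bin lower bound (or highest closed bin).

    Raises
    ------
    NoAdmissibleThresholdError
        If even the floor's tail count falls short of the baseline; the
        error carries that tail count.
    """
    d_floor, d_ceiling, open_lowers = _default_age_range(current_table, stratum)
    floor = d_floor if age_floor is None else age_floor
    ceiling = d_ceiling if age_ceiling is None else age_ceiling
    if floor > ceiling:
        raise ValueError(f"age_floor {floor} > age_ceiling {ceiling}")

    tail_at_floor: Optional[int] = None
    for t in range(ceiling, floor - 1, -1):
        if not is_aligned(current_table, t, stratum):
            continue
        tail = tail_count(current_table, t, stratum)
        tail_at_floor = tail
        if tail >= baseline.group_size:
            return ThresholdRecommendation(
                stratum=stratum,
                recommended_age=t,
                achieved_group_size=tail,
                baseline=baseline,
                capped_by_top_code=t in open_lowers,
                decreased_below_baseline_age=t < baseline.baseline_age,
            )
    raise NoAdmissibleThresholdError(
        f"no age in [{floor}, {ceiling}] has a tail count >= "
        f"{baseline.group_size} in stratum {stratum}",
        tail_at_floor=0 if tail_at_floor is None else tail_at_floor,
    )


def derive_by_stratum(
    baseline_table: CensusTable,
    current_table: CensusTable,
    baseline_age: int,
    group_by: Iterable[str] = (),
    baseline_mode: str = "per_stratum",
    explicit_size: Optional[int] = None,
    age_floor: Optional[int] = None,
    age_ceiling: Optional[int] = None,
    strict: bool = False,
) -> list[ThresholdRecommendation]:
    """Derive one recommendation per stratum of the grouping dimensions.

    ``baseline_mode`` selects the reference group size used for each
    stratum:

    - ``per_stratum`` — each stratum is held to its own historical tail
      count at ``baseline_age``;
    - ``min_stratum`` — every stratum is held to the *smallest* stratum's
      historical tail count (the "the scarcer sex's group was evidently
      acceptable, so it is acceptable for either sex" argument);
    - ``explicit`` — a supplied ``explicit_size`` applies to all strata.

    Failed strata (e.g. no admissible threshold) are reported as warnings
    and omitted unless ``strict=True``, so one bad stratum does not abort
    the rest.
    """
    group_by = set(group_by)
    extra = group_by - {"state", "sex"}
    if extra:
        raise ValueError(f"unknown grouping dimensions: {sorted(extra)}")
    if baseline_mode not in ("per_stratum", "min_stratum", "explicit"):
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    if baseline_mode == "explicit" and explicit_size is None:
        raise ValueError("baseline_mode='explicit' requires explicit_size")

    states = current_table.states() if "state" in group_by else [WILDCARD]
    sexes = current_table.sexes() if "sex" in group_by else [WILDCARD]
    strata = [StratumKey(state=st, sex=sx) for st in states for sx in sexes]

    per_stratum_sizes = {
        s: tail_count(baseline_table, baseline_age, s) for s in strata
    }
    shared_size: Optional[int] = None
    if baseline_mode == "min_stratum":
        shared_size = min(per_stratum_sizes.values())
    elif baseline_mode == "explicit":
        shared_size = explicit_size

    results: list[ThresholdRecommendation] = []
    for s in strata:
        size = per_stratum_sizes[s] if shared_size is None else shared_size
        baseline = BaselineSpec(
            baseline_year=baseline_table.year,
            baseline_age=baseline_age,
            stratum=s,
            group_size=size,
        )
        try:
            results.append(
                derive_threshold(current_table, baseline, s, age_floor, age_ceiling)
            )
        except Exception as exc:
            if strict:
                raise
            warnings.warn(f"stratum {s}: {exc}", stacklevel=2)
    return results


def check_min_group_size(count: int, minimum: int) -> bool:
    """Admissibility of a geographic unit: population strictly greater than the floor.

    Mirrors the Safe Harbor rule admitting 3-digit-zip areas only with
    "a population greater than 20,000" — strictly greater, so a count
    exactly at the floor is not admissible.
    """
    if count < 0 or minimum < 0:
        raise ValueError("count and minimum must be >= 0")
    return count > minimum


def infer_longitudinal_age(
    earlier_recorded_age: int, years_elapsed: int, cap: int
) -> int:
    """Deduce the true minimum age behind a capped record from a linked earlier one.

    If a linked record from ``years_elapsed`` years ago shows an uncensored
    age below the cap, the person's true age today is simply
    ``earlier_recorded_age + years_elapsed`` — the cap on the current
    record hides nothing.  E.g. 89 recorded five years before a capped "90"
    means the person is actually 94.

    Raises
    ------
    InferenceNotApplicableError
        If the earlier record is itself at or above the cap (it may have
        been capped too, so nothing can be deduced).
    """
    if years_elapsed < 0:
        raise ValueError("years_elapsed must be >= 0")
    if earlier_recorded_age >= cap:
        raise InferenceNotApplicableError(
            f"earlier recorded age {earlier_recorded_age} is not below the "
            f"cap {cap}; the earlier record may itself be capped"
        )
    return earlier_recorded_age + years_elapsed
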