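"""Synthetic census microdata with the structure the analysis assumes.

Generates individual-level records (age, sex, state) whose aggregate
shape mimics decennial single-year-of-age tables: counts that thin out
monotonically at advanced ages, more women than men among the oldest
old, per-state allocation, a top-coded terminal bin, and decade-over-
decade growth of the 90-plus population.  Tabulated synthetic microdata
exercise every pipeline stage without any external download, and the raw
records double as a brute-force oracle: any tail count or derived
threshold can be checked by scanning individuals directly.

Ages are drawn from a distribution proportional to Gompertz survivorship

    S_s(a) = exp(-(a_s / b) * (e^(b*a) - 1)),   a = 0 .. max_age,

with baseline hazard ``a_s`` = ``gompertz_a`` for males, scaled by
``female_hazard_multiplier`` (< 1 means women die slower) for females.
This is a stationary-population simplification — no cohorts, migration,
or period shocks — chosen because the pipeline only needs the monotone
old-age decline and the sex differential, not demographic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._states import DEFAULT_STATE_WEIGHTS
from .census import AgeBin, CensusCell, CensusTable
from .dp import NoiseModel


@dataclass(frozen=True)
class SyntheticCensusParams:
    """Generator knobs; defaults give a plausibly census-shaped population.

    ``gompertz_a`` (per year) is the baseline mortality hazard,
    ``gompertz_b`` (per year) its exponential growth rate.
    ``decadal_longevity_improvement`` shrinks ``gompertz_a`` by that
    fraction per decade and ``decadal_growth`` grows the total population
    per decade when generating a census series.
    """

    total_population: int
    gompertz_a: float = 5e-5
    gompertz_b: float = 0.09
    female_hazard_multiplier: float = 0.75
    sex_fraction_female: float = 0.5
    state_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_WEIGHTS)
    )
    top_code_age: int = 100
    max_age: int = 110
    decadal_longevity_improvement: float = 0.1
    decadal_growth: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_population < 0:
            raise ValueError("total_population must be >= 0")
        if self.gompertz_a <= 0 or self.gompertz_b <= 0:
            raise ValueError("Gompertz parameters must be positive")
        if self.female_hazard_multiplier <= 0:
            raise ValueError("female_hazard_multiplier must be positive")
        if not 0 < self.sex_fraction_female < 1:
            raise ValueError("sex_fraction_female must lie in (0, 1)")
        if not self.state_weights or any(
            w <= 0 for w in self.state_weights.values()
        ):
            raise ValueError("state_weights must be non-empty and positive")
        if self.top_code_age > self.max_age:
            raise ValueError("top_code_age must be <= max_age")
        if self.decadal_longevity_improvement < 0:
            raise ValueError("decadal_longevity_improvement must be >= 0")


@dataclass(frozen=True)
class Microdata:
    """Individual-level records backing a census table; the oracle substrate."""

    ages: np.ndarray
    sexes: np.ndarray  # "male" / "female"
    states: np.ndarray
    seed: int

    def __len__(self) -> int:
        return len(self.ages)


def survivorship(ages: np.ndarray, a: float, b: float) -> np.ndarray:
    """Gompertz survivorship S(age) = exp(-(a/b)(e^(b*age) - 1))."""
    return np.exp(-(a / b) * np.expm1(b * np.asarray(ages, dtype=float)))


def age_pmf(params: SyntheticCensusParams, sex: str) -> np.ndarray:
    """Probability of each integer age 0..max_age for one sex.

    Proportional to survivorship, i.e. a stationary population with
    constant birth inflow; exact normalization over the integer grid.
    """
    mult = params.female_hazard_multiplier if sex == "female" else 1.0
    ages = np.arange(params.max_age + 1)
    s = survivorship(ages, params.gompertz_a * mult, params.gompertz_b)
    return s / s.sum()


def tail_probability(params: SyntheticCensusParams, sex: str, min_age: int) -> float:
    """Analytic P(age >= min_age) for one sex under the generator's model."""
    pmf = age_pmf(params, sex)
    return float(pmf[min_age:].sum())


def mixture_tail_probability(params: SyntheticCensusParams, min_age: int) -> float:
    """Analytic P(age >= min_age) for the sex mixture the generator draws."""
    pf = params.sex_fraction_female
    return pf * tail_probability(params, "female", min_age) + (
        1 - pf
    ) * tail_probability(params, "male", min_age)


def generate_microdata(params: SyntheticCensusParams) -> Microdata:
    """Draw the synthetic population; a pure function of ``params`` (incl. seed)."""
    rng = np.random.default_rng(params.seed)
    n = params.total_population

    sexes = np.where(
        rng.random(n) < params.sex_fraction_female, "female", "male"
    ).astype(object)

    state_names = np.array(sorted(params.state_weights), dtype=object)
    w = np.array([params.state_weights[s] for s in state_names], dtype=float)
    states = rng.choice(state_names, size=n, p=w / w.sum())

    ages = np.empty(n, dtype=np.int64)
    for sex in ("female", "male"):
        mask = sexes == sex
        k = int(mask.sum())
        if k:
            ages[mask] = rng.choice(
                params.max_age + 1, size=k, p=age_pmf(params, sex)
            )
    return Microdata(ages=ages, sexes=sexes, states=states, seed=params.seed)


def tabulate(
    micro: Microdata, top_code_age: int, year: int = 0
) -> CensusTable:
    """Aggregate microdata into a census-shaped single-year-of-age table.

    Single-year bins below ``top_code_age``; one open-ended bin at
    ``top_code_age`` collecting everyone at or above it (the top-coded
    group).  Only non-empty cells are emitted, so empty microdata give an
    empty table; the total count always equals the number of records.
    """
    cells: list[CensusCell] = []
    if len(micro):
        capped = np.minimum(micro.ages, top_code_age)
        keys = np.char.add(
            np.char.add(micro.states.astype(str), "|"), micro.sexes.astype(str)
        )
        for key in np.unique(keys):
            state, sex = key.split("|")
            mask = keys == key
            counts = np.bincount(capped[mask], minlength=top_code_age + 1)
            for age in np.nonzero(counts)[0]:
                is_top = int(age) == top_code_age
                cells.append(
                    CensusCell(
                        year=year,
                        state=state,
                        sex=sex,
                        age_bin=AgeBin(int(age), None if is_top else int(age)),
                        count=int(counts[age]),
                    )
                )
    return CensusTable(cells, metadata=f"synthetic tabulation (seed={micro.seed})")


def generate_census_series(
    params: SyntheticCensusParams, years: Sequence[int]
) -> list[CensusTable]:
    """One table per decade-spaced census year, with growth and longevity gains.

    Decade k (zero-based) scales the total population by
    ``(1 + decadal_growth)^k`` and the baseline hazard by
    ``(1 - decadal_longevity_improvement)^k``; each year draws from an
    independent child stream of the params seed, so the whole series is
    deterministic given ``params``.
    """
    years = list(years)
    if any(b - a != 10 for a, b in zip(years, years[1:])):
        raise ValueError(f"years must be strictly increasing and decade-spaced: {years}")
    tables = []
    children = np.random.SeedSequence(params.seed).spawn(len(years))
    for k, year in enumerate(years):
        sub_seed = int(children[k].generate_state(1)[0] % (2**31))
        sub = replace(
            params,
            total_population=int(
                round(params.total_population * (1 + params.decadal_growth) ** k)
            ),
            gompertz_a=params.gompertz_a
            * (1 - params.decadal_longevity_improvement) ** k,
            seed=sub_seed,
        )
        tables.append(tabulate(generate_microdata(sub), params.top_code_age, year=year))
    return tables


def add_dp_noise(table: CensusTable, model: NoiseModel, seed: int) -> CensusTable:
    """Perturb every cell with independent noise of the model's mechanism/scale.

    Emulates a privacy-protected publication of the table: noise is drawn
    per cell, the result rounded to the nearest integer and clamped at
    zero (published tables are non-negative).  Deterministic given seed.
    """
    if model.mechanism == "none":
        raise ValueError("add_dp_noise requires a gaussian or laplace mechanism")
    rng = np.random.default_rng(seed)
    if model.mechanism == "gaussian":
        noise = rng.normal(0.0, model.scale, size=len(table))
    else:
        noise = rng.laplace(0.0, model.scale, size=len(table))
    cells = [
        CensusCell(
            c.year,
            c.state,
            c.sex,
            c.age_bin,
            max(0, int(round(c.count + eps))),
        )
        for c, eps in zip(table.cells, noise)
    ]
    note = (
        f"{table.metadata} [+{model.mechanism} noise, scale={model.scale}, "
        f"seed={seed}]"
    ).strip()
    return CensusTable(cells, metadata=note)


def brute_force_tail(
    micro: Microdata,
    min_age: int,
    state: Optional[str] = None,
    sex: Optional[str] = None,
) -> int:
    """Oracle: count individuals with age >= min_age by direct scan."""
    mask = micro.ages >= min_age
    if state is not None:
        mask &= micro.states == state
    if sex is not None:
        mask &= micro.sexes == sex
    return int(mask.sum())
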