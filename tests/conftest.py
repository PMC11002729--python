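"""Shared fixtures and hypothesis strategies for census-table tests."""

from __future__ import annotations

import hypothesis.strategies as st
import pytest
from hypothesis import settings

from agethresh import AgeBin, CensusCell, CensusTable, StratumKey

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

STATES_SMALL = ["AK", "CA", "IA", "NV", "WY"]


def make_cells(counts_by_age, state="US", sex="male", year=2010, open_age=None):
    """Single-year cells from an {age: count} map; open_age marks the open bin."""
    cells = []
    for age, count in sorted(counts_by_age.items()):
        upper = None if age == open_age else age
        cells.append(CensusCell(year, state, sex, AgeBin(age, upper), count))
    return cells


@pytest.fixture
def planted_table():
    """Single-year counts 90:400, 91:300, 92:250, 93:150 and an open 94+:100.

    Tail counts: >=90 is 1200, >=91 is 800, >=92 is 500, >=93 is 250, >=94 is 100.
    """
    return CensusTable(
        make_cells(
            {90: 400, 91: 300, 92: 250, 93: 150, 94: 100}, open_age=94
        )
    )


@pytest.fixture
def us_male():
    return StratumKey(state="US", sex="male")


@st.composite
def census_tables(draw, states=tuple(STATES_SMALL), sexes=("male", "female"),
                  max_age=12, open_age=None):
    """Small valid tables: single-year bins 0..max_age, optional shared open bin.

    A compact age range keeps examples readable; the table logic never
    depends on the absolute magnitude of ages.
    """
    year = draw(st.integers(1980, 2020))
    cells = []
    for state in draw(st.sets(st.sampled_from(list(states)), min_size=1)):
        for sex in sexes:
            ages = draw(st.sets(st.integers(0, max_age), max_size=8))
            for age in ages:
                count = draw(st.integers(0, 1000))
                upper = None if open_age is not None and age == open_age else age
                if open_age is not None and age > open_age:
                    continue
                cells.append(CensusCell(year, state, sex, AgeBin(age, upper), count))
    return CensusTable(cells)
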