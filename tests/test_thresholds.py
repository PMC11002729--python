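"""Threshold derivation against a historical baseline group size."""

from __future__ import annotations

import numpy as np
import pytest

from agethresh import (
    BaselineSpec,
    CensusTable,
    InferenceNotApplicableError,
    NoAdmissibleThresholdError,
    StratumKey,
    baseline_group_size,
    check_min_group_size,
    derive_by_stratum,
    derive_threshold,
    infer_longitudinal_age,
    tail_count,
)

from conftest import make_cells


class TestBaselineGroupSize:
    def test_hand_summed_baseline(self, planted_table, us_male):
        spec = baseline_group_size(planted_table, 90, us_male)
        assert spec.group_size == 1200
        assert spec.baseline_age == 90
        assert spec.baseline_year == 2010

    def test_empty_table_gives_zero(self):
        spec = baseline_group_size(CensusTable([]), 90, StratumKey())
        assert spec.group_size == 0


class TestDeriveThreshold:
    def test_planted_counts_give_92_for_baseline_500(self, planted_table, us_male):
        baseline = BaselineSpec(1990, 90, us_male, 500)
        rec = derive_threshold(planted_table, baseline, us_male)
        assert rec.recommended_age == 92
        assert rec.achieved_group_size == 500
        assert not rec.capped_by_top_code
        assert not rec.decreased_below_baseline_age
        # feasibility: one year higher falls short
        assert tail_count(planted_table, 93, us_male) < 500

    def test_zero_baseline_is_vacuous_and_hits_top_code(self, planted_table, us_male):
        rec = derive_threshold(planted_table, BaselineSpec(1990, 90, us_male, 0), us_male)
        assert rec.recommended_age == 94  # the open bin's lower bound
        assert rec.capped_by_top_code

    def test_unreachable_baseline_raises_with_floor_tail(self, planted_table, us_male):
        baseline = BaselineSpec(1990, 90, us_male, 10_000)
        with pytest.raises(NoAdmissibleThresholdError) as exc:
            derive_threshold(planted_table, baseline, us_male, age_floor=90)
        assert exc.value.tail_at_floor == 1200

    def test_recommendation_below_baseline_age_is_flagged(self, us_male):
        # population shrank: only 300 people aged 90+, baseline needs 400
        table = CensusTable(make_cells({88: 200, 89: 150, 90: 180, 91: 120}))
        rec = derive_threshold(table, BaselineSpec(1990, 90, us_male, 400), us_male)
        assert rec.recommended_age == 89
        assert rec.decreased_below_baseline_age
        assert rec.achieved_group_size == 450

    def test_monotone_in_baseline_size(self, planted_table, us_male):
        ages = [
            derive_threshold(
                planted_table, BaselineSpec(1990, 90, us_male, b), us_male
            ).recommended_age
            for b in (100, 250, 500, 800, 1200)
        ]
        assert ages == sorted(ages, reverse=True)

    def test_self_consistency_at_own_tail(self, planted_table, us_male):
        spec = baseline_group_size(planted_table, 90, us_male)
        rec = derive_threshold(planted_table, spec, us_male)
        assert rec.recommended_age >= 90


class TestDeriveByStratum:
    @pytest.fixture
    def two_sex_tables(self):
        base = CensusTable(
            make_cells({90: 300, 91: 200, 92: 100}, sex="male")
            + make_cells({90: 500, 91: 400, 92: 300}, sex="female"),
            metadata="baseline",
        )
        cur = CensusTable(
            make_cells({90: 700, 91: 650, 92: 600, 93: 550, 94: 200}, sex="male")
            + make_cells({90: 1100, 91: 1000, 92: 900, 93: 800, 94: 700}, sex="female"),
        )
        return base, cur

    def test_min_stratum_uses_smallest_sex_baseline(self, two_sex_tables):
        base, cur = two_sex_tables
        recs = derive_by_stratum(base, cur, 90, group_by={"sex"},
                                 baseline_mode="min_stratum")
        by_sex = {r.stratum.sex: r for r in recs}
        # male 90+ baseline (600) is the smaller; both sexes held to it
        assert all(r.baseline.group_size == 600 for r in recs)
        # male tails: 2700,2000,1350,750,200 -> max t with tail>=600 is 93
        assert by_sex["male"].recommended_age == 93
        # female tails: 4500,3400,2400,1500,700 -> 94 still has 700 >= 600
        assert by_sex["female"].recommended_age == 94
        assert by_sex["female"].recommended_age >= by_sex["male"].recommended_age

    def test_per_stratum_matches_single_derivation(self, two_sex_tables):
        base, cur = two_sex_tables
        recs = derive_by_stratum(base, cur, 90, group_by={"sex"},
                                 baseline_mode="per_stratum")
        for r in recs:
            s = r.stratum
            single = derive_threshold(cur, baseline_group_size(base, 90, s), s)
            assert r == single

    def test_explicit_baseline_applies_everywhere(self, two_sex_tables):
        base, cur = two_sex_tables
        recs = derive_by_stratum(base, cur, 90, group_by={"sex"},
                                 baseline_mode="explicit", explicit_size=750)
        assert all(r.baseline.group_size == 750 for r in recs)

    def test_failed_stratum_warns_without_aborting_others(self, two_sex_tables):
        base, cur = two_sex_tables
        with pytest.warns(UserWarning, match="male"):
            recs = derive_by_stratum(
                base, cur, 90, group_by={"sex"},
                baseline_mode="explicit", explicit_size=3000,
            )
        assert [r.stratum.sex for r in recs] == ["female"]

    def test_randomized_feasibility_invariants(self):
        """achieved >= B always; tail at t*+1 < B unless top-coded; monotone in B."""
        rng = np.random.default_rng(42)
        stratum = StratumKey(state="US", sex="male")
        for _ in range(50):
            counts = {age: int(c) for age, c in
                      zip(range(85, 95), rng.integers(0, 500, size=10))}
            open_age = 95
            counts[open_age] = int(rng.integers(0, 300))
            table = CensusTable(make_cells(counts, open_age=open_age))
            total = sum(counts.values())
            prev_age = None
            for b in sorted(rng.integers(0, max(total, 1), size=5)):
                baseline = BaselineSpec(1990, 90, stratum, int(b))
                try:
                    rec = derive_threshold(table, baseline, stratum)
                except NoAdmissibleThresholdError:
                    continue
                assert rec.achieved_group_size >= b
                if not rec.capped_by_top_code:
                    nxt = tail_count(table, rec.recommended_age + 1, stratum)
                    assert nxt < b
                if prev_age is not None:  # larger B can only lower t*
                    assert rec.recommended_age <= prev_age
                prev_age = rec.recommended_age


class TestMinGroupSize:
    @pytest.mark.parametrize(
        "count, minimum, admissible",
        [(20001, 20000, True), (20000, 20000, False), (0, 0, False)],
    )
    def test_strictly_greater_than(self, count, minimum, admissible):
        assert check_min_group_size(count, minimum) is admissible

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            check_min_group_size(-1, 0)


class TestLongitudinalInference:
    def test_capped_record_yields_true_age(self):
        # 89 five years before a capped "90" record means the person is 94
        assert infer_longitudinal_age(89, 5, 90) == 94

    def test_no_elapsed_time_is_identity(self):
        assert infer_longitudinal_age(42, 0, 90) == 42

    def test_earlier_record_at_cap_is_not_applicable(self):
        with pytest.raises(InferenceNotApplicableError):
            infer_longitudinal_age(90, 5, 90)

    def test_negative_elapsed_rejected(self):
        with pytest.raises(ValueError):
            infer_longitudinal_age(80, -1, 90)
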