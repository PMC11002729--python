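# agethresh

Tools for re-deriving the **maximum-age generalization threshold** used
when deidentifying health data — the familiar "constrain all ages above
90 to 90" rule — from census-style population counts.

## The problem

Under a group-size (k-anonymity) view of reidentification risk, the risk
contributed by an age value is governed by how many people share it.  A
"90 or older" top-code was calibrated against the population of a
particular era; as the population ages, the group of people aged 90+
grows, and the same cap becomes more conservative than it needs to be.
`agethresh` implements the recipe for updating the cap: take the size of
the original ">= t0" group at the time the cap was adopted as a baseline
equivalence-class size *B*, then find, in a newer census, the highest age
whose at-or-above-age ("tail") count still reaches *B*:

```
t* = max { t : N_current(age >= t) >= B },   B = N_baseline(age >= t0)
```

Because tail counts step downward in age, `t*` is unique, and a
"`t*` or older" group in the new census is at least as large — hence at
least as anonymous — as the "`t0` or older" group was originally.  The
derivation can be stratified by sex and state, held to the scarcest
stratum's baseline (so a cap safe for the rarer sex is safe for both),
and run on differentially-private counts after a conservative
lower-bound adjustment.

The package is aimed at privacy engineers, statisticians doing
statistical disclosure control, and epidemiologists who need defensible
age-binning rules for data on the oldest old.

## What is in the box

- `agethresh.census` — the census count table (one non-negative integer
  count per year x state x sex x age-bin cell, modeled on decennial
  single-year-of-age tabulations), CSV read/write, validation,
  aggregation across dimensions, and exact tail counts.  Queries that
  fall inside an age bin are an error, never an interpolation.
- `agethresh.thresholds` — baseline group sizes, threshold derivation
  (overall and per stratum, with per-stratum / shared-minimum / explicit
  baselines), the strict "population greater than the floor" group-size
  check used for geographic units, and the longitudinal deduction that
  defeats an age cap when a linked earlier record shows an uncensored age.
- `agethresh.dp` — conservative adjustment of noisy published counts:
  each count is replaced by the lower end of a one-sided confidence
  interval under a Gaussian or Laplace additive-noise model.
- `agethresh.synthetic` — a Gompertz-survivorship population generator
  producing microdata (age, sex, state) and census-shaped tables with
  monotone old-age decline, female longevity advantage, state allocation,
  a top-coded terminal bin, and decade-over-decade growth.  The raw
  records double as a brute-force oracle for every tail count.
- `agethresh.trends` — percent changes, per-1000 old-age rates, state
  extrema, and flat `state,value` exports ready for choropleth mapping.

## Worked example

Generate a synthetic three-decade census series (500,000 people in the
first decade, default demographic parameters), then derive the updated
cap for the third decade against the first decade's 90+ group:

```python
import agethresh as at

params = at.SyntheticCensusParams(total_population=500_000, seed=42)
series = at.generate_census_series(params, [1990, 2000, 2010])

national = at.StratumKey()                      # all states, both sexes
for table in series:
    print(table.year, at.tail_count(table, 90, national))

baseline = at.baseline_group_size(series[0], 90, national)
rec = at.derive_threshold(series[-1], baseline, national)
print("B =", baseline.group_size, "-> t* =", rec.recommended_age,
      "achieved =", rec.achieved_group_size)

for r in at.derive_by_stratum(series[0], series[-1], 90,
                              group_by={"sex"}, baseline_mode="min_stratum"):
    print(r.stratum.sex, "t* =", r.recommended_age)
```

prints

```
1990 7101
2000 9444
2010 12821
B = 7101 -> t* = 93 achieved = 7343
female t* = 96
male t* = 93
```

Read: the synthetic 90+ population grew from 7,101 to 12,821 (+80.6%)
over two decades, so a cap of 93 in the third decade leaves a group of
7,343 people — still larger than the 7,101 that the cap of 90 protected
in the first decade.  Held to the scarcer (male) baseline of 2,454,
women can be capped at 96 and men at 93, reflecting the female
longevity advantage built into the generator.

The same workflow is available from the shell:

```
agethresh synth --pop 500000 --seed 42 --years 1990,2000,2010 --out-dir synth/
agethresh derive --baseline synth/1990.csv --current synth/2010.csv \
    --baseline-age 90 --by sex --baseline-mode min_stratum --out recs.csv
agethresh trends --old synth/1990.csv --new synth/2010.csv \
    --min-age 90 --by state --out trends.csv --choropleth percent_change=pc.csv
```

Real census extracts can be used instead of synthetic ones once
converted to the CSV dialect
`year,state,sex,age_lo,age_hi,count` (empty `age_hi` marks the
open-ended top-coded bin; one census year per file).

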