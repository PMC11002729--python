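# Methods

## The threshold recipe

The package treats an age top-code as a group-size guarantee.  Let
`N_y(>= t | s)` be the number of people aged `t` or older in census year
`y` within stratum `s` (a state, a sex, or any aggregate of them).  The
original cap `t0` (90 in the Safe Harbor rule) implicitly accepted the
group size

```
B = N_baseline(>= t0 | s)
```

as sufficiently anonymous.  The updated cap is the largest age whose
current tail count still reaches that size:

```
t* = max { t in [age_floor, age_ceiling] : N_current(>= t | s) >= B }.
```

Tail counts are a non-increasing step function of `t`, so `t*` exists
whenever the floor is admissible and is unique; no tie-breaking is
needed.  The search scans aligned ages downward from the ceiling.  Two
flags qualify the result:

- `capped_by_top_code` — `t*` equals the lower bound of the table's
  open-ended bin.  The data cannot resolve ages above this point, so the
  truly admissible cap may be higher; the recommendation is a lower bound.
- `decreased_below_baseline_age` — `t* < t0`.  A shrinking population can
  legitimately push the cap down; such results are returned and flagged
  rather than suppressed, because adopting them would force data sources
  to re-bin rather than merely relax.

Defaults: `age_floor = 0` and `age_ceiling` = the open bin's lower bound
(or the highest closed bin when no open bin exists).  The search range is
a deliberate design choice — nothing in the recipe itself restricts it.

### Stratified derivation

`derive_by_stratum` derives one recommendation per value combination of
the grouped dimensions (sex, state), with three baseline policies:

- `per_stratum`: each stratum is held to its own historical tail count —
  the natural choice when strata are reported separately;
- `min_stratum`: all strata are held to the *smallest* historical tail
  count among them.  The rationale: if the scarcer group's size was
  evidently acceptable at adoption time, that size is an acceptable floor
  for every group.  Applied to sexes, the (smaller) male 90+ baseline
  yields a higher admissible cap for women, who survive to higher ages in
  greater numbers;
- `explicit`: a user-supplied `B`, for policy counterfactuals.

A stratum whose derivation fails (e.g. its floor tail count never
reaches `B`) is reported as a warning and omitted so the remaining
strata still derive; `strict=True` converts the warning into an
exception.

### Tail counts, alignment, and the no-proration rule

A tail count sums every bin lying entirely at or above the query age; an
open-ended bin with `lower >= t` contributes fully.  A query strictly
inside a bin raises an error.  Prorating (e.g. assuming uniform ages
within a bin) would fabricate equivalence-class sizes in exactly the
place where the analysis needs them to be conservative, and boundary
queries are the only ones the recipe requires.  The same logic makes
cross-stratum aggregation refuse to merge strata whose binning schemes
conflict (one top-coded at 90, another at 100): the conflicting bins
would overlap, and the error names the offending strata.

### Ancillary checks

- `check_min_group_size(count, minimum)` is the generic admissibility
  test for geographic units, strict by construction (`count > minimum`):
  a population exactly at the floor is not admissible, mirroring the
  "greater than 20,000" phrasing of the zip-area rule.
- `infer_longitudinal_age(earlier_age, years_elapsed, cap)` formalizes a
  known failure mode of age caps in linked longitudinal data: a record
  of an uncensored age `a < cap` taken `k` years before a capped record
  reveals the person's true age `a + k` (89 recorded five years before a
  capped "90" means 94).  If the earlier record is itself at or above
  the cap nothing can be deduced, and the function refuses.

## Noisy (differentially-private) counts

Privacy-protected census releases publish noisy counts.  Using a noisy
count as an equivalence-class size risks overstating the protection, so
before derivation every cell count is replaced by the lower end of a
one-sided confidence interval at level `c` (default 0.99) under an
additive-noise model with known scale:

```
gaussian:  adjusted = floor(reported - z_c * sigma)
laplace:   adjusted = floor(reported - b * ln(1 / (2 (1 - c))))
```

clamped at zero.  Three conservative choices are deliberate: flooring
rather than rounding, clamping at zero, and adjusting *per cell before
summing* tails (a sum of per-cell lower bounds is smaller than a lower
bound on the sum).  The additive-noise model with independent per-cell
draws is the simplest framework consistent with a one-line "use the
lower end of a one-sided 99% CI" prescription; it is a stand-in, not a
description of any production disclosure-avoidance system, whose noise
structure (hierarchical post-processing, non-negativity constraints) is
more complex.

## The synthetic census generator

`generate_microdata` draws individuals (age, sex, state) so that every
pipeline stage can be exercised, and audited against a brute-force scan
of the individuals, without any external data.  Ages follow a
distribution proportional to Gompertz survivorship on the integer grid
`0..max_age`:

```
S_s(a) = exp(-(a_s / b) * (e^(b a) - 1))
a_s = gompertz_a            (males)
a_s = gompertz_a * m_f      (females, m_f = female_hazard_multiplier)
```

This is a stationary population with constant birth inflow — the single
simplest mortality law that reproduces the two structural facts the
analysis rests on: counts thin out monotonically at advanced ages, and a
female hazard multiplier below 1 makes the female tail probability
dominate the male one at every age.

Parameters, units, defaults, and why:

| parameter | default | meaning |
|---|---|---|
| `gompertz_a` | 5e-5 /yr | baseline hazard; sets overall longevity scale |
| `gompertz_b` | 0.09 /yr | hazard doubling rate ~ every 7.7 yr, the classic adult value |
| `female_hazard_multiplier` | 0.75 | female mortality advantage |
| `sex_fraction_female` | 0.5 | draw probability of "female" |
| `state_weights` | stylized ~1990 shares | allocation over 50 states + DC |
| `top_code_age` | 100 yr | open-ended bin starts here when tabulating |
| `max_age` | 110 yr | support of the age distribution |
| `decadal_longevity_improvement` | 0.1 /decade | multiplies `gompertz_a` by 0.9 per decade |
| `decadal_growth` | 0.1 /decade | total-population growth per decade |
| `seed` | 0 | every output is a pure function of params incl. seed |

The state weights are fixed, coarse population shares (CA ~ 12%, WY ~
0.2%, ...); they give state-level computations realistic size disparity
but carry no per-state age structure — every state draws from the same
age distribution.  `generate_census_series` scales population by
`(1+growth)^k` and hazard by `(1-improvement)^k` for decade `k`, each
year drawing from an independent child stream of the seed.

`add_dp_noise` perturbs each cell with independent Gaussian or Laplace
noise, rounds, and clamps at zero (published tables are non-negative).
Note the asymmetry with the adjustment side, which floors; clamping the
generator and flooring the adjuster are each the conservative choice for
their own direction.

### What passing tests do and do not show

The generator reproduces monotone old-age decline, the sex differential,
state allocation, top-coding, and decadal growth — the features the
pipeline's correctness depends on.  It deliberately omits cohort effects
(e.g. post-war birth spikes), migration, period shocks, state-specific
age structure, and age heaping/misreporting among the very old.  Tests
passing on synthetic data therefore certify the *computational* recipe
(tail counts, threshold search, adjustment arithmetic) exactly — the
brute-force oracle comparison is bit-exact — but say nothing about
whether real census counts satisfy the demographic assumptions; applying
the package to real extracts is a data question, not a code question.

## Numerical and presentation choices

- Counts are integers end to end; fractional counts are rejected at
  parse time, and no operation introduces fractions.
- Reported reals (percent changes, per-1000 rates) are rounded half-up
  to one decimal via `decimal.Decimal`, matching the precision at which
  such figures are conventionally quoted.  Note that a percent change
  computed from two already-rounded counts can differ from one computed
  on unrounded sums (1.02M -> 1.87M gives 83.3%, while the unrounded
  counts behind those figures round to "about 84%"); the package always
  computes from the counts it is given and rounds last.
- Trend extrema break ties by ascending state code, then sex; rows are
  emitted in that order so outputs are byte-reproducible.
- Degenerate inputs: empty tables have tail count 0 everywhere; a
  baseline of 0 makes every age admissible and returns the ceiling
  (flagged as top-coded when the ceiling is the open bin); percent
  change and per-capita rates refuse a zero denominator.

## Problem sizes

The test suite and the acceptance script size their simulations to be
exact where exactness is claimed and statistically comfortable where
sampling is involved: 100 microdata sets up to 1e5 records for the
oracle comparison (exact equality), 1e6 records for distributional
checks against analytic tail probabilities (3-standard-error bands),
1000 noisy cells for the 99%-confidence coverage experiment (pass floor
97%), and a 1e6-person first decade for the acceptance series.  These
sizes are the package's own defaults for a desk-scale run; all of them
are parameters, not limits.

## Known limitations

- State-level thresholds are derived only from actual per-state
  single-year counts; no cross-state extrapolation of age-decline shape
  is attempted, so a state whose table top-codes early yields a capped
  (lower-bound) recommendation instead.
- Only state, sex, and age are modeled as quasi-identifiers; joint
  derivation with race, ethnicity, or sub-state geography is out of
  scope, as is any legal determination of regulatory compliance.
- The DP adjustment treats per-cell noise as independent with known
  scale; real disclosure-avoidance pipelines violate both assumptions in
  ways that can only make the bound approximate.
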