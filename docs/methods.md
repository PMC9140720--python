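# Methods

## The two estimators

### Index of concentration at the extremes (ICE)

For a group x (a sociodemographic stratum, a district, or a region,
optionally within one survey wave), ICE = (H − L)/T where H and L are
the survey-weighted counts of obese (BMI ≥ 30 kg/m²) and underweight
(BMI < 18.5) members and T the weighted group total. Values lie in
[−1, 1] by construction; normal and overweight members enter T only, so
moving mass between the normal and overweight categories never changes
ICE. The high extreme is *obese only*; pooling overweight into H is
available as a sensitivity option (`include_overweight_high`) and off by
default, because overweight is not an extreme of the distribution in
the sense the index is meant to capture. ICE is reported as a point
value; an optional percentile bootstrap over survey clusters
(`ice.bootstrap_ci`) quantifies sampling noise for users who need it.

### Brass children-ever-born / children-dead estimation

Per maternal five-year age group i = 1…7 (15–19 … 45–49) the method
needs only W_i (women), B_i (children ever born to them) and D_i
(children dead), all weighted by default. From d_i = D_i/B_i and mean
parities P_i = B_i/W_i, Trussell's West-family regression gives
multipliers k_i = a_i + b_i·(P1/P2) + c_i·(P2/P3), and q(x) = k_i·d_i
estimates the probability a child dies by exact age x, with the
standard correspondence 15–19→q(1), 20–24→q(2), 25–29→q(3), 30–34→q(5),
35–39→q(10), 40–44→q(15), 45–49→q(20). Survival l(x) = 1 − q(x) is an
exact identity throughout. Assumptions inherited from the method:
fertility and child mortality roughly constant in the recent past, child
mortality independent of mother's age apart from the modelled pattern,
and reporting of dead children complete. The q(1) estimate from mothers
15–19 is computed (reporting surfaces print it) but flagged
`unreliable`: women bearing children that young are a selected
higher-risk group.

The (a, b, c) coefficients are packaged published constants
(`reference/trussell_west_coefficients.csv`, SHA-256 checksummed) and
are validated in the test suite against the Panama 1976 worked example,
recomputed independently by hand arithmetic and frozen in
`tests/helpers.py`.

### Mortality levels

Each l(x) is mapped to a *level*: the index of the model survival
schedule whose tabulated l(x) matches it, linearly interpolated between
the bracketing integer levels a and a+1,

    level = a + (l(x) − l(x)_a) / (l(x)_{a+1} − l(x)_a),

clamped to [1, 24] with a flag when outside. Higher level = higher
survival, so a *falling* level means *rising* mortality; the package
asserts this orientation in its tests rather than leaving it to
convention. An l(x) exactly equal to a tabulated node returns the
integer level; `level_to_lx` is the exact inverse on the tabulated
range.

**Comparability caveat.** The packaged l(x)-by-level table
(`reference/west_lx_levels_synthetic.csv`) is a *synthetic* West-style
family, generated by `lifetables.build_synthetic_west_lx()`: q(5) is
piecewise log-linear in level through the anchors (1, 0.45), (13, 0.17),
(24, 0.005) for the female schedule, the within-level age pattern uses
cumulative-hazard ratios (x/5)^0.55 below age five and (x/5)^0.30 above
(child mortality front-loaded, slow accumulation after five), and the
both-sexes schedule carries a 7.5% hazard excess over female-only
(male excess child mortality). This reproduces every structural property
the estimator relies on — strict monotonicity in child age and in level,
24 levels, female/both-sexes variants — and demographically plausible
magnitudes, but its level numbers are **not digit-for-digit comparable
with published West model levels**. All internal analyses are
consistent because the same table is used for data generation and for
estimation; absolute level numbers should be read as positions on this
package's scale.

## Survey harmonization

Fixed per-wave order: read → GPS join → impute → derive → exclude
pregnant; waves are merged afterwards and the row count after every
stage is logged (the selection flowchart as data). Imputation precedes
the pregnancy exclusion so a missing pregnancy flag is resolved by the
imputation model instead of being silently treated as "not pregnant".
Rows with age outside 15–49 or with children dead exceeding children
ever born are rejected with a warning, never silently fixed; women with
zero children ever born are retained (they contribute to W_i and hence
to parities). CSV dialects handle DHS storage conventions (BMI ×100,
weight ×1,000,000, coded categories); district labels are free strings
checked against a packaged 28-district list for warnings only.

### CART chained imputation

Single imputation: variables are visited in increasing order of
missingness over 3 sweeps; each is filled by fitting a decision tree
(classifier for categorical, regressor for numeric, minimum leaf size 5)
on the other predictors, then drawing each missing cell uniformly
(seeded) from the observed *donor* values in its leaf. Donor sampling
guarantees imputed values stay inside the observed support and
preserves within-leaf variability; observed values are never altered.
No between-imputation variance is produced — the downstream surfaces are
point estimates. Missing cells are initialized by marginal draws so the
chained trees always see complete predictors.

### Between-wave variation tests

Numeric indicators: one-way ANOVA on wave means (two waves reduce to a
t test with F = t²). Categorical indicators: Pearson chi-square of
homogeneity. A t test is not well defined for a multi-level categorical
block, so the chi-square is used there deliberately even where a
reporting convention might label everything "t test". With weights, both
tests run on weighted proportions/moments scaled to Kish effective
sample sizes n_eff = (Σw)²/Σw² — an approximation to a design-based
test that is exact for unit weights and adequate when the only design
feature carried by the data is an individual relative weight.

Descriptive counts are reported unweighted (sample composition; they sum
to the wave size) with weighted percents by flag; percentages are
computed before rounding, and presentation rounding is half away from
zero to one decimal.

## Synthetic data generator

The generator emulates a four-wave DHS-like female survey: unequal wave
sizes (defaults 11,663 / 10,249 / 20,858 / 22,729), ages uniform on
15–49, clusters nested in the 28 Malawi districts with cluster-level
urban/rural status, education and wealth marginals shifting across
waves, ~7% pregnancy, and lognormal(0, 0.3) weights normalized to mean
one per wave. BMI is truncated-normal (clipped to [12, 60], sd default
3.2 kg/m²) with additive mean effects for wave, urban residence, wealth
quintile, education, age band and region. Parity is Poisson with the
age-group mean from a non-decreasing fertility schedule (default 0.3 …
6.5), truncated at 17; children dead are Binomial(parity, q_true) where
q_true comes from the packaged life table at the configured
`true_mortality_level` (with optional per-BMI-category relative risks,
all 1.0 by default), and the generator exposes those exact
probabilities via `ground_truth()` so recovery tests compare against
recorded truth, not re-derived values.

What it does **not** emulate, and what passing tests therefore cannot
show about real data: multistage selection probabilities and design
effects (weights are pure noise), birth timing within mothers'
reproductive spans (children dead are binomial thinnings, so the
multipliers' timing correction is exercised only through parity ratios),
missing-not-at-random mechanisms (injection is MCAR), and the
right-skew of real BMI distributions — a truncated normal cannot carry
7% mass in both tails at realistic means, so tail shares are a
compromise rather than a match to any published prevalence.

## Numerical and design choices

- Weighted aggregation everywhere by default; unit weights reproduce
  unweighted results exactly (tested).
- q(x) = k_i·d_i is clamped into [0, 1] with a `clamped` flag rather
  than erroring; undefined cells (B_i = 0, or a stratum missing women
  20–24/25–29 so a parity ratio is undefined) yield flagged blank
  cells, not failures.
- Degenerate ICE groups (T = 0) are omitted with a warning; T = 0 passed
  to the scalar `ice()` raises.
- The BMI grid pools overweight with obese into one stratum, matching
  the conventional reporting layout; the `total` column is the chain on
  the unstratified table (tested as an invariance).
- Both-sexes life-table schedule is the default (children dead pool sons
  and daughters); female-only is a flag.
- Reference-period (time-location) estimation for the indirect method is
  out of scope.
- Reproducibility: every stochastic step flows from explicit seeds
  (NumPy `default_rng` with structured seed sequences); identical
  config + seed reproduces tables and output bundles byte for byte
  (tested).

## Problem sizes

The test suite runs at desk scale: shared fixtures use two waves of
1,200–1,500 women; gradient and recovery checks use single waves of
30,000–50,000 (level recovery: 10 seeds × 50,000 women at level 14,
asserting the mean level over mothers 20–44 within ±0.5); imputation
fidelity uses 20 seeds × 2,500 women at 10% MCAR (marginals within 5
percentage points); null calibration uses 100 replicates of two
250-woman waves (KS uniformity of p-values). The acceptance script runs
one full pipeline at the default study-scale wave sizes (~65k women).
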