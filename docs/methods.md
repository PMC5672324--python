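# Methods

## Model

The maintenance energy requirement (MER, kcal/d) of an adult dog at stable
ideal weight is modelled as a power law in body weight `BW` (kg) and age
(years) with multiplicative categorical corrections:

```
MER = ∏ k_i · a · BW^b · age^c
```

Fitting is ordinary least squares on the natural-log scale,

```
ln MER = ln a + b ln BW + c ln age + ε,   ε ~ N(0, σ²),
```

which makes the power law linear, the noise additive, and the implied
measurement error multiplicative (a fixed *percentage* of intake — the
natural error model for ration-based intake records). All r² values,
standard errors and residual spreads are reported on this log scale, the
scale the model is estimated on. Reported constants are rounded only at
the reporting layer (a to an integer, b and c to 3 decimals); internal
values keep full precision.

Assumptions worth stating: records are independent across dogs (one record
per dog, no litter or household clustering); the exponents b and c are
common to all dogs, with categorical heterogeneity acting only on the
constant; and interactions between correction factors are not modelled —
the factors multiply independently, which is exact in the synthetic data
and an approximation on real data.

## Normalized MER and the factor screen

Dividing the systematic part out, `MER / (BW^b · age^c)` is a mass- and
age-adjusted requirement (kcal·kg^-b·y^-c/d) comparable across dogs. Seven
categorical factors are screened on this quantity: ownership, breed group,
sex x neuter status, bedding location, temperament, diet type and meal
frequency. Records whose level for a factor is unrecorded are dropped from
that factor's analysis only, so per-factor sample sizes differ.

Because the adjusted requirement is strongly right-skewed with very
unequal group sizes, screening is rank-based: a Kruskal–Wallis H test
(tie-corrected, chi-square reference) across the factor's levels, followed
— only when the global test is significant at `alpha` (default 0.05) — by
two-sided Mann–Whitney rank-sum tests for every level pair (exact null
distribution for untied samples of combined size ≤ 20, otherwise the
normal approximation with tie and continuity correction). The group
comparisons are between independent samples, which is why the unpaired
rank-sum test is used rather than a paired signed-rank test; a
`pairwise` battery on all level pairs also feeds the compact-letter
display in reports.

A level receives a correction factor

```
k(level) = mean adjusted MER of the level / mean of the reference
```

rounded to 2 decimals, iff its rank-sum comparison against the reference
population is significant; otherwise k = 1. Two reference conventions are
implemented:

- **`level`** (default): each factor has a designated baseline level —
  `other` breeds, intact females, inside sleepers, normal temperament, dry
  diet — and every level is compared against it. This matches how the
  deployed corrections are defined (spayed vs intact females, outside vs
  inside), keeps the baseline at exactly k = 1, and prevents a strong
  level from leaking into every other level's reference.
- **`complement`**: a level is compared against all other analysed
  records. Symmetric and baseline-free, but with a large planted effect
  (e.g. 26 % of the cohort at k = 0.85) every *other* level's complement
  is shifted, so spurious non-unit k values appear at large n. Kept as a
  configurable option.

Five factors may deploy corrections (k1 breed group, k2 sex x neuter,
k3 bedding, k4 temperament, k5 diet type). Ownership and meal frequency
are screened for completeness but never contribute a deployed k; diet
type's only suggestive contrast (commercial + leftovers, n ≈ 15 in a
319-dog cohort) is too thin to act on, so the shipped k5 table is empty.
No multiple-testing adjustment is applied by default, matching the raw
per-test thresholds the screening design uses; with five gated factors
this bounds the probability of an all-identity k table under the null at
0.95^5 ≈ 0.77, which the null-simulation test checks against.

After the screen, the base constants are refit on the factor-adjusted
response `MER / ∏k`. With correct tables this removes categorical variance
from the residual, so the refitted r² exceeds the unadjusted fit's; the
end-to-end estimator `CompositeMERRegressor` wires these stages together.

## Eligibility cascade

A record is retained iff: healthy; age ≥ 1 y; weight variation ≤ 5 % over
the observation window; body condition score 4 or 5 (the ideal band on the
9-point scale); actual weight equal to ideal weight within a relative
tolerance of 0.5 % (configurable — "at ideal weight" needs a numeric
meaning for real-valued weights); forced work ≤ 1 h/d; not housed in a
cage or kennel; observed intake present. Every violated rule is recorded,
not just the first, and the kennel flag travels beside the cohort (no
retained dog has it, so it is not a record field). Missing eligibility
fields are never imputed; an absent intake is the `invalid_data` rule.

## Energy content of foods

Metabolisable energy is computed from proximate analysis with fixed
factors per gram of protein, fat and nitrogen-free extract (NFE =
100 − protein − fat − fibre − ash − moisture, all per 100 g as-fed):
3.5/8.5/3.5 kcal/g (modified Atwater) for complete commercial feeds and
4/9/4 kcal/g (Atwater) for homemade foods and table leftovers, with crude
fibre contributing no energy in either system. The factor sets are a
config mapping (`ME_FACTORS`) and can be overridden per call. Daily intake
is the ration's grams-weighted sum; a directly recorded intake always
beats a ration-derived one (with a logged warning).

## Synthetic-cohort generator

The generator emulates the reference study population so the pipeline is
verifiable by parameter recovery:

- **Body weight**: lognormal truncated to [1.1, 80.0] kg by resampling.
  The parent (μ, σ) are chosen so the *post-truncation* mean and sd equal
  the targets (23.18, 13.55 kg), solving the closed-form truncated-moment
  equations by root finding. Matching the parent's moments instead would
  leave the truncated draw ~0.4 kg light in the mean and ~1.1 kg in the
  sd, because a lognormal's upper tail carries much of its variance — the
  printed statistics describe the bounded sample, so the bounded
  distribution is what gets matched.
- **Age**: `1 + Gamma`, moment-matched to mean 4.91 and sd 3.49 y, so
  every dog is an adult by construction.
- **Categories**: drawn independently of BW, age and each other, with
  probabilities proportional to the reference counts (sex 171 M : 148 F;
  neuter probability 0.243 for males and 0.554 for females; bedding
  192 : 42 : 85 inside/outside/unrecorded; temperament 138 : 112 : 58 : 11
  normal/active/calm/unrecorded; ownership, diet and meal-frequency tables
  likewise). Breed names are drawn within the breed group, including a
  German shepherd in the "other" group as a deliberate near-miss for the
  breed matcher.
- **Response**: `MER = a · BW^b · age^c · ∏k · exp(ε)` with truth
  a = 128, b = 0.730, c = −0.050, the reference k tables (0.88, 1.09,
  0.85, 1.05, 1.05) and ε ~ N(0, σ_log²).

σ_log is calibrated, not assumed: no residual-spread statistic is
available for the reference fit, so `calibrate_sigma` chooses σ to make
the *two-predictor* fit's r² hit its target (0.816). A Monte-Carlo draw
(n = 2×10⁵) from the configured marginals estimates the explained variance
`Var[b ln BW + c ln age]` and the planted-factor variance `Var[ln ∏k]`;
since the unadjusted fit leaves the factor heterogeneity in its residual,

```
σ² = Var_signal · (1 − r²)/r² − Var_k ,
```

floored at zero. The frozen default is σ_log = 0.1796. Under it, the
factor-adjusted refit's r² lands near 0.85, a few points above the
unadjusted 0.816, mirroring the qualitative gap between the plain and
composite reference fits.

What the generator does **not** emulate: correlations between attributes
and body size (a hook exists for breed-BW coupling but is off — no joint
structure is documented for the reference population), within-household
clustering, seasonal/temperature effects, intake measurement rounding,
and breed-level (ungrouped) requirement differences. Passing recovery
tests therefore demonstrate the estimators are correct under the stated
sampling model, not that the reference constants are externally valid.

**Raw-database mode** starts from `n_total` compliant records (default
579) and mutates a uniformly chosen subset of exactly `n_violations`
(default 260) so each violates one (80 %) or two (20 %) eligibility rules,
drawn from a fixed mix across the eight rule codes; the planted truth is
returned so the filter can be validated record-for-record. Retention of
exactly 319 is by construction, for every seed.

## Projections

- **Metabolic age** `age^c`: 0.9227 at 5 y, 0.8913 at 10 y with
  c = −0.050.
- **Weight-gain projection**: feeding an older dog its one-year-old
  ration leaves a daily surplus `predict(BW, 1) − predict(BW, age)`;
  over a year, at an adipose-tissue energy density of 7.7 kcal/g
  (configurable; the conventional value for adipose tissue with its
  associated lean gain), a 30 kg dog at 5 y projects to ≈ 5.6 kg/year.
  At 10 y the same constants give ≈ 7.9 kg/year; quoted figures for that
  scenario of 7.7 kg/year imply a slightly different conversion constant,
  and the implementation keeps one density rather than tuning to both.

## Numerical conventions and sizes

- Presets: `base` (a = 128, b = 0.730, c = −0.050) for BW/age-only
  prediction; `composite` (a = 128, b = 0.740, c = −0.050) whenever the
  k tables are applied. Model selection between the BW-only and BW+age
  fits is by r², ties to the simpler model.
- Degenerate designs (constant ln BW, collinear ln BW/ln age) raise a
  singular-fit error rather than returning a pseudo-inverse fit. All
  physical inputs must be strictly positive.
- Identical-value degenerate cases in the rank tests return H = 0, p = 1
  (no evidence) rather than erroring.
- Simulation sizes in the test suite — 5000-dog cohorts for recovery,
  300 replicates at n = 319 for bias/SE agreement, 30-seed ladders, 1000
  null replicates for test size — were chosen so each check's sampling
  error is several times smaller than the tolerance it enforces.
- Seeds: every stochastic routine takes an explicit seed
  (`numpy.random.default_rng`); the same seed reproduces a cohort
  bit-for-bit. Checks that pin no seed use the generator default (0);
  cohort-specific checks use their conventional seeds (1, 2, 7).

## Known limitations

- Correction factors are point estimates without uncertainty; a bootstrap
  would be the natural extension.
- The `level` reference convention needs a designated baseline per
  factor; for factors without a natural baseline the complement convention
  is the fallback.
- The composite model multiplies k's estimated marginally; joint effects
  (e.g. an active shepherd sleeping outside) extrapolate beyond what any
  single screen estimated.
- The exclusion tolerance for "at ideal weight" (0.5 % relative) is a
  modelling choice; real datasets recording ideal weight at coarser
  precision may need it widened.
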