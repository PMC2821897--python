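# Methods

## The question the model answers

US health spending buys services of wildly uneven value. If patient cost
sharing were tied to each service's value — no copay for highly
cost-effective care, higher copays for care that buys little health per
dollar (value-based insurance design, VBID) — how much health could the
system gain, and at what cost? Because no registry of service-level
cost-effectiveness exists, the model represents the *population* of health
services statistically and simulates individual people buying allotments of
care from it over a lifetime.

## Model structure

### Spending-weighted ICER distribution

Each dollar of expenditure draws an incremental cost-effectiveness ratio
(ICER, $/life-year) from a spending-weighted distribution: in the base case,
log10(ICER) ~ Normal(log10 m, σ²) with σ = 0.8 log10 units. The
spending-weighting matters: tier probabilities are then directly shares of
*expenditure*, which is what the value-tier inferences are about. Services
are tiered as

* **high value**: ICER ≤ $100,000/LY (copay dropped to zero under VBID),
* **low value**: ICER > $300,000/LY (copay raised under the cost-offset
  strategies),
* **intermediate**: in between, or value not estimable from evidence
  (cost sharing unchanged).

A dollar with ICER X buys 1/X life-years, so all tier-level benefit rates
reduce to truncated expectations of 1/X, available in closed form for the
lognormal: E[X⁻¹·1{X<a}] = e^(−μ+σ²/2)·Φ((ln a − μ + σ²)/σ) (natural-log
units). A uniform-in-log10 family with the same SD (half-width √3·σ) is
available as a shape sensitivity.

Two optional fractions modify the distribution:

* `estimable_fraction` ρ: only ρ of spending has estimable value; the rest
  is assigned to the intermediate tier (prevailing copay) while keeping its
  true ICER for benefit accounting. Lowering ρ therefore shrinks the
  tiers VBID can act on without changing baseline benefit.
* `ineffective_fraction` f: f of spending buys nothing. The zero-benefit
  dollars are taken from the top of the ICER distribution — they fill the
  low-value tier first — on the argument that spending already known to be
  poor value is where ineffectiveness plausibly lives. This choice makes
  the ineffective variant nearly neutral for the VBID deltas (the affected
  dollars were already copay-penalized), and it degenerates correctly to
  "no benefit anywhere" at f = 1.

### Cohort

One million simulated persons (configurable) live out a period life table
(Makeham hazard, e0 = 77.23 years; the table only sets the spending
horizon). Each year of life a person buys an age-profiled allotment of
care: an 8-band profile rising ≈6-fold from childhood to 85+, normalized so
the survivorship-weighted mean is exactly $5,688 per person-year — the
national per-capita anchor. The ratio of the printed national total
($1,654 B) to the per-capita figure fixes the implied population
(≈290.8 M) used to scale per-capita results to national dollars.

15% of persons are uninsured. They follow the same expenditure profile but
convert spending to health at a reduced benefit ratio — one knob, solved
against one anchor (below). Allotments are cut into $500 parcels; each
parcel draws its own ICER. Life-years purchased are added to the life-table
lifespan afterwards and do not generate further spending years; letting
them feed back would break the $5,688 anchor the calibration enforces.

### Demand

Demand responds to the coinsurance rate with a uniform elasticity
ε = −0.31. The default functional form is semi-elastic — quantity
multiplier 1 + ε·(c_new − c_old), linear in coinsurance *points* — because
it is the only simple form consistent with the calibrated dollar anchors:
an arc-type form responds to the relative price change and implies a
fixed ≈1.9× jump whenever a copay is removed entirely, regardless of how
small the copay was. The arc form is retained as an option. Multipliers
are clamped at zero. An `inelastic_spending_fraction` (e.g. the 31% of
spending on inpatient care) keeps a multiplier of 1 while still facing the
new copay.

### Calibration (three knobs, three anchors)

1. **Median ICER m** — bisected (60 iterations, log scale) so the expected
   no-VBID population gain equals 4.70 life-years. The gain is strictly
   decreasing in m, so bisection is safe. With the e0 = 77.23 life table
   this lands at m ≈ $495,600 and tier shares 19.2% / 20.0% / 60.7%
   (high/intermediate/low) — the ≈20/20/60 value inference is an output of
   the life-expectancy calibration, not an input.
2. **Uninsured benefit ratio r** — set so the uninsured subgroup's expected
   gain is 3.93 life-years (r ≈ 0.813; the insured level is then 4.84).
3. **Baseline coinsurance c0** — solved so that strategy 1 applied to all
   services raises per-capita expenditure by $72/year. That delta is per
   capita over the *whole* population while only the insured 85% respond,
   which yields c0 ≈ 0.25. c0 is calibrated once under base-case
   assumptions and held fixed across sensitivity scenarios.

### Strategies and solvers

* **Strategy 1**: high-tier coinsurance 0; everything else at c0. No
  offset; spending rises.
* **Strategy 2**: additionally raises the low-tier coinsurance until the
  chosen perspective's expenditure — societal (total), payer (plan-paid),
  or patient (out-of-pocket) — returns to its no-VBID level. Solved by
  bisection (80 iterations) on the closed-form expenditure equations to a
  $1-per-capita tolerance; the Monte-Carlo run confirms neutrality within
  sampling error afterwards. The solved copays are ordered
  societal ≤ payer ≤ patient, matching the published ordering (the printed
  percentages themselves depend on unpublished details of the original
  demand specification and are not reproduced).
* **Strategy 3**: strategy 2 (societal) with the uninsured brought onto the
  insured VBID benefit: their benefit ratio rises to 1 and they follow the
  VBID schedule. Under this package's one-knob uninsured design the newly
  insured already consume the insured profile, so coverage adds no net
  spending and the solved copay coincides with strategy 2's; the health
  effect of coverage is the uninsured jumping from 3.93 to the insured VBID
  level (+1.21 LY for that subgroup, +0.20 LY population-wide).
  Under pharmacy-only scope the covered share of the uninsured equals the
  scope fraction: the offset surplus scales with scope, and the all-services
  surplus is what funds full coverage.
* **Scope**: VBID can be restricted to a fraction of spending (pharmacy
  ≈ 0.10, consistent with the published $7/$72 and 0.03/0.26 ratios).
  Parcels enter scope by independent Bernoulli draws, so deltas scale
  linearly with scope.

### Monte-Carlo engine

Vectorized age-by-age: persons are sorted by death year so the alive set at
each age is an array prefix; each (alive × parcels) block draws ICERs,
assigns tiers, applies multipliers, and accumulates benefit, spending and
out-of-pocket amounts per person. ICER draws use a random stream separate
from cohort and auxiliary draws, so scenarios run at the same seed share
parcel-level randomness — scenario deltas are estimated with common random
numbers and are an order of magnitude more precise than the levels. Draws
are generated in float32 (accumulation in float64); a fixed seed gives
bit-identical results. A baseline run at 10⁶ persons takes ~30 s on one
CPU; the across-seed SD of the mean gain at that size is ≈0.0015 LY,
comfortably inside the 0.01-LY reproducibility target, and scales as 1/√n.

### Sensitivity grid

Each row perturbs one assumption, re-solves the median against the 4.70
anchor (the no-VBID column is 4.70 in every row by construction), keeps c0
fixed, and re-runs all strategies:

* Elasticity −0.23 / −0.39; 31% inelastic spending; 50% estimable;
  30% ineffective; σ = 0.3 / 1.3; uniform family; high threshold $50k/LY;
  31% of spending unsuitable for copays.
* **Narrow distribution (σ = 0.3)**: after recalibration only ~8% of
  spending is low-value, and no low-tier copay ≤ 1 can fund the high-tier
  subsidy. The solver raises the documented infeasibility and the grid
  falls back to raising intermediate *and* low copays together, flagging
  the cell. (The source's footnote names "intermediate- and high-value"
  services, which is read as a typo: high-value copays are being
  eliminated by construction.)
* **Copay-unsuitable spending**: unsuitable services carry no copay in any
  arm; suitable services' coinsurance is scaled up (c0/(1−u)) so mean cost
  sharing is unchanged. Unsuitable spending is placed outside the
  high-value tier (inpatient-style care is not where $100k/LY-or-better
  services concentrate), which concentrates cost sharing on the tier VBID
  subsidizes and magnifies the strategy deltas. With tier-independent
  placement the semi-elastic response would cancel exactly and no
  magnification could occur. At large unsuitable fractions the rescaled
  coinsurance would exceed 1 and an infeasibility error is raised.

## Known limitations

* The σ = 1.3 row comes out at strategy-1 Δ ≈ 0.30 rather than the base
  0.27: with a single calibration knob a wider distribution necessarily
  shifts the high-tier benefit kernel. The original analysis reports this
  row unchanged, presumably because its (unpublished) plausibility
  criteria constrain wide distributions further; this package does not
  invent an extra constraint, so the row is reported as computed.
* The fallback (σ = 0.3) strategy-2 deltas are smaller than published
  (≈0.15 vs 0.21), and the copay-unsuitable magnification reaches ≈0.38
  rather than 0.51 — both depend on unpublished details of the original
  demand/cost-sharing specification.
* The synthetic cohort has no morbidity states, no service-level identity,
  no income heterogeneity, no deductible caps, and mortality independent of
  spending (benefit is added post hoc). Passing tests therefore show the
  *model's* inferences are reproducible from its printed anchors — not that
  the anchors themselves generalize to real claims data.
* Life-years are not quality-weighted and nothing is discounted.

## Numerical choices

* Bisection everywhere a root is needed (calibration 60 iterations on the
  log scale; copay solves 80 iterations), with explicit bracket checks that
  raise `CalibrationError` / `InfeasibilityError` rather than returning a
  boundary value.
* Tier boundaries are inclusive on the high side (≤ $100k is high,
  > $300k is low); unknown ICERs are intermediate; non-positive ICERs are
  rejected.
* Parcel remainders below $10⁻⁹ are dropped; per-person totals conserve
  allotments exactly otherwise, and per-capita spending is invariant to the
  parcel size (only the Monte-Carlo error of the benefit estimate depends
  on it).
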