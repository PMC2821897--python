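# vbidsim

Microsimulation of **value-based insurance design (VBID)** in a US-like
health care system: what happens to population health and to health
spending when patient cost sharing is tied to the *value* of each service —
its incremental cost-effectiveness ratio (ICER, dollars per life-year) —
instead of its price?

The package is aimed at health-policy modelers. It treats the US
"population of health services" statistically: every dollar of expenditure
draws an ICER from a spending-weighted lognormal distribution
(log10 SD 0.8), services are tiered as high value (≤ $100k/LY), low value
(> $300k/LY) or intermediate (in between, or not estimable), and demand
responds to coinsurance with a uniform elasticity ε = −0.31. A synthetic
cohort of one million persons buys age-profiled allotments of care over
life-table lifetimes; each $500 parcel of spending converts to 1/ICER
life-years. The distribution median, the uninsured benefit ratio and the
baseline coinsurance are calibrated so the no-VBID world reproduces the
observed anchors: $5,688 per capita per year, a 4.70 life-year gain
attributable to care (3.93 among the uninsured), and a +$72/capita response
to eliminating high-value copays.

Three VBID designs are evaluated, each for all services or pharmacy-only
scope:

1. **Strategy 1** — zero copay on high-value services, nothing else changes.
2. **Strategy 2** — additionally raise low-value copays until expenditure is
   unchanged from a societal, payer, or patient perspective (bisection on
   the closed-form expenditure equations, $1/capita tolerance).
3. **Strategy 3** — raise low-value copays to fund covering the uninsured.

A one-way sensitivity grid perturbs the elasticity, distribution shape,
estimability, ineffectiveness, copay suitability and tier thresholds, each
time recalibrating so the no-VBID column stays at 4.70 life-years.

See `docs/methods.md` for the model's assumptions, calibration details and
known limitations.

## Worked example

```python
from vbidsim import RunConfig, build_model_from_config, run
from vbidsim.strategies import apply_strategy1, solve_strategy3

model = build_model_from_config(RunConfig())
shares = model.dist.tier_spending_shares(model.tiers)
print(f"low-value share of spending: {shares.low:.1%}")

base = run(model, model.baseline_spec(), n_persons=1_000_000, seed=1)
s1 = run(model, apply_strategy1(model), n_persons=1_000_000, seed=1)
s3 = run(model, solve_strategy3(model), n_persons=1_000_000, seed=1)
print(f"baseline: {base.le_gain:.2f} LY, ${base.per_capita:,.0f}/capita")
print(f"strategy 1: +{s1.le_gain - base.le_gain:.2f} LY, "
      f"+${s1.per_capita - base.per_capita:.0f}/capita")
print(f"strategy 3: +{s3.le_gain - base.le_gain:.2f} LY, "
      f"uninsured +{s3.uninsured.le_gain - base.uninsured.le_gain:.2f} LY")
```

prints (≈30–60 s per run on one CPU; results bit-identical per seed)

```
low-value share of spending: 60.7%
baseline: 4.70 LY, $5,688/capita
strategy 1: +0.27 LY, +$72/capita
strategy 3: +0.44 LY, uninsured +1.21 LY
```

Read: about 61% of calibrated spending buys less than one life-year per
$300k. Dropping high-value copays alone buys +0.27 life-years per person
for +$72/capita/year; making VBID budget-neutral and spending the low-value
copay surplus on covering the uninsured buys +0.44 life-years at unchanged
total spending, with the previously uninsured gaining 1.21 life-years.

The same runs are available from the shell:

```bash
vbidsim calibrate                       # calibration report (JSON)
vbidsim run --strategy s1 --n 100000    # one scenario, JSON result
vbidsim tables --out results/           # table1/2/3 CSVs + audit trail
vbidsim sensitivity --rows all          # sensitivity grid CSV
```

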