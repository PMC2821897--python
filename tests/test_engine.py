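"""Monte-Carlo engine: determinism, conservation, oracle equivalence."""


import numpy as np
import pytest

from vbidsim import (CohortConfig, Cohort, DemandParams, ICERDistributionSpec,
                     Model, ValueTierSchedule, replicate_se, run)
from vbidsim.strategies import apply_strategy1, solve_neutral_copay

from conftest import SMOKE_N, SMOKE_SEED


def _result_fields(r):
    d = r.to_dict()
    d.pop("runtime_s")
    return d


def test_fixed_seed_is_bit_identical(model):
    spec = apply_strategy1(model)
    a = run(model, spec, n_persons=20_000, seed=5)
    b = run(model, spec, n_persons=20_000, seed=5)
    assert _result_fields(a) == _result_fields(b)
    c = run(model, spec, n_persons=20_000, seed=6)
    assert c.le_gain != a.le_gain


def test_expenditure_accounting_conserved(mc_runs):
    for r in mc_runs.values():
        assert r.payer_per_capita + r.oop_per_capita == pytest.approx(
            r.per_capita, rel=1e-12)
        assert r.le_gain_se >= 0


def test_degenerate_distribution_closed_form():
    """With a near-point distribution every dollar buys 1/median life-years,
    so the mean gain is lifetime spend / median exactly in expectation."""
    median = 250_000.0
    cohort = Cohort(CohortConfig(n_persons=30_000, uninsured_fraction=0.0))
    model = Model(
        dist=ICERDistributionSpec(sigma_log10=1e-9, median_icer=median),
        tiers=ValueTierSchedule(), demand=DemandParams(), cohort=cohort,
        baseline_coinsurance=0.25, uninsured_benefit_ratio=1.0)
    r = run(model, model.baseline_spec(), n_persons=30_000, seed=9)
    expected = cohort.expected_lifetime_spend / median
    # the only noise left is the lifespan draw
    assert r.le_gain == pytest.approx(expected, abs=4 * r.le_gain_se)
    # ICER noise is gone, so the residual SE is far below the usual level
    assert r.le_gain_se < 0.005


@pytest.mark.parametrize("scenario", ["s1", "s1_pharmacy", "s3"])
def test_engine_matches_analytic_predictions(model, mc_runs, scenario):
    """Oracle equivalence: with common random numbers the engine's
    LE-gain and expenditure deltas match the closed forms."""
    from vbidsim.strategies import solve_strategy3
    specs = {"s1": apply_strategy1(model),
             "s1_pharmacy": apply_strategy1(model, scope_fraction=0.10),
             "s3": solve_strategy3(model)}
    spec = specs[scenario]
    base_an = model.predict(model.baseline_spec())
    an = model.predict(spec)
    mc, mc_base = mc_runs[scenario], mc_runs["baseline"]
    assert mc.le_gain - mc_base.le_gain == pytest.approx(
        an.le_gain - base_an.le_gain, abs=0.006)
    assert mc.per_capita - mc_base.per_capita == pytest.approx(
        an.per_capita - base_an.per_capita, abs=2.0)
    assert mc.le_gain == pytest.approx(an.le_gain, abs=4 * mc.le_gain_se)


def test_baseline_levels_match_analytic(model, mc_runs):
    base = mc_runs["baseline"]
    an = model.predict(model.baseline_spec())
    assert base.le_gain == pytest.approx(an.le_gain, abs=4 * base.le_gain_se)
    assert base.per_capita == pytest.approx(an.per_capita, rel=0.01)
    assert base.oop_per_capita == pytest.approx(an.oop_per_capita, rel=0.02)


def test_results_invariant_to_parcel_size(model):
    runs = [run(model, model.baseline_spec(), n_persons=30_000, seed=4,
                parcel_size=p) for p in (250.0, 500.0, 1000.0)]
    # per-capita spending is conserved regardless of discretization
    pcs = [r.per_capita for r in runs]
    assert max(pcs) - min(pcs) < 1e-6 * max(pcs)
    gains = [r.le_gain for r in runs]
    se = max(r.le_gain_se for r in runs)
    assert max(gains) - min(gains) < 4 * se


def test_replicate_se_and_scaling(model):
    """Across-run SD agrees with the within-run SE estimate, and the SE
    scales as 1/sqrt(n)."""
    spec = model.baseline_spec()
    sd, means = replicate_se(model, spec, n_persons=30_000,
                             seeds=range(100, 112))
    within = run(model, spec, n_persons=30_000, seed=100).le_gain_se
    assert sd == pytest.approx(within, rel=0.5)
    small = run(model, spec, n_persons=3_000, seed=100).le_gain_se
    assert 2.0 < small / within < 5.0  # ~sqrt(10)
    with pytest.raises(ValueError):
        replicate_se(model, spec, n_persons=1000, seeds=[1])


def test_neutral_solve_holds_in_monte_carlo(model):
    """Post-solve neutrality: the strategy-2 run's per-capita expenditure
    matches baseline within Monte-Carlo error (common random numbers)."""
    spec = solve_neutral_copay(model, "societal")
    base = run(model, model.baseline_spec(), n_persons=SMOKE_N, seed=SMOKE_SEED)
    s2 = run(model, spec, n_persons=SMOKE_N, seed=SMOKE_SEED)
    assert s2.per_capita - base.per_capita == pytest.approx(0.0, abs=3.0)
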