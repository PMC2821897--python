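"""ICER distribution: tiering, shares, benefit rates, calibration."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from vbidsim import (ALL, CalibrationError, Cohort, CohortConfig,
                     ICERDistributionSpec, Tier, ValueTierSchedule, calibrate,
                     median_for_high_share, tier_of)

BASE_TIERS = ValueTierSchedule()


@pytest.mark.parametrize("icer,expected", [
    (50_000.0, Tier.HIGH),
    (100_000.0, Tier.HIGH),          # inclusive boundary: "≤ $100k/LY"
    (100_000.01, Tier.INTERMEDIATE),
    (300_000.0, Tier.INTERMEDIATE),  # low tier is strictly "> $300k/LY"
    (300_000.01, Tier.LOW),
    (5e6, Tier.LOW),
    (None, Tier.INTERMEDIATE),       # value not estimable -> intermediate
    (float("nan"), Tier.INTERMEDIATE),
])
def test_tier_assignment(icer, expected):
    assert tier_of(icer, BASE_TIERS) is expected


@pytest.mark.parametrize("bad", [0.0, -5.0, float("inf")])
def test_tier_rejects_nonpositive_icer(bad):
    with pytest.raises(ValueError):
        tier_of(bad, BASE_TIERS)


def test_tier_schedule_requires_ordered_thresholds():
    with pytest.raises(ValueError):
        ValueTierSchedule(high_max=300_000, low_min=100_000)


def test_uncalibrated_distribution_refuses_shares():
    with pytest.raises(CalibrationError):
        ICERDistributionSpec().tier_spending_shares(BASE_TIERS)


@pytest.mark.parametrize("family", ["lognormal", "uniform"])
def test_shares_match_monte_carlo(family, rng):
    """Closed-form tier shares agree with brute-force sampling."""
    dist = ICERDistributionSpec(family=family, median_icer=495_590.0)
    draws = dist.sample_icers(rng, 10_000_000)
    shares = dist.tier_spending_shares(BASE_TIERS)
    assert shares.high == pytest.approx(np.mean(draws <= 1e5), abs=0.005)
    assert shares.low == pytest.approx(np.mean(draws > 3e5), abs=0.005)
    assert shares.high + shares.intermediate + shares.low == pytest.approx(1.0, abs=1e-9)


def test_degenerate_distribution_is_a_point_mass_in_its_band():
    dist = ICERDistributionSpec(sigma_log10=1e-9, median_icer=200_000.0)
    shares = dist.tier_spending_shares(BASE_TIERS)
    assert (shares.high, shares.intermediate, shares.low) == (0.0, 1.0, 0.0)


def test_median_for_high_share_inverse_normal():
    # with sigma=0.8 and 20% of spending at or below $100k/LY the median is
    # 100k·10^(0.8·z_{0.8}) ≈ $471k, and ≈60% of spending lands low-value
    m = median_for_high_share(0.20, 0.8)
    assert m == pytest.approx(1e5 * 10 ** (0.8 * norm.ppf(0.8)))
    assert m == pytest.approx(4.713e5, rel=1e-3)
    dist = ICERDistributionSpec(median_icer=m)
    shares = dist.tier_spending_shares(BASE_TIERS)
    assert shares.high == pytest.approx(0.20, abs=1e-12)
    assert shares.low == pytest.approx(0.60, abs=0.005)


def test_benefit_rate_matches_truncated_monte_carlo(rng):
    """E[1/ICER | high tier] against a brute-force conditional mean."""
    dist = ICERDistributionSpec(median_icer=495_590.0)
    draws = dist.sample_icers(rng, 10_000_000)
    high = draws[draws <= BASE_TIERS.high_max]
    mc = float(np.mean(1.0 / high))
    assert dist.benefit_rate(Tier.HIGH, BASE_TIERS) == pytest.approx(mc, rel=0.005)


def test_benefit_rate_degenerate_and_ineffective():
    near_point = ICERDistributionSpec(sigma_log10=1e-9, median_icer=250_000.0)
    assert near_point.benefit_rate(ALL) == pytest.approx(1 / 250_000.0, rel=1e-6)
    dead = ICERDistributionSpec(median_icer=5e5, ineffective_fraction=1.0)
    for tier in (Tier.HIGH, Tier.INTERMEDIATE, Tier.LOW, ALL):
        assert dead.benefit_rate(tier, BASE_TIERS) == 0.0


@given(st.floats(1e5, 1e7), st.floats(0.2, 1.5))
def test_benefit_rate_ordering_and_mixture_identity(median, sigma):
    """Higher-value tiers buy more benefit per dollar, and the tier rates
    mix back to the overall rate exactly."""
    dist = ICERDistributionSpec(sigma_log10=sigma, median_icer=median)
    shares = dist.tier_spending_shares(BASE_TIERS)
    rates = {t: dist.benefit_rate(t, BASE_TIERS)
             for t in (Tier.HIGH, Tier.INTERMEDIATE, Tier.LOW)}
    assert rates[Tier.HIGH] > rates[Tier.INTERMEDIATE] > rates[Tier.LOW] > 0
    mixed = sum(shares[t] * rates[t] for t in rates)
    assert mixed == pytest.approx(dist.benefit_rate(ALL), rel=1e-9)


def test_ineffective_tail_fills_the_low_tier_first():
    """30% zero-benefit spending sits entirely above the low-value cutoff
    when the low tier is bigger than 30%."""
    dist = ICERDistributionSpec(median_icer=495_590.0, ineffective_fraction=0.30)
    assert dist.ineffective_threshold() > BASE_TIERS.low_min
    # high-tier benefit is untouched by the truncation
    clean = replace(dist, ineffective_fraction=0.0)
    assert dist.benefit_rate(Tier.HIGH, BASE_TIERS) == pytest.approx(
        clean.benefit_rate(Tier.HIGH, BASE_TIERS), rel=1e-12)
    assert dist.benefit_rate(Tier.LOW, BASE_TIERS) < clean.benefit_rate(
        Tier.LOW, BASE_TIERS)


class TestCalibration:
    def small_cohort(self, per_capita=None):
        cfg = CohortConfig(n_persons=1000)
        if per_capita is not None:
            cfg = replace(cfg, per_capita_anchor=per_capita)
        return Cohort(cfg)

    def test_reproduces_population_anchor(self):
        cohort = self.small_cohort()
        dist, ratio, report = calibrate(ICERDistributionSpec(), cohort)
        u = cohort.config.uninsured_fraction
        insured_gain = cohort.expected_lifetime_spend * dist.benefit_kernel(0, math.inf)
        pop = (1 - u) * insured_gain + u * ratio * insured_gain
        assert pop == pytest.approx(4.70, abs=1e-4)
        assert ratio * insured_gain == pytest.approx(3.93, abs=1e-4)
        assert abs(report["residual_ly"]) < 1e-4

    def test_gain_is_monotone_in_median(self):
        cohort = self.small_cohort()
        spend = cohort.expected_lifetime_spend
        gains = [spend * ICERDistributionSpec(median_icer=m).benefit_kernel(0, math.inf)
                 for m in (1e5, 3e5, 1e6, 1e7)]
        assert all(a > b for a, b in zip(gains, gains[1:]))

    def test_scale_equivariance(self):
        """Doubling the spending anchors at fixed life-year anchors doubles
        the calibrated median (benefit per dollar halves)."""
        d1, _, _ = calibrate(ICERDistributionSpec(), self.small_cohort())
        d2, _, _ = calibrate(ICERDistributionSpec(),
                             self.small_cohort(per_capita=2 * 5688.0))
        assert d2.median_icer == pytest.approx(2 * d1.median_icer, rel=1e-6)

    def test_unreachable_anchor_raises(self):
        with pytest.raises(CalibrationError):
            calibrate(ICERDistributionSpec(), self.small_cohort(),
                      anchors={"pop_le_gain": 1e9})
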