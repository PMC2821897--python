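"""Calibrated model and closed-form scenario expectations.

A :class:`Model` bundles the calibrated ICER distribution, tier schedule,
demand parameters, cohort inputs, the calibrated baseline coinsurance and
the uninsured benefit ratio.  Its :meth:`Model.predict` method evaluates a
scenario's expected per-capita expenditure (total / payer / out-of-pocket)
and life-expectancy gain in closed form.  The Monte-Carlo engine draws the
same quantities parcel by parcel; the closed forms are what the
budget-neutrality solvers iterate on and what the engine is validated
against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .cohort import Cohort, CohortConfig
from .demand import CostSharingSchedule, DemandParams
from .value_model import (CalibrationError, ICERDistributionSpec, Tier,
                          ValueTierSchedule, calibrate)


class InfeasibilityError(RuntimeError):
    """A budget-neutrality (or rescaling) solve has no solution in bounds."""


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully resolved scenario the engine / analytics can evaluate.

    ``schedule`` holds the coinsurance applied to suitable, in-scope parcels
    by *assigned* tier; its ``baseline`` field is the reference rate suitable
    parcels face in the no-VBID world.  ``expansion_fraction`` is the share
    of the uninsured brought onto the insured benefit (strategy 3).
    """

    name: str
    schedule: CostSharingSchedule
    strategy: str = "baseline"
    perspective: Optional[str] = None
    scope_fraction: float = 1.0
    expansion_fraction: float = 0.0
    unsuitable_fraction: float = 0.0
    solved_low_copay: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.scope_fraction <= 1.0:
            raise ValueError("scope_fraction must lie in (0, 1]")
        if not 0.0 <= self.expansion_fraction <= 1.0:
            raise ValueError("expansion_fraction must lie in [0, 1]")
        if not 0.0 <= self.unsuitable_fraction < 1.0:
            raise ValueError("unsuitable_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class AnalyticResult:
    """Expected values of the scenario outcomes (no Monte-Carlo error)."""

    le_gain: float
    le_gain_insured: float
    le_gain_uninsured: float     # persons uninsured at baseline
    per_capita: float
    payer_per_capita: float
    oop_per_capita: float
    national_billion: float


@dataclass
class Model:
    dist: ICERDistributionSpec
    tiers: ValueTierSchedule
    demand: DemandParams
    cohort: Cohort
    baseline_coinsurance: float
    uninsured_benefit_ratio: float
    calibration_report: dict = field(default_factory=dict)

    # -- tier decomposition -------------------------------------------------

    def assigned_shares(self) -> np.ndarray:
        """Spending shares by *assigned* tier [high, intermediate, low].

        Non-estimable spending is assigned to the intermediate tier
        regardless of its true ICER.
        """
        s = self.dist.tier_spending_shares(self.tiers)
        rho = self.dist.estimable_fraction
        high, low = rho * s.high, rho * s.low
        return np.array([high, 1.0 - high - low, low])

    def assigned_kernels(self) -> np.ndarray:
        """Per-dollar benefit carried by each assigned tier's spending.

        Non-estimable dollars keep their true ICER for benefit accounting,
        so the intermediate bucket absorbs their benefit.
        """
        d, t = self.dist, self.tiers
        rho = d.estimable_fraction
        total = d.benefit_kernel(0.0, math.inf)
        high = rho * d.benefit_kernel(0.0, t.high_max)
        low = rho * d.benefit_kernel(t.low_min, math.inf)
        return np.array([high, total - high - low, low])

    # -- scenario plumbing --------------------------------------------------

    def reference_coinsurance(self, unsuitable_fraction: float = 0.0) -> float:
        """Baseline coinsurance on copay-suitable spending.

        When a fraction of spending is intrinsically unsuitable for copays
        (it carries none, in every arm), the remaining services' rate is
        scaled up so cohort-level mean cost sharing stays at the calibrated
        baseline.
        """
        if unsuitable_fraction <= 0.0:
            return self.baseline_coinsurance
        c = self.baseline_coinsurance / (1.0 - unsuitable_fraction)
        if c > 1.0:
            raise InfeasibilityError(
                f"rescaled baseline coinsurance {c:.3f} exceeds 1 for "
                f"unsuitable fraction {unsuitable_fraction:.2f}")
        return c

    def suitable_probabilities(self, unsuitable_fraction: float) -> np.ndarray:
        """P(parcel is copay-suitable | assigned tier) as [high, int, low].

        Unsuitable spending (inpatient-style services) is assumed not to sit
        in the high-value tier: it fills the intermediate/low tiers first and
        spills into the high tier only if it must.
        """
        if unsuitable_fraction <= 0.0:
            return np.ones(3)
        sh = self.assigned_shares()
        nonhigh = sh[1] + sh[2]
        p_unsuit_nonhigh = min(1.0, unsuitable_fraction / nonhigh) if nonhigh > 0 else 0.0
        spill = max(0.0, unsuitable_fraction - nonhigh)
        p_unsuit_high = min(1.0, spill / sh[0]) if sh[0] > 0 else 0.0
        return np.array([1.0 - p_unsuit_high, 1.0 - p_unsuit_nonhigh,
                         1.0 - p_unsuit_nonhigh])

    def baseline_spec(self, unsuitable_fraction: float = 0.0) -> ScenarioSpec:
        c_ref = self.reference_coinsurance(unsuitable_fraction)
        return ScenarioSpec(name="baseline",
                            schedule=CostSharingSchedule.flat(c_ref),
                            strategy="baseline",
                            unsuitable_fraction=unsuitable_fraction)

    # -- closed-form expectations -------------------------------------------

    def _tier_factors(self, spec: ScenarioSpec):
        """Expected per-dollar factors by assigned tier.

        Returns (E[quantity multiplier | tier], E[multiplier·coinsurance | tier])
        for an insured (VBID-covered) person, mixing over the scope,
        suitability and inelastic-parcel Bernoullis.
        """
        eps = self.demand.elasticity
        eta = self.demand.inelastic_spending_fraction
        phi = spec.scope_fraction
        c_ref = self.reference_coinsurance(spec.unsuitable_fraction)
        p_suit = self.suitable_probabilities(spec.unsuitable_fraction)
        c = np.array(spec.schedule.as_tuple())
        elastic_mult = np.maximum(0.0, 1.0 + eps * (c - c_ref))
        in_scope_mult = (1.0 - eta) * elastic_mult + eta  # mix of elastic/inelastic
        e_mult = p_suit * (phi * in_scope_mult + (1.0 - phi)) + (1.0 - p_suit)
        e_mult_coins = p_suit * (phi * c * in_scope_mult + (1.0 - phi) * c_ref)
        return e_mult, e_mult_coins

    def predict(self, spec: ScenarioSpec) -> AnalyticResult:
        cohort = self.cohort
        u = cohort.config.uninsured_fraction
        x = spec.expansion_fraction
        pc_anchor = cohort.config.per_capita_anchor
        lifetime = cohort.expected_lifetime_spend
        shares = self.assigned_shares()
        kernels = self.assigned_kernels()
        e_mult, e_mult_coins = self._tier_factors(spec)

        spend_factor = float(shares @ e_mult)
        oop_factor = float(shares @ e_mult_coins)
        benefit_per_dollar = float(kernels @ e_mult)

        gain_covered = lifetime * benefit_per_dollar
        gain_uncovered = (self.uninsured_benefit_ratio * lifetime
                          * float(kernels.sum()))

        # baseline-uninsured persons: fraction x of them are newly covered
        gain_unins_group = x * gain_covered + (1.0 - x) * gain_uncovered
        le_gain = (1.0 - u) * gain_covered + u * gain_unins_group

        pc = pc_anchor * ((1.0 - u) * spend_factor
                          + u * (x * spend_factor + (1.0 - x)))
        # the uncovered pay everything out of pocket
        oop = pc_anchor * ((1.0 - u) * oop_factor
                           + u * (x * oop_factor + (1.0 - x)))
        return AnalyticResult(
            le_gain=le_gain,
            le_gain_insured=gain_covered,
            le_gain_uninsured=gain_unins_group,
            per_capita=pc,
            payer_per_capita=pc - oop,
            oop_per_capita=oop,
            national_billion=pc * cohort.config.population_total / 1e9,
        )


def calibrate_baseline_coinsurance(
    model: Model,
    target_delta: float = 72.0,
    *,
    tol: float = 1e-9,
    max_iter: int = 80,
) -> float:
    """Solve the prevailing coinsurance rate c0 from the strategy-1 anchor.

    The observed +$72 per capita under strategy 1 (zero copay on the
    high-value tier, all services) pins down how much cost sharing there was
    to remove.  The delta is measured per capita over the whole population
    while only the insured respond, so c0 solves
    (1−u)·pc_anchor·ŝ_high·|ε|·(1−η)·c0 = target_delta.
    Implemented as a bisection on the analytic strategy-1 delta so it stays
    correct for any demand form.
    """
    from .strategies import apply_strategy1  # local import avoids a cycle

    def delta(c0: float) -> float:
        m = replace_c0(model, c0)
        base = m.predict(m.baseline_spec())
        s1 = m.predict(apply_strategy1(m))
        return s1.per_capita - base.per_capita

    lo, hi = 1e-6, 1.0
    f_hi = delta(hi) - target_delta
    if f_hi < 0:
        raise CalibrationError(
            f"strategy-1 delta {f_hi + target_delta:.2f} at coinsurance 1.0 "
            f"cannot reach the ${target_delta:.0f} anchor")
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        if delta(mid) - target_delta > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return (lo + hi) / 2.0


def replace_c0(model: Model, c0: float) -> Model:
    return Model(dist=model.dist, tiers=model.tiers, demand=model.demand,
                 cohort=model.cohort, baseline_coinsurance=c0,
                 uninsured_benefit_ratio=model.uninsured_benefit_ratio,
                 calibration_report=model.calibration_report)


def build_model(
    dist: ICERDistributionSpec,
    tiers: ValueTierSchedule,
    demand: DemandParams,
    cohort: Cohort,
    *,
    anchors: Optional[dict] = None,
    baseline_coinsurance: Optional[float] = None,
    strategy1_expenditure_delta: float = 72.0,
) -> Model:
    """Calibrate a model end to end.

    Order: the distribution median is solved against the population
    life-expectancy anchor, the uninsured benefit ratio against the
    uninsured anchor, and finally (unless supplied) the baseline coinsurance
    against the strategy-1 expenditure anchor.
    """
    calibrated, ratio, report = calibrate(dist, cohort, anchors)
    model = Model(dist=calibrated, tiers=tiers, demand=demand, cohort=cohort,
                  baseline_coinsurance=0.5, uninsured_benefit_ratio=ratio,
                  calibration_report=report)
    if baseline_coinsurance is None:
        c0 = calibrate_baseline_coinsurance(
            model, target_delta=strategy1_expenditure_delta)
        report["baseline_coinsurance"] = c0
        report["strategy1_expenditure_delta"] = strategy1_expenditure_delta
    else:
        c0 = baseline_coinsurance
        report["baseline_coinsurance"] = c0
    shares = calibrated.tier_spending_shares(tiers)
    report["tier_spending_shares"] = {
        "high": shares.high, "intermediate": shares.intermediate,
        "low": shares.low}
    return replace_c0(model, c0)
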