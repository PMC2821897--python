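"""VBID strategies and budget-neutrality solvers.

Strategy 1 drops cost sharing on high-value services and leaves everything
else alone (no cost offset).  Strategy 2 additionally raises the low-value
copay until the chosen perspective's expenditure total (societal: all
spending; payer: plan-paid; patient: out-of-pocket) is back at its no-VBID
level.  Strategy 3 does the same while bringing the uninsured onto the
insured VBID benefit; the share of the uninsured covered equals the VBID
scope fraction (the all-services surplus funds full coverage, and the
surplus scales with scope).  Solvers iterate the closed-form expenditure
equations by bisection; the Monte-Carlo engine is used afterwards to
confirm neutrality within sampling error.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

from .demand import CostSharingSchedule
from .model import InfeasibilityError, Model, ScenarioSpec

PERSPECTIVES = ("societal", "payer", "patient")

#: Default per-capita tolerance ($/year) of the neutrality solves.
NEUTRALITY_TOL = 1.0


def apply_strategy1(model: Model, scope_fraction: float = 1.0,
                    unsuitable_fraction: float = 0.0) -> ScenarioSpec:
    """Zero copay on the high tier; intermediate and low unchanged."""
    c_ref = model.reference_coinsurance(unsuitable_fraction)
    return ScenarioSpec(
        name="strategy1",
        strategy="s1",
        schedule=CostSharingSchedule(high=0.0, intermediate=c_ref, low=c_ref,
                                     baseline=c_ref),
        scope_fraction=scope_fraction,
        unsuitable_fraction=unsuitable_fraction,
    )


def _perspective_metric(result, perspective: str) -> float:
    return {"societal": result.per_capita,
            "payer": result.payer_per_capita,
            "patient": result.oop_per_capita}[perspective]


def _solve_low_copay(model: Model, spec_template: ScenarioSpec,
                     perspective: str, *, raise_intermediate: bool = False,
                     tol: float = NEUTRALITY_TOL, max_iter: int = 80) -> ScenarioSpec:
    """Bisect the low-tier (optionally also intermediate) coinsurance so the
    perspective's expenditure equals its no-VBID baseline."""
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    c_ref = model.reference_coinsurance(spec_template.unsuitable_fraction)
    base = model.predict(model.baseline_spec(spec_template.unsuitable_fraction))
    target = _perspective_metric(base, perspective)

    def with_copay(c: float) -> ScenarioSpec:
        sched = CostSharingSchedule(
            high=0.0,
            intermediate=c if raise_intermediate else c_ref,
            low=c, baseline=c_ref)
        return replace(spec_template, schedule=sched, solved_low_copay=c)

    def excess(c: float) -> float:
        return _perspective_metric(model.predict(with_copay(c)), perspective) - target

    f_lo, f_hi = excess(c_ref), excess(1.0)
    if abs(f_lo) <= tol and abs(f_hi) <= tol:
        raise InfeasibilityError(
            f"{perspective} expenditure is unchanged at any low copay "
            f"(demand unresponsive); the neutral copay is undetermined")
    if f_lo * f_hi > 0.0:
        raise InfeasibilityError(
            f"no amount of increased cost sharing on the "
            f"{'intermediate/low tiers' if raise_intermediate else 'low tier'}"
            f" restores {perspective} expenditure to baseline "
            f"(excess ${f_lo:.2f} at {c_ref:.3f}, ${f_hi:.2f} at 1.0 per capita)")
    lo, hi = c_ref, 1.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        if excess(mid) * f_lo > 0:
            lo = mid
        else:
            hi = mid
    c_star = (lo + hi) / 2.0
    if abs(excess(c_star)) > tol:
        raise InfeasibilityError(
            f"neutrality solve did not converge within ${tol}/capita "
            f"({perspective})")
    return with_copay(c_star)


def solve_neutral_copay(model: Model, perspective: str = "societal",
                        scope_fraction: float = 1.0,
                        unsuitable_fraction: float = 0.0, *,
                        raise_intermediate: bool = False) -> ScenarioSpec:
    """Strategy 2: cost-offset VBID without insurance expansion.

    ``raise_intermediate`` is the documented fallback for narrow ICER
    distributions, where too little spending is low-value for the low tier
    alone to fund the high-tier subsidy: cost sharing is then raised on the
    intermediate and low tiers together.
    """
    template = ScenarioSpec(
        name=f"strategy2_{perspective}",
        strategy="s2",
        perspective=perspective,
        schedule=CostSharingSchedule.flat(
            model.reference_coinsurance(unsuitable_fraction)),
        scope_fraction=scope_fraction,
        unsuitable_fraction=unsuitable_fraction,
    )
    return _solve_low_copay(model, template, perspective,
                            raise_intermediate=raise_intermediate)


def solve_strategy3(model: Model, scope_fraction: float = 1.0,
                    unsuitable_fraction: float = 0.0, *,
                    raise_intermediate: bool = False,
                    expansion_fraction: Optional[float] = None) -> ScenarioSpec:
    """Strategy 3: cost-offset VBID funding insurance expansion.

    Solved from the societal perspective with the newly insured consuming at
    the insured VBID profile.  With no uninsured population this reduces to
    strategy 2 (societal).
    """
    u = model.cohort.config.uninsured_fraction
    if expansion_fraction is None:
        expansion_fraction = scope_fraction if u > 0 else 0.0
    template = ScenarioSpec(
        name="strategy3",
        strategy="s3",
        perspective="societal",
        schedule=CostSharingSchedule.flat(
            model.reference_coinsurance(unsuitable_fraction)),
        scope_fraction=scope_fraction,
        expansion_fraction=expansion_fraction,
        unsuitable_fraction=unsuitable_fraction,
    )
    return _solve_low_copay(model, template, "societal",
                            raise_intermediate=raise_intermediate)
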