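"""Price response of health care demand to cost sharing.

Demand is summarized by a single elasticity applied uniformly across
services (base −0.31, the RAND-style estimate).  The default functional
form is *semi-elastic*: the quantity multiplier is linear in the change in
coinsurance percentage points, factor = 1 + ε·(c_new − c_old).  An arc
elasticity variant (relative price change against the midpoint) is kept for
sensitivity work; it is scale-free in the rates, which makes it inconsistent
with the calibrated dollar anchors, so it is never the default.
"""

from __future__ import annotations

from dataclasses import dataclass

from .value_model import Tier


@dataclass(frozen=True)
class CostSharingSchedule:
    """Coinsurance rate per value tier, plus the no-VBID baseline rate."""

    high: float
    intermediate: float
    low: float
    baseline: float

    def __post_init__(self) -> None:
        for name in ("high", "intermediate", "low", "baseline"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"coinsurance {name}={v} outside [0, 1]")

    def by_tier(self, tier: Tier) -> float:
        return {Tier.HIGH: self.high, Tier.INTERMEDIATE: self.intermediate,
                Tier.LOW: self.low}[tier]

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.high, self.intermediate, self.low)

    @classmethod
    def flat(cls, rate: float) -> "CostSharingSchedule":
        """The no-VBID world: every tier at the prevailing rate."""
        return cls(high=rate, intermediate=rate, low=rate, baseline=rate)


@dataclass(frozen=True)
class DemandParams:
    elasticity: float = -0.31
    functional_form: str = "semi_elastic"
    inelastic_spending_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.elasticity > 0:
            raise ValueError("elasticity must be <= 0")
        if self.functional_form not in ("semi_elastic", "arc"):
            raise ValueError(f"unknown functional form {self.functional_form!r}")
        if not 0.0 <= self.inelastic_spending_fraction <= 1.0:
            raise ValueError("inelastic_spending_fraction must lie in [0, 1]")


def demand_multiplier(c_old: float, c_new: float, params: DemandParams) -> float:
    """Quantity multiplier when coinsurance moves from ``c_old`` to ``c_new``.

    The inelastic spending fraction is handled upstream (those parcels keep a
    multiplier of 1); this function returns the elastic-parcel factor.
    """
    for c in (c_old, c_new):
        if not 0.0 <= c <= 1.0:
            raise ValueError("coinsurance rates must lie in [0, 1]")
    eps = params.elasticity
    if params.functional_form == "semi_elastic":
        return max(0.0, 1.0 + eps * (c_new - c_old))
    mid = (c_new + c_old) / 2.0
    a = 0.0 if mid == 0.0 else eps * (c_new - c_old) / mid
    return max(0.0, (2.0 + a) / (2.0 - a))


def split_expenditure(amount: float, coinsurance: float) -> tuple[float, float]:
    """Partition spending into (payer $, out-of-pocket $) exactly."""
    if amount < 0:
        raise ValueError("amount must be >= 0")
    oop = amount * coinsurance
    return amount - oop, oop
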