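"""Lifetime Monte-Carlo engine.

Each simulated person lives out a lifespan drawn from the period life table
and, in every year of life, buys an age-profiled allotment of care split
into ~$500 spending parcels.  Every parcel draws an ICER from the
spending-weighted distribution; the parcel's dollar amount is scaled by the
tier-specific demand multiplier, and amount/ICER life-years are credited to
the person (zero for the ineffective tail, reduced by the benefit ratio for
the uninsured).  Life-years purchased extend the lifespan post hoc and do
not feed back into future spending years, so the expenditure anchors are
preserved by construction.

The engine is vectorized age-by-age: persons are sorted by death year so
that the set alive at any age is a prefix, and each (alive × parcels)
matrix is processed in one shot.  ICER draws come from a random stream
separate from the cohort and auxiliary (scope / estimability / suitability /
elasticity) streams, so scenarios run with the same seed share parcel-level
draws — deltas between scenarios are estimated with common random numbers.
"""

from __future__ import annotations

import math
import time
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import Cohort
from .model import Model, ScenarioSpec
from .value_model import LN10

_F32 = np.float32


@dataclass(frozen=True)
class SubgroupResult:
    n: int
    le_gain: float
    le_gain_se: float


@dataclass(frozen=True)
class ScenarioResult:
    """Per-scenario simulation outcomes (annualized, per-capita scale)."""

    name: str
    le_gain: float               # mean life-years attributable to care
    le_gain_se: float            # Monte-Carlo SE of the mean
    per_capita: float            # mean annual expenditure, $/person-year
    national_billion: float      # per-capita scaled to the US population
    payer_per_capita: float
    oop_per_capita: float
    insured: SubgroupResult      # insured at baseline
    uninsured: SubgroupResult    # uninsured at baseline (incl. newly covered)
    n_persons: int
    seed: int
    runtime_s: float

    def to_dict(self) -> dict:
        return asdict(self)


def _parcel_amounts(annual: float, parcel_size: float) -> np.ndarray:
    k = int(annual // parcel_size)
    rem = annual - k * parcel_size
    if rem > 1e-9:
        return np.array([parcel_size] * k + [rem])
    return np.full(max(k, 1), parcel_size if k else 0.0)


def run(model: Model, spec: ScenarioSpec, *, n_persons: Optional[int] = None,
        seed: int = 0, parcel_size: Optional[float] = None) -> ScenarioResult:
    """Simulate one scenario and return its :class:`ScenarioResult`.

    Deterministic given ``seed``: two runs with identical arguments return
    bit-identical results.
    """
    t0 = time.perf_counter()
    cohort: Cohort = model.cohort
    cfg = cohort.config
    n = int(n_persons if n_persons is not None else cfg.n_persons)
    p_size = float(parcel_size if parcel_size is not None else cfg.parcel_size)
    if p_size <= 0:
        raise ValueError("parcel_size must be > 0")

    dist = model.dist
    ss = np.random.SeedSequence(seed)
    rng_cohort, rng_icer, rng_aux = (np.random.default_rng(s)
                                     for s in ss.spawn(3))

    # ---- cohort draw (identical across scenarios at the same seed) --------
    death = cohort.lifetable.sample_death_years(rng_cohort, n)
    insured = rng_cohort.random(n) >= cfg.uninsured_fraction
    if spec.expansion_fraction > 0.0:
        newly = (~insured) & (rng_cohort.random(n) < spec.expansion_fraction)
    else:
        newly = np.zeros(n, dtype=bool)
    covered = insured | newly

    order = np.argsort(-death, kind="stable")
    death_s = death[order]
    insured_s = insured[order]
    covered_s = covered[order]

    n_ages = cohort.lifetable.n_ages
    counts = np.bincount(death_s, minlength=n_ages)
    alive = n - np.concatenate(([0], np.cumsum(counts)[:-1]))

    # ---- per-tier constants ----------------------------------------------
    eps = model.demand.elasticity
    eta = model.demand.inelastic_spending_fraction
    phi = spec.scope_fraction
    rho = dist.estimable_fraction
    u_frac = spec.unsuitable_fraction
    c_ref = model.reference_coinsurance(u_frac)
    c_sched = np.array(spec.schedule.as_tuple())
    mult_elastic = np.maximum(0.0, 1.0 + eps * (c_sched - c_ref))
    p_suit = model.suitable_probabilities(u_frac)
    ratio = model.uninsured_benefit_ratio

    med10 = math.log10(dist.median_icer)
    t_hi = math.log10(model.tiers.high_max)
    t_lo = math.log10(model.tiers.low_min)
    x_f = dist.ineffective_threshold()
    t_eff = math.inf if math.isinf(x_f) else math.log10(x_f)
    half_width = math.sqrt(3.0) * dist.sigma_log10  # uniform family

    benefit = np.zeros(n)
    spend = np.zeros(n)
    oop = np.zeros(n)

    # when the schedule is flat and every parcel carries a copay, tier and
    # scope assignment cannot change amounts or coinsurance: skip them
    flat_schedule = bool(np.all(c_sched == c_ref)) and u_frac <= 0.0

    for age in range(n_ages):
        m = int(alive[age])
        if m == 0:
            break
        annual = cohort.spend_by_age[age]
        base_p = _parcel_amounts(annual, p_size)
        cols = base_p.size
        if cols == 0 or annual <= 0:
            continue
        shape = (m, cols)

        # spending-weighted log10(ICER) draws
        if dist.family == "lognormal":
            x10 = rng_icer.standard_normal(shape, dtype=_F32)
            x10 *= dist.sigma_log10
            x10 += med10
        else:
            x10 = rng_icer.uniform(med10 - half_width, med10 + half_width,
                                   shape).astype(_F32)

        inv_icer = np.exp(x10 * np.float32(-LN10))
        if math.isfinite(t_eff):
            inv_icer[x10 > t_eff] = 0.0

        if flat_schedule:  # no-VBID world: amounts are the raw parcels
            cov = covered_s[:m]
            benefit[:m] += inv_icer @ base_p
            spend[:m] += annual
            oop[:m] += annual * np.where(cov, c_ref, 1.0)
            continue

        tier_idx = (x10 > t_hi).astype(np.uint8)
        tier_idx += x10 > t_lo
        if rho < 1.0:  # non-estimable parcels are treated as intermediate
            est = rng_aux.random(shape, dtype=_F32) < rho
            tier_idx[~est] = 1

        mult = mult_elastic[tier_idx]
        coins = c_sched[tier_idx]
        if phi < 1.0:
            out_of_scope = rng_aux.random(shape, dtype=_F32) >= phi
            mult[out_of_scope] = 1.0
            coins[out_of_scope] = c_ref
        if u_frac > 0.0:
            unsuitable = rng_aux.random(shape, dtype=_F32) >= p_suit[tier_idx]
            mult[unsuitable] = 1.0
            coins[unsuitable] = 0.0
        if eta > 0.0:  # inelastic parcels face the copay but keep quantity
            inelastic = rng_aux.random(shape, dtype=_F32) < eta
            mult[inelastic] = 1.0
        uncov = ~covered_s[:m]
        mult[uncov, :] = 1.0
        coins[uncov, :] = 1.0  # the uncovered pay everything out of pocket

        amount = mult
        amount *= base_p
        benefit[:m] += np.einsum("ij,ij->i", amount, inv_icer,
                                 dtype=np.float64, casting="unsafe")
        spend[:m] += amount.sum(axis=1, dtype=np.float64)
        oop[:m] += np.einsum("ij,ij->i", amount, coins)

    benefit[~covered_s] *= ratio

    person_years = float(np.sum(death_s + 1))
    total = float(spend.sum())
    total_oop = float(oop.sum())
    per_capita = total / person_years

    def subgroup(mask: np.ndarray) -> SubgroupResult:
        k = int(mask.sum())
        if k == 0:
            return SubgroupResult(n=0, le_gain=math.nan, le_gain_se=math.nan)
        vals = benefit[mask]
        se = float(vals.std(ddof=1) / math.sqrt(k)) if k > 1 else math.nan
        return SubgroupResult(n=k, le_gain=float(vals.mean()), le_gain_se=se)

    return ScenarioResult(
        name=spec.name,
        le_gain=float(benefit.mean()),
        le_gain_se=float(benefit.std(ddof=1) / math.sqrt(n)),
        per_capita=per_capita,
        national_billion=per_capita * cfg.population_total / 1e9,
        payer_per_capita=(total - total_oop) / person_years,
        oop_per_capita=total_oop / person_years,
        insured=subgroup(insured_s),
        uninsured=subgroup(~insured_s),
        n_persons=n,
        seed=seed,
        runtime_s=time.perf_counter() - t0,
    )


def replicate_se(model: Model, spec: ScenarioSpec, *, n_persons: int,
                 seeds: Sequence[int], parcel_size: Optional[float] = None
                 ) -> tuple[float, list[float]]:
    """Across-run reproducibility: SD of the mean LE gain over seeds."""
    if len(seeds) < 2:
        raise ValueError("need at least two seeds")
    means = [run(model, spec, n_persons=n_persons, seed=int(s),
                 parcel_size=parcel_size).le_gain for s in seeds]
    return float(np.std(means, ddof=1)), means
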