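"""Synthetic cohort: ages, insurance, expenditure stream, mortality.

The simulated population is stylized but anchored: an age-stratified annual
expenditure profile (8 bands rising roughly six-fold from childhood to 85+)
is normalized so that, in a stationary population following the shipped
period life table (e0 ≈ 77.2 years), mean annual spending per person equals
the national per-capita anchor of $5,688.  The life table only sets the
spending horizon; life-years purchased from care are added to the lifespan
after the fact and do not feed back into spending.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

#: National per-capita and total expenditure anchors; their ratio fixes the
#: implied population size used to scale per-capita results to $ billions.
PER_CAPITA_SPEND = 5_688.0
NATIONAL_SPEND = 1_654e9
POPULATION_TOTAL = NATIONAL_SPEND / PER_CAPITA_SPEND  # ≈ 290.8 million


def _data_path(name: str):
    return resources.files("vbidsim").joinpath("data", name)


@dataclass(frozen=True)
class CohortConfig:
    n_persons: int = 1_000_000
    uninsured_fraction: float = 0.15
    population_total: float = POPULATION_TOTAL
    per_capita_anchor: float = PER_CAPITA_SPEND
    parcel_size: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not 0.0 <= self.uninsured_fraction < 1.0:
            raise ValueError("uninsured_fraction must lie in [0, 1)")
        if self.parcel_size <= 0:
            raise ValueError("parcel_size must be > 0")


class LifeTable:
    """Period life table: per-age annual death probability without care."""

    def __init__(self, qx: Sequence[float]):
        qx = np.asarray(qx, dtype=float)
        if qx.size == 0:
            raise ValueError("life table is empty")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("death probabilities must lie in [0, 1]")
        if qx[-1] < 1.0:
            raise ValueError("terminal age must close the table (qx=1)")
        self.qx = qx
        surv = np.cumprod(1.0 - qx)
        self.l = np.concatenate([[1.0], surv[:-1]])  # P(alive during year a)
        self.death_pmf = self.l * qx                 # P(die during year a)

    @property
    def n_ages(self) -> int:
        return self.qx.size

    @property
    def life_expectancy(self) -> float:
        """Expected years lived (counterfactual, without care benefit)."""
        return float(self.l.sum())

    def sample_death_years(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Sample the last year of life (person lives years 0..d inclusive)."""
        return rng.choice(self.n_ages, size=n, p=self.death_pmf / self.death_pmf.sum())

    @classmethod
    def from_csv(cls, path=None) -> "LifeTable":
        src = path if path is not None else _data_path("life_table.csv")
        df = pd.read_csv(src)
        return cls(df["qx"].to_numpy())


class AgeExpenditureProfile:
    """Age-banded annual expenditure weights, normalized to an anchor."""

    def __init__(self, age_min: Sequence[int], age_max: Sequence[int],
                 weight: Sequence[float]):
        self.age_min = np.asarray(age_min, dtype=int)
        self.age_max = np.asarray(age_max, dtype=int)
        self.weight = np.asarray(weight, dtype=float)
        if self.weight.size == 0:
            raise ValueError("expenditure profile is empty")
        if np.any(self.weight < 0):
            raise ValueError("expenditure weights must be non-negative")

    @classmethod
    def from_csv(cls, path=None) -> "AgeExpenditureProfile":
        src = path if path is not None else _data_path("age_expenditure_profile.csv")
        df = pd.read_csv(src)
        return cls(df["age_min"], df["age_max"], df["weight"])

    def weights_by_age(self, n_ages: int) -> np.ndarray:
        w = np.zeros(n_ages)
        for lo, hi, wt in zip(self.age_min, self.age_max, self.weight):
            w[lo:min(hi + 1, n_ages)] = wt
        if np.any(w == 0.0) and self.weight.min() > 0:
            # extend the last band upward if the table outlives the profile
            w[w == 0.0] = self.weight[-1]
        return w

    def spend_by_age(self, lifetable: LifeTable, anchor: float) -> np.ndarray:
        """Annual $ spend per age, scaled so the survivorship-weighted
        (stationary-population) mean equals ``anchor`` per person-year."""
        w = self.weights_by_age(lifetable.n_ages)
        mean_w = float(lifetable.l @ w) / lifetable.life_expectancy
        if mean_w <= 0:
            raise ValueError("profile carries no spending")
        return w * (anchor / mean_w)


@dataclass
class Person:
    """One simulated individual (summary view of the vectorized engine state)."""

    insured: bool
    death_year: int                      # last calendar year of life (age)
    annual_spend: np.ndarray = field(repr=False, default=None)
    spending_by_tier: dict = field(default_factory=dict)
    life_years_purchased: float = 0.0

    @property
    def lifespan(self) -> int:
        return self.death_year + 1


class Cohort:
    """Bundles config, profile and life table; precomputes expectations."""

    def __init__(self, config: CohortConfig,
                 profile: Optional[AgeExpenditureProfile] = None,
                 lifetable: Optional[LifeTable] = None):
        self.config = config
        self.profile = profile if profile is not None else AgeExpenditureProfile.from_csv()
        self.lifetable = lifetable if lifetable is not None else LifeTable.from_csv()
        self.spend_by_age = self.profile.spend_by_age(
            self.lifetable, config.per_capita_anchor)

    @property
    def life_expectancy(self) -> float:
        return self.lifetable.life_expectancy

    @property
    def expected_lifetime_spend(self) -> float:
        """Expected undiscounted lifetime expenditure per person ($)."""
        return float(self.lifetable.l @ self.spend_by_age)

    def draw(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized cohort draw: (death_year, insured) arrays."""
        n = self.config.n_persons
        death = self.lifetable.sample_death_years(rng, n)
        insured = rng.random(n) >= self.config.uninsured_fraction
        return death, insured


def generate_cohort(config: CohortConfig,
                    profile: Optional[AgeExpenditureProfile] = None,
                    lifetable: Optional[LifeTable] = None) -> Iterator[Person]:
    """Yield the cohort as a stream of :class:`Person` records.

    Reproducible under ``config.seed``.  The Monte-Carlo engine uses the
    equivalent vectorized :meth:`Cohort.draw` internally.
    """
    cohort = Cohort(config, profile, lifetable)
    rng = np.random.default_rng(config.seed)
    death, insured = cohort.draw(rng)
    for d, ins in zip(death, insured):
        yield Person(insured=bool(ins), death_year=int(d),
                     annual_spend=cohort.spend_by_age[: int(d) + 1])


def lifetime_parcels(annual_amounts: Sequence[float],
                     parcel_size: float) -> list[tuple[int, float]]:
    """Discretize annual allotments into (year, $amount) spending parcels.

    Each year is split into full parcels of ``parcel_size`` plus a remainder
    parcel, so parcel amounts sum to the allotment exactly.
    """
    if parcel_size <= 0:
        raise ValueError("parcel_size must be > 0")
    out: list[tuple[int, float]] = []
    for year, amount in enumerate(np.asarray(annual_amounts, dtype=float)):
        if amount < 0:
            raise ValueError("annual amounts must be non-negative")
        k = int(amount // parcel_size)
        rem = amount - k * parcel_size
        out.extend((year, parcel_size) for _ in range(k))
        if rem > 1e-9:
            out.append((year, rem))
    return out
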