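"""One-way sensitivity grid over the model's structural assumptions.

Each named scenario perturbs one assumption (elasticity, distribution
shape, estimability, ineffectiveness, copay suitability, tier threshold),
recalibrates the distribution median so the no-VBID benefit anchor (4.70
life-years) still holds, keeps the baseline coinsurance fixed at its
base-case calibration, and reruns every strategy.  When the low tier alone
cannot fund budget neutrality (narrow ICER distributions), the documented
fallback raises intermediate- and low-tier cost sharing together; the
affected cells are flagged rather than crashing the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .config import RunConfig, build_model_from_config
from .engine import run as engine_run
from .model import InfeasibilityError, Model, ScenarioSpec
from .strategies import apply_strategy1, solve_neutral_copay, solve_strategy3

COLUMNS = ("no_vbid", "s1", "s2_societal", "s2_payer", "s2_patient", "s3")


@dataclass(frozen=True)
class SensitivityScenario:
    name: str
    label: str
    overrides: dict = field(default_factory=dict)


#: The standard one-way grid (base case first).
STANDARD_SCENARIOS: tuple[SensitivityScenario, ...] = (
    SensitivityScenario("base", "Base case", {}),
    SensitivityScenario(
        "estimable_50",
        "Only can estimate value for 50% of expenditures",
        {"distribution.estimable_fraction": 0.5}),
    SensitivityScenario(
        "elasticity_high", "Elasticity of demand is higher (-0.39)",
        {"demand.elasticity": -0.39}),
    SensitivityScenario(
        "elasticity_low", "Elasticity of demand is lower (-0.23)",
        {"demand.elasticity": -0.23}),
    SensitivityScenario(
        "inelastic_31",
        "31% of expenditures (inpatient care) completely inelastic",
        {"demand.inelastic_spending_fraction": 0.31}),
    SensitivityScenario(
        "sigma_wide_13", "ICER distribution wider (SD 1.3 log units)",
        {"distribution.sigma_log10": 1.3}),
    SensitivityScenario(
        "sigma_narrow_03", "ICER distribution narrower (SD 0.3 log units)",
        {"distribution.sigma_log10": 0.3}),
    SensitivityScenario(
        "uniform_family", "ICER distribution uniform rather than lognormal",
        {"distribution.family": "uniform"}),
    SensitivityScenario(
        "ineffective_30", "30% of expenditures are ineffective",
        {"distribution.ineffective_fraction": 0.30}),
    SensitivityScenario(
        "copay_unsuitable_31",
        "31% of expenditures intrinsically unsuitable for copays",
        {"unsuitable_fraction": 0.31}),
    SensitivityScenario(
        "high_threshold_50k", "High-value threshold $50k/LY",
        {"tiers.high_max": 50_000.0}),
)


def scenario_model(base_config: RunConfig, scenario: SensitivityScenario,
                   base_model: Model) -> tuple[Model, float]:
    """Recalibrated model for one sensitivity row.

    The distribution median is re-solved against the life-expectancy anchor
    (the no-VBID column stays at 4.70 for every row); the baseline
    coinsurance is carried over from the base calibration.
    """
    cfg = base_config.with_overrides(scenario.overrides)
    cfg = cfg.with_overrides(
        {"baseline_coinsurance": base_model.baseline_coinsurance})
    model = build_model_from_config(cfg)
    return model, cfg.unsuitable_fraction


def _solve_with_fallback(solver, *args, **kwargs):
    """(spec, flag): retry with the intermediate-tier fallback on
    infeasibility; a doubly infeasible cell is reported, not raised."""
    try:
        return solver(*args, **kwargs), ""
    except InfeasibilityError:
        try:
            return solver(*args, **kwargs, raise_intermediate=True), "fallback"
        except InfeasibilityError:
            return None, "infeasible"


def _strategy_specs(model: Model, unsuitable: float, scope: float = 1.0
                    ) -> dict[str, tuple[Optional[ScenarioSpec], str]]:
    """Resolve every strategy column, flagging fallback/infeasible cells."""
    out: dict[str, tuple[Optional[ScenarioSpec], str]] = {
        "no_vbid": (model.baseline_spec(unsuitable), ""),
        "s1": (apply_strategy1(model, scope, unsuitable), ""),
    }
    for persp in ("societal", "payer", "patient"):
        out[f"s2_{persp}"] = _solve_with_fallback(
            solve_neutral_copay, model, persp, scope, unsuitable)
    out["s3"] = _solve_with_fallback(solve_strategy3, model, scope, unsuitable)
    return out


def run_grid(base_config: RunConfig, base_model: Optional[Model] = None,
             scenarios: Optional[Sequence[SensitivityScenario]] = None, *,
             method: str = "analytic", n_persons: Optional[int] = None,
             seed: int = 0, scope: float = 1.0) -> pd.DataFrame:
    """Strategy-wise LE-gain table, one row per sensitivity scenario.

    ``method="analytic"`` evaluates the closed forms; ``"monte-carlo"`` runs
    the engine at ``n_persons`` with common random numbers across columns.
    Cells solved with the intermediate-tier fallback get ``flag='fallback'``.
    """
    if method not in ("analytic", "monte-carlo"):
        raise ValueError(f"unknown method {method!r}")
    if base_model is None:
        base_model = build_model_from_config(base_config)
    scenarios = tuple(scenarios if scenarios is not None else STANDARD_SCENARIOS)

    rows = []
    for scen in scenarios:
        model, unsuitable = scenario_model(base_config, scen, base_model)
        specs = _strategy_specs(model, unsuitable, scope)
        row: dict = {"scenario": scen.name, "label": scen.label}
        flags = []
        for col in COLUMNS:
            spec, flag = specs[col]
            if spec is None:
                row[col] = float("nan")
            elif method == "analytic":
                row[col] = model.predict(spec).le_gain
            else:
                row[col] = engine_run(model, spec, n_persons=n_persons,
                                      seed=seed).le_gain
            if flag:
                flags.append(f"{col}:{flag}")
        for col in COLUMNS[1:]:
            row[f"delta_{col}"] = row[col] - row["no_vbid"]
        row["flag"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows).set_index("scenario")


def copay_unsuitable_variant(base_config: RunConfig, base_model: Model,
                             fraction: float = 0.31, *,
                             method: str = "analytic",
                             n_persons: Optional[int] = None,
                             seed: int = 0) -> pd.DataFrame:
    """The copay-unsuitable variant at an arbitrary spending fraction.

    Unsuitable spending carries no copay in any arm; suitable services'
    coinsurance is scaled so cohort-level mean cost sharing matches the base
    model, which concentrates cost sharing — and hence the VBID response —
    on the suitable services.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    scen = SensitivityScenario(
        "copay_unsuitable", f"{fraction:.0%} unsuitable for copays",
        {"unsuitable_fraction": fraction})
    return run_grid(base_config, base_model, [scen], method=method,
                    n_persons=n_persons, seed=seed)
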