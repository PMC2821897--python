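import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vbidsim import RunConfig, build_model_from_config, run
from vbidsim.strategies import apply_strategy1, solve_strategy3

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Cohort size for Monte-Carlo smoke checks (the full-scale runs live in
#: scripts/acceptance.py).
SMOKE_N = 100_000
SMOKE_SEED = 11


@pytest.fixture(scope="session")
def base_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def model(base_config):
    """Fully calibrated base-case model (shared; treat as read-only)."""
    return build_model_from_config(base_config)


@pytest.fixture(scope="session")
def mc_runs(model):
    """Common-random-number engine runs of the headline scenarios."""
    specs = {
        "baseline": model.baseline_spec(),
        "s1": apply_strategy1(model),
        "s1_pharmacy": apply_strategy1(model, scope_fraction=0.10),
        "s3": solve_strategy3(model),
    }
    return {name: run(model, spec, n_persons=SMOKE_N, seed=SMOKE_SEED)
            for name, spec in specs.items()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20100216)
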