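import math

import pytest

from cbcprs.eligibility import apply_eligibility, build_risk_intervals
from cbcprs.simulate import SimulationConfig, simulate_study


def make_intervals(
    n_subjects: int,
    seed: int,
    beta_true: float = math.log(1.12),
    gamma_true: float = 0.0,
    event_definition: str = "all_cbc",
    **config_kwargs,
):
    """Simulate (z iid standard normal), apply eligibility, build intervals."""
    cfg = SimulationConfig(
        n_subjects=n_subjects,
        beta_true=beta_true,
        gamma_true=gamma_true,
        seed=seed,
        **config_kwargs,
    )
    study = simulate_study(cfg, with_genotypes=False)
    eligible, _ = apply_eligibility(study["records_complete"])
    return build_risk_intervals(eligible, event_definition).intervals


@pytest.fixture(scope="session")
def midsize_intervals():
    """One shared 3,000-subject cohort with a true per-SD HR of 1.12."""
    return make_intervals(3000, seed=42)


@pytest.fixture(scope="session")
def null_intervals():
    """Cohort generated with no PRS effect."""
    return make_intervals(2000, seed=43, beta_true=0.0)
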