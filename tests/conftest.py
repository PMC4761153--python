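"""Shared fixtures: simulation scenarios reused across acceptance tests.

The forward-simulation scenarios are the expensive part of the suite, so
each demography x selection combination is run once per session and shared
by every test that needs it. Replicate counts are reduced relative to the
standalone analysis scripts; tolerances in the tests are Monte-Carlo-aware
(3 SE bands or the stated relative tolerance).
"""

from __future__ import annotations

import numpy as np
import pytest

from sfsweep.simulate import (
    DFEConfig,
    SimulationConfig,
    constant_schedule,
    growth_schedule,
    mean_theta_by_size,
    run_simulation,
)

# rescaling factors chosen so the largest sample (512 haplotypes) stays a
# small fraction of the smallest sampled population (<= ~0.11) and the final
# size stays above 1,024 haplotypes in both branches
LAMBDA_CONSTANT = 4
LAMBDA_EXPONENTIAL = 100

SAMPLE_SIZES = (16, 32, 64, 128, 256, 512)


def scenario_config(branch: str, mean_gamma: float, n_replicates: int, seed: int) -> SimulationConfig:
    lam = LAMBDA_EXPONENTIAL if branch == "exponential-branch" else LAMBDA_CONSTANT
    return SimulationConfig(
        demography=growth_schedule(branch),
        dfe=DFEConfig(
            mean_gamma=mean_gamma,
            neutral_fraction=1.0 if mean_gamma == 0 else 0.0,
        ),
        rescale_lambda=lam,
        sample_sizes=SAMPLE_SIZES,
        n_replicates=n_replicates,
        seed=seed,
        burn_in_factor=10.0,
    )


def run_scenario(branch: str, mean_gamma: float, n_replicates: int, seed: int):
    cfg = scenario_config(branch, mean_gamma, n_replicates, seed)
    reps = run_simulation(cfg)
    return cfg, reps, mean_theta_by_size(reps)


@pytest.fixture(scope="session")
def exponential_neutral():
    """Neutral loci through the exponential-growth branch."""
    return run_scenario("exponential-branch", 0.0, 250, 101)


@pytest.fixture(scope="session")
def exponential_gamma2000():
    """Strongly constrained loci (gamma_bar = 2000), exponential growth."""
    return run_scenario("exponential-branch", 2000.0, 250, 102)


@pytest.fixture(scope="session")
def constant_gamma_grid():
    """Constant-growth branch across the gamma_bar grid {2, 20, 200, 2000}."""
    out = {}
    for gamma, reps, seed in ((2.0, 150, 103), (20.0, 80, 104), (200.0, 80, 105), (2000.0, 150, 106)):
        out[gamma] = run_scenario("constant-branch", gamma, reps, seed)
    return out


@pytest.fixture(scope="session")
def neutral_constant_size():
    """Plain constant-size neutral population (theta check against 4 N mu)."""
    cfg = SimulationConfig(
        seq_length=5_000,
        base_Ne=512,
        mu=2e-7,
        demography=constant_schedule(512),
        dfe=DFEConfig(neutral_fraction=1.0),
        sample_sizes=SAMPLE_SIZES,
        n_replicates=500,
        seed=107,
        burn_in_factor=8.0,
    )
    reps = run_simulation(cfg)
    return cfg, reps, mean_theta_by_size(reps)


def slope_with_ci(df, stat="theta_w_mean", alpha_t=2.776):
    """Log2-log2 OLS slope and half-width of its ~95% CI (t, 4 dof)."""
    from scipy import stats as sps

    x = np.log2(df["sample_size"].to_numpy(dtype=float))
    y = np.log2(df[stat].to_numpy(dtype=float))
    res = sps.linregress(x, y)
    return res.slope, alpha_t * res.stderr
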