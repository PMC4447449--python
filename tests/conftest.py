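"""Shared fixtures.

The heavy Wright–Fisher runs are session-scoped so the accuracy criteria
share one set of simulations.  Replicate counts are the desk-scale study
conditions: 5 replicate 30 kb sequences at μ = ρ = 1e-4 and 30 at 1e-5
(diversity is ten-fold lower there, so more sequences are pooled).
"""
from __future__ import annotations

import numpy as np
import pytest

from thetacall.simulate import SimulationConfig, run_experiment


@pytest.fixture(scope="session")
def t1_records():
    """Main validation runs: N=100, mu=rho=1e-4, 5 replicates."""
    cfg = SimulationConfig(
        N=100, L=30000, mu=1e-4, rho=1e-4, n_replicates=5, seed=101
    )
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def low_rate_records():
    """Low-rate runs: N=100, mu=rho=1e-5, 30 replicates."""
    cfg = SimulationConfig(
        N=100, L=30000, mu=1e-5, rho=1e-5, n_replicates=30, seed=102
    )
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def n50_records():
    """Small-population runs: N=50, mu=rho=1e-4, 5 replicates."""
    cfg = SimulationConfig(
        N=50, L=30000, mu=1e-4, rho=1e-4, n_replicates=5, seed=103
    )
    return run_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
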