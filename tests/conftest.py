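import numpy as np
import pandas as pd
import pytest

from airbw.simulate import (SimConfig, lattice_weights, simulate_lattice,
                            simulate_tract_covariates, simulate_true_effects)


@pytest.fixture(scope="session")
def lattice15():
    """15 x 15 tract lattice with rook weights, shared across tests."""
    tracts = simulate_lattice(15)
    return tracts, lattice_weights(tracts)


@pytest.fixture(scope="session")
def small_cohort():
    """Small full synthetic cohort (5 x 5 lattice) for integration-style tests."""
    from airbw.simulate import simulate_cohort
    cfg = SimConfig(grid_side=5, births_per_tract_range=(60, 120), seed=42)
    births, tracts, weights, truth = simulate_cohort(cfg)
    return births, tracts, weights, truth, cfg


def synthetic_stage2_inputs(rep: int, lattice, noise_sd: float = 0.3,
                            sim_kwargs: dict | None = None):
    """Stage-two inputs with known truth: slopes observed with iid noise.

    Emulates stage-one output (posterior means with known sampling sd) so
    stage two can be exercised directly against the generating truth.
    """
    tracts0, W = lattice
    cfg = SimConfig(seed=1000 + rep, **(sim_kwargs or {}))
    tracts = simulate_tract_covariates(tracts0, seed=2000 + rep, weights=W)
    truth = simulate_true_effects(tracts, W, cfg, seed=3000 + rep)
    rng = np.random.default_rng(4000 + rep)
    table = pd.DataFrame({
        "tract_id": tracts["tract_id"],
        "beta_mean": truth.beta_true + rng.normal(0.0, noise_sd, len(tracts)),
        "beta_sd": noise_sd,
    })
    return table, tracts, W, truth, cfg
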