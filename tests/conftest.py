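import logging

import numpy as np
import pytest

import dmdgp
from dmdgp.simulate import (
    gapped_days,
    simulate_genotypes,
    simulate_operator_family,
    simulate_trajectories,
)

logging.getLogger("dmdgp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_population():
    """A compact noise-free population with genotype-dependent dynamics."""
    G = simulate_genotypes(40, 30, seed=11)
    truth = simulate_operator_family(
        G, p=6, r_true=2, entry_h2=1.0, seed=12,
        spectral_interval=(0.7, 1.0), effect_scale=0.005,
    )
    tensor = simulate_trajectories(
        truth, gapped_days(), noise_sd=0.0,
        x1_spec={"genetic_h2": 1.0, "genetic_sd": 0.02, "noise_sd": 0.0}, seed=13,
    )
    return G, tensor, truth


@pytest.fixture(scope="session")
def noisy_population():
    """Moderate heritability with measurement noise (fast, 60 lines)."""
    G = simulate_genotypes(60, 80, seed=21)
    truth = simulate_operator_family(
        G, p=5, r_true=2, entry_h2=0.5, seed=22,
        spectral_interval=(0.7, 1.05), effect_scale=0.03,
    )
    tensor = simulate_trajectories(
        truth, gapped_days(), noise_sd=0.05,
        x1_spec={"genetic_h2": 0.5, "genetic_sd": 0.3, "noise_sd": 0.05}, seed=23,
    )
    return G, tensor, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def single_model(small_population):
    G, tensor, _ = small_population
    pair = dmdgp.build_snapshot_pair(tensor, tensor.line_ids[0])
    return dmdgp.fit_schur_dmd(pair, r=2)
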