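"""Shared fixtures: tiny enumerable landscapes and simulation helpers."""

from __future__ import annotations

import numpy as np
import pytest

import ssafold as sf


@pytest.fixture(scope="session")
def toy_energy_model():
    return sf.ToyEnergyModel()


@pytest.fixture(scope="session")
def toy_config(toy_energy_model):
    return sf.SimulationConfig(
        energy=toy_energy_model,
        rates=sf.RateModel("metropolis", toy_energy_model.RT),
    )


@pytest.fixture(scope="session")
def hairpin_space(toy_energy_model):
    """GAAAC: the 2-state landscape {open chain, single hairpin}."""
    return sf.build_state_space(sf.TOY_HAIRPIN, toy_energy_model)


@pytest.fixture(scope="session")
def triplex_space(toy_energy_model):
    """GGGAAACCC: a small funnel landscape with a 3-pair stem."""
    return sf.build_state_space(sf.TOY_TRIPLEX, toy_energy_model)


def run_trajectories(seq, target, config, n, seed, start=None):
    """First-passage times of n independent single-molecule runs,
    sharing one RNG stream, cache and energy cache."""
    start = start if start is not None else sf.open_chain(len(seq))
    rng = np.random.default_rng(seed)
    cache = config.new_cache()
    ecache: dict = {}
    out = []
    for _ in range(n):
        traj = sf.simulate_fold(seq, start, target, config, rng=rng,
                                cache=cache, ecache=ecache, record=False)
        assert traj.terminated_reason == "target_reached"
        out.append(traj.first_passage_time)
    return np.asarray(out)


@pytest.fixture(scope="session")
def run_many():
    return run_trajectories
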