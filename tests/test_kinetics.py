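"""SSA kernels: rates, event rule, reproducibility, ensembles, caching."""

import math

import numpy as np
import pytest

import ssafold as sf
from ssafold.errors import AbsorbingStateError

from conftest import run_trajectories


class TestTransitionRate:
    def test_metropolis_downhill_is_one(self):
        model = sf.RateModel("metropolis")
        assert sf.transition_rate(-1.5, model) == 1.0
        assert sf.transition_rate(-0.001, model) == 1.0

    def test_metropolis_uphill(self):
        model = sf.RateModel("metropolis")
        assert sf.transition_rate(model.RT * math.log(2), model) \
            == pytest.approx(0.5)

    def test_kawasaki(self):
        model = sf.RateModel("kawasaki")
        assert sf.transition_rate(0.0, model) == pytest.approx(1.0)
        assert sf.transition_rate(2 * model.RT, model) \
            == pytest.approx(math.exp(-1.0))

    @pytest.mark.parametrize("kind", ["metropolis", "kawasaki"])
    def test_detailed_balance_ratio(self, kind):
        """rate(i->j)/rate(j->i) = exp(-dG/RT) for random dG."""
        model = sf.RateModel(kind)
        rng = np.random.default_rng(1)
        for dg in rng.normal(0, 3, 50):
            fwd = sf.transition_rate(dg, model)
            bwd = sf.transition_rate(-dg, model)
            assert fwd / bwd == pytest.approx(math.exp(-dg / model.RT))

    def test_overflow_clamped(self):
        from ssafold.kinetics import MAX_RATE

        model = sf.RateModel("kawasaki")
        assert sf.transition_rate(-1e5, model) == MAX_RATE


class TestSSAStep:
    def test_cumulative_selection_rule(self):
        # smallest j with cumsum[j] > xi1 * a_sum (0-based)
        j, _ = sf.ssa_step([1.0, 3.0], 4.0, 0.2, 0.5)
        assert j == 0  # cumsum[0] = 1 > 0.8
        j, _ = sf.ssa_step([1.0, 3.0], 4.0, 0.5, 0.5)
        assert j == 1  # 1 <= 2.0 < 4

    def test_waiting_time(self):
        _, tau = sf.ssa_step([2.0], 2.0, 0.5, math.exp(-1.0))
        assert tau == pytest.approx(0.5)

    def test_absorbing_state_raises(self):
        with pytest.raises(AbsorbingStateError):
            sf.ssa_step([], 0.0, 0.5, 0.5)


class TestBuildRates:
    def test_absorbing_target_has_zero_rates(self, toy_energy_model):
        nb, rates, a_sum = sf.build_rates(
            sf.TOY_HAIRPIN, "(...)", toy_energy_model,
            sf.RateModel("metropolis"), absorbing=True)
        assert len(nb) == 0 and a_sum == 0.0

    def test_downhill_single_neighbor(self, toy_energy_model):
        nb, rates, a_sum = sf.build_rates(
            sf.TOY_HAIRPIN, ".....", toy_energy_model,
            sf.RateModel("metropolis", toy_energy_model.RT))
        assert nb.structs == ["(...)"]
        assert rates[0] == 1.0  # dG = -3.0 < 0

    def test_cache_hit_is_identical(self, toy_energy_model):
        cache = sf.NeighborhoodCache(100)
        model = sf.RateModel("metropolis", toy_energy_model.RT)
        first = sf.build_rates(sf.TOY_TRIPLEX, ".........",
                               toy_energy_model, model, cache=cache)
        second = sf.build_rates(sf.TOY_TRIPLEX, ".........",
                                toy_energy_model, model, cache=cache)
        assert first[0].structs == second[0].structs
        assert np.array_equal(first[1], second[1])
        assert cache.hits >= 1


class TestSimulateFold:
    def test_start_equals_target(self, toy_config):
        traj = sf.simulate_fold(sf.TOY_HAIRPIN, "(...)", "(...)",
                                toy_config, seed=0)
        assert traj.first_passage_time == 0.0
        assert len(traj.records) == 1
        assert traj.terminated_reason == "target_reached"

    def test_two_state_mean_folding_time(self, toy_config):
        """open -> hairpin is downhill with rate 1: first-passage times
        are Exp(1); the empirical mean must sit within 3 s.e. of 1."""
        times = run_trajectories(sf.TOY_HAIRPIN, "(...)", toy_config,
                                 n=10_000, seed=42)
        se = times.std(ddof=1) / math.sqrt(len(times))
        assert abs(times.mean() - 1.0) < 3 * se

    def test_reproducible_from_seed(self, toy_config):
        a = sf.simulate_fold(sf.TOY_TRIPLEX, "." * 9, "(((...)))",
                             toy_config, seed=7)
        b = sf.simulate_fold(sf.TOY_TRIPLEX, "." * 9, "(((...)))",
                             toy_config, seed=7)
        assert a.records == b.records

    def test_times_strictly_increasing(self, toy_config):
        traj = sf.simulate_fold(sf.TOY_TRIPLEX, "." * 9, "(((...)))",
                                toy_config, seed=3)
        times = [t for t, _, _ in traj.records]
        assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))
        structs = [s for _, s, _ in traj.records]
        for s1, s2 in zip(structs, structs[1:]):
            assert sf.base_pair_distance(s1, s2) in (1, 2)

    def test_step_limit_returns_truncated(self, toy_energy_model):
        config = sf.SimulationConfig(energy=toy_energy_model, max_steps=3)
        traj = sf.simulate_fold(sf.TOY_TRIPLEX, "." * 9, "(((...)))",
                                config, seed=12)
        if traj.terminated_reason == "step_limit":
            assert traj.first_passage_time is None
            assert traj.n_steps == 3


class TestCacheTransparency:
    def test_capacity_does_not_change_events(self, toy_energy_model):
        """LRU capacities 0, 10, 10000 yield event-identical paths."""
        runs = []
        for capacity in (0, 10, 10_000):
            config = sf.SimulationConfig(energy=toy_energy_model,
                                         cache_capacity=capacity)
            traj = sf.simulate_fold(sf.TOY_TRIPLEX, "." * 9, "(((...)))",
                                    config, seed=99)
            runs.append(traj.records)
        assert runs[0] == runs[1] == runs[2]


class TestEnsemble:
    def test_single_molecule_matches_version_one(self, toy_config):
        traj = sf.simulate_fold(sf.TOY_TRIPLEX, "." * 9, "(((...)))",
                                toy_config, seed=5)
        records, state = sf.simulate_ensemble(
            [(sf.TOY_TRIPLEX, "." * 9, "(((...)))")], toy_config, seed=5)
        assert records[0].folded
        assert records[0].fold_time == traj.first_passage_time
        assert state.n_events == traj.n_steps

    def test_all_molecules_fold(self, toy_config):
        specs = [(sf.TOY_TRIPLEX, "." * 9, "(((...)))")] * 20
        records, state = sf.simulate_ensemble(specs, toy_config, seed=8)
        assert state.all_folded
        assert all(r.folded and r.fold_time > 0 for r in records)
        assert all(r.bp_distance_remaining == 0 for r in records)

    def test_empty_specs_rejected(self, toy_config):
        with pytest.raises(ValueError):
            sf.simulate_ensemble([], toy_config, seed=1)

    def test_start_at_target_counts_as_folded_at_zero(self, toy_config):
        records, _ = sf.simulate_ensemble(
            [(sf.TOY_HAIRPIN, "(...)", "(...)")], toy_config, seed=1)
        assert records[0].folded and records[0].fold_time == 0.0

    def test_mixed_sequences_cosimulated(self, toy_config):
        specs = [(sf.TOY_HAIRPIN, ".....", "(...)"),
                 (sf.TOY_TRIPLEX, "." * 9, "(((...)))")]
        records, state = sf.simulate_ensemble(specs, toy_config, seed=2)
        assert state.all_folded
        assert {r.sequence for r in records} == {sf.TOY_HAIRPIN,
                                                 sf.TOY_TRIPLEX}


class TestAnytimeExtraction:
    def test_extract_at_zero_and_infinity(self, toy_config):
        specs = [(sf.TOY_TRIPLEX, "." * 9, "(((...)))")] * 10
        _, state = sf.simulate_ensemble(specs, toy_config, seed=4)
        folded, unfolded = sf.extract_results(state, math.inf)
        assert len(folded) == 10 and not unfolded
        folded, unfolded = sf.extract_results(state, 0.0)
        assert not folded and len(unfolded) == 10
        # after a completed run the remaining distance is zero
        assert all(d == 0 for _, d in unfolded)

    def test_interrupt_and_resume_is_exact(self, toy_config):
        """Stopping at an intermediate horizon and resuming reproduces
        the uninterrupted run event for event."""
        specs = [(sf.TOY_TRIPLEX, "." * 9, "(((...)))")] * 30
        full, _ = sf.simulate_ensemble(specs, toy_config, seed=11)
        part, state = sf.simulate_ensemble(specs, toy_config, seed=11,
                                           stop_time=2.0)
        assert any(not r.folded for r in part)
        resumed, state = sf.simulate_ensemble(None, toy_config, state=state)
        assert [r.fold_time for r in resumed] == [r.fold_time for r in full]

    def test_unfolded_report_distance(self, toy_config):
        specs = [(sf.TOY_TRIPLEX, "." * 9, "(((...)))")] * 10
        _, state = sf.simulate_ensemble(specs, toy_config, seed=13,
                                        stop_time=0.05)
        folded, unfolded = sf.extract_results(state, 0.05)
        # distance counts pairs still to form plus wrong pairs to undo:
        # bounded by |target pairs| + max pairs of a 9-mer (3 each)
        for _, dist in unfolded:
            assert 0 < dist <= 6


def test_mfe_structure_toy():
    assert sf.mfe_structure(sf.TOY_HAIRPIN, sf.ToyEnergyModel()) == "(...)"
    assert sf.mfe_structure(sf.TOY_TRIPLEX, sf.ToyEnergyModel()) \
        == "(((...)))"
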