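"""Monte Carlo correctness: Metropolis limits, Boltzmann statistics,
replica exchange, and pool bookkeeping."""

import numpy as np
import pytest
from scipy import integrate, stats

from flexsaxs.energy import KB_KCAL, EnergyCalculator, EnergyModel
from flexsaxs.sampler import (MCState, REMCConfig, mc_sweep, plan_pool_size,
                              run_remc, swap_acceptance_probability)
from flexsaxs.synthetic import SyntheticSpec, make_toy_complex
from flexsaxs.topology import Bead, ComplexTopology, LinkerChain


class TestPlanPoolSize:
    @pytest.mark.parametrize("kwargs,expected", [
        # solution protocol: 2 runs x 16 replicas x 5e6 sweeps / 1000
        (dict(n_runs=2, n_replicas=16, n_sweeps=5_000_000, save_interval=1000,
              save_policy="all"), 160_000),
        # membrane protocol: 20 runs x 8 replicas, room-T only
        (dict(n_runs=20, n_replicas=8, n_sweeps=2_500_000, save_interval=1000,
              save_policy="lowest", membrane=True), 50_000),
        (dict(n_runs=1, n_replicas=1, n_sweeps=1000, save_interval=1000),
         1),
    ])
    def test_protocol_bookkeeping(self, kwargs, expected):
        assert plan_pool_size(REMCConfig(**kwargs)) == expected

    def test_trajectory_count_solution_protocol(self):
        cfg = REMCConfig(n_runs=2, n_replicas=16, n_sweeps=5_000_000,
                         save_interval=1000, save_policy="all")
        assert cfg.n_runs * cfg.n_replicas == 32
        assert plan_pool_size(cfg) // (cfg.n_runs * cfg.n_replicas) == 5000

    def test_sweeps_must_divide_save_interval(self):
        with pytest.raises(ValueError):
            REMCConfig(n_sweeps=1500, save_interval=1000)


def _free_bead_state(external=None):
    beads = [Bead(0, "G", np.zeros(3), 0.0, "l0")]
    topo = ComplexTopology(beads, [], [LinkerChain("l0", np.array([0]))])
    model = EnergyModel(external=external)
    calc = EnergyCalculator(topo, model)
    return MCState(topo, calc), topo


class TestMCSweep:
    def test_zero_amplitude_moves_accept_and_hold(self, dumbbell):
        topo, _ = dumbbell
        calc = EnergyCalculator(topo, EnergyModel())
        state = MCState(topo, calc)
        before = state.coords.copy()
        cfg = REMCConfig(n_sweeps=1000, save_interval=1000,
                         translation_amp=0.0, rotation_amp=0.0,
                         linker_amp=0.0, pivot_amp=0.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            mc_sweep(state, 300.0, rng, cfg)
        np.testing.assert_allclose(state.coords, before, atol=1e-12)
        assert state.n_accepted == state.n_attempted

    def test_infinite_temperature_accepts_everything(self):
        state, _ = _free_bead_state(
            external=lambda c: 10.0 * float(np.sum(c**2)))
        cfg = REMCConfig(n_sweeps=1000, save_interval=1000, linker_amp=2.0)
        rng = np.random.default_rng(4)
        for _ in range(1000):
            mc_sweep(state, np.inf, rng, cfg)
        assert state.n_accepted == state.n_attempted == 1000

    def test_rigid_bodies_stay_rigid_through_sampling(self, dumbbell):
        from scipy.spatial.distance import pdist

        topo, _ = dumbbell
        calc = EnergyCalculator(topo, EnergyModel())
        state = MCState(topo, calc)
        reference = [pdist(state.coords[b.bead_indices])
                     for b in topo.rigid_bodies]
        cfg = REMCConfig(n_sweeps=1000, save_interval=1000)
        rng = np.random.default_rng(9)
        for _ in range(200):
            mc_sweep(state, 400.0, rng, cfg)
        for body, ref_d in zip(topo.rigid_bodies, reference):
            np.testing.assert_allclose(pdist(state.coords[body.bead_indices]),
                                       ref_d, atol=1e-6)

    def test_harmonic_well_variance(self):
        # z-variance of a bead in 0.5 k z^2 must equal k_B T / k
        k = 0.1
        state, _ = _free_bead_state(
            external=lambda c: 0.5 * k * float(np.sum(c[:, 2] ** 2)))
        cfg = REMCConfig(n_sweeps=1000, save_interval=1000, linker_amp=3.0)
        rng = np.random.default_rng(11)
        temperature = 300.0
        zs = np.empty(60_000)
        for s in range(60_000):
            mc_sweep(state, temperature, rng, cfg)
            zs[s] = state.coords[0, 2]
        expected = KB_KCAL * temperature / k
        assert zs[2000:].var() == pytest.approx(expected, rel=0.05)

    def test_three_state_boltzmann_occupancies(self):
        # triple-well potential in z with enumerable (quadrature) weights
        a, tilt = 6.5e-4, 0.15

        def v(z):
            return a * z * z * (z * z - 25.0) ** 2 + tilt * z

        state, _ = _free_bead_state(
            external=lambda c: float(np.sum(v(c[:, 2]))))
        cfg = REMCConfig(n_sweeps=1000, save_interval=1000, linker_amp=3.0)
        rng = np.random.default_rng(3)
        temperature = 300.0
        beta = 1 / (KB_KCAL * temperature)
        samples = []
        for s in range(150_000):
            mc_sweep(state, temperature, rng, cfg)
            if s >= 10_000 and s % 20 == 0:
                samples.append(state.coords[0, 2])
        counts = np.histogram(samples, bins=[-np.inf, -2.5, 2.5, np.inf])[0]
        weights = [integrate.quad(lambda z: np.exp(-beta * v(z)), lo, hi)[0]
                   for lo, hi in [(-15, -2.5), (-2.5, 2.5), (2.5, 15)]]
        p = np.array(weights) / np.sum(weights)
        _, pval = stats.chisquare(counts, p * counts.sum())
        assert pval > 0.01


class TestReplicaExchange:
    def test_equal_temperature_swap_probability_is_one(self):
        assert swap_acceptance_probability(5.0, -3.0, 300.0, 300.0) == 1.0
        assert swap_acceptance_probability(-3.0, 5.0, 300.0, 300.0) == 1.0

    def test_same_seed_is_bit_identical(self, anchored_dumbbell):
        topo, _ = anchored_dumbbell
        cfg = REMCConfig(n_runs=2, n_replicas=3, n_sweeps=300,
                         save_interval=100, save_policy="all", seed=21,
                         t_min=300, t_max=400, membrane=True)
        pool_a = run_remc(topo, EnergyModel(), cfg)
        pool_b = run_remc(topo, EnergyModel(), cfg)
        assert len(pool_a) == len(pool_b) == plan_pool_size(cfg)
        for a, b in zip(pool_a.conformations, pool_b.conformations):
            assert np.array_equal(a.coords, b.coords)
            assert a.energy == b.energy

    def test_recorded_energies_match_recomputation(self, dumbbell):
        topo, _ = dumbbell
        model = EnergyModel()
        cfg = REMCConfig(n_runs=1, n_replicas=2, n_sweeps=500,
                         save_interval=100, save_policy="all", seed=8)
        pool = run_remc(topo, model, cfg)
        calc = EnergyCalculator(topo, model)
        for conf in pool.conformations:
            full = calc.total(np.ascontiguousarray(conf.coords))
            assert conf.energy == pytest.approx(full, abs=1e-6)

    def test_saved_temperatures_are_ladder_members(self, dumbbell):
        topo, _ = dumbbell
        cfg = REMCConfig(n_runs=1, n_replicas=4, n_sweeps=400,
                         save_interval=100, save_policy="all", seed=2)
        pool = run_remc(topo, EnergyModel(), cfg)
        ladder = set(np.round(cfg.temperature_ladder(), 10))
        seen = {round(c.replica_temperature, 10) for c in pool.conformations}
        assert seen == ladder

    def test_two_well_occupancy_vs_quadrature(self):
        # asymmetric double well: REMC at two temperatures must reproduce
        # the 300 K Boltzmann occupancies of the two basins
        a, tilt = 6.0e-4, 0.1

        def v(z):
            return a * (z * z - 25.0) ** 2 + tilt * z

        beads = [Bead(0, "G", np.zeros(3), 0.0, "l0")]
        topo = ComplexTopology(beads, [], [LinkerChain("l0", np.array([0]))])
        model = EnergyModel(external=lambda c: float(np.sum(v(c[:, 2]))))
        cfg = REMCConfig(n_runs=1, n_replicas=2, t_min=300.0, t_max=600.0,
                         n_sweeps=200_000, save_interval=20,
                         save_policy="lowest", seed=13, linker_amp=3.0)
        pool = run_remc(topo, model, cfg)
        zs = np.array([c.coords[0, 2] for c in pool.conformations])[500:]
        beta = 1 / (KB_KCAL * 300.0)
        w_low = integrate.quad(lambda z: np.exp(-beta * v(z)), -15, 0)[0]
        w_high = integrate.quad(lambda z: np.exp(-beta * v(z)), 0, 15)[0]
        expected = w_low / (w_low + w_high)
        observed = np.mean(zs < 0)
        assert observed == pytest.approx(expected, abs=0.05)

    def test_pool_size_matches_plan(self, dumbbell):
        topo, _ = dumbbell
        cfg = REMCConfig(n_runs=2, n_replicas=2, n_sweeps=300,
                         save_interval=100, save_policy="lowest", seed=1)
        assert len(run_remc(topo, EnergyModel(), cfg)) == plan_pool_size(cfg)
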