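"""Metropolis Monte Carlo: pair energies, detailed balance, move tuning,
initialisation protocols."""

import math

import numpy as np
import pytest

from slospt.geometry import RodConfiguration, segment_pair_metrics
from slospt.mc import (EnergyModel, SimulationConfig, SimulationState,
                       aligned_configuration, equilibrate, expansion_protocol,
                       metropolis_sweep, nematic_order, pair_energy,
                       random_configuration, sample_snapshots, total_energy,
                       truncated_shifted_energy, tune_move_sizes)

MODEL = EnergyModel(A_prime=3.0, kappa=1.0, D=1.0, d_c=4.0)


class TestPairEnergy:
    def test_contact_perpendicular_equals_amplitude(self):
        # at x = D the screening factor is unity: u = A' / sin(theta)
        assert pair_energy(1.0, 1.0, MODEL) == pytest.approx(3.0, rel=1e-14)

    def test_pure_exponential_screening(self):
        e0 = pair_energy(1.0, 1.0, MODEL)
        e1 = pair_energy(1.0 + 1.0 / MODEL.kappa, 1.0, MODEL)
        assert e1 == pytest.approx(e0 / math.e, rel=1e-12)

    def test_inverse_sine_angle_dependence(self):
        assert pair_energy(1.5, 0.5, MODEL) == pytest.approx(
            2 * pair_energy(1.5, 1.0, MODEL), rel=1e-12)

    def test_hard_core_is_infinite(self):
        assert pair_energy(0.99, 1.0, MODEL) == math.inf

    def test_sin_theta_floor_keeps_aligned_pairs_finite(self):
        assert np.isfinite(pair_energy(2.0, 0.0, MODEL))


class TestTruncatedShifted:
    def test_zero_at_and_beyond_cutoff(self):
        assert truncated_shifted_energy(MODEL.d_c, 0.7, MODEL) == 0.0
        assert truncated_shifted_energy(MODEL.d_c + 2.0, 0.7, MODEL) == 0.0

    def test_continuous_at_cutoff(self):
        eps = 1e-9
        just_inside = truncated_shifted_energy(MODEL.d_c - eps, 0.7, MODEL)
        assert 0 < just_inside < 1e-8

    def test_equals_bare_minus_angle_matched_shift(self, rng):
        for _ in range(200):
            x = rng.uniform(1.0, MODEL.d_c - 1e-6)
            s = rng.uniform(0.05, 1.0)
            expected = pair_energy(x, s, MODEL) - pair_energy(MODEL.d_c, s, MODEL)
            assert truncated_shifted_energy(x, s, MODEL) == pytest.approx(
                expected, rel=1e-12)


class TestMetropolis:
    def test_hard_overlap_always_rejected(self, rng):
        """Constructed overlapping trial positions are rejected every time."""
        box = np.full(3, 12.0)
        model = EnergyModel(A_prime=0.0, kappa=1.0, D=1.0, d_c=1.0 + 1e-9)
        legal = RodConfiguration(box=box, centers=[[6, 6, 6], [6, 8, 6]],
                                 orientations=[[0, 0, 1], [0, 0, 1]],
                                 L=3.0, D=1.0)
        sim = SimulationConfig(n_rods=2, L_over_D=3.0, max_disp=1.5,
                               n_sweeps_sample=1)
        state = SimulationState(configuration=legal, energy=0.0)
        for _ in range(200):
            metropolis_sweep(state, sim, model, rng)
            state.audit_energy(model)   # raises if an overlap ever slipped in

    def test_dilute_zero_amplitude_acceptance_near_unity(self, rng):
        model = EnergyModel(A_prime=0.0, kappa=1.0, D=1.0, d_c=1.0 + 1e-9)
        config = random_configuration(40, 3.0, 1.0, 0.005, rng)
        sim = SimulationConfig(n_rods=40, L_over_D=3.0, max_disp=0.2,
                               max_rot=0.2)
        state = SimulationState(configuration=config, energy=0.0)
        for _ in range(20):
            metropolis_sweep(state, sim, model, rng)
        assert state.acceptance_ratio() > 0.9

    def test_energy_cache_tracks_full_recomputation(self, rng):
        model = EnergyModel(A_prime=2.0, kappa=1.0, D=1.0, d_c=3.0)
        config = random_configuration(30, 3.0, 1.0, 0.03, rng)
        sim = SimulationConfig(n_rods=30, L_over_D=3.0)
        state = SimulationState(configuration=config,
                                energy=total_energy(config, model))
        for _ in range(30):
            metropolis_sweep(state, sim, model, rng)
        full = total_energy(state.configuration, model)
        assert state.energy == pytest.approx(full, abs=1e-8)

    def test_two_rod_distance_distribution_matches_boltzmann(self, rng):
        """Long MC run of two rods reproduces the Boltzmann-weighted axis
        distance distribution obtained by direct numerical integration."""
        L, D = 2.0, 1.0
        box = np.full(3, 8.0)
        model = EnergyModel(A_prime=4.0, kappa=1.0, D=D, d_c=2.5)
        sim = SimulationConfig(n_rods=2, L_over_D=L / D, max_disp=1.0,
                               max_rot=1.0, reorient_fraction=0.5)
        config = RodConfiguration(box=box, centers=[[2, 2, 2], [5, 5, 5]],
                                  orientations=[[0, 0, 1], [0, 1, 0]], L=L, D=D)
        state = SimulationState(configuration=config,
                                energy=total_energy(config, model))
        bins = np.array([1.0, 1.5, 2.0, 2.5, 3.5])
        counts = np.zeros(len(bins) - 1)
        n_sweeps = 12_000
        for k in range(n_sweeps):
            metropolis_sweep(state, sim, model, rng)
            if k % 2:
                c = state.configuration
                from slospt.geometry import minimum_image
                r12 = minimum_image(c.centers[1] - c.centers[0], box)
                x, _ = segment_pair_metrics(r12, c.orientations[0],
                                            c.orientations[1], L / 2)
                j = np.searchsorted(bins, float(x)) - 1
                if 0 <= j < len(counts):
                    counts[j] += 1
        mc_probs = counts / counts.sum()
        # oracle: direct Monte Carlo integration of the 2-body Boltzmann
        # weight over uniform configurations (independent of Metropolis)
        n_or = 400_000
        r = rng.uniform(0, 1, (n_or, 3)) * box
        r12 = r - box / 2
        r12 -= box * np.round(r12 / box)
        u = rng.normal(size=(n_or, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        u0 = rng.normal(size=(n_or, 3))
        u0 /= np.linalg.norm(u0, axis=1, keepdims=True)
        x, s = segment_pair_metrics(r12, u0, u, L / 2)
        w = np.where(x < D, 0.0, np.exp(-truncated_shifted_energy(x, s, model)))
        ref = np.array([np.sum(w[(x >= lo) & (x < hi)])
                        for lo, hi in zip(bins[:-1], bins[1:])])
        ref /= ref.sum()
        assert np.abs(mc_probs - ref).max() < 0.03


class TestTuning:
    def _state_with_ratio(self, n_accept, n_attempt):
        state = SimulationState(configuration=None, energy=0.0)
        state.accepted["translate"] = n_accept
        state.attempted["translate"] = n_attempt
        state.accepted["rotate"] = n_accept
        state.attempted["rotate"] = n_attempt
        return state

    def test_high_acceptance_grows_moves(self):
        sim = SimulationConfig(n_rods=8, max_disp=0.2, max_rot=0.2)
        tune_move_sizes(self._state_with_ratio(80, 100), sim)
        assert sim.max_disp > 0.2 and sim.max_rot > 0.2

    def test_low_acceptance_shrinks_moves(self):
        sim = SimulationConfig(n_rods=8, max_disp=0.2, max_rot=0.2)
        tune_move_sizes(self._state_with_ratio(10, 100), sim)
        assert sim.max_disp < 0.2 and sim.max_rot < 0.2

    def test_dilute_gas_saturates_at_caps(self):
        sim = SimulationConfig(n_rods=8, max_disp=2.0, max_rot=1.0,
                               max_disp_cap=2.0, max_rot_cap=1.0)
        saturated = tune_move_sizes(self._state_with_ratio(95, 100), sim)
        assert saturated
        assert sim.max_disp == 2.0 and sim.max_rot == 1.0


class TestProtocols:
    def test_aligned_configuration_is_overlap_free_and_aligned(self):
        config = aligned_configuration(64, 5.0, 1.0, 0.25)
        assert nematic_order(config.orientations) == pytest.approx(1.0)
        model = EnergyModel(A_prime=0.0, kappa=1.0, D=1.0, d_c=1.0 + 1e-9)
        assert total_energy(config, model) == 0.0

    def test_affine_expansion_preserves_structure(self):
        config = aligned_configuration(32, 4.0, 1.0, 0.2)
        frac = config.centers / config.box
        new_box = config.box * 1.3
        rescaled = RodConfiguration(box=new_box, centers=frac * new_box,
                                    orientations=config.orientations.copy(),
                                    L=config.L, D=config.D)
        np.testing.assert_allclose(rescaled.centers / rescaled.box, frac,
                                   atol=1e-12)
        np.testing.assert_array_equal(rescaled.orientations,
                                      config.orientations)

    def test_expansion_protocol_relaxes_aligned_start_at_low_density(self, rng):
        """From the aligned start the nematic order decays to the isotropic
        finite-size baseline once the density is low enough to rotate."""
        model = EnergyModel(A_prime=0.0, kappa=1.0, D=1.0, d_c=1.0 + 1e-9)
        sim = SimulationConfig(n_rods=64, L_over_D=3.0, n_sweeps_equil=150,
                               n_sweeps_sample=20, snapshot_interval=10)
        results = list(expansion_protocol(sim, model, [0.06, 0.03], rng,
                                          relax_sweeps=200))
        assert [phi for phi, _, _ in results] == [0.06, 0.03]
        s_final = nematic_order(results[-1][1].configuration.orientations)
        baseline = np.mean([nematic_order(
            rng.normal(size=(64, 3)) / np.linalg.norm(
                rng.normal(size=(64, 3)), axis=1, keepdims=True))
            for _ in range(20)])
        assert s_final < max(3 * baseline, 0.35)

    def test_expansion_requires_decreasing_schedule(self, rng):
        model = EnergyModel(A_prime=0.0, kappa=1.0, D=1.0, d_c=1.0 + 1e-9)
        sim = SimulationConfig(n_rods=16, L_over_D=3.0)
        with pytest.raises(ValueError, match="decreasing"):
            list(expansion_protocol(sim, model, [0.05, 0.1], rng))

    def test_seed_independence_of_sampled_alpha(self, rng):
        """Two seeds give insertion estimates within mutual error bars."""
        from slospt.widom import insertion_estimates
        model = EnergyModel(A_prime=0.0, kappa=1.0, D=1.0, d_c=1.0 + 1e-9)
        estimates = []
        for seed in (11, 12):
            r = np.random.default_rng(seed)
            config = random_configuration(64, 3.0, 1.0, 0.05, r)
            sim = SimulationConfig(n_rods=64, L_over_D=3.0,
                                   n_sweeps_sample=175, snapshot_interval=25)
            state = SimulationState(configuration=config, energy=0.0)
            equilibrate(state, sim, model, r, n_sweeps=200)
            snaps = sample_snapshots(state, sim, model, r)
            est, _ = insertion_estimates(snaps, 1.0, 20_000, r)
            estimates.append(est)
        diff = abs(estimates[0].alpha - estimates[1].alpha)
        err = math.hypot(estimates[0].std_err, estimates[1].std_err)
        assert diff < 4 * err
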