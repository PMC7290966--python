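"""Engine unit tests: energy conventions, Metropolis dynamics, observables."""

import numpy as np
import pytest

from conftest import exact_moments
from gimbrain.ising import (
    CouplingMatrix,
    SimulationParams,
    SpinTrace,
    delta_energy,
    metropolis_sweep,
    normalize_coupling,
    random_spins,
    simulate_at_temperature,
    susceptibility,
    total_energy,
)


class TestCouplingMatrix:
    def test_rejects_asymmetry_negative_and_allzero(self):
        with pytest.raises(ValueError, match="symmetric"):
            CouplingMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="negative"):
            CouplingMatrix(np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError, match="all-zero"):
            CouplingMatrix(np.zeros((3, 3)))

    def test_normalize_scales_max_to_one_and_zeroes_diagonal(self):
        out = normalize_coupling(np.array([[0.0, 4.0], [4.0, 0.0]]))
        np.testing.assert_allclose(out.J, [[0, 1], [1, 0]])
        assert out.normalization == "max_one"
        # self-coupling removed before scaling
        out = normalize_coupling(np.array([[5.0, 4.0], [4.0, 5.0]]))
        np.testing.assert_allclose(out.J, [[0, 1], [1, 0]])

    def test_normalize_rejects_degenerate(self):
        with pytest.raises(ValueError):
            normalize_coupling(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            normalize_coupling(np.array([[0.0, 1.0], [-1.0, 0.0]]))


class TestEnergy:
    def test_pair_energies_double_sum_convention(self, pair_coupling):
        assert total_energy(pair_coupling, np.array([1, 1])) == -2.0
        assert total_energy(pair_coupling, np.array([1, -1])) == 2.0

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 8))
            J = rng.random((n, n))
            J = 0.5 * (J + J.T)
            np.fill_diagonal(J, 0.0)
            coupling = CouplingMatrix(J)
            s = rng.choice([-1.0, 1.0], size=n)
            brute = -sum(
                J[i, j] * s[i] * s[j] for i in range(n) for j in range(n)
            )
            assert total_energy(coupling, s) == pytest.approx(brute, rel=1e-12)

    def test_delta_energy_pair(self, pair_coupling):
        assert delta_energy(pair_coupling, np.array([1, 1]), 0) == 4.0
        assert delta_energy(pair_coupling, np.array([1, -1]), 0) == -4.0

    def test_delta_energy_equals_flip_and_recompute(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 10))
            J = rng.random((n, n)) * rng.choice([0.0, 1.0], size=(n, n))
            J = 0.5 * (J + J.T)
            np.fill_diagonal(J, 0.0)
            if J.max() == 0:
                J[0, 1] = J[1, 0] = 1.0
            coupling = CouplingMatrix(J)
            s = rng.choice([-1.0, 1.0], size=n)
            k = int(rng.integers(0, n))
            flipped = s.copy()
            flipped[k] *= -1
            expected = total_energy(coupling, flipped) - total_energy(coupling, s)
            assert delta_energy(coupling, s, k) == pytest.approx(expected, abs=1e-10)

    def test_index_out_of_range(self, pair_coupling):
        with pytest.raises(IndexError):
            delta_energy(pair_coupling, np.array([1, 1]), 2)

    def test_rejects_non_spin_values(self, pair_coupling):
        with pytest.raises(ValueError):
            total_energy(pair_coupling, np.array([1.0, 0.5]))


class TestMetropolis:
    def test_frozen_limit_keeps_aligned_state(self, pair_coupling):
        """At T -> 0 a ferromagnetic ground state never flips."""
        s = np.ones(2)
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = metropolis_sweep(pair_coupling, s, 1e-6, rng)
        np.testing.assert_array_equal(s, [1, 1])

    def test_downhill_proposals_always_accepted(self, pair_coupling):
        """From the anti-aligned (maximum-energy) pair state, any accepted
        proposal moves downhill; at tiny T only downhill moves happen, so
        one sweep must end aligned or stay anti-aligned only if no site
        was proposed twice symmetrically."""
        rng = np.random.default_rng(1)
        ends = set()
        for _ in range(50):
            out = metropolis_sweep(pair_coupling, np.array([1.0, -1.0]), 1e-6, rng)
            ends.add(tuple(out.tolist()))
        # every end state is a ground state or the start; never uphill
        assert all(np.prod(e) == 1 or e == (1, -1) for e in ends)
        assert any(np.prod(e) == 1 for e in ends)

    def test_sweep_rejects_nonpositive_temperature(self, pair_coupling):
        with pytest.raises(ValueError):
            metropolis_sweep(pair_coupling, np.array([1.0, 1.0]), 0.0, np.random.default_rng(0))

    def test_detailed_balance_three_spins(self):
        """Long-run state frequencies match the exact Boltzmann weights
        (chi-squared goodness of fit not rejected at alpha = 0.01)."""
        from scipy.stats import chisquare

        J = np.full((3, 3), 0.4)
        np.fill_diagonal(J, 0.0)
        coupling = CouplingMatrix(J)
        oracle = exact_moments(coupling, T=1.0)
        params = SimulationParams(
            temperature=1.0, n_equil_sweeps=500, n_samples=40_000,
            sample_interval_sweeps=10, seed=12345,
        )
        trace = simulate_at_temperature(coupling, params)
        keys = (trace.samples > 0) @ np.array([4, 2, 1])
        counts = np.bincount(keys, minlength=8)
        order = (oracle["states"] > 0) @ np.array([4, 2, 1])
        probs = np.empty(8)
        probs[order] = oracle["probs"]
        res = chisquare(counts, probs * counts.sum())
        assert res.pvalue > 0.01

    def test_trace_magnetization_and_energy_consistency(self, uniform5):
        params = SimulationParams(temperature=1.3, n_equil_sweeps=50, n_samples=40, seed=7)
        trace = simulate_at_temperature(uniform5, params)
        assert trace.samples.shape == (40, 5)
        assert set(np.unique(trace.samples)) <= {-1, 1}
        np.testing.assert_allclose(trace.magnetization, trace.samples.mean(axis=1))
        expected_E = [total_energy(uniform5, s) for s in trace.samples]
        np.testing.assert_allclose(trace.energy, expected_E)

    def test_determinism_bit_identical(self, uniform5):
        params = SimulationParams(temperature=1.0, n_equil_sweeps=100, n_samples=50, seed=99)
        a = simulate_at_temperature(uniform5, params)
        b = simulate_at_temperature(uniform5, params)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.energy, b.energy)

    def test_disordered_limit_small_magnetization(self):
        J = np.full((84, 84), 0.1)
        np.fill_diagonal(J, 0.0)
        coupling = CouplingMatrix(J)
        params = SimulationParams(temperature=1000.0, n_equil_sweeps=100, n_samples=300, seed=3)
        trace = simulate_at_temperature(coupling, params)
        assert abs(trace.magnetization.mean()) < 0.1

    def test_magnetization_decreases_with_temperature(self, uniform5):
        """Ferromagnetic |m| is ordered at low T and disordered at high T."""
        mabs = []
        for i, T in enumerate([0.5, 1.6, 8.0]):
            params = SimulationParams(temperature=T, n_equil_sweeps=300, n_samples=500, seed=40 + i)
            trace = simulate_at_temperature(uniform5, params)
            mabs.append(np.abs(trace.magnetization).mean())
        assert mabs[0] > mabs[1] > mabs[2]
        assert mabs[0] > 0.95


class TestBoltzmannOracle:
    @pytest.mark.parametrize("T", [1.0, 1.6, 2.5])
    def test_moments_match_enumeration(self, uniform5, T):
        """MC <m^2> and chi agree with exact 32-state enumeration within
        3 standard errors over independent replicate chains."""
        oracle = exact_moments(uniform5, T)
        m2s, chis = [], []
        for rep in range(10):
            params = SimulationParams(
                temperature=T, n_equil_sweeps=500, n_samples=1500,
                sample_interval_sweeps=2, seed=6000 + rep,
            )
            trace = simulate_at_temperature(uniform5, params)
            m2s.append(np.mean(trace.magnetization**2))
            chis.append(susceptibility(trace))
        for mc, exact in ((m2s, oracle["m2"]), (chis, oracle["chi"])):
            se = np.std(mc, ddof=1) / np.sqrt(len(mc))
            assert abs(np.mean(mc) - exact) < 3 * se + 1e-9


class TestSusceptibility:
    def _trace_from_m(self, m_values, T=1.0, n=2):
        m = np.asarray(m_values, dtype=float)
        samples = np.where(m[:, None] >= 0, 1, -1).astype(np.int8)
        samples = np.repeat(samples, n, axis=1)[:, :n]
        params = SimulationParams(temperature=T, n_samples=max(len(m), 2), seed=0)
        return SpinTrace(
            samples=samples, magnetization=m, energy=np.zeros(len(m)), params=params
        )

    def test_constant_trace_zero(self):
        trace = self._trace_from_m([1.0] * 10)
        assert susceptibility(trace) == 0.0

    def test_symmetric_pm_one_folds_to_zero(self):
        """Samples alternating +-1: <m^2> = <|m|>^2 = 1, so chi = 0 under
        the |m| convention."""
        trace = self._trace_from_m([1.0, -1.0] * 5)
        assert susceptibility(trace) == 0.0
        # raw-<m> estimator keeps the tunnelling variance instead
        assert susceptibility(trace, use_abs=False) == pytest.approx(2.0)

    def test_global_flip_invariance(self, uniform5):
        params = SimulationParams(temperature=1.2, n_equil_sweeps=100, n_samples=200, seed=11)
        trace = simulate_at_temperature(uniform5, params)
        flipped = SpinTrace(
            samples=-trace.samples,
            magnetization=-trace.magnetization,
            energy=trace.energy,
            params=params,
        )
        assert susceptibility(flipped) == pytest.approx(susceptibility(trace))

    def test_rejects_short_trace(self):
        with pytest.raises(ValueError):
            susceptibility(self._trace_from_m([1.0]))


def test_random_spins_are_pm_one(rng):
    s = random_spins(100, rng)
    assert set(np.unique(s)) <= {-1, 1}
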