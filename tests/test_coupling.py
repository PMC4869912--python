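"""Coupled Markov-chain model: kernel construction, likelihood, estimation."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from coopgate import coupling
from coopgate.coupling import (
    CoupledGatingModel,
    OccupancyTrace,
    estimate_kappa,
    log_likelihood,
    quantize_trace,
    simulate_occupancy,
    stationary_distribution,
    transition_matrix,
)
from coopgate.presets import get_gating_preset, get_signal_preset
from coopgate.synthetic import make_sparklet_trace
from coopgate.traces import CalciumTrace


def brute_force_independent_kernel(n, p_open, p_close):
    """Enumerate all per-channel transitions; oracle for T_ind."""
    t = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        # channel states: k open, n-k closed; enumerate each channel's fate
        for fates in product([0, 1], repeat=n):
            p = 1.0
            k_next = 0
            for ch in range(n):
                is_open = ch < k
                opens = fates[ch] == 1
                if is_open:
                    p *= (1 - p_close) if opens else p_close
                else:
                    p *= p_open if opens else (1 - p_open)
                k_next += opens
            t[k, k_next] += p
    return t


class TestTransitionMatrix:
    def test_independent_limit_is_binomial(self):
        m = CoupledGatingModel(2, 0.5, 0.5, 0.0)
        row = transition_matrix(m)[1]
        assert np.allclose(row, [0.25, 0.5, 0.25])

    def test_fully_coupled_mass_on_extremes(self):
        for n in (1, 2, 4):
            m = CoupledGatingModel(n, 0.3, 0.4, 1.0)
            t = transition_matrix(m)
            assert t[0, 0] == pytest.approx(0.7)
            assert t[0, n] == pytest.approx(0.3)
            interior = t[:, 1:n] if n > 1 else np.zeros((n + 1, 0))
            assert np.all(interior == 0)

    def test_half_mixture_matches_hand_enumeration(self):
        po, pc, n = 0.31, 0.47, 2
        m = CoupledGatingModel(n, po, pc, 0.5)
        t_ind = brute_force_independent_kernel(n, po, pc)
        t_coh = np.zeros((3, 3))
        t_coh[0] = [1 - po, 0, po]
        t_coh[1] = [pc, 0, 1 - pc]
        t_coh[2] = [pc, 0, 1 - pc]
        expected = 0.5 * t_ind + 0.5 * t_coh
        assert np.allclose(transition_matrix(m), expected, atol=1e-14)

    def test_kappa_zero_equals_independent_kernel_exactly(self):
        po, pc = 0.2, 0.6
        for n in (1, 2, 3):
            m = CoupledGatingModel(n, po, pc, 0.0)
            assert np.allclose(
                transition_matrix(m), brute_force_independent_kernel(n, po, pc), atol=1e-14
            )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 6),
        po=st.floats(1e-4, 1 - 1e-4),
        pc=st.floats(1e-4, 1 - 1e-4),
        kappa=st.floats(0, 1),
    )
    def test_rows_are_stochastic(self, n, po, pc, kappa):
        t = transition_matrix(CoupledGatingModel(n, po, pc, kappa))
        assert np.all(t >= 0)
        assert np.max(np.abs(t.sum(axis=1) - 1.0)) < 1e-12

    def test_extreme_state_mass_nondecreasing_in_kappa(self):
        for po, pc, n in [(0.1, 0.3, 2), (0.05, 0.5, 3), (0.4, 0.2, 4)]:
            masses = []
            for kappa in np.linspace(0, 1, 11):
                pi = stationary_distribution(CoupledGatingModel(n, po, pc, kappa))
                masses.append(pi[0] + pi[n])
            assert np.all(np.diff(masses) >= -1e-10)


class TestSimulation:
    def test_absorbing_closed_state(self):
        # p_open tiny and init 0 with kappa=0: still possible to open;
        # instead verify determinism and state bounds.
        m = CoupledGatingModel(2, 0.2, 0.4, 0.3)
        occ1 = simulate_occupancy(m, 5000, seed=9)
        occ2 = simulate_occupancy(m, 5000, seed=9)
        assert np.array_equal(occ1.k, occ2.k)
        assert occ1.k.min() >= 0 and occ1.k.max() <= 2

    def test_longrun_frequencies_match_stationary(self):
        m = CoupledGatingModel(2, 0.15, 0.35, 0.4)
        occ = simulate_occupancy(m, 100_000, seed=3)
        pi = stationary_distribution(m)
        freqs = np.bincount(occ.k, minlength=3) / occ.k.size
        # 3-sigma multinomial bound per state
        for s in range(3):
            sigma = np.sqrt(pi[s] * (1 - pi[s]) / occ.k.size)
            assert abs(freqs[s] - pi[s]) < 4 * sigma + 1e-3

    def test_fully_coupled_visits_only_extremes(self):
        m = CoupledGatingModel(3, 0.2, 0.3, 1.0)
        occ = simulate_occupancy(m, 5000, seed=11, init=0)
        assert set(np.unique(occ.k)) <= {0, 3}

    def test_invalid_init_rejected(self):
        m = CoupledGatingModel(2, 0.2, 0.3, 0.0)
        with pytest.raises(ValueError):
            simulate_occupancy(m, 10, seed=0, init=5)


class TestQuantize:
    def test_baseline_only_gives_zeros(self):
        tr = CalciumTrace(values=np.full(20, 100.0), dt=0.01)
        assert np.all(quantize_trace(tr, q=38.0, baseline=100.0).k == 0)

    def test_half_rounds_away_from_zero(self):
        tr = CalciumTrace(values=np.array([100.0 + 1.5 * 38.0] * 3), dt=0.01)
        assert np.all(quantize_trace(tr, q=38.0, baseline=100.0).k == 2)

    def test_noiseless_roundtrip_recovers_occupancy(self, sparklet_gating):
        sig = get_signal_preset("sparklet_default", noise_sd=0.0)
        tr, occ = make_sparklet_trace(sparklet_gating, sig, 1000, seed=21)
        k = quantize_trace(tr, q=38.0, baseline=100.0, n_channels=2)
        assert np.array_equal(k.k, occ.k)


class TestLikelihood:
    def test_single_frame_is_mixture_density(self):
        m = CoupledGatingModel(2, 0.2, 0.3, 0.4)
        pi = stationary_distribution(m)
        x = np.array([57.0])
        expected = np.log(sum(pi[k] * norm.pdf(57.0, 20 + 38 * k, 9.0) for k in range(3)))
        assert log_likelihood(m, x, q=38.0, baseline=20.0, noise_sd=9.0) == pytest.approx(expected)

    @pytest.mark.parametrize("kappa", [0.0, 0.5, 1.0])
    def test_forward_equals_exhaustive_enumeration(self, kappa, rng):
        m = CoupledGatingModel(2, 0.25, 0.35, kappa)
        x = rng.normal(40, 35, size=6)
        t = transition_matrix(m)
        pi = stationary_distribution(m)
        total = 0.0
        for path in product(range(3), repeat=6):
            p = pi[path[0]]
            for a, b in zip(path[:-1], path[1:]):
                p *= t[a, b]
            for k, xi in zip(path, x):
                p *= norm.pdf(xi, 20 + 38 * k, 10.0)
            total += p
        ll = log_likelihood(m, x, q=38.0, baseline=20.0, noise_sd=10.0)
        assert abs(ll - np.log(total)) < 1e-8

    def test_shift_invariance(self, rng):
        m = CoupledGatingModel(2, 0.2, 0.3, 0.3)
        x = rng.normal(100, 30, size=50)
        a = log_likelihood(m, x, q=38.0, baseline=100.0, noise_sd=8.0)
        b = log_likelihood(m, x + 7.5, q=38.0, baseline=107.5, noise_sd=8.0)
        assert a == pytest.approx(b, abs=1e-9)

    def test_nonfinite_trace_rejected(self):
        m = CoupledGatingModel(2, 0.2, 0.3, 0.3)
        with pytest.raises(ValueError):
            log_likelihood(m, np.array([1.0, np.nan]), 38.0, 0.0, 8.0)


class TestEstimateKappa:
    def test_fully_coupled_recovered(self, sparklet_signal):
        g = get_gating_preset("cav13s_sparklet", kappa=1.0)
        khats = []
        for i in range(5):
            tr, _ = make_sparklet_trace(g, sparklet_signal, 2000, seed=400 + i)
            fit = estimate_kappa(tr, n_channels=2, q=38.0, baseline=100.0, noise_sd=8.0)
            khats.append(fit.kappa_hat)
            assert fit.coupled
        assert np.mean(khats) > 0.9

    def test_independent_classified_uncoupled(self, sparklet_signal):
        g = get_gating_preset("uncoupled_sparklet")
        khats = []
        for i in range(5):
            tr, _ = make_sparklet_trace(g, sparklet_signal, 2000, seed=500 + i)
            khats.append(estimate_kappa(tr, 2, 38.0, 100.0, 8.0).kappa_hat)
        assert np.mean(khats) < 0.1

    def test_occupancy_input_path(self, sparklet_gating):
        m = CoupledGatingModel(2, 0.05, 0.3, 0.21)
        occ = simulate_occupancy(m, 5000, seed=77)
        fit = estimate_kappa(occ, n_channels=2)
        assert 0.05 < fit.kappa_hat < 0.4

    def test_constant_trace_flagged(self):
        tr = CalciumTrace(values=np.full(200, 100.0), dt=0.01)
        fit = estimate_kappa(tr, n_channels=2, q=38.0, baseline=100.0, noise_sd=8.0)
        assert fit.no_transitions
        assert fit.kappa_hat == 0.0
        assert not fit.coupled

    def test_short_trace_warns(self):
        tr = CalciumTrace(values=np.r_[np.full(30, 100.0), np.full(30, 138.0)], dt=0.01)
        with pytest.warns(UserWarning, match="shorter than 100"):
            estimate_kappa(tr, n_channels=2, q=38.0, baseline=100.0, noise_sd=8.0)

    def test_consistency_improves_with_length(self):
        """Mean |kappa_hat - kappa| shrinks from 10^3 to 10^4 frames."""
        sig = get_signal_preset("sparklet_default")
        g = get_gating_preset("cav13s_sparklet", kappa=0.5)
        errs = {}
        for n_frames in (1000, 10_000):
            e = []
            for i in range(3):
                tr, _ = make_sparklet_trace(g, sig, n_frames, seed=900 + i)
                e.append(abs(estimate_kappa(tr, 2, 38.0, 100.0, 8.0).kappa_hat - 0.5))
            errs[n_frames] = np.mean(e)
        assert errs[10_000] <= errs[1000] + 0.02


class TestModelValidation:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            CoupledGatingModel(2, 0.0, 0.5, 0.1)
        with pytest.raises(ValueError):
            CoupledGatingModel(2, 0.5, 1.0, 0.1)

    def test_kappa_clipped(self):
        assert CoupledGatingModel(2, 0.5, 0.5, 1.5).kappa == 1.0
        assert CoupledGatingModel(2, 0.5, 0.5, -0.2).kappa == 0.0

    def test_occupancy_trace_bounds(self):
        with pytest.raises(ValueError):
            OccupancyTrace(k=np.array([0, 3]), dt=0.01, n_channels=2)
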