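"""Generators: determinism, ground-truth consistency, statistical structure."""

import numpy as np
import pytest

from coopgate.coupling import CoupledGatingModel, stationary_distribution
from coopgate.presets import (
    BleachPreset,
    EmitterCloudPreset,
    GatingPreset,
    PresetError,
    SignalPreset,
    get_gating_preset,
    get_signal_preset,
    get_wholecell_preset,
)
from coopgate.synthetic import (
    make_bleach_stack,
    make_localizations,
    make_single_channel_sweeps,
    make_sparklet_trace,
    make_whole_cell_from_preset,
    make_whole_cell_trace,
)


class TestSparkletTrace:
    def test_no_openings_gives_constant_baseline(self):
        g = GatingPreset("quiet", n_channels=2, p_open=1e-9, p_close=0.5, kappa=0.0)
        s = SignalPreset("clean", quantal_amplitude=38.0, baseline=100.0, noise_sd=0.0, dt=0.01)
        tr, occ = make_sparklet_trace(g, s, 500, seed=1, init=0)
        assert np.all(occ.k == 0)
        assert np.all(tr.values == 100.0)

    def test_occupancy_conditioned_means_are_quantal(self, sparklet_gating, sparklet_signal):
        tr, occ = make_sparklet_trace(sparklet_gating, sparklet_signal, 20_000, seed=2)
        for k in range(3):
            sel = occ.k == k
            if sel.sum() < 10:
                continue
            expected = 100.0 + 38.0 * k
            tol = 3 * 8.0 / np.sqrt(sel.sum())
            assert abs(tr.values[sel].mean() - expected) < tol

    def test_same_seed_bit_identical(self, sparklet_gating, sparklet_signal):
        tr1, occ1 = make_sparklet_trace(sparklet_gating, sparklet_signal, 300, seed=5)
        tr2, occ2 = make_sparklet_trace(sparklet_gating, sparklet_signal, 300, seed=5)
        assert np.array_equal(tr1.values, tr2.values)
        assert np.array_equal(occ1.k, occ2.k)

    def test_noise_is_additive_and_unbiased(self, sparklet_gating, sparklet_signal):
        tr, occ = make_sparklet_trace(sparklet_gating, sparklet_signal, 50_000, seed=6)
        resid = tr.values - 100.0 - 38.0 * occ.k
        assert abs(resid.mean()) < 4 * 8.0 / np.sqrt(resid.size)

    def test_too_short_rejected(self, sparklet_gating, sparklet_signal):
        with pytest.raises(ValueError):
            make_sparklet_trace(sparklet_gating, sparklet_signal, 1, seed=0)


class TestSingleChannelSweeps:
    def test_always_open_noiseless(self):
        g = GatingPreset("on", n_channels=1, p_open=0.999, p_close=1e-4, kappa=0.0)
        s = SignalPreset("clean", quantal_amplitude=-0.49, baseline=0.0, noise_sd=0.0, dt=1e-4)
        sweeps, occs = make_single_channel_sweeps(g, s, 3, 100, seed=1)
        # stationary Po ~ 1: nearly all frames at the open level
        assert np.mean(sweeps.sweeps == -0.49) > 0.99

    def test_open_minus_closed_level_is_unitary_current(self):
        g = get_gating_preset("single_channel_po30")
        s = get_signal_preset("cav13s_ca_m30", noise_sd=0.0)
        sweeps, occs = make_single_channel_sweeps(g, s, 5, 5000, seed=3)
        vals = np.unique(sweeps.sweeps)
        assert set(np.round(vals, 6)) <= {0.0, -0.49}
        assert (vals.min() - vals.max()) == pytest.approx(-0.49)

    def test_occupancy_matches_stationary_distribution(self):
        g = get_gating_preset("single_channel_po30")
        s = get_signal_preset("cav13s_ca_m30")
        sweeps, occs = make_single_channel_sweeps(g, s, 10, 5000, seed=4)
        k = np.concatenate([o.k for o in occs])
        pi = stationary_distribution(CoupledGatingModel(1, g.p_open, g.p_close, 0.0))
        po_hat = k.mean()
        assert abs(po_hat - pi[1]) < 4 * np.sqrt(pi[1] * (1 - pi[1]) / k.size) * 10
        # (factor 10: frames within a sweep are autocorrelated)

    def test_sweep_frames_validation(self):
        g = get_gating_preset("single_channel_po30")
        s = get_signal_preset("cav13s_ca_m30")
        with pytest.raises(ValueError):
            make_single_channel_sweeps(g, s, 2, 1, seed=0)


class TestWholeCellTrace:
    def test_no_inactivation_limit_reaches_ohmic_plateau(self):
        tr = make_whole_cell_trace(5.0, -10.0, 54.0, tau_act=1.0, tau_inact=np.inf, duration=50.0, dt=0.05)
        assert tr.values[-1] == pytest.approx(5.0 * (-10.0 - 54.0), rel=1e-6)

    def test_zero_driving_force_gives_zero_trace(self):
        tr = make_whole_cell_trace(5.0, 54.0, 54.0, tau_act=1.0, tau_inact=100.0, duration=10.0, dt=0.1)
        assert np.all(tr.values == 0.0)

    def test_preset_lookup_and_waveform_shape(self):
        tr = make_whole_cell_from_preset(get_wholecell_preset("cav13s_cdi_ca"), duration=300, dt=0.1)
        peak = np.argmax(np.abs(tr.values))
        assert 0 < peak < len(tr) - 1  # rises then inactivates

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            make_whole_cell_trace(5.0, -10.0, 54.0, tau_act=-1.0, tau_inact=100.0)


class TestBleachStack:
    def test_single_fluorophore_single_step(self):
        p = BleachPreset("one", n_fluorophores=1, step_amplitude=300.0, bleach_rate=0.02, noise_sd=0.0, n_frames=200)
        stack, gt = make_bleach_stack(p, n_spots=1, image_size=32, seed=1)
        assert gt.n_steps[0] == 1
        r, c = gt.centers[0]
        z = stack[:, r, c]
        drops = np.flatnonzero(np.diff(z) < -1.0)
        assert drops.size == 1

    def test_forced_bleach_frames_build_exact_staircase(self):
        p = BleachPreset("forced", n_fluorophores=3, step_amplitude=100.0, bleach_rate=0.01, noise_sd=0.0, n_frames=400)
        stack, gt = make_bleach_stack(p, n_spots=1, image_size=32, seed=2, forced_bleach_frames=[100, 200, 300])
        assert gt.bleach_frames[0] == [100, 200, 300]
        r, c = gt.centers[0]
        z = stack[:, r, c]
        assert np.all(np.flatnonzero(np.diff(z) < -1.0) + 1 == [100, 200, 300])

    def test_count_spec_mixture_proportions(self):
        p = BleachPreset("mix", n_fluorophores=0, step_amplitude=100.0, bleach_rate=0.01, noise_sd=0.0, n_frames=60)
        spec = {"kind": "categorical", "values": [1, 5], "probs": [0.3, 0.7]}
        stack, gt = make_bleach_stack(p, n_spots=36, image_size=64, seed=3, count_spec=spec)
        # pool several stacks for a chi-square-scale check
        counts = list(gt.n_steps)
        for s in range(4, 18):
            _, g2 = make_bleach_stack(p, n_spots=36, image_size=64, seed=s, count_spec=spec)
            counts += list(g2.n_steps)
        counts = np.array(counts)
        frac1 = np.mean(counts == 1)
        n = counts.size
        assert abs(frac1 - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_overfull_field_rejected(self):
        p = BleachPreset("full", n_fluorophores=1, step_amplitude=10.0, bleach_rate=0.1, noise_sd=0.0, n_frames=10)
        with pytest.raises(ValueError):
            make_bleach_stack(p, n_spots=1000, image_size=32, seed=0)


class TestLocalizations:
    def _preset(self, **kw):
        base = dict(
            name="t",
            n_clusters=1,
            channels_per_cluster={"kind": "fixed", "value": 1},
            cluster_radius=0.0,
            localizations_per_fluorophore={"kind": "fixed", "value": 10_000},
            photons_per_localization={"kind": "fixed", "value": 1900.0},
            dlr=710.0,
            field_size=(1000.0, 1000.0),
        )
        base.update(kw)
        return EmitterCloudPreset(**base)

    def test_empirical_sd_matches_dlr_over_sqrt_n(self):
        locs, centers = make_localizations(self._preset(), seed=9)
        expected = 710.0 / np.sqrt(1900.0)
        for coord in (locs.x, locs.y):
            assert abs(np.std(coord) - expected) / expected < 0.02

    def test_infinite_photons_collapse_to_truth(self):
        locs, centers = make_localizations(
            self._preset(photons_per_localization={"kind": "fixed", "value": 1e12},
                         localizations_per_fluorophore={"kind": "fixed", "value": 100}),
            seed=4,
        )
        assert np.max(np.hypot(locs.x - centers[0, 0], locs.y - centers[0, 1])) < 0.1

    def test_photon_counts_attached(self):
        locs, _ = make_localizations(self._preset(), seed=1)
        assert np.all(locs.photons == 1900.0)

    def test_determinism(self):
        a, _ = make_localizations(self._preset(), seed=8)
        b, _ = make_localizations(self._preset(), seed=8)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.photons, b.photons)


class TestPresetValidation:
    def test_bad_fields_name_the_field(self):
        with pytest.raises(PresetError, match="p_open"):
            GatingPreset("bad", n_channels=2, p_open=0.0, p_close=0.5, kappa=0.1)
        with pytest.raises(PresetError, match="dt"):
            SignalPreset("bad", quantal_amplitude=38.0, baseline=0.0, noise_sd=1.0, dt=0.0)
        with pytest.raises(PresetError, match="hazard"):
            BleachPreset("bad", n_fluorophores=1, step_amplitude=1.0, bleach_rate=0.0, noise_sd=0.0, n_frames=10)

    def test_unknown_preset_name(self):
        with pytest.raises(PresetError, match="unknown"):
            get_gating_preset("nope")
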