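import numpy as np
import pytest
from scipy import signal

from laminarlfp import synth
from laminarlfp.io import EventTable
from laminarlfp.spikes import plv, spike_phases

DEPTHS = synth.DEFAULT_DEPTHS_UM


class TestLoadings:
    def test_linear_column_has_zero_second_difference(self):
        V = synth.make_loadings(
            [synth.SourceSpec("linear_volume_conducted")], DEPTHS
        )
        d2 = np.diff(V[:, 0], 2)
        np.testing.assert_allclose(d2, 0.0, atol=1e-12)

    def test_deep_reversing_crosses_zero_once_near_1000(self):
        V = synth.make_loadings([synth.SourceSpec("deep_reversing")], DEPTHS)
        v = V[:, 0]
        signs = np.sign(v[v != 0])
        crossings = np.nonzero(np.diff(signs) != 0)[0]
        assert crossings.size == 1
        z_cross = DEPTHS[crossings[0]], DEPTHS[crossings[0] + 1]
        assert z_cross[0] < 1000.0 <= z_cross[1]

    def test_columns_max_normalized_with_positive_extremum(self):
        V = synth.make_loadings(synth.default_source_specs(), DEPTHS)
        peaks = np.abs(V).max(axis=0)
        np.testing.assert_allclose(peaks, 1.0)
        assert np.all(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])] > 0)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="3 channels"):
            synth.make_loadings([synth.SourceSpec("deep_reversing")], [100.0])

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError, match="unknown loading shape"):
            synth.SourceSpec("spiral")

    def test_curvature_matches_finite_difference(self):
        z = np.linspace(300, 1500, 400)
        for shape in ("deep_reversing", "superficial_reversing", "nonreversing_superficial"):
            v = synth.archetype_loading(shape, z)
            d2 = synth.archetype_loading_curvature(shape, z)
            num = np.gradient(np.gradient(v, z), z)
            scale = np.abs(d2).max()
            np.testing.assert_allclose(
                d2[5:-5], num[5:-5], rtol=1e-3, atol=1e-3 * scale
            )


class TestTimecourses:
    def test_deterministic_under_seed(self, toy_events):
        specs = synth.default_source_specs()
        a, _ = synth.make_timecourses(specs, toy_events, 500.0, 10.0, seed=5)
        b, _ = synth.make_timecourses(specs, toy_events, 500.0, 10.0, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_aliasing_fs_rejected(self, toy_events):
        with pytest.raises(ValueError, match="alias"):
            synth.make_timecourses(
                synth.default_source_specs(), toy_events, 200.0, 10.0
            )

    def test_hold_pull_gain_recovered_from_bandpower(self):
        """2:1 hold:pull slow-gamma power gain shows up in the band power of
        every trial (direct bandpower oracle on the generated source)."""
        spec = synth.SourceSpec(
            "nonreversing_superficial",
            band_powers={"slow_gamma": 1.0},
            hold_gain={"slow_gamma": 2.0},
            pull_gain={"slow_gamma": 1.0},
        )
        fs = 500.0
        ev = synth.make_events(n_trials=12, interval_s=3.0, jitter_s=0.0, seed=0)
        s, _ = synth.make_timecourses(
            [spec], ev, fs, ev.pull_onsets[-1] + 1.5, seed=2, burst_sigma=0.0
        )
        sos = signal.butter(4, [20, 50], btype="bandpass", fs=fs, output="sos")
        filt = signal.sosfiltfilt(sos, s[0])
        hold_p, pull_p = [], []
        for onset in ev.pull_onsets:
            h = filt[int((onset - 1.0) * fs) : int((onset - 0.5) * fs)]
            p = filt[int((onset - 0.15) * fs) : int((onset + 0.25) * fs)]
            hold_p.append(np.mean(h**2))
            pull_p.append(np.mean(p**2))
        # hold power dominates in (nearly) every trial and the trial-averaged
        # ratio recovers the 2:1 power gain
        assert np.mean(np.array(hold_p) > np.array(pull_p)) >= 0.8
        ratio = np.mean(hold_p) / np.mean(pull_p)
        assert 1.4 < ratio < 2.8  # nominal 2.0, finite-sample spread

    def test_delayed_pull_gain_rises_after_onset(self):
        """A source-2-like spec: slow gamma power increases ~100 ms after
        pull onset relative to the immediate pre-onset level."""
        spec = synth.SourceSpec(
            "deep_reversing",
            band_powers={"slow_gamma": 1.0},
            hold_gain={"slow_gamma": 0.3},
            pull_gain={"slow_gamma": 1.5},
            pull_delay_s={"slow_gamma": 0.3},
        )
        fs = 500.0
        ev = synth.make_events(n_trials=20, interval_s=3.0, jitter_s=0.0, seed=0)
        s, _ = synth.make_timecourses(
            [spec], ev, fs, ev.pull_onsets[-1] + 1.5, seed=3, burst_sigma=0.0
        )
        sos = signal.butter(4, [20, 50], btype="bandpass", fs=fs, output="sos")
        env = np.abs(signal.hilbert(signal.sosfiltfilt(sos, s[0]))) ** 2
        pre, post = [], []
        for onset in ev.pull_onsets:
            pre.append(env[int((onset - 0.4) * fs) : int(onset * fs)].mean())
            post.append(env[int((onset + 0.15) * fs) : int((onset + 0.55) * fs)].mean())
        assert np.mean(post) > 1.5 * np.mean(pre)


class TestMix:
    def test_zero_noise_exact(self):
        V = synth.make_loadings(synth.default_source_specs(), DEPTHS)
        s = np.random.default_rng(0).standard_normal((4, 200))
        rec = synth.mix(V, s, 0.0, DEPTHS, 500.0)
        np.testing.assert_array_equal(rec.samples, V @ s)

    def test_single_source_rank_one(self):
        V = synth.make_loadings([synth.SourceSpec("deep_reversing")], DEPTHS)
        s = np.random.default_rng(0).standard_normal((1, 300))
        rec = synth.mix(V, s, 0.0, DEPTHS, 500.0)
        assert np.linalg.matrix_rank(rec.samples) == 1

    def test_negative_noise_rejected(self):
        V = synth.make_loadings([synth.SourceSpec("deep_reversing")], DEPTHS)
        with pytest.raises(ValueError):
            synth.mix(V, np.zeros((1, 10)), -0.1, DEPTHS, 500.0)


class TestSpikes:
    @pytest.fixture()
    def gamma_source(self):
        spec = synth.SourceSpec(
            "nonreversing_superficial", band_powers={"slow_gamma": 1.0}
        )
        s, _ = synth.make_timecourses(
            [spec], EventTable(pull_onsets=np.array([])), 500.0, 400.0, seed=0
        )
        return s[0]

    def test_zero_target_is_homogeneous_poisson(self, gamma_source):
        unit = synth.make_spikes(
            gamma_source, 500.0, (20, 50), 0.0, rate=5.0, seed=1
        )
        n = unit.times.size
        assert abs(n - 2000) < 4 * np.sqrt(2000)  # Poisson count at rate*T
        ph = spike_phases(unit.times, gamma_source, 500.0, (20, 50))
        assert plv(ph) < 0.05

    def test_unit_target_locks_all_spikes(self, gamma_source):
        unit = synth.make_spikes(
            gamma_source, 500.0, (20, 50), 1.0, rate=5.0, preferred_phase=0.5, seed=1
        )
        ph = spike_phases(unit.times, gamma_source, 500.0, (20, 50))
        assert plv(ph) > 0.95

    def test_intermediate_target_recovered(self, gamma_source):
        """kappa solved from A(kappa) = 0.5 gives measured PLV within 0.05."""
        unit = synth.make_spikes(
            gamma_source, 500.0, (20, 50), 0.5, rate=8.0, preferred_phase=1.0, seed=4
        )
        assert unit.times.size > 2500
        ph = spike_phases(unit.times, gamma_source, 500.0, (20, 50))
        assert abs(plv(ph) - 0.5) <= 0.05

    def test_kappa_inversion_against_bessel_ratio(self):
        from scipy import special

        for target in (0.1, 0.4, 0.8):
            k = synth.vonmises_kappa_for_plv(target)
            assert special.i1e(k) / special.i0e(k) == pytest.approx(target, abs=1e-8)

    def test_nonpositive_rate_rejected(self, gamma_source):
        with pytest.raises(ValueError):
            synth.make_spikes(gamma_source, 500.0, (20, 50), 0.5, rate=0.0)


class TestLever:
    def test_one_excursion_per_event(self):
        ev = synth.make_events(n_trials=18, seed=0)
        t, pos = synth.make_lever(ev, fs_lever=200.0, seed=0)
        above = pos > 0.5
        n_exc = np.count_nonzero(np.diff(above.astype(int)) == 1)
        assert n_exc == 18

    def test_zero_jitter_trials_identical(self):
        ev = synth.make_events(n_trials=5, jitter_s=0.0, seed=0)
        t, pos = synth.make_lever(ev, fs_lever=200.0, amplitude_jitter=0.0, seed=0)
        segs = [
            pos[int(round((o - 0.1) * 200)) : int(round((o + 0.7) * 200))]
            for o in ev.pull_onsets
        ]
        for seg in segs[1:]:
            np.testing.assert_allclose(seg, segs[0], atol=1e-12)

    def test_short_hold_rejected(self):
        ev = EventTable(pull_onsets=np.array([2.0, 3.0]))
        with pytest.raises(ValueError, match="held >= 1 s"):
            synth.make_lever(ev)

    def test_flat_hold_before_onset(self):
        ev = synth.make_events(n_trials=4, seed=2)
        t, pos = synth.make_lever(ev, fs_lever=500.0, seed=2)
        for onset in ev.pull_onsets:
            hold = pos[int((onset - 1.0) * 500) : int(onset * 500) - 1]
            np.testing.assert_allclose(hold, 0.0, atol=1e-12)


class TestDatasetDeterminism:
    def test_identical_seeds_identical_outputs(self):
        a = synth.generate_dataset(n_trials=4, fs=500.0, seed=7)
        b = synth.generate_dataset(n_trials=4, fs=500.0, seed=7)
        np.testing.assert_array_equal(a["recording"].samples, b["recording"].samples)
        np.testing.assert_array_equal(
            a["spikes"].units[0].times, b["spikes"].units[0].times
        )
        np.testing.assert_array_equal(a["lever"][1], b["lever"][1])
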