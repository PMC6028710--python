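import numpy as np
import pytest

from laminarlfp import coupling as cpl
from laminarlfp import synth
from laminarlfp.io import LaminarRecording

FS = 500.0


class TestBandpass:
    def test_in_band_tone_amplitude_preserved(self):
        t = np.arange(int(20 * FS)) / FS
        out = cpl.bandpass(np.cos(2 * np.pi * 8 * t), FS, cpl.THETA_BAND)
        core = out[int(5 * FS) : int(15 * FS)]
        assert np.abs(core).max() == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_tone_attenuated_40db(self):
        t = np.arange(int(20 * FS)) / FS
        out = cpl.bandpass(np.cos(2 * np.pi * 80 * t), FS, cpl.THETA_BAND)
        core = out[int(5 * FS) : int(15 * FS)]
        assert np.sqrt(np.mean(core**2)) < 10 ** (-40 / 20) / np.sqrt(2)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            cpl.bandpass(np.zeros(5000), FS, (100.0, 300.0))


class TestAnalyticPhaseAmp:
    def test_cosine_phase_advances_at_carrier_rate(self):
        t = np.arange(int(10 * FS)) / FS
        phase, env = cpl.analytic_phase_amp(np.cos(2 * np.pi * 8 * t))
        core = slice(int(FS), int(9 * FS))
        rate = np.diff(np.unwrap(phase)[core]).mean() * FS / (2 * np.pi)
        assert rate == pytest.approx(8.0, rel=1e-3)
        np.testing.assert_allclose(env[core], 1.0, atol=0.01)

    def test_envelope_recovers_known_modulator(self):
        t = np.arange(int(20 * FS)) / FS
        mod = 1.0 + 0.5 * np.cos(2 * np.pi * 1.0 * t)
        x = mod * np.cos(2 * np.pi * 40 * t)
        _, env = cpl.analytic_phase_amp(x)
        core = slice(int(2 * FS), int(18 * FS))
        np.testing.assert_allclose(env[core], mod[core], rtol=0.03)

    def test_zero_trace_rejected(self):
        with pytest.raises(ValueError, match="zero trace"):
            cpl.analytic_phase_amp(np.zeros(100))


class TestPhaseAmpDistribution:
    def test_constant_envelope_is_uniform(self):
        rng = np.random.default_rng(0)
        phases = rng.uniform(0, 2 * np.pi, 100_000)
        centers, dist = cpl.phase_amp_distribution(phases, np.ones(100_000))
        assert centers.size == 18
        np.testing.assert_allclose(dist, 1 / 18, atol=1e-12)

    def test_raised_cosine_profile_closed_form(self):
        """env = 1 + cos(phase) gives bin values proportional to the bin
        averages of the raised cosine, maximal at 0 deg."""
        phases = np.linspace(0, 2 * np.pi, 360_000, endpoint=False)
        env = 1.0 + np.cos(phases)
        centers, dist = cpl.phase_amp_distribution(phases, env)
        edges = np.deg2rad(np.arange(0, 361, 20.0))
        expected = np.array(
            [
                1 + (np.sin(b) - np.sin(a)) / (b - a)
                for a, b in zip(edges[:-1], edges[1:])
            ]
        )
        expected /= expected.sum()
        np.testing.assert_allclose(dist, expected, rtol=1e-3)
        assert np.argmax(dist) in (0, 17)  # peak bins flank 0 deg

    def test_sums_to_one(self):
        rng = np.random.default_rng(1)
        _, dist = cpl.phase_amp_distribution(
            rng.uniform(0, 2 * np.pi, 5000), rng.random(5000)
        )
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_bin_warns(self):
        phases = np.full(100, 0.1)  # single bin occupied
        with pytest.warns(UserWarning, match="empty phase bin"):
            _, dist = cpl.phase_amp_distribution(phases, np.ones(100))
        assert dist[0] == 1.0


class TestModulationIndex:
    def test_uniform_is_zero(self):
        assert cpl.modulation_index(np.full(18, 1 / 18)) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_is_one(self):
        bins = np.zeros(18)
        bins[4] = 1.0
        assert cpl.modulation_index(bins) == pytest.approx(1.0)

    def test_matches_direct_entropy_computation(self):
        phases = np.linspace(0, 2 * np.pi, 36_000, endpoint=False)
        _, dist = cpl.phase_amp_distribution(phases, 1.0 + np.cos(phases))
        h = -np.sum(dist * np.log(dist))
        assert cpl.modulation_index(dist) == pytest.approx(
            (np.log(18) - h) / np.log(18), abs=1e-12
        )

    def test_invariant_to_envelope_scaling(self):
        rng = np.random.default_rng(2)
        ph = rng.uniform(0, 2 * np.pi, 20_000)
        env = rng.random(20_000) * (1 + np.cos(ph))
        a = cpl.coupling_result(ph, env).mi
        b = cpl.coupling_result(ph, 7.3 * env).mi
        assert a == pytest.approx(b, rel=1e-12)

    def test_negative_bin_rejected(self):
        bins = np.full(18, 1 / 18)
        bins[0], bins[1] = -bins[1], 2 * bins[1]
        with pytest.raises(ValueError):
            cpl.modulation_index(bins)


def _coupled_session(kc, seed, n_trials=20, fs=FS):
    src = synth.SourceSpec(
        "nonreversing_superficial",
        band_powers={"slow_gamma": 1.0},
        coupling_depth={"slow_gamma": kc},
        preferred_phase_deg=90.0,
    )
    ref = synth.SourceSpec(
        "linear_volume_conducted", band_powers={"theta": 1.0}, theta_coherent=True
    )
    ev = synth.make_events(n_trials=n_trials, interval_s=2.0, jitter_s=0.1, seed=seed)
    s, _ = synth.make_timecourses([src, ref], ev, fs, ev.pull_onsets[-1] + 1.5, seed=seed)
    phase = cpl.analytic_phase_amp(cpl.bandpass(s[1], fs, cpl.THETA_BAND))[0]
    env = cpl.analytic_phase_amp(cpl.bandpass(s[0], fs, cpl.SLOW_GAMMA))[1]
    phs, envs = [], []
    for onset in ev.pull_onsets:
        a, b = int((onset - 1.0) * fs), int((onset + 0.5) * fs)
        phs.append(phase[a:b])
        envs.append(env[a:b])
    return phs, envs


class TestSurrogateMI:
    def test_mi_monotone_in_coupling_depth(self):
        for seed in (0, 1):
            mis = [
                cpl.surrogate_mi(*_coupled_session(kc, seed), seed=seed).mi
                for kc in (0.0, 0.3, 0.6, 0.9)
            ]
            assert all(np.diff(mis) > 0)

    def test_strong_coupling_detected(self):
        res = cpl.surrogate_mi(*_coupled_session(0.9, 3), seed=1)
        assert res.significant
        assert res.p_empirical < 0.01

    def test_null_false_positive_rate_near_alpha(self):
        """At zero coupling the empirical-rank flag fires at ~1% (binomial
        check over 150 seeds)."""
        hits = sum(
            cpl.surrogate_mi(*_coupled_session(0.0, 500 + s, n_trials=12), seed=s).significant
            for s in range(150)
        )
        assert hits <= 8  # P(X > 8 | n=150, p=0.01) ~ 2e-5

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="2 aligned trials"):
            cpl.surrogate_mi([np.zeros(10)], [np.zeros(10)])


class TestThetaChannelSelection:
    def test_picks_channel_with_strongest_theta(self):
        rng = np.random.default_rng(0)
        t = np.arange(int(10 * FS)) / FS
        samples = 0.05 * rng.standard_normal((4, t.size))
        samples[2] += np.sin(2 * np.pi * 7 * t)
        rec = LaminarRecording(
            samples=samples, depths=np.arange(4) * 150.0 + 100.0, fs=FS
        )
        assert cpl.select_theta_channel(rec) == 2


class TestWatsonWilliams:
    def test_identical_groups_give_f_near_zero(self):
        rng = np.random.default_rng(0)
        g = rng.vonmises(0.0, 5.0, 100)
        F, p, info = cpl.watson_williams(g, g.copy())
        assert F == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_power_for_90_degree_separation(self):
        rng = np.random.default_rng(1)
        a = rng.vonmises(0.0, 5.0, 100)
        b = rng.vonmises(np.pi / 2, 5.0, 100)
        F, p, info = cpl.watson_williams(a, b)
        assert p < 0.01

    def test_type_one_error_calibrated(self):
        """Two groups from one von Mises: rejection at alpha = 0.05 happens
        at about the nominal rate (Monte-Carlo, 400 draws)."""
        rng = np.random.default_rng(2)
        rej = 0
        n = 400
        for _ in range(n):
            a = rng.vonmises(1.0, 3.0, 50)
            b = rng.vonmises(1.0, 3.0, 50)
            _, p, _ = cpl.watson_williams(a, b)
            rej += p < 0.05
        assert 0.025 < rej / n < 0.08

    def test_low_concentration_flagged_invalid(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-np.pi, np.pi, 50)
        b = rng.uniform(-np.pi, np.pi, 50)
        _, _, info = cpl.watson_williams(a, b)
        assert info["valid"] is False

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            cpl.watson_williams(np.array([0.1]), np.array([0.2, 0.3]))
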