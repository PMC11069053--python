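"""Generator correctness: determinism, phase-locking law, kernels, bounds."""

import numpy as np
import pytest
from scipy.special import i0, i1

from oracles import circular_resultant
from spikefield.session import validate_session
from spikefield.synth import (
    SynthConfig,
    draw_oscillation_phases,
    generate_calcium,
    generate_lfp,
    generate_session,
    generate_speed,
    generate_spikes,
    generate_trajectory,
    get_preset,
    resample_speed,
    theta_phase_series,
)


def rng(seed=0):
    return np.random.default_rng(seed)


class TestLfp:
    def test_zero_amplitude_zero_noise_gives_silence(self):
        cfg = SynthConfig(
            duration_s=12,
            oscillations=tuple((n, f, 0.0) for n, f, _ in SynthConfig().oscillations),
            noise_scale=0.0,
        )
        lfp = generate_lfp(cfg, rng())
        assert np.all(lfp.samples == 0.0)

    def test_pure_theta_tone_concentrates_power_in_theta(self):
        from spikefield.lfp import band_power, compute_psd

        cfg = SynthConfig(
            duration_s=30,
            oscillations=(("delta", 2, 0.0), ("theta", 8, 50.0),
                          ("beta", 20, 0.0), ("gamma", 40, 0.0)),
            noise_scale=0.0,
        )
        psd = compute_psd(generate_lfp(cfg, rng()))
        assert band_power(psd, "theta").relative >= 0.99

    def test_determinism_same_seed_identical_samples(self):
        cfg = SynthConfig(duration_s=15)
        a = generate_lfp(cfg, rng(7))
        b = generate_lfp(cfg, rng(7))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            generate_lfp(SynthConfig(duration_s=5), rng())


class TestSpikes:
    def _spikes(self, kappa, seed, duration=600.0, rate=5.0):
        cfg = SynthConfig(duration_s=duration, kappa=kappa, n_rs=1, n_fs=0,
                          rs_rate_range_hz=(rate, rate))
        phases = draw_oscillation_phases(cfg, rng(seed))
        theta = theta_phase_series(cfg, phases)
        return cfg, theta, generate_spikes(cfg, theta, rng(seed))[0]

    def test_kappa_zero_is_homogeneous_poisson(self):
        rate = 5.0
        cfg, _, unit = self._spikes(kappa=0.0, seed=1, duration=600.0, rate=rate)
        n = unit.n_spikes
        se = np.sqrt(rate * cfg.duration_s)
        assert abs(n - rate * cfg.duration_s) < 3 * se

    def test_von_mises_resultant_matches_closed_form(self):
        kappa = 4.0
        lengths, means = [], []
        for seed in range(5):
            cfg, theta, unit = self._spikes(kappa, seed, duration=600.0)
            ph = np.interp(unit.spike_times,
                           np.arange(theta.size) / cfg.fs_lfp, theta)
            R, mu = circular_resultant(ph)
            lengths.append(R)
            means.append(mu)
        expected = i1(kappa) / i0(kappa)
        assert abs(np.mean(lengths) - expected) < 0.02
        assert abs(np.angle(np.mean(np.exp(1j * np.array(means))))) < 0.15

    def test_fs_template_half_the_rs_width(self):
        cfg = SynthConfig(duration_s=12, n_rs=1, n_fs=1)
        phases = draw_oscillation_phases(cfg, rng(3))
        units = generate_spikes(cfg, theta_phase_series(cfg, phases), rng(3))
        widths = {u.unit_class: u.trough_to_peak_ms for u in units}
        assert widths["FS"] / widths["RS"] == pytest.approx(0.5)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            self._spikes(kappa=-1.0, seed=0, duration=12.0)

    def test_resultant_monotone_in_kappa(self):
        kappas = [0.0, 0.5, 1.0, 2.0, 4.0]
        mean_R = []
        for kappa in kappas:
            Rs = []
            for seed in range(10):
                cfg, theta, unit = self._spikes(kappa, seed, duration=120.0)
                ph = np.interp(unit.spike_times,
                               np.arange(theta.size) / cfg.fs_lfp, theta)
                Rs.append(circular_resultant(ph)[0])
            mean_R.append(np.mean(Rs))
        assert all(a < b for a, b in zip(mean_R, mean_R[1:]))


class TestCalcium:
    def test_no_events_no_noise_gives_zero_traces(self):
        cfg = SynthConfig(duration_s=30, transient_rate_hz=0.0,
                          trace_noise_sd=0.0, n_neurons_ca=3)
        speed = generate_speed(cfg, rng(1))
        ca = generate_calcium(cfg, speed, rng(1))
        assert np.all(ca.traces == 0.0)

    def test_exponential_kernel_shape(self):
        # a single event of amplitude 100 at frame 50 (tau = 1 s, fs = 10)
        # peaks at 100 there and decays to 100/e ~ 36.8 at frame 60
        from spikefield.synth import decay_kernel

        kernel = decay_kernel(tau_s=1.0, fs=10.0)
        impulses = np.zeros(200)
        impulses[50] = 100.0
        trace = np.convolve(impulses, kernel)[:200]
        assert trace[50] == pytest.approx(100.0)
        assert trace[60] == pytest.approx(100.0 * np.exp(-1.0), rel=1e-9)
        assert np.argmax(trace) == 50

    def test_shared_latent_raises_pairwise_correlation(self):
        from spikefield.correlations import corr_matrix

        diffs = []
        for seed in range(20):
            means = {}
            for a in (0.0, 1.0):
                cfg = SynthConfig(duration_s=120, latent_loading=a,
                                  speed_coupling=0.0, n_neurons_ca=10,
                                  trace_noise_sd=2.0)
                speed = generate_speed(cfg, rng(seed))
                ca = generate_calcium(cfg, speed, rng(seed))
                m = corr_matrix(ca.traces)
                means[a] = m[np.triu_indices_from(m, k=1)].mean()
            diffs.append(means[1.0] - means[0.0])
        assert np.mean(diffs) > 0.02


class TestSpeedAndTrajectory:
    def test_zero_volatility_zero_mean_is_silent(self):
        cfg = SynthConfig(duration_s=20, speed_volatility=0.0, speed_mean_cms=0.0)
        sp = generate_speed(cfg, rng(0))
        assert np.all(sp.speed == 0.0)

    def test_trajectory_stays_inside_arena(self):
        cfg = SynthConfig(duration_s=4000, fs_traj=25.0)  # 1e5 steps
        tr = generate_trajectory(cfg, rng(2))
        assert tr.x.size == 100000
        assert np.all((tr.x >= 0) & (tr.x <= cfg.arena_length_cm))
        assert np.all((tr.y >= 0) & (tr.y <= cfg.arena_width_cm))

    def test_doubling_mean_speed_doubles_path_length(self):
        ratios = []
        for seed in range(5):
            dists = {}
            for mean in (4.0, 8.0):
                cfg = SynthConfig(duration_s=300, speed_mean_cms=mean,
                                  move_fraction=1.0)
                tr = generate_trajectory(cfg, rng(seed))
                dists[mean] = np.hypot(np.diff(tr.x), np.diff(tr.y)).sum()
            ratios.append(dists[8.0] / dists[4.0])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_resample_speed_linear_interpolation(self):
        from spikefield.session import SpeedTrace

        sp = SpeedTrace(np.array([0.0, 10.0]), fs=1.0)
        out = resample_speed(sp, fs_out=4.0, n_out=5)
        np.testing.assert_allclose(out, [0.0, 2.5, 5.0, 7.5, 10.0])


class TestSessionComposition:
    def test_vehicle_session_is_valid(self, vehicle_session):
        assert validate_session(vehicle_session) == []

    def test_same_preset_and_seed_bit_identical(self):
        base = SynthConfig(duration_s=30)
        a = generate_session("MK801", 5, base)
        b = generate_session("MK801", 5, base)
        np.testing.assert_array_equal(a.lfp.samples, b.lfp.samples)
        np.testing.assert_array_equal(a.calcium.traces, b.calcium.traces)
        for ua, ub in zip(a.units, b.units):
            np.testing.assert_array_equal(ua.spike_times, ub.spike_times)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            generate_session("KETAMINE", 0)

    def test_mk801_raises_theta_power_at_matched_seeds(self):
        from spikefield.lfp import band_power, bandsplit, compute_psd

        for seed in range(3):
            powers = {}
            for preset in ("VEHICLE", "MK801"):
                s = generate_session(preset, seed, SynthConfig(duration_s=30))
                psd = compute_psd(bandsplit(s.lfp)[0])
                powers[preset] = band_power(psd, "theta").power
            assert powers["MK801"] > powers["VEHICLE"]

    def test_preset_overrides_leave_delta_beta_and_tau_unchanged(self):
        veh = get_preset("VEHICLE")
        mk = get_preset("MK801")
        ari = get_preset("MK801_ARI")
        amp_veh, amp_mk = (dict((n, a) for n, _, a in c.oscillations)
                           for c in (veh, mk))
        assert amp_mk["delta"] == amp_veh["delta"]
        assert amp_mk["beta"] == amp_veh["beta"]
        assert mk.tau_decay_s == veh.tau_decay_s
        # ARI parameters sit strictly between MK801 and vehicle
        for attr in ("kappa", "transient_rate_hz", "latent_loading",
                     "speed_coupling", "speed_mean_cms"):
            lo, hi = sorted([getattr(veh, attr), getattr(mk, attr)])
            assert lo < getattr(ari, attr) < hi
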