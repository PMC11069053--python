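"""RS/FS classification, firing rate, and spike-field coherence.

The coherence checks use the two analytic limits: identical windows
(perfect phase locking) give 100%, and spikes independent of the LFP give
an STA whose power shrinks like 1/N, so coherence ~ 100/N percent.
"""

import numpy as np
import pytest

from spikefield.session import LfpSignal, SpeedTrace
from spikefield.spikes import (
    classify_unit,
    coherent_unit_summary,
    equalized_spike_count,
    firing_rate,
    locomotion_mask,
    spike_field_coherence,
)
from spikefield.synth import (
    SynthConfig,
    draw_oscillation_phases,
    generate_lfp,
    generate_spikes,
    theta_phase_series,
)


def sine_lfp_signal(freq=8.0, amp=50.0, fs=1000.0, dur=60.0):
    t = np.arange(int(dur * fs)) / fs
    return LfpSignal(amp * np.sin(2 * np.pi * freq * t), fs=fs, band="lfp")


class TestClassification:
    @pytest.mark.parametrize(
        "width_ms, rate_hz, expected",
        [
            (0.8, 5.0, "RS"),    # broad waveform, low rate
            (0.4, 30.0, "FS"),   # narrow waveform, high rate
            (0.8, 20.0, "RS"),   # width-primary: rate inconsistency only flags
            (0.46, 10.0, "RS"),  # just above the 0.45 ms boundary
            (0.45, 30.0, "FS"),  # boundary itself is FS
        ],
    )
    def test_width_primary_classification(self, unit_factory, width_ms,
                                          rate_hz, expected):
        dur = 100.0
        times = np.arange(0, dur, 1.0 / rate_hz)
        unit = unit_factory(times, width_ms=width_ms)
        assert classify_unit(unit, dur) == expected

    def test_rate_inconsistency_is_logged(self, unit_factory, caplog):
        dur = 100.0
        unit = unit_factory(np.arange(0, dur, 0.05), width_ms=0.8)  # 20/s, broad
        with caplog.at_level("WARNING"):
            cls = classify_unit(unit, dur)
        assert cls == "RS"
        assert "inconsistent" in caplog.text

    def test_missing_waveform_unclassified(self, unit_factory, caplog):
        unit = unit_factory([1.0, 2.0], width_ms=0.8)
        unit.waveform = np.array([])
        with caplog.at_level("WARNING"):
            assert classify_unit(unit, 10.0) == "unclassified"


class TestFiringRate:
    def test_counts_over_bin_duration(self, unit_factory):
        unit = unit_factory(np.linspace(0.05, 1.95, 10))  # 10 spikes in [0, 2)
        rs = firing_rate(unit, bin_s=2.0, duration_s=2.0)
        assert rs.rate.tolist() == [5.0]

    def test_empty_train_all_zero(self, unit_factory):
        unit = unit_factory([])
        rs = firing_rate(unit, bin_s=1.0, duration_s=5.0)
        assert np.all(rs.rate == 0.0)
        assert rs.rate.size == 5

    def test_uniform_grid_constant_rate(self, unit_factory):
        unit = unit_factory(np.arange(0, 10, 0.1))
        rs = firing_rate(unit, bin_s=1.0, duration_s=10.0)
        assert np.all(rs.rate == 10.0)

    def test_half_open_bins(self, unit_factory):
        # a spike exactly at a bin edge belongs to the right-hand bin
        unit = unit_factory([1.0])
        rs = firing_rate(unit, bin_s=1.0, duration_s=2.0)
        assert rs.rate.tolist() == [0.0, 1.0]


class TestSpikeFieldCoherence:
    def test_perfect_phase_locking_gives_100_percent_at_theta(self, unit_factory):
        lfp = sine_lfp_signal()
        # spikes exactly at successive sinusoid peaks: t = 1/32 + k/8
        times = 1.0 / 32.0 + np.arange(8, 450) / 8.0
        unit = unit_factory(times)
        spec = spike_field_coherence(unit, lfp, None, n_spikes=200, seed=0)
        i8 = np.argmin(np.abs(spec.freqs - 8.0))
        assert spec.coherence[i8] == pytest.approx(100.0, abs=1e-6)
        assert spec.theta_peak_pct == pytest.approx(100.0, abs=1e-6)
        # the 300 ms window gives ~3.3 Hz bins; the theta peak must sit
        # within one bin of the true 8 Hz rhythm
        assert abs(spec.theta_peak_freq_hz - 8.0) <= spec.freqs[1]

    def test_independent_spikes_follow_one_over_n_law(self, unit_factory):
        fs, dur = 1000.0, 120.0
        means = {}
        for n_spikes in (50, 200):
            vals = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                lfp = LfpSignal(rng.normal(0, 20, int(dur * fs)), fs=fs,
                                band="lfp")
                times = np.sort(rng.uniform(1, dur - 1, 600))
                spec = spike_field_coherence(unit_factory(times), lfp, None,
                                             n_spikes=n_spikes, seed=seed)
                vals.append(spec.coherence[spec.freqs > 0].mean())
            means[n_spikes] = np.mean(vals)
        assert means[50] == pytest.approx(100.0 / 50, rel=0.5)
        assert means[200] == pytest.approx(100.0 / 200, rel=0.5)
        assert means[200] < means[50]

    def test_coherence_bounded_and_deterministic(self, unit_factory):
        rng = np.random.default_rng(5)
        lfp = LfpSignal(rng.normal(0, 10, 60000) +
                        30 * np.sin(2 * np.pi * 8 * np.arange(60000) / 1000),
                        fs=1000.0, band="lfp")
        times = np.sort(rng.uniform(1, 59, 400))
        unit = unit_factory(times)
        a = spike_field_coherence(unit, lfp, None, n_spikes=100, seed=3)
        b = spike_field_coherence(unit, lfp, None, n_spikes=100, seed=3)
        np.testing.assert_array_equal(a.coherence, b.coherence)
        assert np.all((a.coherence >= 0) & (a.coherence <= 100))

    def test_theta_peak_increases_with_locking_strength(self):
        mean_peaks = []
        for kappa in (0.0, 2.0, 4.0):
            vals = []
            for seed in range(8):
                cfg = SynthConfig(duration_s=120, kappa=kappa, n_rs=1, n_fs=0,
                                  rs_rate_range_hz=(5.0, 5.0), noise_scale=10.0)
                rng = np.random.default_rng(seed)
                phases = draw_oscillation_phases(cfg, rng)
                lfp = generate_lfp(cfg, rng, phases=phases)
                unit = generate_spikes(
                    cfg, theta_phase_series(cfg, phases), rng)[0]
                spec = spike_field_coherence(unit, lfp, None, n_spikes=200,
                                             seed=seed)
                vals.append(spec.theta_peak_pct)
            mean_peaks.append(np.mean(vals))
        assert mean_peaks[0] < mean_peaks[1] < mean_peaks[2]

    def test_too_few_eligible_spikes_errors_with_count(self, unit_factory):
        lfp = sine_lfp_signal(dur=10.0)
        unit = unit_factory(np.linspace(1, 9, 30))
        with pytest.raises(ValueError, match="30 eligible"):
            spike_field_coherence(unit, lfp, None, n_spikes=50, seed=0)

    def test_locomotion_restriction_drops_resting_spikes(self, unit_factory):
        lfp = sine_lfp_signal(dur=20.0)
        # moving during the first 10 s only
        speed = SpeedTrace(np.r_[np.full(500, 5.0), np.zeros(500)], fs=50.0)
        assert locomotion_mask(speed).sum() > 400
        unit = unit_factory(np.linspace(0.5, 19.5, 100))
        n = equalized_spike_count([unit], lfp, speed)
        assert 40 <= n <= 55  # only the first-half spikes are eligible


class TestSummary:
    def _spec_with_peak(self, peak, freq=8.0):
        from spikefield.spikes import CoherenceSpectrum

        return CoherenceSpectrum(
            freqs=np.array([freq]), coherence=np.array([peak]),
            n_spikes_used=100, peak_value_pct=peak, peak_freq_hz=freq,
            theta_peak_pct=peak, theta_peak_freq_hz=freq,
        )

    def test_threshold_count_matches_published_example(self):
        # two example units with peaks 43.93% and 6.55%: one exceeds 20%
        spectra = [self._spec_with_peak(43.93), self._spec_with_peak(6.55)]
        s = coherent_unit_summary(spectra, threshold_pct=20.0)
        assert s.n_above_threshold == 1
        assert s.fraction_above == 0.5

    def test_all_below_threshold(self):
        s = coherent_unit_summary([self._spec_with_peak(5.0)] * 3)
        assert s.n_above_threshold == 0

    def test_zero_threshold_counts_nonzero_peaks(self):
        spectra = [self._spec_with_peak(0.0), self._spec_with_peak(1.0),
                   self._spec_with_peak(15.0)]
        s = coherent_unit_summary(spectra, threshold_pct=0.0)
        assert s.n_above_threshold == 2
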