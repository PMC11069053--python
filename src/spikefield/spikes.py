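"""Unit classification, firing rates, and spike–field coherence.

Spike–field coherence (SFC) quantifies how consistently a unit fires at a
particular LFP phase.  For a fixed number of randomly chosen spikes emitted
during locomotion, a 300 ms LFP window is extracted around each spike; the
ratio of the power spectrum of the spike-triggered average (STA) to the
mean power spectrum of the individual windows, expressed in percent, is the
coherence.  Perfectly phase-locked spikes give identical windows and 100%
coherence; spikes independent of the LFP give an STA that shrinks like
1/N, so expected coherence is about 100/N percent.  Using the same spike
count for every unit (the count of the sparsest unit) removes the
spike-number bias when comparing units.  The theta-band SFC of a unit is
the maximum coherence in 5–12 Hz.

RS/FS classification is width-primary: fast-spiking (putative interneuron)
waveforms are roughly half the trough-to-peak width of regular-spiking
(putative pyramidal) ones, so the boundary defaults to 0.45 ms; firing-rate
ranges (RS < 15/s, FS 15–50/s) serve as a consistency check only, because
the ranges meet at 15/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .session import LfpSignal, SpeedTrace, SpikeUnit

logger = logging.getLogger(__name__)

THETA_BAND_HZ = (5.0, 12.0)
RS_RATE_RANGE_HZ = (0.0, 15.0)
FS_RATE_RANGE_HZ = (15.0, 50.0)
DEFAULT_WIDTH_BOUNDARY_MS = 0.45


@dataclass
class RateSeries:
    """Instantaneous firing rate: spike count per bin / bin duration."""

    bin_edges: np.ndarray  # s, len = n_bins + 1
    rate: np.ndarray  # spikes/s


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray  # Hz
    coherence: np.ndarray  # percent, in [0, 100]
    n_spikes_used: int
    peak_value_pct: float
    peak_freq_hz: float
    theta_peak_pct: float
    theta_peak_freq_hz: float
    unit_id: str = ""
    meta: dict = field(default_factory=dict)


def classify_unit(unit: SpikeUnit, session_duration_s: float,
                  width_boundary_ms: float = DEFAULT_WIDTH_BOUNDARY_MS) -> str:
    """Width-primary RS/FS classification with a rate consistency check."""
    if unit.waveform is None or unit.waveform.size == 0 or unit.trough_to_peak_ms <= 0:
        logger.warning("unit %s: missing/invalid waveform -> unclassified",
                       unit.unit_id)
        return "unclassified"
    cls = "RS" if unit.trough_to_peak_ms > width_boundary_ms else "FS"
    rate = unit.mean_rate(session_duration_s)
    lo, hi = RS_RATE_RANGE_HZ if cls == "RS" else FS_RATE_RANGE_HZ
    if np.isfinite(rate) and not (lo <= rate <= hi):
        logger.warning(
            "unit %s: rate %.2f/s inconsistent with width-based class %s "
            "(expected %g-%g/s); keeping %s",
            unit.unit_id, rate, cls, lo, hi, cls,
        )
    return cls


def firing_rate(unit: SpikeUnit, bin_s: float,
                duration_s: float | None = None) -> RateSeries:
    """Spike counts in half-open bins [t, t + bin_s), divided by bin_s."""
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    if duration_s is None:
        duration_s = float(unit.spike_times[-1]) if unit.n_spikes else bin_s
    n_bins = max(1, int(np.ceil(duration_s / bin_s)))
    edges = np.arange(n_bins + 1) * bin_s
    idx = np.floor(unit.spike_times / bin_s).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    counts = np.bincount(idx, minlength=n_bins)
    return RateSeries(bin_edges=edges, rate=counts / bin_s)


def locomotion_mask(speed: SpeedTrace, threshold_cms: float = 1.0,
                    smooth_s: float = 0.5) -> np.ndarray:
    """Boolean locomotion mask: median-smoothed speed above threshold."""
    k = int(round(smooth_s * speed.fs))
    k = max(1, k | 1)  # odd kernel
    smoothed = sps.medfilt(speed.speed, kernel_size=k)
    return smoothed > threshold_cms


def _window_psd(windows: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered one-sided periodogram of each row (density, µV²/Hz)."""
    n = windows.shape[-1]
    taper = sps.windows.hann(n, sym=False)
    taper = taper / np.sqrt(np.sum(taper**2))
    demeaned = windows - windows.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(taper * demeaned, axis=-1)
    pxx = np.abs(spec) ** 2 / fs
    pxx[..., 1:] *= 2.0
    if n % 2 == 0:
        pxx[..., -1] /= 2.0
    return np.fft.rfftfreq(n, d=1.0 / fs), pxx


def spike_field_coherence(unit: SpikeUnit, lfp: LfpSignal,
                          speed: SpeedTrace | None, n_spikes: int, seed: int,
                          window_s: float = 0.3,
                          speed_threshold_cms: float = 1.0,
                          smooth_s: float = 0.5) -> CoherenceSpectrum:
    """Spike-count-equalized spike–field coherence of one unit.

    Steps: restrict spikes to locomotion epochs (all spikes if ``speed`` is
    None); drop spikes whose centered window crosses a record edge;
    subsample exactly ``n_spikes`` without replacement; average the windows
    (STA); divide the STA power spectrum by the mean single-window power
    spectrum; express in percent, clipped to [0, 100].
    """
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    fs = lfp.fs
    half = int(round(window_s / 2.0 * fs))
    times = unit.spike_times

    if speed is not None:
        mask = locomotion_mask(speed, speed_threshold_cms, smooth_s)
        moving = np.interp(times, speed.times, mask.astype(float)) >= 0.5
        times = times[moving]
    centers = np.round(times * fs).astype(int)
    ok = (centers - half >= 0) & (centers + half <= lfp.samples.size)
    centers = centers[ok]
    if centers.size < n_spikes:
        raise ValueError(
            f"unit {unit.unit_id or '?'}: only {centers.size} eligible spikes, "
            f"need {n_spikes}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(centers, size=n_spikes, replace=False)
    windows = np.stack([lfp.samples[c - half : c + half] for c in chosen])

    sta = windows.mean(axis=0)
    freqs, psd_each = _window_psd(windows, fs)
    _, psd_sta = _window_psd(sta[None, :], fs)
    denom = psd_each.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = 100.0 * psd_sta[0] / denom
    coh[~np.isfinite(coh)] = 0.0
    coh = np.clip(coh, 0.0, 100.0)

    nz = freqs > 0  # DC excluded from peak search
    f_nz, c_nz = freqs[nz], coh[nz]
    i_peak = int(np.argmax(c_nz))  # ties resolve to the lowest frequency
    th = (f_nz >= THETA_BAND_HZ[0]) & (f_nz <= THETA_BAND_HZ[1])
    if not th.any():
        raise ValueError("frequency grid has no bins inside the theta band")
    i_th = int(np.argmax(c_nz[th]))
    return CoherenceSpectrum(
        freqs=freqs,
        coherence=coh,
        n_spikes_used=n_spikes,
        peak_value_pct=float(c_nz[i_peak]),
        peak_freq_hz=float(f_nz[i_peak]),
        theta_peak_pct=float(c_nz[th][i_th]),
        theta_peak_freq_hz=float(f_nz[th][i_th]),
        unit_id=unit.unit_id,
        meta={"window_s": window_s, "seed": seed,
              "speed_threshold_cms": speed_threshold_cms},
    )


def equalized_spike_count(units: list[SpikeUnit], lfp: LfpSignal,
                          speed: SpeedTrace | None,
                          window_s: float = 0.3,
                          speed_threshold_cms: float = 1.0,
                          smooth_s: float = 0.5) -> int:
    """Eligible-spike count of the sparsest unit (the equalization target)."""
    counts = []
    fs = lfp.fs
    half = int(round(window_s / 2.0 * fs))
    mask = None
    if speed is not None:
        mask = locomotion_mask(speed, speed_threshold_cms, smooth_s)
    for u in units:
        t = u.spike_times
        if speed is not None:
            moving = np.interp(t, speed.times, mask.astype(float)) >= 0.5
            t = t[moving]
        c = np.round(t * fs).astype(int)
        counts.append(int(((c - half >= 0) & (c + half <= lfp.samples.size)).sum()))
    if not counts:
        raise ValueError("no units supplied")
    return min(counts)


@dataclass
class CoherenceSummary:
    n_units: int
    n_above_threshold: int
    fraction_above: float
    threshold_pct: float
    peak_freqs_hz: np.ndarray
    theta_peaks_pct: np.ndarray


def coherent_unit_summary(spectra: list[CoherenceSpectrum],
                          threshold_pct: float = 20.0) -> CoherenceSummary:
    """Count units whose peak coherence exceeds the threshold (default 20%)."""
    if not spectra:
        raise ValueError("need at least one coherence spectrum")
    peaks = np.array([s.peak_value_pct for s in spectra])
    n_above = int((peaks > threshold_pct).sum())
    return CoherenceSummary(
        n_units=len(spectra),
        n_above_threshold=n_above,
        fraction_above=n_above / len(spectra),
        threshold_pct=threshold_pct,
        peak_freqs_hz=np.array([s.peak_freq_hz for s in spectra]),
        theta_peaks_pct=np.array([s.theta_peak_pct for s in spectra]),
    )
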