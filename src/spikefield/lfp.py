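"""LFP band-splitting and multitaper band-power estimation.

Band conventions (Hz): delta 1–4, theta 5–12, beta 13–30, gamma 30–80.

The raw wideband signal is split with zero-phase 4th-order Butterworth
filters into the LFP band (1–300 Hz) and the spike band (300–5000 Hz);
zero-phase filtering preserves the spike–field timing relationships that
the coherence analysis depends on.

Power spectra use DPSS (Slepian) multitapers averaged over 50%-overlapping
windows — the conventional multitaper estimator for hippocampal LFP — with
2 s windows, time–bandwidth 3 and 5 tapers by default.  The estimate is a
one-sided density in µV²/Hz satisfying Parseval: the integral over
frequency matches the signal variance for broadband inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .session import LfpSignal

logger = logging.getLogger(__name__)

BANDS_HZ: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (5.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}

LFP_CORNERS_HZ = (1.0, 300.0)
SPIKEBAND_CORNERS_HZ = (300.0, 5000.0)


@dataclass
class PowerSpectrum:
    freqs: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # µV²/Hz, >= 0
    method: dict = field(default_factory=dict)

    def total_power(self, lo_hz: float | None = None,
                    hi_hz: float | None = None) -> float:
        """Trapezoidal integral of the density over [lo, hi] (µV²)."""
        lo = self.freqs[0] if lo_hz is None else lo_hz
        hi = self.freqs[-1] if hi_hz is None else hi_hz
        m = (self.freqs >= lo) & (self.freqs <= hi)
        if m.sum() < 2:
            raise ValueError(f"band [{lo}, {hi}] Hz outside spectrum range")
        return float(np.trapezoid(self.power[m], self.freqs[m]))


@dataclass
class BandPower:
    band: str
    lo_hz: float
    hi_hz: float
    power: float  # µV², band-integrated
    relative: float  # fraction of total 1–80 Hz power


def bandsplit(raw: LfpSignal) -> tuple[LfpSignal, LfpSignal | None]:
    """Split a wideband signal into LFP (1–300 Hz) and spike band (300–5000 Hz).

    Returns ``(lfp, spikeband)``; ``spikeband`` is ``None`` with a warning
    when the sampling rate cannot represent 5 kHz.
    """
    fs = raw.fs
    if fs < 2 * LFP_CORNERS_HZ[1]:
        raise ValueError(
            f"sampling rate {fs} Hz too low to extract the 1-300 Hz LFP band"
        )
    sos_lfp = sps.butter(4, LFP_CORNERS_HZ, btype="bandpass", fs=fs, output="sos")
    lfp = LfpSignal(sps.sosfiltfilt(sos_lfp, raw.samples), fs=fs, band="lfp")

    spikeband = None
    if fs >= 2 * SPIKEBAND_CORNERS_HZ[1]:
        sos_spk = sps.butter(
            4, SPIKEBAND_CORNERS_HZ, btype="bandpass", fs=fs, output="sos"
        )
        spikeband = LfpSignal(
            sps.sosfiltfilt(sos_spk, raw.samples), fs=fs, band="spikeband"
        )
    else:
        logger.warning(
            "fs = %g Hz < 10 kHz: spike band (300-5000 Hz) omitted", fs
        )
    return lfp, spikeband


def compute_psd(lfp: LfpSignal, window_s: float = 2.0, n_tapers: int = 5,
                time_bandwidth: float = 3.0, overlap: float = 0.5) -> PowerSpectrum:
    """Multitaper PSD averaged over 50%-overlapping windows."""
    x = np.asarray(lfp.samples, dtype=float)
    fs = lfp.fs
    nper = int(round(window_s * fs))
    if x.size < 2 * nper:
        raise ValueError(
            f"record ({x.size / fs:.1f} s) shorter than 2 windows of {window_s} s"
        )
    step = max(1, int(round(nper * (1.0 - overlap))))
    tapers = sps.windows.dpss(nper, time_bandwidth, Kmax=n_tapers)
    # unit-energy tapers make the periodogram integrate to the segment variance
    tapers = tapers / np.sqrt(np.sum(tapers**2, axis=1, keepdims=True))
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)

    acc = np.zeros(freqs.size)
    n_seg = 0
    for start in range(0, x.size - nper + 1, step):
        seg = x[start : start + nper]
        seg = seg - seg.mean()
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        pxx = (np.abs(spec) ** 2).mean(axis=0) / fs
        # one-sided density: double everything except DC (and Nyquist if present)
        pxx[1:] *= 2.0
        if nper % 2 == 0:
            pxx[-1] /= 2.0
        acc += pxx
        n_seg += 1
    power = acc / n_seg
    return PowerSpectrum(
        freqs=freqs,
        power=power,
        method={
            "estimator": "dpss-multitaper",
            "window_s": window_s,
            "n_tapers": n_tapers,
            "time_bandwidth": time_bandwidth,
            "overlap": overlap,
            "n_segments": n_seg,
        },
    )


def band_power(psd: PowerSpectrum, band: str) -> BandPower:
    """Integrated power in one of the four named bands."""
    if band not in BANDS_HZ:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS_HZ)}")
    lo, hi = BANDS_HZ[band]
    if lo < psd.freqs[0] or hi > psd.freqs[-1]:
        raise ValueError(
            f"band {band} [{lo}, {hi}] Hz outside spectrum range "
            f"[{psd.freqs[0]}, {psd.freqs[-1]}] Hz"
        )
    p = psd.total_power(lo, hi)
    total = psd.total_power(1.0, 80.0)
    return BandPower(band=band, lo_hz=lo, hi_hz=hi, power=p,
                     relative=p / total if total > 0 else 0.0)


def band_power_table(psd: PowerSpectrum) -> dict[str, BandPower]:
    """All four canonical band powers of one spectrum."""
    return {b: band_power(psd, b) for b in BANDS_HZ}
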