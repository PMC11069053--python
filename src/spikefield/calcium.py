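"""Calcium transient detection, decay estimation, and trace standardization.

Transients are detected on raw fluorescence traces (baseline ~ 0) as local
maxima with ``height >= 20``, inter-peak ``distance >= 10`` frames and
topographic ``prominence >= 20`` — at the 10 Hz frame rate, 10 frames is
1 s.  When two candidates fall closer than ``distance``, the higher one is
kept.

The per-neuron decay constant is estimated on the 10 best-isolated
transients (isolation = minimum frame gap to the nearest other transient):
each post-peak segment is fit to ``A * g**n`` by least squares on the log
of its positive samples, the per-frame factor ``g`` is combined across
transients by an amplitude-weighted mean (larger transients carry higher
SNR), and ``tau = -dt / ln(g)``.  A decay above 2.5 s marks a failed
extraction: the neuron is excluded from decay summaries (its detected
transients remain in rate/amplitude analyses).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.signal import find_peaks

from .session import CalciumTraces

logger = logging.getLogger(__name__)

DEFAULT_HEIGHT = 20.0
DEFAULT_DISTANCE = 10
DEFAULT_PROMINENCE = 20.0
MAX_DECAY_S = 2.5


@dataclass
class TransientSet:
    """Detected transients of one neuron."""

    neuron_id: int
    peak_frames: np.ndarray  # frame indices
    amplitudes: np.ndarray  # raw trace value at the peak frame
    fs: float  # frames per second
    n_frames: int  # trace length, for rate normalisation
    decay_tau_s: float | None = None
    decay_valid: bool | None = None
    isolation_scores: np.ndarray | None = None

    @property
    def n_transients(self) -> int:
        return int(self.peak_frames.size)

    @property
    def rate_per_min(self) -> float:
        dur_min = self.n_frames / self.fs / 60.0
        return self.n_transients / dur_min if dur_min > 0 else float("nan")


def detect_transients(trace: np.ndarray, fs: float = 10.0,
                      height: float = DEFAULT_HEIGHT,
                      distance: int = DEFAULT_DISTANCE,
                      prominence: float = DEFAULT_PROMINENCE,
                      neuron_id: int = 0) -> TransientSet:
    """Peak detection on a raw fluorescence trace (scipy ``find_peaks``)."""
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    peaks, _ = find_peaks(trace, height=height, distance=distance,
                          prominence=prominence)
    return TransientSet(
        neuron_id=neuron_id,
        peak_frames=peaks,
        amplitudes=trace[peaks],
        fs=fs,
        n_frames=trace.size,
    )


def isolation_scores(peak_frames: np.ndarray) -> np.ndarray:
    """Minimum frame gap to any neighboring transient (ends use one neighbor)."""
    p = np.asarray(peak_frames)
    n = p.size
    if n == 0:
        return np.array([])
    if n == 1:
        return np.array([np.inf])
    gaps = np.diff(p).astype(float)
    left = np.concatenate(([np.inf], gaps))
    right = np.concatenate((gaps, [np.inf]))
    return np.minimum(left, right)


def select_isolated(ts: TransientSet, k: int = 10) -> TransientSet:
    """The k best-isolated transients; ties by amplitude, then earlier frame."""
    if ts.n_transients == 0:
        raise ValueError("no transients to select from")
    scores = isolation_scores(ts.peak_frames)
    if ts.n_transients < k:
        logger.info("neuron %d: only %d transients (< %d); keeping all",
                    ts.neuron_id, ts.n_transients, k)
    order = sorted(
        range(ts.n_transients),
        key=lambda i: (-scores[i], -ts.amplitudes[i], ts.peak_frames[i]),
    )[:k]
    idx = np.array(order, dtype=int)
    return dc_replace(
        ts,
        peak_frames=ts.peak_frames[idx],
        amplitudes=ts.amplitudes[idx],
        isolation_scores=scores[idx],
    )


def _fit_segment_g(segment: np.ndarray) -> float | None:
    """Per-frame decay factor of one post-peak segment, or None on failure.

    Least squares of log(y) on the frame index over the initial contiguous
    run of positive samples — the first non-positive sample marks where the
    transient has reached the noise floor and ends the fit.  (Keeping later
    isolated positive samples would select positive noise excursions and
    bias the decay long.)  Requires at least 3 usable points and a factor
    in (0, 1).
    """
    y = np.asarray(segment, dtype=float)
    nonpos = np.nonzero(y <= 0)[0]
    end = nonpos[0] if nonpos.size else y.size
    if end < 3:
        return None
    slope = np.polyfit(np.arange(end), np.log(y[:end]), 1)[0]
    g = math.exp(slope)
    if not (0.0 < g < 1.0):
        return None
    return g


def estimate_decay(ts_isolated: TransientSet, trace: np.ndarray, fs_ca: float,
                   max_fit_s: float = 3.0,
                   max_decay_s: float = MAX_DECAY_S) -> tuple[float | None, bool]:
    """Amplitude-weighted per-neuron decay constant with the 2.5 s validity rule.

    Each selected transient contributes the decay factor of its post-peak
    segment, which runs to the next selected transient or ``max_fit_s``,
    whichever comes first.  Returns ``(tau_s, valid)``; ``valid`` is False
    when estimation fails or ``tau_s`` exceeds ``max_decay_s``.
    """
    if ts_isolated.n_transients == 0:
        raise ValueError("need at least one isolated transient")
    trace = np.asarray(trace, dtype=float)
    max_len = int(round(max_fit_s * fs_ca))
    order = np.argsort(ts_isolated.peak_frames)
    frames = ts_isolated.peak_frames[order]
    amps = ts_isolated.amplitudes[order]

    gs, ws = [], []
    for i, p in enumerate(frames):
        end = frames[i + 1] if i + 1 < frames.size else trace.size
        end = min(end, p + max_len, trace.size)
        seg = trace[p:end]
        g = _fit_segment_g(seg)
        if g is not None:
            gs.append(g)
            ws.append(amps[i])
    if not gs:
        logger.warning("neuron %d: decay estimation failed on all transients",
                       ts_isolated.neuron_id)
        return None, False
    g_bar = float(np.average(gs, weights=ws))
    tau = -(1.0 / fs_ca) / math.log(g_bar)
    valid = tau <= max_decay_s
    if not valid:
        logger.info("neuron %d: decay %.2f s > %.1f s -> failed extraction",
                    ts_isolated.neuron_id, tau, max_decay_s)
    return tau, valid


def analyze_neuron(trace: np.ndarray, fs: float = 10.0, neuron_id: int = 0,
                   height: float = DEFAULT_HEIGHT,
                   distance: int = DEFAULT_DISTANCE,
                   prominence: float = DEFAULT_PROMINENCE,
                   k_isolated: int = 10) -> TransientSet:
    """Detection + decay estimation for one neuron in a single call."""
    ts = detect_transients(trace, fs, height, distance, prominence, neuron_id)
    if ts.n_transients == 0:
        return ts
    iso = select_isolated(ts, k_isolated)
    tau, valid = estimate_decay(iso, trace, fs)
    return dc_replace(ts, decay_tau_s=tau, decay_valid=valid,
                      isolation_scores=isolation_scores(ts.peak_frames))


def zscore_traces(traces: CalciumTraces) -> tuple[CalciumTraces, list[int]]:
    """Per-neuron standardization to mean 0, SD 1.

    Constant traces cannot be standardized; they are excluded (not NaN-
    propagated) and their neuron indices returned alongside the result.
    """
    x = traces.traces
    sd = x.std(axis=1)
    constant = np.where(sd == 0)[0].tolist()
    for i in constant:
        logger.warning("neuron %d: constant trace excluded from z-scoring", i)
    keep = sd > 0
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return CalciumTraces(traces=z, fs=traces.fs), constant
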