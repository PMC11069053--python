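"""Domain types for a single recording session.

A :class:`Session` bundles the modalities acquired from one head-fixed or
open-field recording: wideband or band-split LFP, sorted spike units with
mean waveforms, calcium fluorescence traces, treadmill speed and an
open-field trajectory.  All time series share one clock with ``t = 0`` at
session start; times are stored as offsets in seconds, never wall-clock
timestamps.

Optional modalities are ``None`` when not recorded — an absent modality is
distinct from a recorded-but-empty one.  :func:`validate_session` returns
violations as data rather than raising, so callers can report every problem
in a file at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

GROUPS = ("vehicle", "mk801")
TREATMENTS = ("saline", "ari", "none")
LFP_BANDS = ("wideband", "lfp", "spikeband")
UNIT_CLASSES = ("RS", "FS", "unclassified")


@dataclass
class LfpSignal:
    """Continuous extracellular voltage in microvolts.

    ``band`` records the filtering state: ``wideband`` (unfiltered digitized
    signal), ``lfp`` (1–300 Hz band) or ``spikeband`` (300–5000 Hz band).
    """

    samples: np.ndarray  # µV, 1-D
    fs: float  # Hz
    band: str = "wideband"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class SpikeUnit:
    """One sorted single unit: spike times, mean waveform, and class.

    ``trough_to_peak_ms`` is the waveform width used for RS/FS
    classification (regular-spiking putative pyramidal cells have broad
    waveforms, fast-spiking putative interneurons roughly half the width).
    """

    spike_times: np.ndarray  # s, strictly increasing
    waveform: np.ndarray  # mean waveform, amplitude vs sample
    waveform_fs: float  # Hz of the waveform samples
    trough_to_peak_ms: float
    unit_class: str = "unclassified"
    unit_id: str = ""

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.waveform = np.asarray(self.waveform, dtype=float)

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def mean_rate(self, duration_s: float) -> float:
        return self.n_spikes / duration_s if duration_s > 0 else float("nan")


@dataclass
class CalciumTraces:
    """Raw fluorescence, neurons × frames, in arbitrary units (baseline ≈ 0)."""

    traces: np.ndarray  # (n_neurons, n_frames)
    fs: float = 10.0  # frames per second

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs


@dataclass
class SpeedTrace:
    """Treadmill or tracked locomotion speed in cm/s, non-negative."""

    speed: np.ndarray  # cm/s
    fs: float  # Hz

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.speed.size) / self.fs


@dataclass
class Trajectory:
    """Open-field position in cm within a rectangular arena."""

    x: np.ndarray
    y: np.ndarray
    fs: float
    arena_length_cm: float = 55.0
    arena_width_cm: float = 40.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.x.size / self.fs


@dataclass
class Session:
    """One recording session; at least one modality must be present."""

    session_id: str
    group: str  # vehicle | mk801
    treatment: str = "none"  # saline | ari | none
    lfp: Optional[LfpSignal] = None
    units: Optional[list[SpikeUnit]] = None
    calcium: Optional[CalciumTraces] = None
    speed: Optional[SpeedTrace] = None
    trajectory: Optional[Trajectory] = None
    provenance: dict = field(default_factory=dict)

    @property
    def modalities(self) -> list[str]:
        out = []
        for name in ("lfp", "units", "calcium", "speed", "trajectory"):
            if getattr(self, name) is not None:
                out.append(name)
        return out


def _finite(a: np.ndarray) -> bool:
    return bool(np.all(np.isfinite(a)))


def validate_session(session: Session) -> list[str]:
    """Check every type invariant; return one message per violation.

    Pure: identical input yields an identical list.  An empty list means
    the session is valid.
    """
    v: list[str] = []
    if session.group not in GROUPS:
        v.append(f"Session.group: {session.group!r} not in {GROUPS}")
    if session.treatment not in TREATMENTS:
        v.append(f"Session.treatment: {session.treatment!r} not in {TREATMENTS}")
    if not session.modalities:
        v.append("Session: empty session (no modality present)")

    lfp = session.lfp
    if lfp is not None:
        if lfp.band not in LFP_BANDS:
            v.append(f"LfpSignal.band: {lfp.band!r} not in {LFP_BANDS}")
        if lfp.fs <= 0:
            v.append("LfpSignal.fs: must be > 0")
        if not _finite(lfp.samples):
            v.append("LfpSignal.samples: non-finite values")

    if session.units is not None:
        dur = lfp.duration_s if lfp is not None else None
        for i, u in enumerate(session.units):
            if u.spike_times.size > 1 and not np.all(np.diff(u.spike_times) > 0):
                v.append(f"SpikeUnit[{i}].spike_times: not strictly increasing")
            if dur is not None and u.spike_times.size and u.spike_times[-1] > dur:
                v.append(
                    f"SpikeUnit[{i}].spike_times: exceed session duration {dur:.3f} s"
                )
            if u.trough_to_peak_ms <= 0:
                v.append(f"SpikeUnit[{i}].trough_to_peak_ms: must be > 0")
            if u.unit_class not in UNIT_CLASSES:
                v.append(f"SpikeUnit[{i}].unit_class: {u.unit_class!r} invalid")

    ca = session.calcium
    if ca is not None:
        if ca.fs <= 0:
            v.append("CalciumTraces.fs: must be > 0")
        if ca.n_neurons < 1:
            v.append("CalciumTraces.traces: need >= 1 neuron")
        if not _finite(ca.traces):
            v.append("CalciumTraces.traces: non-finite values")

    sp = session.speed
    if sp is not None:
        if sp.fs <= 0:
            v.append("SpeedTrace.fs: must be > 0")
        if np.any(sp.speed < 0):
            v.append("SpeedTrace.speed: negative values")
        if not _finite(sp.speed):
            v.append("SpeedTrace.speed: non-finite values")

    tr = session.trajectory
    if tr is not None:
        if tr.fs <= 0:
            v.append("Trajectory.fs: must be > 0")
        if tr.x.size != tr.y.size:
            v.append("Trajectory: x and y lengths differ")
        if np.any(tr.x < 0) or np.any(tr.x > tr.arena_length_cm):
            v.append(
                f"Trajectory.x: outside arena bound [0, {tr.arena_length_cm}] cm"
            )
        if np.any(tr.y < 0) or np.any(tr.y > tr.arena_width_cm):
            v.append(f"Trajectory.y: outside arena bound [0, {tr.arena_width_cm}] cm")
    return v
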