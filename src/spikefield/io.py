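"""Session readers and writers.

One HDF5 file per session with the layout::

    /                     attrs: session_id, group, treatment, provenance (JSON)
    /lfp                  dataset: samples (µV); attrs: fs, band
    /units/<k>            datasets: spike_times, waveform; attrs: waveform_fs,
                          trough_to_peak_ms, unit_class, unit_id
    /calcium              dataset: traces (neurons × frames); attrs: fs
    /speed                dataset: speed (cm/s); attrs: fs
    /trajectory           datasets: x, y; attrs: fs, arena_length_cm, arena_width_cm

Absent groups mean the modality was not recorded.  Numeric arrays round-trip
bit-exactly (float64 throughout).  CSV export is provided for 1-D series and
per-unit spike times for quick inspection.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .session import (
    CalciumTraces,
    LfpSignal,
    Session,
    SpeedTrace,
    SpikeUnit,
    Trajectory,
    validate_session,
)

logger = logging.getLogger(__name__)

_FORMATS = ("hdf5", "hdf5_csv", "nwb")


class SessionFormatError(ValueError):
    """File does not conform to the documented session layout."""


def write_session(session: Session, path: str | Path, format: str = "hdf5") -> None:
    """Write ``session`` to ``path``; losslessly readable by :func:`read_session`."""
    if format == "nwb":
        raise NotImplementedError(
            "NWB output is not built into this package; use the HDF5 layout"
        )
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}")
    violations = validate_session(session)
    if violations:
        raise SessionFormatError("; ".join(violations))

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["session_id"] = session.session_id
        f.attrs["group"] = session.group
        f.attrs["treatment"] = session.treatment
        f.attrs["provenance"] = json.dumps(session.provenance)
        if session.lfp is not None:
            g = f.create_group("lfp")
            g.create_dataset("samples", data=session.lfp.samples)
            g.attrs["fs"] = float(session.lfp.fs)
            g.attrs["band"] = session.lfp.band
        if session.units is not None:
            ug = f.create_group("units")
            for k, u in enumerate(session.units):
                g = ug.create_group(str(k))
                g.create_dataset("spike_times", data=u.spike_times)
                g.create_dataset("waveform", data=u.waveform)
                g.attrs["waveform_fs"] = float(u.waveform_fs)
                g.attrs["trough_to_peak_ms"] = float(u.trough_to_peak_ms)
                g.attrs["unit_class"] = u.unit_class
                g.attrs["unit_id"] = u.unit_id
        if session.calcium is not None:
            g = f.create_group("calcium")
            g.create_dataset("traces", data=session.calcium.traces)
            g.attrs["fs"] = float(session.calcium.fs)
        if session.speed is not None:
            g = f.create_group("speed")
            g.create_dataset("speed", data=session.speed.speed)
            g.attrs["fs"] = float(session.speed.fs)
        if session.trajectory is not None:
            g = f.create_group("trajectory")
            g.create_dataset("x", data=session.trajectory.x)
            g.create_dataset("y", data=session.trajectory.y)
            g.attrs["fs"] = float(session.trajectory.fs)
            g.attrs["arena_length_cm"] = float(session.trajectory.arena_length_cm)
            g.attrs["arena_width_cm"] = float(session.trajectory.arena_width_cm)
    logger.info("wrote session %s -> %s", session.session_id, path)


def _require_attr(obj, name: str, where: str):
    if name not in obj.attrs:
        raise SessionFormatError(f"missing mandatory field: {where}@{name}")
    val = obj.attrs[name]
    return val.decode() if isinstance(val, bytes) else val


def read_session(path: str | Path, format: str = "hdf5") -> Session:
    """Read a session written by :func:`write_session`."""
    if format == "nwb":
        raise NotImplementedError(
            "NWB input is not built into this package; use the HDF5 layout"
        )
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    with h5py.File(path, "r") as f:
        session = Session(
            session_id=str(_require_attr(f, "session_id", "/")),
            group=str(_require_attr(f, "group", "/")),
            treatment=str(_require_attr(f, "treatment", "/")),
            provenance=json.loads(f.attrs.get("provenance", "{}")),
        )
        if "lfp" in f:
            g = f["lfp"]
            session.lfp = LfpSignal(
                samples=g["samples"][()],
                fs=float(_require_attr(g, "fs", "/lfp")),
                band=str(_require_attr(g, "band", "/lfp")),
            )
        if "units" in f:
            units = []
            for k in sorted(f["units"], key=int):
                g = f["units"][k]
                units.append(
                    SpikeUnit(
                        spike_times=g["spike_times"][()],
                        waveform=g["waveform"][()],
                        waveform_fs=float(_require_attr(g, "waveform_fs", f"/units/{k}")),
                        trough_to_peak_ms=float(
                            _require_attr(g, "trough_to_peak_ms", f"/units/{k}")
                        ),
                        unit_class=str(g.attrs.get("unit_class", "unclassified")),
                        unit_id=str(g.attrs.get("unit_id", k)),
                    )
                )
            session.units = units
        if "calcium" in f:
            g = f["calcium"]
            session.calcium = CalciumTraces(
                traces=g["traces"][()], fs=float(_require_attr(g, "fs", "/calcium"))
            )
        if "speed" in f:
            g = f["speed"]
            session.speed = SpeedTrace(
                speed=g["speed"][()], fs=float(_require_attr(g, "fs", "/speed"))
            )
        if "trajectory" in f:
            g = f["trajectory"]
            session.trajectory = Trajectory(
                x=g["x"][()],
                y=g["y"][()],
                fs=float(_require_attr(g, "fs", "/trajectory")),
                arena_length_cm=float(
                    _require_attr(g, "arena_length_cm", "/trajectory")
                ),
                arena_width_cm=float(_require_attr(g, "arena_width_cm", "/trajectory")),
            )
    if not session.modalities:
        raise SessionFormatError("empty session")
    violations = validate_session(session)
    if violations:
        raise SessionFormatError("; ".join(violations))
    return session


def export_csv(session: Session, outdir: str | Path) -> list[Path]:
    """Export the 1-D series and per-unit spike times as CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, frame: pd.DataFrame) -> None:
        p = outdir / f"{session.session_id}_{name}.csv"
        frame.to_csv(p, index=False)
        written.append(p)

    if session.lfp is not None:
        _write(
            "lfp",
            pd.DataFrame({"t_s": session.lfp.times, "uv": session.lfp.samples}),
        )
    if session.speed is not None:
        _write(
            "speed",
            pd.DataFrame({"t_s": session.speed.times, "cm_s": session.speed.speed}),
        )
    if session.trajectory is not None:
        tr = session.trajectory
        t = np.arange(tr.x.size) / tr.fs
        _write("trajectory", pd.DataFrame({"t_s": t, "x_cm": tr.x, "y_cm": tr.y}))
    if session.units is not None:
        for k, u in enumerate(session.units):
            _write(f"unit{k}_spikes", pd.DataFrame({"spike_time_s": u.spike_times}))
    return written
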