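"""Pairwise neuron–neuron and neuron–speed correlations with Fisher z.

Correlations are computed on z-scored fluorescence as Pearson or Spearman
(Pearson on average-ranked data) coefficients; the Fisher transform
``z = atanh(r)`` stabilizes their variance for group comparisons.  Because
``atanh(±1)`` diverges, r is clipped to ``|r| <= 1 - 1e-6`` before the
transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .session import CalciumTraces, SpeedTrace

R_CLIP = 1.0 - 1e-6
MIN_FRAMES = 30


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing transform atanh(r), with |r| clipped below 1."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def _as_matrix(traces) -> np.ndarray:
    if isinstance(traces, CalciumTraces):
        return traces.traces
    return np.atleast_2d(np.asarray(traces, dtype=float))


def corr_matrix(traces, method: str = "pearson") -> np.ndarray:
    """Full symmetric correlation matrix across neurons (rows)."""
    x = _as_matrix(traces)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 neurons")
    if x.shape[1] < MIN_FRAMES:
        raise ValueError(f"need >= {MIN_FRAMES} frames, got {x.shape[1]}")
    if method == "spearman":
        x = np.apply_along_axis(rankdata, 1, x)  # average ranks for ties
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    return np.corrcoef(x)


def pairwise_corr(traces, method: str = "pearson") -> pd.DataFrame:
    """Upper-triangle pairwise correlations (diagonal excluded) with Fisher z."""
    m = corr_matrix(traces, method)
    i, j = np.triu_indices_from(m, k=1)
    r = m[i, j]
    return pd.DataFrame(
        {"i": i, "j": j, "method": method, "r": r, "fisher_z": fisher_z(r)}
    )


def speed_corr(traces: CalciumTraces, speed: SpeedTrace,
               method: str = "pearson") -> pd.DataFrame:
    """Per-neuron correlation with locomotion speed.

    Speed is linearly interpolated onto the calcium frame clock; frames
    beyond the speed record are dropped.
    """
    x = _as_matrix(traces)
    fs = traces.fs if isinstance(traces, CalciumTraces) else 10.0
    t_frames = np.arange(x.shape[1]) / fs
    in_support = t_frames <= speed.times[-1]
    if in_support.sum() < MIN_FRAMES:
        raise ValueError(
            f"only {int(in_support.sum())} overlapping frames; need {MIN_FRAMES}"
        )
    sp = np.interp(t_frames[in_support], speed.times, speed.speed)
    xs = x[:, in_support]
    if method == "spearman":
        xs = np.apply_along_axis(rankdata, 1, xs)
        sp = rankdata(sp)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    sp_c = sp - sp.mean()
    x_c = xs - xs.mean(axis=1, keepdims=True)
    denom = np.sqrt((x_c**2).sum(axis=1) * (sp_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x_c @ sp_c) / denom
    return pd.DataFrame(
        {"neuron": np.arange(x.shape[0]), "method": method, "r": r,
         "fisher_z": fisher_z(r)}
    )


@dataclass
class ECDF:
    """Right-continuous empirical CDF; final value 1."""

    x: np.ndarray  # sorted sample
    F: np.ndarray  # cumulative fractions, (1..n)/n

    def __call__(self, q) -> np.ndarray | float:
        return np.searchsorted(self.x, q, side="right") / self.x.size

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "cdf": self.F})


def empirical_cdf(values) -> ECDF:
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("need at least one value")
    return ECDF(x=v, F=np.arange(1, v.size + 1) / v.size)
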