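"""End-to-end per-session analysis: every headline metric in one pass.

Given a session (synthetic or read from disk) this computes the scalar
summaries that the group comparisons operate on: band-integrated LFP powers,
RS/FS mean firing rates, spike-count-equalized theta spike–field coherence,
calcium transient rate / amplitude / decay, Fisher-z pairwise and speed
correlations, locomotion totals, and open-field metrics.
"""

from __future__ import annotations

import logging

import numpy as np

from . import behavior, calcium, correlations, lfp as lfpmod, spikes
from .session import Session

logger = logging.getLogger(__name__)


DIRECTION_OF_EFFECT = {
    # expected MK801-vs-vehicle direction of each summary metric
    "theta_power_uv2": "up",
    "gamma_power_uv2": "up",
    "transient_rate_per_min": "up",
    "transient_amp_au": "up",
    "speed_integral_cm": "up",
    "theta_sfc_pct": "down",
    "pairwise_fisher_z": "down",
    "speed_fisher_z": "down",
    "delta_power_uv2": "unchanged",
    "beta_power_uv2": "unchanged",
    "rs_rate_hz": "unchanged",
    "fs_rate_hz": "unchanged",
    "decay_tau_s": "unchanged",
}


def preset_comparison(n_seeds: int = 10, duration_s: float = 240.0,
                      base=None, seed_offset: int = 0,
                      presets=("VEHICLE", "MK801", "MK801_ARI")) -> dict:
    """Per-preset metric arrays over matched seeds.

    Returns ``{preset: {metric: array over seeds}}`` for the metrics in
    :data:`DIRECTION_OF_EFFECT`; each seed generates one session per preset
    so conditions are compared on matched random streams.
    """
    from dataclasses import replace

    from .synth import SynthConfig, generate_session

    base = base if base is not None else SynthConfig()
    base = replace(base, duration_s=duration_s)
    values: dict[str, dict[str, list]] = {
        p: {m: [] for m in DIRECTION_OF_EFFECT} for p in presets
    }
    for k in range(n_seeds):
        seed = seed_offset + k
        for p in presets:
            m = session_metrics(generate_session(p, seed, base), sfc_seed=seed)
            for name in DIRECTION_OF_EFFECT:
                values[p][name].append(m.get(name, np.nan))
    return {
        p: {name: np.asarray(v) for name, v in d.items()}
        for p, d in values.items()
    }


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference (b - a) with pooled SD."""
    va = np.nanvar(a, ddof=1)
    vb = np.nanvar(b, ddof=1)
    sd = np.sqrt((va + vb) / 2.0)
    if sd == 0:
        return 0.0
    return float((np.nanmean(b) - np.nanmean(a)) / sd)


def session_metrics(session: Session, sfc_seed: int = 0,
                    n_spikes: int | None = None,
                    min_spikes: int = 50) -> dict[str, float]:
    """All scalar summaries of one session; absent modalities yield no keys.

    ``n_spikes=None`` equalizes the spike–field coherence to the eligible
    count of the sparsest unit (capped below at ``min_spikes``: units with
    fewer eligible spikes are dropped rather than degrading every unit).
    """
    out: dict[str, float] = {}

    if session.lfp is not None:
        raw = session.lfp
        if raw.band == "wideband":
            lfp_sig, _ = lfpmod.bandsplit(raw) if raw.fs >= 600 else (raw, None)
        else:
            lfp_sig = raw
        psd = lfpmod.compute_psd(lfp_sig)
        for band, bp in lfpmod.band_power_table(psd).items():
            out[f"{band}_power_uv2"] = bp.power
            out[f"{band}_power_rel"] = bp.relative
    else:
        lfp_sig = None

    if session.units is not None and lfp_sig is not None:
        dur = lfp_sig.duration_s
        rs_rates, fs_rates = [], []
        for u in session.units:
            cls = spikes.classify_unit(u, dur)
            (rs_rates if cls == "RS" else fs_rates if cls == "FS" else []).append(
                u.mean_rate(dur)
            )
        if rs_rates:
            out["rs_rate_hz"] = float(np.mean(rs_rates))
        if fs_rates:
            out["fs_rate_hz"] = float(np.mean(fs_rates))

        eligible = []
        for u in session.units:
            try:
                c = spikes.equalized_spike_count([u], lfp_sig, session.speed)
            except ValueError:
                c = 0
            eligible.append(c)
        usable = [u for u, c in zip(session.units, eligible) if c >= min_spikes]
        if usable:
            n_eq = n_spikes or min(
                c for c in eligible if c >= min_spikes
            )
            theta_peaks = []
            for u in usable:
                spec = spikes.spike_field_coherence(
                    u, lfp_sig, session.speed, n_spikes=n_eq, seed=sfc_seed
                )
                theta_peaks.append(spec.theta_peak_pct)
            out["theta_sfc_pct"] = float(np.mean(theta_peaks))
            out["sfc_n_spikes"] = float(n_eq)
        else:
            logger.warning("session %s: no unit with >= %d eligible spikes",
                           session.session_id, min_spikes)

    if session.calcium is not None:
        ca = session.calcium
        rates, amps, taus = [], [], []
        for i in range(ca.n_neurons):
            ts = calcium.analyze_neuron(ca.traces[i], fs=ca.fs, neuron_id=i)
            rates.append(ts.rate_per_min)
            if ts.n_transients:
                amps.append(float(ts.amplitudes.mean()))
            if ts.decay_valid:
                taus.append(ts.decay_tau_s)
        out["transient_rate_per_min"] = float(np.mean(rates))
        if amps:
            out["transient_amp_au"] = float(np.mean(amps))
        if taus:
            out["decay_tau_s"] = float(np.mean(taus))

        z, _ = calcium.zscore_traces(ca)
        if z.n_neurons >= 2:
            out["pairwise_fisher_z"] = float(
                correlations.pairwise_corr(z)["fisher_z"].mean()
            )
        if session.speed is not None:
            out["speed_fisher_z"] = float(
                correlations.speed_corr(z, session.speed)["fisher_z"].mean()
            )

    if session.speed is not None:
        sp = session.speed
        out["speed_integral_cm"] = float(sp.speed.sum() / sp.fs)
        out["mean_speed_cms"] = float(sp.speed.mean())

    if session.trajectory is not None:
        m = behavior.oft_metrics(session.trajectory,
                                 duration_s=session.trajectory.duration_s)
        out["oft_distance_cm"] = m.total_distance_cm
        out["oft_pct_center"] = m.pct_time_center

    return out
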