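"""Synthetic session generator.

Emulates the statistical structure of head-fixed hippocampal recordings in
vehicle, MK-801-exposed, and aripiprazole-treated mice so that every
downstream analysis can be exercised and verified without real recordings:

* LFP — a sum of delta/theta/beta/gamma sinusoids plus 1/f (power-law)
  noise.  Theta phase is known analytically from the generated component,
  giving ground truth for phase-locking analyses.
* Spike units — inhomogeneous Poisson processes whose intensity follows a
  von Mises modulation of theta phase,
  ``lambda(t) = r0 * exp(kappa * cos(theta(t) - phi0)) / I0(kappa)``.
  The ``I0`` normalisation makes the time-averaged rate equal ``r0``
  regardless of ``kappa``, so synchrony manipulations leave firing rates
  untouched.  Sampling is by thinning, which is exact.
* Calcium traces — per-frame Poisson event counts whose log-rate combines a
  shared standardized latent process (loading ``a``) and locomotion speed
  (coupling ``beta``); events carry truncated-normal amplitudes and are
  convolved with an exponential-decay kernel ``exp(-t/tau)`` with unit
  value at the event frame, plus white measurement noise.  Baseline is ~0
  so raw-trace detection thresholds apply directly.
* Speed — a rectified mean-reverting (Ornstein–Uhlenbeck) process gated by
  alternating move/rest bouts with exponential durations.
* Trajectory — a smooth heading random walk driven by the speed process
  inside a rectangular arena with reflecting walls.

Condition presets encode the direction of the drug effects: MK-801 raises
theta and gamma LFP amplitude, lowers phase-locking concentration, raises
calcium transient rate and amplitude, lowers shared-latent loading and
speed coupling, and raises locomotion speed; delta/beta amplitude and the
calcium decay constant are untouched.  Aripiprazole on MK-801 returns every
altered parameter halfway toward the vehicle value.

All generators are deterministic functions of (config, seed); independent
random streams are spawned per modality so that matched seeds stay
comparable across presets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy.special import i0 as bessel_i0

from .session import (
    CalciumTraces,
    LfpSignal,
    Session,
    SpeedTrace,
    SpikeUnit,
    Trajectory,
)

PRESET_NAMES = ("VEHICLE", "MK801", "VEHICLE_ARI", "MK801_ARI")


@dataclass
class SynthConfig:
    """All generative parameters for one synthetic session.

    Oscillation amplitudes are in µV; rates in Hz; ``kappa`` is the von
    Mises concentration of spike phase-locking to theta; ``latent_loading``
    (in [0, 1]) scales the shared latent drive of calcium events and
    ``speed_coupling`` (>= 0, per cm/s of log-rate) their locomotion drive.
    """

    seed: int = 0
    duration_s: float = 600.0
    # --- LFP ---
    fs_lfp: float = 1000.0
    oscillations: tuple = (
        ("delta", 2.0, 30.0),
        ("theta", 8.0, 40.0),
        ("beta", 20.0, 15.0),
        ("gamma", 40.0, 10.0),
    )  # (name, center Hz, amplitude µV)
    noise_exponent: float = 1.0  # power ~ f^-exponent
    noise_scale: float = 10.0  # µV (SD of the colored noise)
    # --- spikes ---
    n_rs: int = 6
    n_fs: int = 4
    rs_rate_range_hz: tuple = (1.0, 15.0)
    fs_rate_range_hz: tuple = (15.0, 50.0)
    kappa: float = 2.0
    preferred_phase: float = 0.0  # rad, 0 = theta peak
    rs_width_ms: float = 0.8
    waveform_fs: float = 25000.0
    # --- calcium ---
    n_neurons_ca: int = 30
    fs_ca: float = 10.0
    transient_rate_hz: float = 0.10
    transient_amp_mean: float = 60.0
    transient_amp_sd: float = 15.0
    tau_decay_s: float = 1.0
    latent_loading: float = 0.6
    speed_coupling: float = 0.40  # per SD of (session-standardized) speed
    trace_noise_sd: float = 5.0
    latent_ar_coef: float = 0.9  # AR(1) coefficient of the latent at fs_ca
    # --- speed process ---
    fs_speed: float = 50.0
    speed_mean_cms: float = 6.0
    speed_relaxation_hz: float = 0.5
    speed_volatility: float = 0.5  # relative (fraction of mean) per sqrt(s)
    move_fraction: float = 0.6
    mean_bout_s: float = 8.0  # mean move+rest cycle length
    # --- trajectory ---
    fs_traj: float = 25.0
    arena_length_cm: float = 55.0
    arena_width_cm: float = 40.0
    heading_diffusion: float = 1.5  # rad / sqrt(s)
    # --- between-session (between-animal) variability ---
    session_cv: float = 0.15  # log-normal CV on amplitudes, rates, mean speed
    tau_cv: float = 0.10  # log-normal CV on the calcium decay constant

    def validate(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.tau_decay_s <= 0:
            raise ValueError("tau_decay_s must be > 0")
        if not (0.0 <= self.latent_loading <= 1.0):
            raise ValueError("latent_loading must be in [0, 1]")
        if self.speed_coupling < 0:
            raise ValueError("speed_coupling must be >= 0")
        if self.transient_rate_hz < 0:
            raise ValueError("transient_rate_hz must be >= 0")
        if any(amp < 0 for _, _, amp in self.oscillations):
            raise ValueError("oscillation amplitudes must be >= 0")
        if self.fs_ca <= 0:
            raise ValueError("fs_ca must be > 0")


@dataclass
class ConditionPreset:
    """Named experimental condition as overrides on a base config."""

    name: str
    overrides: dict = field(default_factory=dict)


def _scaled_oscillations(osc, theta_factor: float, gamma_factor: float):
    out = []
    for name, f, a in osc:
        if name == "theta":
            a = a * theta_factor
        elif name == "gamma":
            a = a * gamma_factor
        out.append((name, f, a))
    return tuple(out)


def get_preset(name: str, base: SynthConfig | None = None) -> SynthConfig:
    """Resolve a named condition preset into a full config.

    MK-801 effect sizes (documented defaults): theta and gamma amplitude
    x1.5, kappa 2 -> 0.7, transient rate x1.4, transient amplitude x1.25,
    latent loading 0.6 -> 0.35, speed coupling 0.10 -> 0.04, mean speed
    x1.8.  MK801_ARI places each altered parameter at the midpoint between
    the MK-801 and vehicle values; VEHICLE_ARI equals VEHICLE.
    """
    base = base if base is not None else SynthConfig()
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    if name in ("VEHICLE", "VEHICLE_ARI"):
        return replace(base)

    def _mix(v_veh, v_mk, w):  # w=1 -> full MK801, w=0.5 -> ARI midpoint
        return v_veh + w * (v_mk - v_veh)

    w = 1.0 if name == "MK801" else 0.5
    return replace(
        base,
        oscillations=_scaled_oscillations(
            base.oscillations, _mix(1.0, 1.5, w), _mix(1.0, 1.5, w)
        ),
        kappa=_mix(base.kappa, base.kappa * 0.35, w),
        transient_rate_hz=_mix(base.transient_rate_hz, base.transient_rate_hz * 1.4, w),
        transient_amp_mean=_mix(
            base.transient_amp_mean, base.transient_amp_mean * 1.25, w
        ),
        latent_loading=_mix(base.latent_loading, base.latent_loading * 0.58, w),
        speed_coupling=_mix(base.speed_coupling, base.speed_coupling * 0.4, w),
        speed_mean_cms=_mix(base.speed_mean_cms, base.speed_mean_cms * 1.8, w),
    )


# ---------------------------------------------------------------------------
# component generators
# ---------------------------------------------------------------------------


def draw_oscillation_phases(config: SynthConfig, rng: np.random.Generator) -> dict:
    """Uniform initial phase per oscillatory component (radians)."""
    return {name: float(rng.uniform(0, 2 * np.pi)) for name, _, _ in config.oscillations}


def _colored_noise(n: int, exponent: float, scale: float, fs: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectral density ~ f^-exponent, SD = scale."""
    if scale == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * shaping, n)
    sd = shaped.std()
    return shaped * (scale / sd) if sd > 0 else shaped


def generate_lfp(config: SynthConfig, rng: np.random.Generator,
                 phases: dict | None = None) -> LfpSignal:
    """Sum of band sinusoids plus 1/f noise on the session clock."""
    config.validate()
    if config.duration_s < 10:
        raise ValueError("duration must be >= 10 s for spectral analysis")
    if phases is None:
        phases = draw_oscillation_phases(config, rng)
    n = int(round(config.duration_s * config.fs_lfp))
    t = np.arange(n) / config.fs_lfp
    x = np.zeros(n)
    for name, f, a in config.oscillations:
        x += a * np.sin(2 * np.pi * f * t + phases[name])
    x += _colored_noise(n, config.noise_exponent, config.noise_scale,
                        config.fs_lfp, rng)
    return LfpSignal(samples=x, fs=config.fs_lfp, band="wideband")


def theta_phase_series(config: SynthConfig, phases: dict) -> np.ndarray:
    """Analytic (unwrapped) theta phase on the LFP clock; 0 = theta peak.

    The theta component is ``A sin(2 pi f t + phi)``; its peak occurs where
    the argument equals pi/2, so the peak-referenced phase is
    ``2 pi f t + phi - pi/2``.
    """
    f_theta = next(f for name, f, _ in config.oscillations if name == "theta")
    n = int(round(config.duration_s * config.fs_lfp))
    t = np.arange(n) / config.fs_lfp
    return 2 * np.pi * f_theta * t + phases["theta"] - np.pi / 2


def _waveform_template(width_ms: float, fs: float) -> np.ndarray:
    """Biphasic extracellular template with the given trough-to-peak width."""
    w = width_ms / 1000.0
    t = np.arange(-1.5 * w, 2.5 * w, 1.0 / fs)
    trough = -np.exp(-0.5 * (t / (0.35 * w)) ** 2)
    peak = 0.45 * np.exp(-0.5 * ((t - w) / (0.6 * w)) ** 2)
    return trough + peak


def generate_spikes(config: SynthConfig, theta_phase: np.ndarray,
                    rng: np.random.Generator) -> list[SpikeUnit]:
    """Theta-locked units sampled by exact thinning of a von Mises intensity.

    RS units draw base rates from ``rs_rate_range_hz`` and carry the broad
    template; FS units draw from ``fs_rate_range_hz`` with a template half
    the trough-to-peak width.
    """
    config.validate()
    kappa, phi0 = config.kappa, config.preferred_phase
    duration = config.duration_s
    t_grid = np.arange(theta_phase.size) / config.fs_lfp

    # base rates first so the draw sequence is independent of kappa
    r0_rs = rng.uniform(*config.rs_rate_range_hz, size=config.n_rs)
    r0_fs = rng.uniform(*config.fs_rate_range_hz, size=config.n_fs)

    norm = bessel_i0(kappa)
    lam_peak_factor = math.exp(kappa) / norm

    units: list[SpikeUnit] = []
    specs = [(r, "RS", config.rs_width_ms) for r in r0_rs] + [
        (r, "FS", config.rs_width_ms * 0.5) for r in r0_fs
    ]
    for k, (r0, cls, width_ms) in enumerate(specs):
        lam_max = r0 * lam_peak_factor
        n_cand = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(0, duration, size=n_cand))
        phase_at = np.interp(cand, t_grid, theta_phase)
        accept_p = np.exp(kappa * (np.cos(phase_at - phi0) - 1.0))  # lam/lam_max
        keep = rng.uniform(size=n_cand) < accept_p
        times = cand[keep]
        units.append(
            SpikeUnit(
                spike_times=times,
                waveform=_waveform_template(width_ms, config.waveform_fs),
                waveform_fs=config.waveform_fs,
                trough_to_peak_ms=width_ms,
                unit_class=cls,
                unit_id=f"{cls.lower()}{k}",
            )
        )
    return units


def generate_speed(config: SynthConfig, rng: np.random.Generator) -> SpeedTrace:
    """Rectified OU speed gated by alternating move/rest bouts.

    The mean-reverting process is simulated in normalized units (target 1
    while moving, 0 at rest; ``speed_volatility`` is relative) and scaled
    by ``speed_mean_cms``, so the whole speed profile — and hence any path
    length — is exactly linear in the mean-speed parameter.
    """
    config.validate()
    fs = config.fs_speed
    n = int(round(config.duration_s * fs))
    dt = 1.0 / fs

    # exponential bout durations with the requested move fraction
    mean_move = config.move_fraction * config.mean_bout_s
    mean_rest = (1.0 - config.move_fraction) * config.mean_bout_s
    mask = np.zeros(n, dtype=bool)
    i, moving = 0, True
    while i < n:
        mean_d = mean_move if moving else mean_rest
        if mean_d <= 0:
            length = 0
        else:
            length = max(1, int(round(rng.exponential(mean_d) * fs)))
        mask[i : i + length] = moving
        i += length
        moving = not moving
    if config.move_fraction >= 1.0:
        mask[:] = True
    elif config.move_fraction <= 0.0:
        mask[:] = False

    shocks = rng.standard_normal(n)
    x = np.zeros(n)
    u = 0.0  # normalized speed (target 1 while moving)
    relax = config.speed_relaxation_hz
    vol = config.speed_volatility
    for j in range(n):
        target = 1.0 if mask[j] else 0.0
        # faster relaxation toward rest emulates abrupt stopping
        k = relax if mask[j] else 4.0 * relax
        noise = vol * math.sqrt(dt) * shocks[j] if mask[j] else 0.0
        u = u + k * (target - u) * dt + noise
        u = max(u, 0.0)
        x[j] = u
    return SpeedTrace(speed=config.speed_mean_cms * x, fs=fs)


def generate_trajectory(config: SynthConfig, rng: np.random.Generator) -> Trajectory:
    """Heading random walk driven by the speed process, reflecting walls."""
    config.validate()
    fs = config.fs_traj
    dt = 1.0 / fs
    traj_cfg = replace(config, fs_speed=fs)
    v = generate_speed(traj_cfg, rng).speed
    n = v.size
    L, W = config.arena_length_cm, config.arena_width_cm
    heading = rng.uniform(0, 2 * np.pi) + np.cumsum(
        config.heading_diffusion * math.sqrt(dt) * rng.standard_normal(n)
    )
    dx = v * dt * np.cos(heading)
    dy = v * dt * np.sin(heading)
    x = np.empty(n)
    y = np.empty(n)
    px, py = L / 2.0, W / 2.0
    for j in range(n):
        px += dx[j]
        py += dy[j]
        # reflect off the walls (steps are much shorter than the arena)
        if px < 0:
            px = -px
        elif px > L:
            px = 2 * L - px
        if py < 0:
            py = -py
        elif py > W:
            py = 2 * W - py
        x[j] = px
        y[j] = py
    return Trajectory(x=x, y=y, fs=fs, arena_length_cm=L, arena_width_cm=W)


def resample_speed(speed: SpeedTrace, fs_out: float, n_out: int) -> np.ndarray:
    """Linear interpolation of speed onto a target clock (t = 0 aligned)."""
    t_out = np.arange(n_out) / fs_out
    return np.interp(t_out, speed.times, speed.speed)


def decay_kernel(tau_s: float, fs: float, n: int | None = None) -> np.ndarray:
    """Exponential-decay transient kernel exp(-t/tau) with unit peak value."""
    if tau_s <= 0 or fs <= 0:
        raise ValueError("tau_s and fs must be > 0")
    if n is None:
        n = max(1, int(round(10 * tau_s * fs)))
    return np.exp(-np.arange(n) / (tau_s * fs))


def generate_calcium(config: SynthConfig, speed: SpeedTrace,
                     rng: np.random.Generator) -> CalciumTraces:
    """Latent- and speed-driven transients convolved with an exp(-t/tau) kernel.

    Per-frame event counts are Poisson with
    ``log rate = const + a * L(t) + beta * z(speed(t))``, where ``L`` is a
    shared standardized AR(1) latent and ``z(.)`` standardizes speed over
    the session, making ``beta`` dimensionless (per SD of speed) like the
    latent loading and keeping coupling strength independent of locomotion
    vigor; ``const`` is set so the time-averaged event rate equals
    ``transient_rate_hz`` exactly for the realised modulation.  The kernel has unit value at the event frame so an event
    of amplitude ``A`` produces a trace peak of ``A`` on the ~0 baseline.
    """
    config.validate()
    fs = config.fs_ca
    n_frames = int(round(config.duration_s * fs))
    sp = resample_speed(speed, fs, n_frames)

    # shared standardized latent (AR(1), stationary unit variance)
    rho = config.latent_ar_coef
    innov = rng.standard_normal(n_frames) * math.sqrt(1 - rho**2)
    lat = np.empty(n_frames)
    prev = rng.standard_normal()
    for j in range(n_frames):
        prev = rho * prev + innov[j]
        lat[j] = prev
    lat = (lat - lat.mean()) / (lat.std() if lat.std() > 0 else 1.0)

    sp_sd = sp.std()
    sp_z = (sp - sp.mean()) / sp_sd if sp_sd > 0 else np.zeros_like(sp)
    modulation = np.exp(config.latent_loading * lat + config.speed_coupling * sp_z)
    mean_mod = modulation.mean()
    base_per_frame = config.transient_rate_hz / fs
    rate = base_per_frame * modulation / mean_mod if mean_mod > 0 else np.zeros(n_frames)

    kernel = decay_kernel(config.tau_decay_s, fs)

    traces = np.empty((config.n_neurons_ca, n_frames))
    for i in range(config.n_neurons_ca):
        child = np.random.default_rng(rng.integers(0, 2**31 - 1))
        counts = child.poisson(rate)
        impulses = np.zeros(n_frames)
        idx = np.nonzero(counts)[0]
        for j in idx:
            amps = child.normal(
                config.transient_amp_mean, config.transient_amp_sd, size=counts[j]
            )
            impulses[j] = np.maximum(amps, 0.0).sum()
        clean = np.convolve(impulses, kernel)[:n_frames]
        noise = (
            child.standard_normal(n_frames) * config.trace_noise_sd
            if config.trace_noise_sd > 0
            else 0.0
        )
        traces[i] = clean + noise
    return CalciumTraces(traces=traces, fs=fs)


# ---------------------------------------------------------------------------
# session composition
# ---------------------------------------------------------------------------

def apply_session_variability(config: SynthConfig,
                              rng: np.random.Generator) -> SynthConfig:
    """Between-animal variability: log-normal multipliers on scale parameters.

    One multiplier per oscillation amplitude, plus transient rate, transient
    amplitude, decay constant and mean speed.  Multipliers have mean 1
    (log-normal with sigma = the configured CV).  The number of draws is
    fixed, so with a shared stream the same seed yields the same multipliers
    in every preset — matched sessions differ only by the preset's effects.
    """

    def _mult(cv: float) -> float:
        if cv <= 0:
            return 1.0
        sigma = math.sqrt(math.log(1 + cv**2))
        return float(rng.lognormal(-(sigma**2) / 2.0, sigma))

    osc = tuple((n, f, a * _mult(config.session_cv)) for n, f, a in config.oscillations)
    return replace(
        config,
        oscillations=osc,
        transient_rate_hz=config.transient_rate_hz * _mult(config.session_cv),
        transient_amp_mean=config.transient_amp_mean * _mult(config.session_cv),
        tau_decay_s=config.tau_decay_s * _mult(config.tau_cv),
        speed_mean_cms=config.speed_mean_cms * _mult(config.session_cv),
    )


_PRESET_GROUP = {
    "VEHICLE": ("vehicle", "saline"),
    "MK801": ("mk801", "saline"),
    "VEHICLE_ARI": ("vehicle", "ari"),
    "MK801_ARI": ("mk801", "ari"),
}


def generate_session(preset: str, seed: int,
                     base: SynthConfig | None = None) -> Session:
    """Fully populated synthetic session for a named condition preset.

    Independent random streams are spawned per modality from ``seed`` so a
    parameter change in one modality does not perturb the realisations of
    the others — matched seeds stay matched.
    """
    config = get_preset(preset, base)
    config = replace(config, seed=seed)
    streams = np.random.SeedSequence(seed).spawn(7)
    rng_lfp, rng_spk, rng_spd, rng_ca, rng_traj, rng_phase, rng_var = (
        np.random.default_rng(s) for s in streams
    )
    config = apply_session_variability(config, rng_var)

    phases = draw_oscillation_phases(config, rng_phase)
    lfp = generate_lfp(config, rng_lfp, phases=phases)
    theta = theta_phase_series(config, phases)
    units = generate_spikes(config, theta, rng_spk)
    speed = generate_speed(config, rng_spd)
    calcium = generate_calcium(config, speed, rng_ca)
    trajectory = generate_trajectory(config, rng_traj)

    group, treatment = _PRESET_GROUP[preset]
    prov = {
        "generator": "spikefield.synth",
        "preset": preset,
        "seed": int(seed),
        "config": {
            k: (list(map(list, v)) if k == "oscillations" else v)
            for k, v in asdict(config).items()
        },
        "oscillation_phases": phases,
    }
    return Session(
        session_id=f"synth-{preset.lower()}-{seed}",
        group=group,
        treatment=treatment,
        lfp=lfp,
        units=units,
        calcium=calcium,
        speed=speed,
        trajectory=trajectory,
        provenance=prov,
    )
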