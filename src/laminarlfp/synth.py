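"""Synthetic laminar LFP generator with exposed ground truth.

Emulates the statistical structure the analysis pipeline assumes: a handful
of depth-stationary sources that mix linearly and instantaneously into an
8-channel laminar recording.  Each source has a closed-form spatial loading
(one of four archetypes: a non-reversing superficial profile peaking near
700 um, a deep profile peaking near 1450 um that reverses polarity near
1000 um, a superficial profile with the same reversal depth, and an exactly
depth-linear profile standing in for volume conduction) and a time course
built from band-limited noise carriers in the theta (4-10 Hz), slow-gamma
(20-50 Hz) and fast-gamma (60-120 Hz) bands.

Behavioural state (lever hold vs pull) modulates per-band power through
multiplicative gains; a shared frequency-wandering theta oscillator
modulates the gamma amplitudes through a raised-cosine law

    m(t) = 1 - k_c + k_c * (1 + cos(theta(t) - phi0)) / 2,

whose coupling depth ``k_c`` maps monotonically onto the Tort modulation
index, giving parameter-recovery tests a closed-form oracle.  Spike trains
are inhomogeneous Poisson with a von Mises phase kernel whose concentration
is solved numerically so the expected phase-locking value equals a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, special

from .io import EventTable, LaminarRecording, SpikeTrain, SpikeTrainSet

__all__ = [
    "BANDS",
    "SourceSpec",
    "GroundTruth",
    "archetype_loading",
    "archetype_loading_curvature",
    "make_loadings",
    "make_timecourses",
    "mix",
    "make_spikes",
    "make_lever",
    "make_events",
    "default_source_specs",
    "generate_dataset",
    "vonmises_kappa_for_plv",
]

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 10.0),
    "slow_gamma": (20.0, 50.0),
    "fast_gamma": (60.0, 120.0),
}

LOADING_SHAPES = (
    "nonreversing_superficial",
    "deep_reversing",
    "superficial_reversing",
    "linear_volume_conducted",
)

# Gaussian-bump parameters (centre um, width um) for the closed-form
# archetypes; the reversing shapes are differences of two bumps with the
# secondary amplitude pinned so the profile crosses zero at 1000 um.
_BUMPS = {
    "nonreversing_superficial": ((700.0, 150.0), None),
    "deep_reversing": ((1450.0, 180.0), (500.0, 250.0)),
    "superficial_reversing": ((450.0, 220.0), (1300.0, 150.0)),
}
_REVERSAL_UM = 1000.0


def _gauss(z, mu, sd):
    return np.exp(-((z - mu) ** 2) / (2.0 * sd**2))


def _gauss_d2(z, mu, sd):
    g = _gauss(z, mu, sd)
    return g * (((z - mu) ** 2) / sd**4 - 1.0 / sd**2)


def _secondary_weight(shape: str) -> float:
    (mu1, sd1), sec = _BUMPS[shape]
    mu2, sd2 = sec
    return _gauss(_REVERSAL_UM, mu1, sd1) / _gauss(_REVERSAL_UM, mu2, sd2)


def archetype_loading(shape: str, depths_um: np.ndarray) -> np.ndarray:
    """Closed-form (un-normalized) loading profile of one archetype."""
    z = np.asarray(depths_um, dtype=float)
    if shape == "linear_volume_conducted":
        return z.copy()
    if shape not in _BUMPS:
        raise ValueError(f"unknown loading shape {shape!r}")
    (mu1, sd1), sec = _BUMPS[shape]
    out = _gauss(z, mu1, sd1)
    if sec is not None:
        mu2, sd2 = sec
        out = out - _secondary_weight(shape) * _gauss(z, mu2, sd2)
    return out


def archetype_loading_curvature(shape: str, depths_um: np.ndarray) -> np.ndarray:
    """Analytic second depth-derivative of :func:`archetype_loading`."""
    z = np.asarray(depths_um, dtype=float)
    if shape == "linear_volume_conducted":
        return np.zeros_like(z)
    (mu1, sd1), sec = _BUMPS[shape]
    out = _gauss_d2(z, mu1, sd1)
    if sec is not None:
        mu2, sd2 = sec
        out = out - _secondary_weight(shape) * _gauss_d2(z, mu2, sd2)
    return out


@dataclass
class SourceSpec:
    """Parameters of one laminar LFP source.

    ``band_powers`` are nominal hold-state variances in mV^2; ``hold_gain``
    and ``pull_gain`` are multiplicative *power* factors applied per band in
    the two behavioural states; ``pull_delay_s`` shifts the pull-state window
    of a band relative to pull onset; ``coupling_depth`` is the fraction of a
    gamma band's amplitude modulated by theta phase; ``preferred_phase_deg``
    is the theta phase of maximal gamma amplitude.
    """

    loading_shape: str
    band_powers: dict[str, float] = field(
        default_factory=lambda: {"theta": 0.05, "slow_gamma": 1.0, "fast_gamma": 0.5}
    )
    hold_gain: dict[str, float] = field(default_factory=dict)
    pull_gain: dict[str, float] = field(default_factory=dict)
    pull_delay_s: dict[str, float] = field(default_factory=dict)
    coupling_depth: dict[str, float] = field(default_factory=dict)
    preferred_phase_deg: float = 0.0
    theta_coherent: bool = False
    evoked_amp: float = 0.0  # mV peak of the slow event-locked deflection
    evoked_center_s: float = 0.0  # deflection centre relative to pull onset
    evoked_width_s: float = 0.4  # full width of the raised-cosine deflection
    name: str = ""

    def __post_init__(self) -> None:
        if self.loading_shape not in LOADING_SHAPES:
            raise ValueError(f"unknown loading shape {self.loading_shape!r}")
        for band, p in self.band_powers.items():
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r}")
            if p < 0:
                raise ValueError("band powers must be >= 0")
        for kc in self.coupling_depth.values():
            if not 0.0 <= kc <= 1.0:
                raise ValueError("coupling_depth must lie in [0, 1]")


def make_loadings(specs, depths_um) -> np.ndarray:
    """Stack archetype loadings into a channels x sources matrix.

    Each column is max-normalized (|max| = 1) with its largest-magnitude
    extremum positive; the linear archetype stays exactly affine in depth.
    """
    depths_um = np.asarray(depths_um, dtype=float)
    if depths_um.size < 3:
        raise ValueError("need >= 3 channels to represent a laminar loading")
    cols = []
    for spec in specs:
        v = archetype_loading(spec.loading_shape, depths_um)
        peak = v[np.argmax(np.abs(v))]
        cols.append(v / peak)
    return np.column_stack(cols)


def _wandering_theta_phase(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Phase of a theta oscillator whose frequency wanders inside 4-10 Hz."""
    drift = rng.standard_normal(n)
    # ~0.5 s smoothing gives slow, realistic frequency drift
    width = max(int(0.5 * fs), 3)
    kernel = np.exp(-0.5 * (np.linspace(-3, 3, 4 * width) ** 2))
    kernel /= kernel.sum()
    drift = signal.fftconvolve(drift, kernel, mode="same")
    sd = drift.std()
    if sd > 0:
        drift = drift / sd
    freq = np.clip(7.0 + 1.8 * drift, 4.1, 9.9)
    return np.cumsum(2.0 * np.pi * freq / fs)


def _band_noise(band, fs, n, rng):
    lo, hi = band
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x / s if s > 0 else x


def _burst_envelope(fs, n, rng, sigma=0.8, timescale_s=0.25):
    """Unit-RMS lognormal slow envelope.

    Cortical source amplitudes are lognormal-like rather than Gaussian;
    this burstiness is also what gives a maximum-non-Gaussianity ICA the
    statistical structure it needs to demix the sources.
    """
    slow = rng.standard_normal(n)
    width = max(int(timescale_s * fs), 3)
    kernel = np.exp(-0.5 * np.linspace(-3, 3, 4 * width) ** 2)
    kernel /= np.sqrt((kernel**2).sum())  # keep unit variance after smoothing
    slow = signal.fftconvolve(slow, kernel, mode="same")
    env = np.exp(sigma * slow)
    return env / np.sqrt(np.mean(env**2))


def _evoked_waveform(
    events: EventTable, fs: float, n: int, center_s: float, width_s: float
) -> np.ndarray:
    """Unit-peak raised-cosine deflection around each pull onset.

    Emulates the slow event-locked LFP component each source shows in
    trial averages; it is the part of a source that survives the 10 Hz
    low-pass feeding the reservoir, hence the trial-locked information.
    """
    out = np.zeros(n)
    half = width_s / 2.0
    for onset in events.pull_onsets:
        a = int(round((onset + center_s - half) * fs))
        b = int(round((onset + center_s + half) * fs))
        a0, b0 = max(a, 0), min(b, n)
        if a0 >= b0:
            continue
        t = np.arange(a0, b0)
        phase = (t - a) / max(b - a, 1)
        out[a0:b0] += 0.5 * (1 - np.cos(2 * np.pi * phase))
    return out


def _state_gain_envelope(
    spec: SourceSpec, band: str, events: EventTable, fs: float, n: int
) -> np.ndarray:
    """Amplitude envelope switching hold -> pull gains around each onset.

    The pull state spans [-200, +300] ms around onset (shifted by the band's
    ``pull_delay_s``) with 50 ms raised-cosine ramps.
    """
    g_hold = np.sqrt(spec.hold_gain.get(band, 1.0))
    g_pull = np.sqrt(spec.pull_gain.get(band, 1.0))
    env = np.full(n, g_hold)
    if g_hold == g_pull or events.n_events == 0:
        return env
    delay = spec.pull_delay_s.get(band, 0.0)
    ramp = int(round(0.05 * fs))
    up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    for onset in events.pull_onsets:
        a = int(round((onset - 0.2 + delay) * fs))
        b = int(round((onset + 0.3 + delay) * fs))
        a0, b0 = max(a, 0), min(b, n)
        if a0 >= b0:
            continue
        env[a0:b0] = g_pull
        seg = up * (g_pull - g_hold) + g_hold
        if a >= ramp:
            env[a - ramp : a] = seg
        rev = seg[::-1]
        if b + ramp <= n:
            env[b : b + ramp] = rev
    return env


def make_timecourses(
    specs,
    events: EventTable,
    fs: float,
    duration: float,
    seed: int | np.random.Generator = 0,
    burst_sigma: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate source time courses (sources x time) and the theta phase.

    Each source is a sum over bands of band-limited Gaussian noise carriers
    scaled to the spec's band power, multiplied by the behavioural-state gain
    envelope and (for gamma bands) by the theta-phase raised-cosine
    amplitude modulation.  A single frequency-wandering theta oscillator
    sets the modulation phase of every source; its waveform is injected as
    the theta-band content of sources flagged ``theta_coherent`` (the
    volume-conducted archetype by default), which is what makes the raw-LFP
    theta phase a usable coupling reference downstream.
    """
    if fs < 2 * BANDS["fast_gamma"][1]:
        raise ValueError(f"fs = {fs} Hz aliases the fast-gamma band (need >= 240 Hz)")
    n = int(round(duration * fs))
    if events.n_events:
        events.check_margins(duration)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    theta_phase = _wandering_theta_phase(n, fs, rng)
    rows = []
    for spec in specs:
        src = np.zeros(n)
        for band, power in spec.band_powers.items():
            if power == 0:
                continue
            genv = _state_gain_envelope(spec, band, events, fs, n)
            if band == "theta":
                # only a theta_coherent source (the volume-conducted one by
                # default) carries the shared oscillator waveform; others get
                # independent theta-band noise so the sources stay independent
                if spec.theta_coherent:
                    src += np.sqrt(2.0 * power) * np.cos(theta_phase) * genv
                else:
                    src += np.sqrt(power) * _band_noise(BANDS[band], fs, n, rng) * genv
                continue
            carrier = _band_noise(BANDS[band], fs, n, rng)
            burst = _burst_envelope(fs, n, rng, sigma=burst_sigma)
            kc = spec.coupling_depth.get(band, 0.0)
            phi0 = np.deg2rad(spec.preferred_phase_deg)
            mod = 1.0 - kc + kc * (1.0 + np.cos(theta_phase - phi0)) / 2.0
            src += np.sqrt(power) * carrier * burst * genv * mod
        if spec.evoked_amp != 0.0 and events.n_events:
            src += spec.evoked_amp * _evoked_waveform(
                events, fs, n, spec.evoked_center_s, spec.evoked_width_s
            )
        rows.append(src)
    return np.vstack(rows), theta_phase


def mix(
    V_star: np.ndarray,
    s_star: np.ndarray,
    noise_sd: float,
    depths_um: np.ndarray,
    fs: float,
    seed: int | np.random.Generator = 0,
) -> LaminarRecording:
    """Linear instantaneous mixture plus white Gaussian sensor noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    V_star = np.asarray(V_star, dtype=float)
    s_star = np.asarray(s_star, dtype=float)
    if V_star.shape[1] != s_star.shape[0]:
        raise ValueError("V_star columns must match s_star rows")
    samples = V_star @ s_star
    if noise_sd > 0:
        rng = (
            np.random.default_rng(seed)
            if not isinstance(seed, np.random.Generator)
            else seed
        )
        samples = samples + noise_sd * rng.standard_normal(samples.shape)
    return LaminarRecording(samples=samples, depths=np.asarray(depths_um, float), fs=fs)


def vonmises_kappa_for_plv(plv: float) -> float:
    """Invert the von Mises mean resultant length A(kappa) = I1/I0."""
    if not 0.0 <= plv <= 1.0:
        raise ValueError("plv must lie in [0, 1]")
    if plv == 0.0:
        return 0.0
    if plv >= 0.999:
        return np.inf

    def f(k):
        return special.i1e(k) / special.i0e(k) - plv

    return optimize.brentq(f, 1e-8, 1e4)


def make_spikes(
    phase_ref: np.ndarray,
    fs: float,
    band: tuple[float, float],
    plv_target: float,
    rate: float,
    preferred_phase: float = 0.0,
    layer: str = "superficial",
    cell_class: str = "RS",
    seed: int | np.random.Generator = 0,
    unit_id: str = "u0",
) -> SpikeTrain:
    """Poisson spikes phase-locked to the band phase of a reference trace.

    The rate is modulated by a von Mises kernel of the Hilbert phase of the
    band-filtered reference; the kernel concentration is solved so the
    expected phase-locking value equals ``plv_target``.  ``plv_target`` at or
    above 0.999 degenerates to one spike per cycle at the preferred phase.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # use the same zero-phase FIR as the analysis side so generated and
    # measured spike phases refer to one and the same band signal
    from .coupling import bandpass

    filt = bandpass(np.asarray(phase_ref, dtype=float), fs, tuple(band))
    phase = np.unwrap(np.angle(signal.hilbert(filt)))
    duration = phase_ref.size / fs
    kappa = vonmises_kappa_for_plv(plv_target)
    if np.isinf(kappa):
        # spikes exactly at preferred-phase crossings
        delta = np.mod(phase - preferred_phase + np.pi, 2 * np.pi) - np.pi
        cross = np.nonzero((delta[:-1] < 0) & (delta[1:] >= 0))[0]
        frac = -delta[cross] / (delta[cross + 1] - delta[cross])
        times = (cross + frac) / fs
    elif kappa == 0.0:
        n_sp = rng.poisson(rate * duration)
        times = np.sort(rng.uniform(0, duration, n_sp))
    else:
        lam_max = rate / special.i0e(kappa)  # rate * exp(kappa)/I0(kappa)
        n_cand = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(0, duration, n_cand))
        ph = np.interp(cand * fs, np.arange(phase.size), phase)
        accept = rng.uniform(size=n_cand) < np.exp(
            kappa * (np.cos(ph - preferred_phase) - 1.0)
        )
        times = cand[accept]
    return SpikeTrain(unit_id=unit_id, times=times, layer=layer, cell_class=cell_class)


def make_events(
    n_trials: int = 18,
    interval_s: float = 3.0,
    jitter_s: float = 0.2,
    start_s: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> EventTable:
    """Regularly spaced pull onsets with uniform jitter."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    onsets = start_s + interval_s * np.arange(n_trials)
    if jitter_s > 0:
        onsets = onsets + rng.uniform(-jitter_s, jitter_s, n_trials)
    return EventTable(pull_onsets=np.sort(onsets))


def make_lever(
    events: EventTable,
    fs_lever: float = 1000.0,
    duration: float | None = None,
    amplitude_jitter: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Hold-then-pull lever trajectory (times_s, normalized position).

    Flat hold at 0 for >= 1 s before each onset; a smooth raised-cosine pull
    excursion (rise 200 ms, plateau 100 ms, fall 300 ms) begins at onset.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    exc_len = 0.2 + 0.1 + 0.3
    onsets = events.pull_onsets
    if onsets.size:
        if onsets[0] < 1.0:
            raise ValueError("lever must be held >= 1 s before the first pull onset")
        gaps = np.diff(onsets) - exc_len
        if np.any(np.diff(onsets) < exc_len):
            raise ValueError("overlapping pull excursions")
        if np.any(gaps < 1.0):
            raise ValueError("lever must be held >= 1 s before every pull onset")
    if duration is None:
        duration = (onsets[-1] if onsets.size else 0.0) + exc_len + 1.0
    n = int(round(duration * fs_lever))
    t = np.arange(n) / fs_lever
    pos = np.zeros(n)
    for onset in onsets:
        amp = 1.0 * (1.0 + amplitude_jitter * rng.standard_normal())
        rel = t - onset
        rise = (rel >= 0) & (rel < 0.2)
        plateau = (rel >= 0.2) & (rel < 0.3)
        fall = (rel >= 0.3) & (rel < 0.6)
        pos[rise] = amp * 0.5 * (1 - np.cos(np.pi * rel[rise] / 0.2))
        pos[plateau] = amp
        pos[fall] = amp * 0.5 * (1 + np.cos(np.pi * (rel[fall] - 0.3) / 0.3))
    return t, pos


@dataclass
class GroundTruth:
    """Generator-side truth exposed for parameter-recovery tests."""

    V_star: np.ndarray
    s_star: np.ndarray
    specs: list[SourceSpec]
    theta_phase: np.ndarray
    events: EventTable
    unit_truth: list[dict]
    depths_um: np.ndarray
    fs: float
    noise_sd: float

    def summary(self) -> dict:
        """JSON-serializable summary (omits the bulky time courses)."""
        return {
            "V_star": self.V_star.tolist(),
            "depths_um": self.depths_um.tolist(),
            "fs": self.fs,
            "noise_sd": self.noise_sd,
            "sources": [
                {
                    "name": sp.name or sp.loading_shape,
                    "loading_shape": sp.loading_shape,
                    "band_powers": sp.band_powers,
                    "coupling_depth": sp.coupling_depth,
                    "preferred_phase_deg": sp.preferred_phase_deg,
                }
                for sp in self.specs
            ],
            "events_s": self.events.pull_onsets.tolist(),
            "units": self.unit_truth,
        }


def default_source_specs() -> list[SourceSpec]:
    """The four default sources mirroring the laminar archetypes.

    Source 1 (superficial, non-reversing): slow gamma dominant during hold,
    suppressed during pull; strongest theta-slow-gamma coupling.  Source 2
    (deep, reversing): slow gamma *enhanced* ~100 ms after pull onset; fast
    gamma rises around movement.  Source 3 (superficial, reversing): weakest
    gamma powers.  Source 4 (depth-linear, volume-conducted): carries most of
    the theta.
    """
    return [
        SourceSpec(
            "nonreversing_superficial",
            band_powers={"theta": 0.08, "slow_gamma": 1.0, "fast_gamma": 0.5},
            hold_gain={"slow_gamma": 1.0, "fast_gamma": 0.3},
            pull_gain={"slow_gamma": 0.4, "fast_gamma": 1.0},
            coupling_depth={"slow_gamma": 0.6, "fast_gamma": 0.4},
            preferred_phase_deg=140.0,
            evoked_amp=-0.9,
            evoked_center_s=-0.10,
            evoked_width_s=0.8,
            name="src1",
        ),
        SourceSpec(
            "deep_reversing",
            band_powers={"theta": 0.03, "slow_gamma": 0.8, "fast_gamma": 0.45},
            hold_gain={"slow_gamma": 0.4, "fast_gamma": 0.3},
            pull_gain={"slow_gamma": 1.0, "fast_gamma": 1.0},
            pull_delay_s={"slow_gamma": 0.3},
            coupling_depth={"slow_gamma": 0.4, "fast_gamma": 0.4},
            preferred_phase_deg=220.0,
            evoked_amp=0.8,
            evoked_center_s=0.05,
            evoked_width_s=0.6,
            name="src2",
        ),
        SourceSpec(
            "superficial_reversing",
            band_powers={"theta": 0.02, "slow_gamma": 0.4, "fast_gamma": 0.28},
            hold_gain={"slow_gamma": 1.0, "fast_gamma": 0.3},
            pull_gain={"slow_gamma": 0.5, "fast_gamma": 1.0},
            coupling_depth={"slow_gamma": 0.5, "fast_gamma": 0.5},
            preferred_phase_deg=200.0,
            evoked_amp=0.9,
            evoked_center_s=0.10,
            evoked_width_s=0.35,
            name="src3",
        ),
        SourceSpec(
            "linear_volume_conducted",
            band_powers={"theta": 0.9, "slow_gamma": 0.8, "fast_gamma": 0.2},
            hold_gain={"slow_gamma": 1.0, "fast_gamma": 1.0},
            pull_gain={"slow_gamma": 0.5, "fast_gamma": 1.0},
            coupling_depth={"slow_gamma": 0.4, "fast_gamma": 0.3},
            preferred_phase_deg=60.0,
            theta_coherent=True,
            evoked_amp=-0.7,
            evoked_center_s=-0.15,
            evoked_width_s=0.9,
            name="src4",
        ),
    ]


DEFAULT_DEPTHS_UM = np.arange(400.0, 1451.0, 150.0)  # 8 channels, 150 um apart


def generate_dataset(
    n_trials: int = 18,
    fs: float = 1000.0,
    depths_um: np.ndarray = DEFAULT_DEPTHS_UM,
    snr: float = 10.0,
    specs: list[SourceSpec] | None = None,
    with_spikes: bool = True,
    seed: int = 0,
) -> dict:
    """Generate a full synthetic session: recording, events, lever, spikes.

    ``snr`` is the ratio of mean per-channel signal power to sensor-noise
    power.  Returns a dict with keys ``recording``, ``events``, ``lever``
    (times, position), ``spikes`` and ``truth``.
    """
    rng = np.random.default_rng(seed)
    if specs is None:
        specs = default_source_specs()
    events = make_events(n_trials=n_trials, seed=rng)
    duration = events.pull_onsets[-1] + 1.5
    V_star = make_loadings(specs, depths_um)
    s_star, theta_phase = make_timecourses(specs, events, fs, duration, seed=rng)
    clean = V_star @ s_star
    p_sig = clean.var(axis=1).mean()
    noise_sd = np.sqrt(p_sig / snr) if snr > 0 else 0.0
    rec = mix(V_star, s_star, noise_sd, depths_um, fs, seed=rng)
    lever_t, lever_pos = make_lever(events, fs_lever=fs, duration=duration, seed=rng)
    events.lever = lever_pos
    events.fs_lever = fs

    spikes = SpikeTrainSet()
    unit_truth: list[dict] = []
    if with_spikes:
        plan = [
            # (source idx, band, plv, rate Hz, pref deg, layer, class)
            (0, "slow_gamma", 0.35, 8.0, 45.0, "superficial", "RS"),
            (0, "fast_gamma", 0.30, 10.0, 120.0, "superficial", "RS"),
            (1, "fast_gamma", 0.30, 12.0, 200.0, "deep", "RS"),
            (1, "slow_gamma", 0.25, 9.0, 300.0, "deep", "RS"),
            (3, "slow_gamma", 0.40, 15.0, 80.0, "deep", "FS"),
            (2, "fast_gamma", 0.35, 14.0, 260.0, "superficial", "FS"),
            (0, "slow_gamma", 0.0, 10.0, 0.0, "deep", "RS"),
            (1, "slow_gamma", 0.0, 10.0, 0.0, "superficial", "RS"),
        ]
        for i, (src, band, plv, rate, pref, layer, cls) in enumerate(plan):
            unit = make_spikes(
                s_star[src],
                fs,
                BANDS[band],
                plv_target=plv,
                rate=rate,
                preferred_phase=np.deg2rad(pref),
                layer=layer,
                cell_class=cls,
                seed=rng,
                unit_id=f"u{i}",
            )
            spikes.append(unit)
            unit_truth.append(
                {
                    "unit_id": f"u{i}",
                    "source": src,
                    "band": band,
                    "plv_target": plv,
                    "preferred_phase_deg": pref,
                    "rate_hz": rate,
                    "layer": layer,
                    "cell_class": cls,
                }
            )

    truth = GroundTruth(
        V_star=V_star,
        s_star=s_star,
        specs=specs,
        theta_phase=theta_phase,
        events=events,
        unit_truth=unit_truth,
        depths_um=np.asarray(depths_um, float),
        fs=fs,
        noise_sd=noise_sd,
    )
    return {
        "recording": rec,
        "events": events,
        "lever": (lever_t, lever_pos),
        "spikes": spikes,
        "truth": truth,
    }
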