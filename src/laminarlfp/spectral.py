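"""Morlet spectrograms, Welch PSDs, and event-triggered power averages.

The spectrogram is the squared magnitude of a continuous wavelet transform
with complex Morlet atoms of a fixed number of cycles (default 7): at
frequency f the atom is a complex exponential under a Gaussian envelope of
width sigma_t = n_cycles / (2 pi f), normalized so a unit-amplitude
sinusoid yields unit power at its ridge.  Edges are reflect-padded and a
cone-of-influence mask marks samples within sqrt(2) sigma_t of the edges.

Longer stretches of signal are summarized by Welch's power spectral
density with a 4096-point FFT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import EventTable, LaminarRecording

__all__ = [
    "Spectrogram",
    "BandPowerTrace",
    "morlet_spectrogram",
    "welch_psd",
    "triggered_power",
    "band_power",
]


@dataclass
class Spectrogram:
    power: np.ndarray  # freq x time, mV^2
    freqs: np.ndarray  # Hz, ascending
    times_ms: np.ndarray  # relative to alignment point
    coi: np.ndarray  # bool mask, True where edge effects contaminate

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("spectrogram power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0) or (
            self.times_ms.size > 1 and np.any(np.diff(self.times_ms) <= 0)
        ):
            raise ValueError("frequency and time grids must ascend")


@dataclass
class BandPowerTrace:
    band: tuple[float, float]
    power: np.ndarray  # mV^2 vs time
    times_ms: np.ndarray
    peak_power: float
    peak_freq: float


def morlet_spectrogram(
    trace: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    n_cycles: float = 7.0,
    times_ms: np.ndarray | None = None,
) -> Spectrogram:
    """Complex-Morlet wavelet power of a single trace."""
    trace = np.asarray(trace, dtype=float)
    if freqs is None:
        freqs = np.arange(2.0, min(150.0, fs / 2 - 1) + 1e-9, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= fs / 2:
        raise ValueError("requested frequencies reach the Nyquist limit")
    n = trace.size
    pad = min(n - 1, int(np.ceil(n_cycles / freqs.min() * fs)))
    padded = np.pad(trace, pad, mode="reflect")
    power = np.empty((freqs.size, n))
    coi = np.zeros((freqs.size, n), dtype=bool)
    idx = np.arange(n)
    for i, f in enumerate(freqs):
        sigma_t = n_cycles / (2 * np.pi * f)
        half = int(np.ceil(4 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        atom = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2 * sigma_t**2))
        atom /= np.abs(atom).sum() / 2.0  # unit ridge power for a unit cosine
        conv = sps.fftconvolve(padded, atom[::-1], mode="same")[pad : pad + n]
        power[i] = np.abs(conv) ** 2
        edge = np.sqrt(2.0) * sigma_t * fs
        coi[i] = (idx < edge) | (idx > n - 1 - edge)
    if times_ms is None:
        times_ms = np.arange(n) / fs * 1000.0
    return Spectrogram(power=power, freqs=freqs, times_ms=np.asarray(times_ms, float), coi=coi)


def welch_psd(
    trace: np.ndarray, fs: float, nfft: int = 4096
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD with an ``nfft``-point FFT; returns (freqs, psd)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < nfft:
        raise ValueError(f"trace of {trace.size} samples is shorter than nfft={nfft}")
    f, p = sps.welch(trace, fs=fs, nperseg=nfft, nfft=nfft)
    return f, p


def triggered_power(
    spectrograms: list[Spectrogram] | None = None,
    *,
    trace: np.ndarray | None = None,
    rec_fs: float | None = None,
    events: EventTable | None = None,
    window: tuple[float, float] = (1.0, 0.5),
    freqs: np.ndarray | None = None,
    n_cycles: float = 7.0,
) -> Spectrogram:
    """Pull-onset-triggered average wavelet power.

    Either pass precomputed per-trial ``spectrograms`` (pointwise mean), or a
    continuous ``trace`` with ``events``: wavelet power is computed on the
    whole trace once, then windows fully inside the recording are averaged,
    aligning time 0 to each onset.
    """
    if spectrograms is not None:
        if len(spectrograms) == 0:
            raise ValueError("need at least one trial")
        ref = spectrograms[0]
        mean = np.mean([s.power for s in spectrograms], axis=0)
        coi = np.any([s.coi for s in spectrograms], axis=0)
        return Spectrogram(power=mean, freqs=ref.freqs, times_ms=ref.times_ms, coi=coi)
    if trace is None or rec_fs is None or events is None:
        raise ValueError("provide spectrograms, or trace + rec_fs + events")
    spect = morlet_spectrogram(trace, rec_fs, freqs=freqs, n_cycles=n_cycles)
    n_pre = int(round(window[0] * rec_fs))
    n_post = int(round(window[1] * rec_fs))
    n = trace.size
    segs = []
    for onset in events.pull_onsets:
        c = int(round(onset * rec_fs))
        if c - n_pre < 0 or c + n_post + 1 > n:
            continue
        segs.append(spect.power[:, c - n_pre : c + n_post + 1])
    if not segs:
        raise ValueError("no trial window fits inside the recording")
    times_ms = np.arange(-n_pre, n_post + 1) / rec_fs * 1000.0
    mean = np.mean(segs, axis=0)
    coi = np.zeros_like(mean, dtype=bool)
    return Spectrogram(power=mean, freqs=spect.freqs, times_ms=times_ms, coi=coi)


def band_power(
    spect: Spectrogram,
    band: tuple[float, float],
    probe_freq: float | None = None,
) -> BandPowerTrace:
    """Power time course of one band.

    Without ``probe_freq`` the trace is taken at the in-band frequency of
    maximum power (the slow-gamma convention); with ``probe_freq`` (e.g.
    80 Hz for fast gamma) at the grid frequency nearest the probe.
    """
    lo, hi = band
    if lo < spect.freqs.min() - 0.5 or hi > spect.freqs.max() + 0.5:
        raise ValueError(f"band {band} outside the spectrogram frequency grid")
    if probe_freq is not None:
        row = int(np.argmin(np.abs(spect.freqs - probe_freq)))
    else:
        sel = (spect.freqs >= lo) & (spect.freqs <= hi)
        sub = spect.power[sel]
        row = np.nonzero(sel)[0][int(np.unravel_index(sub.argmax(), sub.shape)[0])]
    trace = spect.power[row]
    return BandPowerTrace(
        band=band,
        power=trace,
        times_ms=spect.times_ms,
        peak_power=float(trace.max()),
        peak_freq=float(spect.freqs[row]),
    )
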