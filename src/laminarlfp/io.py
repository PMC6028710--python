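"""Core data types for laminar recordings, events, spikes and decompositions.

A :class:`LaminarRecording` is the channels x time voltage matrix recorded by
a linear multi-electrode array spanning the cortical depth, together with the
per-channel depths (increasing downward from the pia) and the sampling rate.
Containers are deliberately simple (dataclasses over numpy arrays) and are
serialized to flat, diff-able formats: a float32 channel-major binary with a
JSON sidecar for the voltage matrix, and TSV for events, spikes and the lever
trace.  Times are stored in seconds; analysis windows elsewhere in the
package are quoted in milliseconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LaminarRecording",
    "EventTable",
    "SpikeTrain",
    "SpikeTrainSet",
    "ICDecomposition",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_spikes",
    "write_spikes",
    "segment_trials",
]

LAYERS = ("superficial", "deep")
CELL_CLASSES = ("RS", "FS")


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match its sidecar."""


@dataclass
class LaminarRecording:
    """Multi-channel laminar LFP.

    Parameters
    ----------
    samples : ndarray, shape (channels, time)
        Voltage in mV, channel-major.
    depths : ndarray, shape (channels,)
        Cortical depth of each electrode in micrometres, strictly increasing
        and equally spaced.
    fs : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    depths: np.ndarray
    fs: float
    units: str = "mV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.samples.ndim != 2 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty channels x time matrix")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN or infinite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.depths.shape != (self.samples.shape[0],):
            raise ValueError("depths must have one entry per channel")
        if self.n_channels < 3:
            raise ValueError("need >= 3 channels (CSD requires interior points)")
        steps = np.diff(self.depths)
        if np.any(steps <= 0):
            raise ValueError("depths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("electrode depths must be equally spaced")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def h(self) -> float:
        """Inter-electrode spacing in micrometres."""
        return float(self.depths[1] - self.depths[0])

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class EventTable:
    """Lever-pull onsets with reward flags and the lever-position trace."""

    pull_onsets: np.ndarray
    rewarded: np.ndarray | None = None
    lever: np.ndarray | None = None
    fs_lever: float | None = None

    def __post_init__(self) -> None:
        self.pull_onsets = np.asarray(self.pull_onsets, dtype=float)
        if self.pull_onsets.ndim != 1:
            raise ValueError("pull_onsets must be one-dimensional")
        if self.pull_onsets.size and np.any(np.diff(self.pull_onsets) <= 0):
            raise ValueError("pull_onsets must be strictly increasing")
        if self.rewarded is None:
            self.rewarded = np.ones(self.pull_onsets.size, dtype=bool)
        else:
            self.rewarded = np.asarray(self.rewarded, dtype=bool)
            if self.rewarded.shape != self.pull_onsets.shape:
                raise ValueError("rewarded must align with pull_onsets")

    @property
    def n_events(self) -> int:
        return self.pull_onsets.size

    def check_margins(self, duration: float, pre_s: float = 1.0, post_s: float = 0.5) -> None:
        """Ensure every onset has at least ``pre_s``/``post_s`` margin in a span."""
        if self.pull_onsets.size == 0:
            return
        if self.pull_onsets[0] < pre_s or self.pull_onsets[-1] > duration - post_s:
            raise ValueError(
                f"events need >= {pre_s} s pre- and >= {post_s} s post-margin "
                f"inside the {duration:.3f} s recording"
            )


@dataclass
class SpikeTrain:
    unit_id: str
    times: np.ndarray
    layer: str
    cell_class: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted")
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}")
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"cell_class must be one of {CELL_CLASSES}")


@dataclass
class SpikeTrainSet:
    units: list[SpikeTrain] = field(default_factory=list)

    def __iter__(self):
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)

    def append(self, unit: SpikeTrain) -> None:
        self.units.append(unit)


@dataclass
class ICDecomposition:
    """Result of PCA + ICA demixing of a laminar recording.

    The model is ``LFP(t) = sum_n V[:, n] * s[n, :]`` up to the PCA-discarded
    remainder and the per-channel mean.  ``V`` is the mixing (spatial loading)
    matrix in channel space, ``s`` the component time courses, ``W`` the
    unmixing matrix such that ``W @ (LFP - mean) = s``.
    """

    V: np.ndarray
    s: np.ndarray
    W: np.ndarray
    var_retained: float
    mean: np.ndarray
    depths: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.V.shape[1] != self.s.shape[0]:
            raise ValueError("V columns must match s rows")
        if not np.all(np.isfinite(self.V)) or np.any(np.all(self.V == 0, axis=0)):
            raise ValueError("columns of V must be finite and nonzero")

    @property
    def n_components(self) -> int:
        return self.V.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Channel-space reconstruction of the PCA-retained signal (centered)."""
        return self.V @ self.s


# ---------------------------------------------------------------------------
# file I/O: flat float32 binary + JSON sidecar, TSV for tabular artifacts
# ---------------------------------------------------------------------------

def write_recording(rec: LaminarRecording, path: str | Path) -> Path:
    """Write ``<path>.bin`` (float32 channel-major) and ``<path>.json``."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in {".bin", ".json"} else path
    sidecar = {
        "fs": rec.fs,
        "depths_um": rec.depths.tolist(),
        "units": rec.units,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "float32",
        "order": "channel_major",
    }
    base.with_suffix(".bin").write_bytes(
        np.ascontiguousarray(rec.samples, dtype=np.float32).tobytes()
    )
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return base.with_suffix(".bin")


def read_recording(path: str | Path) -> LaminarRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in {".bin", ".json"} else path
    sidecar_path = base.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    raw = np.fromfile(base.with_suffix(".bin"), dtype=np.float32)
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    if raw.size != n_ch * n_s:
        raise FormatError(
            f"sidecar claims {n_ch} x {n_s} samples but file holds {raw.size}"
        )
    return LaminarRecording(
        samples=raw.reshape(n_ch, n_s).astype(np.float32),
        depths=np.asarray(meta["depths_um"], dtype=float),
        fs=float(meta["fs"]),
        units=meta.get("units", "mV"),
    )


def write_events(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"onset_s": events.pull_onsets, "rewarded": events.rewarded.astype(int)}
    ).to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    return EventTable(
        pull_onsets=df["onset_s"].to_numpy(),
        rewarded=df["rewarded"].to_numpy(dtype=bool),
    )


def write_spikes(spikes: SpikeTrainSet, path: str | Path) -> Path:
    rows = [
        {"unit_id": u.unit_id, "time_s": t, "layer": u.layer, "cell_class": u.cell_class}
        for u in spikes
        for t in u.times
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s", "layer", "cell_class"]).to_csv(
        Path(path), sep="\t", index=False
    )
    return Path(path)


def read_spikes(path: str | Path) -> SpikeTrainSet:
    df = pd.read_csv(path, sep="\t")
    out = SpikeTrainSet()
    for uid, grp in df.groupby("unit_id", sort=False):
        out.append(
            SpikeTrain(
                unit_id=str(uid),
                times=np.sort(grp["time_s"].to_numpy()),
                layer=grp["layer"].iloc[0],
                cell_class=grp["cell_class"].iloc[0],
            )
        )
    return out


def write_lever(times: np.ndarray, position: np.ndarray, path: str | Path) -> Path:
    pd.DataFrame({"time_s": times, "position": position}).to_csv(
        Path(path), sep="\t", index=False
    )
    return Path(path)


def read_lever(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["time_s"].to_numpy(), df["position"].to_numpy()


def segment_trials(
    rec: LaminarRecording,
    events: EventTable,
    window: tuple[float, float] = (1.0, 0.5),
) -> np.ndarray:
    """Cut onset-aligned trials out of a recording.

    ``window = (pre_s, post_s)`` spans ``[-pre_s, +post_s]`` around each pull
    onset, both endpoints included, so a (1.0, 0.5) window at 1 kHz yields
    1501 samples.  Returns a (trials, channels, time) tensor in event order.
    """
    pre_s, post_s = window
    n_pre = int(round(pre_s * rec.fs))
    n_post = int(round(post_s * rec.fs))
    onset_idx = np.round(events.pull_onsets * rec.fs).astype(int)
    starts = onset_idx - n_pre
    stops = onset_idx + n_post + 1
    if np.any(starts < 0) or np.any(stops > rec.n_samples):
        raise ValueError("trial window exceeds recording span")
    return np.stack([rec.samples[:, a:b] for a, b in zip(starts, stops)])


def trial_times_ms(window: tuple[float, float], fs: float) -> np.ndarray:
    """Millisecond time axis matching :func:`segment_trials` (0 = onset)."""
    n_pre = int(round(window[0] * fs))
    n_post = int(round(window[1] * fs))
    return np.arange(-n_pre, n_post + 1) / fs * 1000.0
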