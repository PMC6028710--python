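"""Functional-subtype classification of trial-averaged responses.

Each neuron's trial-averaged, min-max-normalized response on the
[-1000, +500] ms segment around pull onset is screened for *phasic* epochs:
contiguous runs where activity leaves the mu +/- 3 sigma band of its
baseline (1000-250 ms before onset) for more than 60 ms.  Epochs are then
labelled with the task-related subtypes:

* Pre-movement  — a positive epoch starting earlier than 500 ms before
  onset whose activity drops below half its peak after onset;
* Post-movement — a positive epoch starting at onset and over within
  350 ms;
* Movement-related — a positive epoch during the movement window;
* Hold-related / Movement-off — a phasic *decrease* during movement (the
  two are not distinguished);
* Others — everything else (the classifier is total).

Populations are ordered by the activation time t_hat, the amplitude-
weighted circular mean of response timing over the segment (period
T = 750 two-millisecond bins, i.e. the 1500 ms segment), wrapped into
(-1000, +500] ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubtypeRuleSet",
    "PhasicEpoch",
    "SortedPopulation",
    "LABELS",
    "detect_phasic",
    "classify",
    "classify_population",
    "activation_time",
    "sort_population",
    "population_fractions",
]

LABELS = (
    "hold_movement_off",
    "movement_related",
    "pre_movement",
    "post_movement",
    "others",
)


@dataclass
class SubtypeRuleSet:
    baseline_window_ms: tuple[float, float] = (-1000.0, -250.0)
    threshold_sigma: float = 3.0
    min_duration_ms: float = 60.0
    pre_movement_start_before_ms: float = -500.0
    pre_movement_drop_frac: float = 0.5
    post_movement_deadline_ms: float = 350.0
    movement_window_ms: tuple[float, float] = (-200.0, 300.0)


@dataclass
class PhasicEpoch:
    sign: int  # +1 increase, -1 decrease
    start_ms: float
    end_ms: float


@dataclass
class SortedPopulation:
    labels: list[str]
    activation_times_ms: np.ndarray
    order: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.order is None:
            self.order = np.argsort(self.activation_times_ms, kind="stable")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = np.nonzero(d == 1)[0] + 1
    stops = np.nonzero(d == -1)[0]
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size - 1]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_phasic(
    response: np.ndarray,
    times_ms: np.ndarray,
    rules: SubtypeRuleSet | None = None,
) -> tuple[list[PhasicEpoch], bool]:
    """Supra/infra-threshold runs longer than the minimum duration.

    Returns ``(epochs, classifiable)``; a flat baseline (sigma = 0) makes
    the neuron non-classifiable and yields no epochs.
    """
    rules = rules or SubtypeRuleSet()
    response = np.asarray(response, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    lo, hi = rules.baseline_window_ms
    base = response[(times_ms >= lo) & (times_ms <= hi)]
    if base.size == 0:
        raise ValueError("baseline window outside the response time axis")
    mu, sd = base.mean(), base.std()
    if sd == 0:
        return [], False
    dt = np.median(np.diff(times_ms))
    min_samples = int(np.ceil(rules.min_duration_ms / dt))
    epochs: list[PhasicEpoch] = []
    for sign, mask in (
        (1, response > mu + rules.threshold_sigma * sd),
        (-1, response < mu - rules.threshold_sigma * sd),
    ):
        for a, b in _runs(mask):
            if (b - a + 1) > min_samples:
                epochs.append(PhasicEpoch(sign, times_ms[a], times_ms[b]))
    epochs.sort(key=lambda e: e.start_ms)
    return epochs, True


def classify(
    epochs: list[PhasicEpoch],
    response: np.ndarray,
    times_ms: np.ndarray,
    rules: SubtypeRuleSet | None = None,
    classifiable: bool = True,
) -> str:
    """Label one neuron; precedence pre -> post -> movement -> hold -> others."""
    rules = rules or SubtypeRuleSet()
    if not classifiable or not epochs:
        return "others"
    response = np.asarray(response, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    mw_lo, mw_hi = rules.movement_window_ms
    post = times_ms > 0

    for e in epochs:
        if e.sign > 0 and e.start_ms < rules.pre_movement_start_before_ms:
            in_epoch = (times_ms >= e.start_ms) & (times_ms <= e.end_ms)
            peak = response[in_epoch].max()
            if post.any() and response[post].min() < rules.pre_movement_drop_frac * peak:
                return "pre_movement"
    for e in epochs:
        if (
            e.sign > 0
            and 0.0 <= e.start_ms <= rules.post_movement_deadline_ms
            and e.end_ms <= rules.post_movement_deadline_ms
        ):
            return "post_movement"
    for e in epochs:
        if e.sign > 0 and e.start_ms <= mw_hi and e.end_ms >= mw_lo:
            return "movement_related"
    for e in epochs:
        if e.sign < 0 and e.start_ms <= mw_hi and e.end_ms >= mw_lo:
            return "hold_movement_off"
    return "others"


def classify_population(
    responses: np.ndarray,
    times_ms: np.ndarray,
    rules: SubtypeRuleSet | None = None,
) -> list[str]:
    """Label every neuron of a (neurons x time) response matrix."""
    rules = rules or SubtypeRuleSet()
    out = []
    for resp in np.atleast_2d(responses):
        epochs, ok = detect_phasic(resp, times_ms, rules)
        out.append(classify(epochs, resp, times_ms, rules, classifiable=ok))
    return out


def activation_time(
    response: np.ndarray,
    times_ms: np.ndarray,
    T: int = 750,
) -> float:
    """Amplitude-weighted circular mean time of a non-negative response.

    The response is averaged onto T two-millisecond bins covering
    (-1000, +500] ms; the phasor sum sum_t r(t) exp(i 2 pi t'/T) over bin
    indices t' = 1..T gives t_hat = wrap((T/pi) arg - 1000) in
    (-1000, +500] ms.  Point masses return their own bin time.
    """
    response = np.asarray(response, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if np.any(response < 0):
        raise ValueError("response must be non-negative")
    if not np.any(response):
        raise ValueError("activation time of an all-zero response is undefined")
    # bin onto the 2 ms grid t_ms = 2 t' - 1000, t' = 1..T; the segment is
    # circular with period 2T ms, so -1000 ms wraps onto the +500 ms bin
    tprime = (np.round((times_ms + 1000.0) / 2.0).astype(int) - 1) % T + 1
    r_binned = np.bincount(tprime, weights=response, minlength=T + 1)[1:]
    angles = 2.0 * np.pi * np.arange(1, T + 1) / T
    phasor = np.sum(r_binned * np.exp(1j * angles)) / r_binned.sum()
    t_hat = (T / np.pi) * np.angle(phasor) - 1000.0
    # wrap into (-1000, +500]; the segment period is 2T ms = 1500 ms
    period = 2.0 * T
    while t_hat <= -1000.0:
        t_hat += period
    while t_hat > 500.0:
        t_hat -= period
    return float(t_hat)


def sort_population(
    responses: np.ndarray,
    times_ms: np.ndarray,
    rules: SubtypeRuleSet | None = None,
    T: int = 750,
) -> SortedPopulation:
    labels = classify_population(responses, times_ms, rules)
    t_hats = np.array(
        [
            activation_time(resp, times_ms, T) if np.any(resp) else 500.0
            for resp in np.atleast_2d(responses)
        ]
    )
    return SortedPopulation(labels=labels, activation_times_ms=t_hats)


def population_fractions(labels_per_condition: dict[str, list[str]]) -> pd.DataFrame:
    """Subtype fractions per input condition; columns sum to 1."""
    if not labels_per_condition:
        raise ValueError("no populations to tabulate")
    table = {}
    for cond, labels in labels_per_condition.items():
        if len(labels) == 0:
            raise ValueError(f"condition {cond!r} has an empty population")
        counts = pd.Series(labels).value_counts()
        table[cond] = [counts.get(lab, 0) / len(labels) for lab in LABELS]
    return pd.DataFrame(table, index=list(LABELS))
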