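"""Rate-based recurrent reservoir driven by LFP components, FORCE-trained.

The network follows the echo-state / FORCE paradigm: N_G rate units with

    tau dx_i/dt = -x_i + g_G sum_j J^GG_ij r_j + J^Gz_i z + sum_mu J^GI_imu I_mu,
    r_i = [tanh(x_i)]_+                        (rates bounded in [0, 1)),
    z   = w^T r,

where J^GG is a sparse random matrix (connection probability p, Gaussian
weights of standard deviation ``weight_sd``, default 0.6).  For these
*rectified* tanh units — roughly half silent at any instant — the chaotic
transition at g_G = 1.5 sits near weight sd ~ 0.55, so the default gives
sustained irregular pre-training activity while remaining weak enough for
the unit-range readout feedback to entrain during learning; the feedback
weights J^Gz are uniform on (-1, 1), and only the readout w is plastic.  FORCE learning updates w online by recursive least squares while
the feedback loop carries z, suppressing the chaos into the target
trajectory — here the lever position on [-1000, +500] ms segments around
each pull onset.  Inputs are the reconstructed component traces, low-pass
filtered at 10 Hz and normalized to [-1, 1], assigned to neurons by one of
three schemes (one random component per neuron, equal partition without
overlap, or a single component for all neurons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "ReservoirParams",
    "InputConfig",
    "ReservoirModel",
    "build",
    "prepare_inputs",
    "simulate",
    "force_train",
    "rollout_nrmse",
    "collect_responses",
    "nrmse",
    "scale_to_range",
]


@dataclass
class ReservoirParams:
    N_G: int = 300
    tau: float = 50.0  # ms
    g_G: float = 1.5
    p: float = 0.1
    N_I: int = 4
    dt: float = 1.0  # ms
    weight_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt > self.tau / 10:
            raise ValueError("dt must be <= tau/10 for a stable Euler step")


@dataclass
class InputConfig:
    assignment: str = "one_random_ic_per_neuron"
    single_ic: int = 0
    cutoff_hz: float = 10.0
    norm_range: tuple[float, float] = (-1.0, 1.0)
    input_gain: float = 2.0  # scales the U(-1,1) input weights


@dataclass
class ReservoirModel:
    params: ReservoirParams
    J_GG: np.ndarray
    J_Gz: np.ndarray
    J_GI: np.ndarray
    w: np.ndarray
    P: np.ndarray | None = None
    x: np.ndarray = field(default=None)  # type: ignore[assignment]
    z: float = 0.0

    def reset(self, rng: np.random.Generator | None = None) -> None:
        if rng is None:
            self.x = np.zeros(self.params.N_G)
        else:
            self.x = 0.5 * rng.standard_normal(self.params.N_G)
        self.z = 0.0

    @property
    def rates(self) -> np.ndarray:
        return np.maximum(np.tanh(self.x), 0.0)


def build(
    params: ReservoirParams,
    input_cfg: InputConfig | None = None,
    seed: int | None = None,
) -> ReservoirModel:
    """Draw the fixed random connectivity; the readout starts at zero."""
    input_cfg = input_cfg or InputConfig()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.N_G
    mask = rng.uniform(size=(n, n)) < params.p
    J_GG = np.where(mask, rng.standard_normal((n, n)) * params.weight_sd, 0.0)
    J_Gz = rng.uniform(-1.0, 1.0, n)
    J_GI = np.zeros((n, params.N_I))
    weights = rng.uniform(-1.0, 1.0, n) * input_cfg.input_gain
    if input_cfg.assignment == "one_random_ic_per_neuron":
        chan = rng.integers(params.N_I, size=n)
    elif input_cfg.assignment == "partitioned_equal_no_overlap":
        chan = rng.permutation(np.arange(n) % params.N_I)
    elif input_cfg.assignment == "single_ic":
        chan = np.full(n, input_cfg.single_ic)
    else:
        raise ValueError(f"unknown input assignment {input_cfg.assignment!r}")
    J_GI[np.arange(n), chan] = weights
    model = ReservoirModel(
        params=params, J_GG=J_GG, J_Gz=J_Gz, J_GI=J_GI, w=np.zeros(n)
    )
    model.reset(rng)
    return model


def prepare_inputs(
    ic_traces: np.ndarray,
    fs: float,
    cutoff_hz: float = 10.0,
    norm_range: tuple[float, float] = (-1.0, 1.0),
) -> np.ndarray:
    """Low-pass each component trace at ``cutoff_hz`` and map to [-1, 1].

    ``ic_traces`` is channels x time (the concatenated training segments);
    the affine map is fitted per channel over the whole set so trials share
    one scale.
    """
    ic_traces = np.atleast_2d(np.asarray(ic_traces, dtype=float))
    sos = sps.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    out = np.empty_like(ic_traces)
    lo, hi = norm_range
    for i, tr in enumerate(ic_traces):
        f = sps.sosfiltfilt(sos, tr)
        fmin, fmax = f.min(), f.max()
        if fmax == fmin:
            raise ValueError("constant input trace cannot be range-normalized")
        out[i] = (f - fmin) / (fmax - fmin) * (hi - lo) + lo
    return out


def _step(model: ReservoirModel, inp: np.ndarray, r: np.ndarray, dt: float) -> np.ndarray:
    p = model.params
    drive = p.g_G * (model.J_GG @ r) + model.J_Gz * model.z + model.J_GI @ inp
    model.x = model.x + dt / p.tau * (-model.x + drive)
    r = np.maximum(np.tanh(model.x), 0.0)
    model.z = float(model.w @ r)
    return r


def simulate(
    model: ReservoirModel,
    inputs: np.ndarray | None,
    duration_ms: float | None = None,
    record_rates: bool = True,
) -> dict:
    """Run the network forward with explicit Euler; feedback active.

    ``inputs`` is N_I x steps (or None for autonomous dynamics over
    ``duration_ms``).  Returns ``{'rates': steps x N_G or None, 'z': steps}``.
    Raises on numerical blow-up.
    """
    p = model.params
    if inputs is not None:
        inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
        steps = inputs.shape[1]
    else:
        if duration_ms is None:
            raise ValueError("need inputs or duration_ms")
        steps = int(round(duration_ms / p.dt))
    zeros = np.zeros(p.N_I)
    r = model.rates
    zs = np.empty(steps)
    rates = np.empty((steps, p.N_G)) if record_rates else None
    for t in range(steps):
        inp = inputs[:, t] if inputs is not None else zeros
        r = _step(model, inp, r, p.dt)
        if not np.all(np.isfinite(model.x)):
            raise FloatingPointError(f"reservoir state diverged at step {t}")
        zs[t] = model.z
        if record_rates:
            rates[t] = r
    return {"rates": rates, "z": zs}


def nrmse(z: np.ndarray, target: np.ndarray) -> float:
    """RMS error normalized by the target's centered RMS."""
    z = np.asarray(z, float)
    target = np.asarray(target, float)
    denom = np.sqrt(np.mean((target - target.mean()) ** 2))
    if denom == 0:
        return float(np.sqrt(np.mean((z - target) ** 2)))
    return float(np.sqrt(np.mean((z - target) ** 2)) / denom)


def _rls_update(model: ReservoirModel, r: np.ndarray, e: float) -> None:
    k = model.P @ r
    c = 1.0 / (1.0 + float(r @ k))
    model.P -= c * np.outer(k, k)
    model.w -= c * e * k
    model.z = float(model.w @ r)


def force_train(
    model: ReservoirModel,
    inputs_per_trial: list[np.ndarray],
    targets_per_trial: list[np.ndarray],
    n_epochs: int = 8,
    rls_alpha: float = 1.0,
    update_every: int = 1,
    washout_ms: float = 200.0,
    washout_target: float | None = None,
    shuffle_seed: int = 0,
) -> tuple[ReservoirModel, list[float]]:
    """FORCE-train the readout by recursive least squares.

    Trials are concatenated in shuffled order each epoch with a short
    washout between them (state carried over).  When ``washout_target`` is
    given (typically the hold level of the normalized lever) the readout is
    also trained toward that constant during washouts, which keeps the
    feedback loop entrained through the inter-trial gaps — important
    because a free-running washout lets the pre-training chaos re-emerge.
    Returns the trained model and the per-epoch RMS error; raises when the
    error grows tenfold across epochs (divergence).
    """
    p = model.params
    n = p.N_G
    if model.P is None:
        model.P = np.eye(n) / rls_alpha
    rng = np.random.default_rng(shuffle_seed)
    wash_steps = int(round(washout_ms / p.dt))
    zeros = np.zeros(p.N_I)
    errors: list[float] = []
    for epoch in range(n_epochs):
        order = rng.permutation(len(inputs_per_trial))
        sq_sum, count = 0.0, 0
        for ti in order:
            inp = np.atleast_2d(inputs_per_trial[ti])
            tgt = np.asarray(targets_per_trial[ti], float)
            r = model.rates
            for t in range(wash_steps):
                r = _step(model, zeros, r, p.dt)
                if washout_target is not None and t % update_every == 0:
                    _rls_update(model, r, model.z - washout_target)
            for t in range(inp.shape[1]):
                r = _step(model, inp[:, t], r, p.dt)
                e = model.z - tgt[t]
                if t % update_every == 0:
                    _rls_update(model, r, e)
                sq_sum += e * e
                count += 1
        rms = float(np.sqrt(sq_sum / count))
        if errors and rms > 10 * max(errors[0], 1e-9):
            raise RuntimeError(f"FORCE training diverged in epoch {epoch}")
        errors.append(rms)
    return model, errors


def rollout_nrmse(
    model: ReservoirModel,
    inputs_per_trial: list[np.ndarray],
    targets_per_trial: list[np.ndarray],
    washout_ms: float = 200.0,
) -> list[float]:
    """Autonomous test error: learning off, feedback on, state carried over."""
    p = model.params
    wash_steps = int(round(washout_ms / p.dt))
    zeros = np.zeros(p.N_I)
    out = []
    r = model.rates
    for inp, tgt in zip(inputs_per_trial, targets_per_trial):
        for _ in range(wash_steps):
            r = _step(model, zeros, r, p.dt)
        res = simulate(model, np.atleast_2d(inp), record_rates=False)
        r = model.rates
        out.append(nrmse(res["z"], np.asarray(tgt, float)))
    return out


def scale_to_range(
    x: np.ndarray, lo: float = -1.0, hi: float = 1.0
) -> np.ndarray:
    """Affine map of a trace onto [lo, hi] (used for the lever target)."""
    x = np.asarray(x, dtype=float)
    xmin, xmax = x.min(), x.max()
    if xmax == xmin:
        raise ValueError("constant trace cannot be range-normalized")
    return (x - xmin) / (xmax - xmin) * (hi - lo) + lo


def collect_responses(
    model: ReservoirModel,
    inputs_per_trial: list[np.ndarray],
    washout_ms: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged, min-max-normalized rates (learning off, feedback on).

    Returns ``(responses, flat_mask)``: responses is neurons x time in
    [0, 1]; neurons whose averaged response is flat cannot be normalized and
    are zeroed with their mask bit set (the classifier treats them as
    non-phasic).
    """
    p = model.params
    wash_steps = int(round(washout_ms / p.dt))
    zeros = np.zeros(p.N_I)
    acc = None
    for inp in inputs_per_trial:
        inp = np.atleast_2d(inp)
        r = model.rates
        for _ in range(wash_steps):
            r = _step(model, zeros, r, p.dt)
        out = simulate(model, inp, record_rates=True)
        acc = out["rates"] if acc is None else acc + out["rates"]
    mean = acc.T / len(inputs_per_trial)  # neurons x time
    lo = mean.min(axis=1, keepdims=True)
    hi = mean.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] <= 1e-12
    span[flat] = 1.0
    norm = (mean - lo) / span
    norm[flat] = 0.0
    return norm, flat
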