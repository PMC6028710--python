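"""PCA preprocessing, ICA demixing, and component-level summaries.

The demixing model is LFP(t) = sum_n V_n s_n(t): statistically independent,
spatially stationary sources that mix linearly and instantaneously across
the electrode array.  Dimensionality is first reduced by PCA keeping a
configurable fraction of the LFP variance (default 99.0%), then a
maximum-non-Gaussianity ICA (FastICA) unmixes the retained subspace.  The
mixing matrix mapped back to channel space gives the spatial voltage
loadings V_n; per-component summaries follow:

* relative contribution  W_n = ||V_n||^2 var(s_n) / sum_m ||V_m||^2 var(s_m)
* reconstructed trace    IC_n(t) = V_n(k*) s_n(t),  k* = argmax_k |V_n(k)|,

the latter removing ICA's scale/sign ambiguity by re-expressing each
component in mV at its dominant electrode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .io import ICDecomposition, LaminarRecording
from .loadings import LoadingDistanceParams, loading_distance

__all__ = [
    "ComponentProfile",
    "pca_reduce",
    "run_ica",
    "major_components",
    "relative_contribution",
    "reconstruct_ic",
    "match_components",
]


@dataclass
class ComponentProfile:
    index: int
    V_n: np.ndarray
    s_n: np.ndarray
    W_n: float
    max_electrode: int
    trace: np.ndarray  # IC_n(t) in mV


def pca_reduce(
    rec: LaminarRecording | np.ndarray, var_frac: float = 0.99
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Project onto the fewest principal components covering ``var_frac``.

    Returns ``(reduced, components, var_retained, mean)`` where ``reduced``
    is k x time, ``components`` the channels x k orthonormal back-projection
    map, and ``mean`` the per-channel mean removed before the projection.
    """
    if not 0.0 < var_frac <= 1.0:
        raise ValueError("var_frac must lie in (0, 1]")
    X = rec.samples if isinstance(rec, LaminarRecording) else np.asarray(rec, float)
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    if not np.any(Xc):
        raise ValueError("constant recording has no principal components")
    U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    var = sv**2
    var = var / var.sum()
    cum = np.cumsum(var)
    k = int(np.searchsorted(cum, var_frac - 1e-12) + 1)
    k = min(k, np.count_nonzero(sv > sv[0] * 1e-12))
    comps = U[:, :k]
    reduced = comps.T @ Xc
    return reduced, comps, float(cum[k - 1]), mean[:, 0]


def run_ica(
    rec: LaminarRecording | np.ndarray,
    var_frac: float = 0.99,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-4,
    strict: bool = False,
    depths_um: np.ndarray | None = None,
    fs: float | None = None,
) -> ICDecomposition:
    """PCA-reduce then unmix a laminar recording into independent components.

    Components are sign-fixed (largest-magnitude loading extremum positive)
    and ordered by descending relative contribution.  V s reproduces the
    PCA-retained centered signal to numerical precision.

    FastICA is restarted with fresh deterministic initializations when its
    fixed-point iteration stalls; if no restart reaches ``tol`` the best
    attempt is kept with a warning (``strict=True`` raises instead, with the
    iteration diagnostics).  Stalling on the near-Gaussian noise components
    of the retained subspace is common and harmless to the source loadings.
    """
    if isinstance(rec, LaminarRecording):
        depths_um = rec.depths
        fs = rec.fs
    reduced, comps, var_retained, mean = pca_reduce(rec, var_frac)
    k = reduced.shape[0]
    ica = s = None
    fallback = None
    for attempt in range(4):
        cand = FastICA(
            n_components=k,
            whiten="unit-variance",
            random_state=seed + 1000 * attempt,
            max_iter=max_iter,
            tol=tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            cand_s = cand.fit_transform(reduced.T).T  # k x time
        if not hasattr(cand, "mixing_"):
            continue
        if cand.n_iter_ < max_iter:
            ica, s = cand, cand_s
            break
        if fallback is None:
            fallback = (cand, cand_s)
    if ica is None:
        if strict or fallback is None:
            raise RuntimeError(
                f"ICA did not reach tol={tol} within {max_iter} iterations "
                f"over 4 restarts"
            )
        warnings.warn(
            f"FastICA stalled at max_iter={max_iter}; keeping the best attempt"
        )
        ica, s = fallback
    # mixing back to channel space; add the ICA mean so V s equals the
    # PCA-retained signal, not just the doubly-centered one
    V = comps @ ica.mixing_
    resid = comps @ ica.mean_[:, None]
    # fold the small residual mean into the overall channel mean
    mean = mean + resid[:, 0]

    # sign convention: largest-|.| extremum of each loading positive
    ext = V[np.abs(V).argmax(axis=0), np.arange(k)]
    flip = np.where(ext < 0, -1.0, 1.0)
    V = V * flip
    s = s * flip[:, None]

    # order by descending relative contribution
    w = (V**2).sum(axis=0) * s.var(axis=1)
    order = np.argsort(w)[::-1]
    V, s = V[:, order], s[order]
    W = np.linalg.pinv(V)
    return ICDecomposition(
        V=V,
        s=s,
        W=W,
        var_retained=var_retained,
        mean=mean,
        depths=np.asarray(depths_um, float) if depths_um is not None else np.arange(V.shape[0], dtype=float),
        fs=float(fs) if fs is not None else 1.0,
    )


def major_components(dec: ICDecomposition, n: int = 4) -> np.ndarray:
    """Indices of the ``n`` most non-Gaussian components.

    The physiological sources are bursty (heavy-tailed) while the retained
    sensor-noise components stay near-Gaussian, so excess kurtosis of the
    time courses separates "major" components far more reliably than the
    variance share does.
    """
    from scipy.stats import kurtosis

    if not 1 <= n <= dec.n_components:
        raise ValueError("n out of range")
    kur = kurtosis(dec.s, axis=1)
    return np.sort(np.argsort(kur)[::-1][:n])


def relative_contribution(dec: ICDecomposition) -> np.ndarray:
    """Per-component share of LFP variance; sums to 1."""
    w = (dec.V**2).sum(axis=0) * dec.s.var(axis=1)
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero decomposition")
    return w / total


def reconstruct_ic(dec: ICDecomposition, n: int) -> ComponentProfile:
    """Scale-unambiguous component trace at its dominant electrode."""
    if not 0 <= n < dec.n_components:
        raise IndexError(f"component {n} out of range")
    v = dec.V[:, n]
    k_star = int(np.argmax(np.abs(v)))  # ties resolve to the smallest index
    return ComponentProfile(
        index=n,
        V_n=v,
        s_n=dec.s[n],
        W_n=float(relative_contribution(dec)[n]),
        max_electrode=k_star,
        trace=v[k_star] * dec.s[n],
    )


def match_components(
    recovered: np.ndarray,
    truth: np.ndarray,
    params: LoadingDistanceParams | None = None,
) -> tuple[list[tuple[int, int]], np.ndarray, list[int]]:
    """Optimal one-to-one pairing of recovered and true loadings.

    Minimizes total Sobolev distance by the Hungarian algorithm over the
    (possibly rectangular) cost matrix.  Returns ``(pairs, distances,
    unmatched)`` where pairs are (recovered index, truth index) and
    unmatched lists leftover indices on the larger side.
    """
    recovered = np.atleast_2d(np.asarray(recovered, float))
    truth = np.atleast_2d(np.asarray(truth, float))
    if recovered.size == 0 or truth.size == 0:
        raise ValueError("empty loading sets cannot be matched")
    nr, nt = recovered.shape[0], truth.shape[0]
    cost = np.empty((nr, nt))
    for i in range(nr):
        for j in range(nt):
            cost[i, j] = loading_distance(recovered[i], truth[j], params)
    rows, cols = linear_sum_assignment(cost)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    dists = cost[rows, cols]
    if nr > nt:
        unmatched = sorted(set(range(nr)) - set(rows.tolist()))
    else:
        unmatched = sorted(set(range(nt)) - set(cols.tolist()))
    return pairs, dists, unmatched
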