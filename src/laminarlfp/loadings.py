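"""Spatial-loading geometry: Sobolev distance, clustering, CSD, volume conduction.

The dissimilarity between two depth profiles V_n, V_m is

    d(V_n, V_m) = 1 - |<V_n, V_m>| / (||V_n|| ||V_m||),

with the Sobolev-type inner product

    <V_n, V_m> = int_Omega V_n V_m + kappa grad(V_n) grad(V_m)
                 + kappa^2 lap(V_n) lap(V_m) dx,

where Omega is the electrode depth span and kappa (default 150 um^2)
weights the derivative terms to magnify shape differences at coarse
inter-electrode spacing.  Because the discrete form is a Gram matrix with
non-negative trapezoid weights, Cauchy-Schwarz bounds d in [0, 1].

The current-source-density loading is the negative discrete Laplacian of a
voltage loading, I_k = -sigma (V_{k-1} - 2 V_k + V_{k+1}) / h^2 at interior
electrodes (sigma fixed at 1); it vanishes identically for depth-linear
(volume-conducted) profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "LoadingDistanceParams",
    "CSDLoading",
    "loading_inner",
    "loading_norm",
    "loading_distance",
    "sobolev_embedding",
    "cluster_loadings",
    "csd_loading",
    "is_volume_conducted",
]


@dataclass
class LoadingDistanceParams:
    """kappa in um^2 and the depth grid defining the integration domain."""

    kappa: float = 150.0
    depths_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


def _grid(v: np.ndarray, params: LoadingDistanceParams) -> np.ndarray:
    if params.depths_um is not None:
        x = np.asarray(params.depths_um, dtype=float)
        if x.size != v.size:
            raise ValueError("depth grid must match loading length")
        steps = np.diff(x)
        if not np.allclose(steps, steps[0]):
            raise ValueError("depth grid must be uniform")
        return x
    return np.arange(v.size, dtype=float)


def _second_derivative(v: np.ndarray, h: float) -> np.ndarray:
    """Central second difference, one-sided second-order at the boundaries.

    Exact for quadratics everywhere, which makes the curvature term of the
    inner product vanish identically on affine profiles.
    """
    d2 = np.empty_like(v, dtype=float)
    d2[1:-1] = (v[:-2] - 2 * v[1:-1] + v[2:]) / h**2
    d2[0] = (2 * v[0] - 5 * v[1] + 4 * v[2] - v[3]) / h**2 if v.size >= 4 else d2[1]
    d2[-1] = (
        (2 * v[-1] - 5 * v[-2] + 4 * v[-3] - v[-4]) / h**2 if v.size >= 4 else d2[-2]
    )
    return d2


def _derivatives(v, params):
    x = _grid(v, params)
    h = x[1] - x[0]
    d1 = np.gradient(v, x, edge_order=2)
    d2 = _second_derivative(np.asarray(v, dtype=float), h)
    return x, d1, d2


def loading_inner(
    V_n: np.ndarray, V_m: np.ndarray, params: LoadingDistanceParams | None = None
) -> float:
    """Sobolev-type inner product of two loadings (trapezoid over depth)."""
    params = params or LoadingDistanceParams()
    V_n = np.asarray(V_n, dtype=float)
    V_m = np.asarray(V_m, dtype=float)
    if V_n.shape != V_m.shape:
        raise ValueError("loadings must have equal length")
    if V_n.size < 3:
        raise ValueError("need >= 3 support points for derivative terms")
    x, d1n, d2n = _derivatives(V_n, params)
    _, d1m, d2m = _derivatives(V_m, params)
    k = params.kappa
    integrand = V_n * V_m + k * d1n * d1m + k**2 * d2n * d2m
    return float(np.trapezoid(integrand, x))


def loading_norm(V_n: np.ndarray, params: LoadingDistanceParams | None = None) -> float:
    return float(np.sqrt(loading_inner(V_n, V_n, params)))


def loading_distance(
    V_n: np.ndarray, V_m: np.ndarray, params: LoadingDistanceParams | None = None
) -> float:
    """Normalized dissimilarity in [0, 1]; 0 for collinear profiles."""
    params = params or LoadingDistanceParams()
    nn = loading_norm(V_n, params)
    nm = loading_norm(V_m, params)
    if nn == 0.0 or nm == 0.0:
        raise ValueError("zero-norm loading has no defined distance")
    d = 1.0 - abs(loading_inner(V_n, V_m, params)) / (nn * nm)
    # guard the floating-point fringe of Cauchy-Schwarz
    return float(min(max(d, 0.0), 1.0))


def sobolev_embedding(
    loadings: np.ndarray, params: LoadingDistanceParams | None = None
) -> np.ndarray:
    """Feature map whose squared Euclidean norm equals the Eq.-4 norm.

    Concatenates sqrt(w_i) V, sqrt(kappa w_i) grad V and kappa sqrt(w_i)
    lap V, with w_i the trapezoid weights, so Ward linkage on the embedding
    is consonant with the Sobolev metric.
    """
    params = params or LoadingDistanceParams()
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    feats = []
    for v in loadings:
        x, d1, d2 = _derivatives(v, params)
        h = x[1] - x[0]
        w = np.full(v.size, h)
        w[0] = w[-1] = h / 2.0
        sw = np.sqrt(w)
        feats.append(
            np.concatenate(
                [sw * v, np.sqrt(params.kappa) * sw * d1, params.kappa * sw * d2]
            )
        )
    return np.vstack(feats)


def cluster_loadings(
    loadings: np.ndarray,
    n_groups: int,
    params: LoadingDistanceParams | None = None,
    method: str = "ward_sobolev",
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Group loadings across replicates by hierarchical clustering.

    ``method='ward_sobolev'`` (default) applies Ward's minimum-variance
    linkage with a Euclidean metric on the Sobolev feature embedding;
    ``method='average_d'`` applies average linkage directly to the pairwise
    distance matrix.  Loadings are max-normalized first (their scale is an
    ICA artefact).  Returns (linkage matrix, labels in 1..n_groups).
    """
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    if loadings.shape[0] < n_groups:
        raise ValueError("fewer loadings than requested groups")
    params = params or LoadingDistanceParams()
    if normalize:
        peaks = np.abs(loadings).max(axis=1, keepdims=True)
        signs = np.take_along_axis(
            loadings, np.abs(loadings).argmax(axis=1, keepdims=True), axis=1
        )
        loadings = loadings / np.where(signs != 0, signs, peaks)
    if method == "ward_sobolev":
        Z = hierarchy.linkage(sobolev_embedding(loadings, params), method="ward")
    elif method == "average_d":
        m = loadings.shape[0]
        dm = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                dm[i, j] = dm[j, i] = loading_distance(loadings[i], loadings[j], params)
        Z = hierarchy.linkage(squareform(dm, checks=False), method="average")
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    labels = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    return Z, labels


@dataclass
class CSDLoading:
    """CSD loading at interior electrodes (sigma = 1, arbitrary units)."""

    values: np.ndarray
    depths_um: np.ndarray | None = None
    boundary_policy: str = "strict_interior"


def csd_loading(
    V_n: np.ndarray, h: float, sigma: float = 1.0, depths_um: np.ndarray | None = None
) -> CSDLoading:
    """Negative discrete Laplacian of a voltage loading along depth."""
    V_n = np.asarray(V_n, dtype=float)
    if V_n.size < 3:
        raise ValueError("CSD needs >= 3 channels")
    if depths_um is not None:
        steps = np.diff(np.asarray(depths_um, float))
        if not np.allclose(steps, h):
            raise ValueError("non-uniform electrode spacing")
    vals = -sigma * (V_n[:-2] - 2 * V_n[1:-1] + V_n[2:]) / h**2
    interior = np.asarray(depths_um, float)[1:-1] if depths_um is not None else None
    return CSDLoading(values=vals, depths_um=interior)


def is_volume_conducted(
    V_n: np.ndarray, h: float, threshold: float = 0.05
) -> tuple[bool, float]:
    """Flag depth-linear profiles by their dimensionless curvature ratio.

    score = ||I||_2 / (||V||_2 / h^2); exactly affine profiles score 0.
    """
    V_n = np.asarray(V_n, dtype=float)
    csd = csd_loading(V_n, h)
    norm_v = np.linalg.norm(V_n)
    if norm_v == 0:
        return True, 0.0
    score = float(np.linalg.norm(csd.values) / (norm_v / h**2))
    return score < threshold, score
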