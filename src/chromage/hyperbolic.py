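"""Information distance, Euclidean/hyperbolic MDS, and geodesic readouts.

The information distance between two samples is the variation of
information of their feature-value histograms, normalized by the joint
entropy so that ``D in [0, 1]``:

    D(X, Y) = (2 H(X,Y) - H(X) - H(Y)) / H(X,Y)

with 10 bins of width ``h = 0.1`` on min-max normalized values.  Because D
is a ratio of entropies, the logarithm base cancels.

Hyperbolic embeddings use the Lorentz (hyperboloid) model: points live on
the unit hyperboloid ``<x, x>_L = -1`` in Minkowski space and physical
distances in a space of curvature ``-kappa`` are

    d_H(x, y) = arcosh(-<x, y>_L) / sqrt(kappa).

The hyperboloid constraint is kept exactly by optimizing only the spatial
coordinates (the time-like coordinate is recomputed), which is why the
stress can be minimized with an ordinary quasi-Newton method on the chart
rather than explicit Riemannian retraction steps.  Karcher means and
geodesic projection use the closed-form log/exp maps of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

_EPS = 1e-12


# --------------------------------------------------------------------------
# information distance
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InfoDistanceConfig:
    bin_width: float = 0.1
    base: float = 2.0
    normalization: str = "joint"   # "joint": min-max over the two samples
                                   # "given": inputs already in [0, 1]

    def __post_init__(self):
        n = 1.0 / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("1/bin_width must be an integer")

    @property
    def n_bins(self) -> int:
        return int(round(1.0 / self.bin_width))


def _entropy(p: np.ndarray, base: float) -> float:
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


def _bin_indices(v: np.ndarray, n_bins: int) -> np.ndarray:
    # edges [0,0.1), ..., [0.9,1.0]: the final bin is closed
    idx = np.floor(v * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def information_distance(x: np.ndarray, y: np.ndarray,
                         config: InfoDistanceConfig = InfoDistanceConfig()) -> float:
    """Normalized variation of information between two samples' values."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("samples must have the same length")
    if config.normalization == "joint":
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
        span = hi - lo if hi > lo else 1.0
        x = (x - lo) / span
        y = (y - lo) / span
    n_bins = config.n_bins
    bx = _bin_indices(x, n_bins)
    by = _bin_indices(y, n_bins)
    n = len(x)
    px = np.bincount(bx, minlength=n_bins) / n
    py = np.bincount(by, minlength=n_bins) / n
    pxy = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins) / n
    hx = _entropy(px, config.base)
    hy = _entropy(py, config.base)
    hxy = _entropy(pxy, config.base)
    if hxy <= 0:
        return 0.0
    return float((2 * hxy - hx - hy) / hxy)


def distance_matrix(rows: np.ndarray, metric: str = "information",
                    config: InfoDistanceConfig = InfoDistanceConfig()) -> np.ndarray:
    """Symmetric pairwise distance matrix over sample rows."""
    rows = np.asarray(rows, dtype=float)
    if len(rows) < 2:
        raise ValueError("need >= 2 rows")
    if metric == "euclidean":
        from scipy.spatial.distance import pdist, squareform
        return squareform(pdist(rows))
    if metric != "information":
        raise ValueError("metric must be 'information' or 'euclidean'")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = information_distance(rows[i], rows[j], config)
    return d


# --------------------------------------------------------------------------
# Euclidean MDS + diagnostics
# --------------------------------------------------------------------------

def kruskal_stress(target: np.ndarray, achieved: np.ndarray) -> float:
    """Kruskal stress-1: sqrt(sum (d_hat - d)^2 / sum d^2) over pairs."""
    iu = np.triu_indices_from(target, k=1)
    d, dh = target[iu], achieved[iu]
    denom = (d**2).sum()
    if denom == 0:
        raise ValueError("all target distances are zero")
    return float(np.sqrt(((dh - d) ** 2).sum() / denom))


def shepherd_r2(target: np.ndarray, achieved: np.ndarray) -> float:
    """Squared Pearson correlation of target vs achieved pairwise distances."""
    iu = np.triu_indices_from(np.asarray(target), k=1)
    a, b = np.asarray(target)[iu], np.asarray(achieved)[iu]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant distances")
    return float(stats.pearsonr(a, b).statistic ** 2)


def emds(distances: np.ndarray, dim: int) -> tuple[np.ndarray, float]:
    """Classical (Torgerson) MDS into ``dim`` dimensions; returns (coords, stress-1)."""
    d = np.asarray(distances, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances")
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dim]
    lam = np.clip(vals[order], 0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    from scipy.spatial.distance import pdist, squareform
    achieved = squareform(pdist(coords))
    return coords, kruskal_stress(d, achieved)


# --------------------------------------------------------------------------
# Lorentz-model primitives (unit hyperboloid; physical scale 1/sqrt(kappa))
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperbolicSpace:
    dim: int
    kappa: float = 1.0   # positive magnitude; space curvature is -kappa

    def __post_init__(self):
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def minkowski_dot(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lorentz inner product, time-like coordinate first."""
    return -x[..., 0] * y[..., 0] + (x[..., 1:] * y[..., 1:]).sum(axis=-1)


def lift(spatial: np.ndarray) -> np.ndarray:
    """Spatial chart -> unit hyperboloid point(s)."""
    s = np.atleast_2d(np.asarray(spatial, dtype=float))
    x0 = np.sqrt(1.0 + (s**2).sum(axis=1, keepdims=True))
    pts = np.hstack([x0, s])
    return pts if np.asarray(spatial).ndim > 1 else pts[0]

def lorentz_distance(x: np.ndarray, y: np.ndarray, kappa: float = 1.0) -> np.ndarray:
    u = np.clip(-minkowski_dot(x, y), 1.0, None)
    return np.arccosh(u) / np.sqrt(kappa)


def log_map(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Tangent vector at x pointing toward y, length = unit-hyperboloid distance."""
    alpha = np.clip(-minkowski_dot(x, y), 1.0, None)
    u = y - np.expand_dims(np.asarray(alpha), -1) * x
    norm = np.sqrt(np.clip(minkowski_dot(u, u), 0.0, None))
    dist = np.arccosh(alpha)
    factor = np.where(norm > _EPS, dist / np.maximum(norm, _EPS), 0.0)
    return u * np.expand_dims(np.asarray(factor), -1)


def exp_map(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Geodesic step from x along tangent vector v (unit hyperboloid)."""
    theta = np.sqrt(np.clip(minkowski_dot(v, v), 0.0, None))
    if np.ndim(theta) == 0:
        if theta < _EPS:
            return x.copy()
        return np.cosh(theta) * x + np.sinh(theta) * v / theta
    theta = np.where(theta < _EPS, _EPS, theta)
    return np.cosh(theta)[..., None] * x + np.sinh(theta)[..., None] * v / theta[..., None]


# --------------------------------------------------------------------------
# HMDS
# --------------------------------------------------------------------------

@dataclass
class HyperbolicEmbedding:
    points: np.ndarray              # (n, dim+1) on the unit hyperboloid
    space: HyperbolicSpace
    target: np.ndarray
    stress: float
    shepherd_r2: float

    @property
    def achieved(self) -> np.ndarray:
        n = len(self.points)
        out = np.zeros((n, n))
        for i in range(n):
            out[i] = lorentz_distance(self.points[i], self.points, self.space.kappa)
        np.fill_diagonal(out, 0.0)
        return out

    def poincare(self) -> np.ndarray:
        """Poincare-ball coordinates, for visualization export only."""
        return self.points[:, 1:] / (1.0 + self.points[:, :1])


def _stress_and_grad(flat: np.ndarray, delta_unit: np.ndarray, n: int, dim: int):
    """Squared stress and gradient in the spatial chart.

    ``delta_unit`` holds target distances already scaled to unit-hyperboloid
    units (multiplied by sqrt(kappa)).
    """
    s = flat.reshape(n, dim)
    x0 = np.sqrt(1.0 + (s**2).sum(axis=1))
    u = -(-np.outer(x0, x0) + s @ s.T)         # -<xi, xj>_L
    np.fill_diagonal(u, 1.0)
    u = np.clip(u, 1.0 + 1e-12, None)
    d = np.arccosh(u)
    np.fill_diagonal(d, 0.0)
    resid = d - delta_unit
    np.fill_diagonal(resid, 0.0)
    stress = 0.5 * (resid**2).sum()            # = sum over unordered pairs

    dd_du = 1.0 / np.sqrt(u**2 - 1.0)
    np.fill_diagonal(dd_du, 0.0)
    w = resid * dd_du
    # u_ij = x0_i x0_j - s_i . s_j ;  du/ds_i = (s_i / x0_i) x0_j - s_j
    grad = (w @ x0)[:, None] * (s / x0[:, None]) - w @ s
    return stress, grad.ravel()


def hmds(distances: np.ndarray, space: HyperbolicSpace, seed: int = 0,
         n_starts: int = 5, max_iter: int = 500) -> HyperbolicEmbedding:
    """Embed a distance matrix into hyperbolic space by stress minimization.

    Deterministic given ``seed``: ``n_starts`` initializations (classical
    MDS scaled onto the chart, plus random perturbations) are optimized with
    L-BFGS on the spatial chart and the lowest-stress solution kept.
    """
    delta = np.asarray(distances, dtype=float)
    if not np.isfinite(delta).all():
        raise ValueError("non-finite distances")
    n = len(delta)
    dim = space.dim
    delta_unit = delta * np.sqrt(space.kappa)

    rng = np.random.default_rng(seed)
    inits = []
    coords0, _ = emds(delta_unit, dim)
    inits.append(coords0)
    for _ in range(n_starts - 1):
        inits.append(coords0 + rng.standard_normal(coords0.shape) * 0.1
                     if n > 2 else rng.standard_normal((n, dim)) * 0.5)

    best = None
    for init in inits:
        res = optimize.minimize(
            _stress_and_grad, init.ravel(), args=(delta_unit, n, dim),
            jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError("HMDS optimizer diverged")

    points = lift(best.x.reshape(n, dim))
    emb = HyperbolicEmbedding(points, space, delta, 0.0, 0.0)
    achieved = emb.achieved
    emb.stress = kruskal_stress(delta, achieved) if delta[np.triu_indices(n, 1)].sum() > 0 else 0.0
    try:
        emb.shepherd_r2 = shepherd_r2(delta, achieved)
    except ValueError:
        emb.shepherd_r2 = 1.0 if np.allclose(delta, achieved) else 0.0
    return emb


def select_geometry(distances: np.ndarray, dims: Sequence[int],
                    kappas: Sequence[float], seed: int = 0) -> tuple[HyperbolicSpace, list[dict]]:
    """Grid search over (dim, kappa) maximizing shepherd R^2.

    Ties break toward the smallest dimension, then smallest curvature.
    Returns the chosen space and the full diagnostic table.
    """
    if not len(dims) or not len(kappas):
        raise ValueError("grids must be non-empty")
    table = []
    for d in dims:
        for k in kappas:
            emb = hmds(distances, HyperbolicSpace(d, k), seed=seed)
            table.append({"dim": d, "kappa": k, "r2": emb.shepherd_r2,
                          "stress": emb.stress})
    best = max(table, key=lambda r: (r["r2"], -r["dim"], -r["kappa"]))
    return HyperbolicSpace(best["dim"], best["kappa"]), table


# --------------------------------------------------------------------------
# centroids and geodesic readouts
# --------------------------------------------------------------------------

def hyperbolic_centroid(points: np.ndarray, tol: float = 1e-8,
                        max_iter: int = 1000) -> np.ndarray:
    """Karcher mean on the unit hyperboloid via iterated log/exp averaging."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) == 0:
        raise ValueError("need >= 1 point")
    c = pts[0].copy() if len(pts) == 1 else lift(pts[:, 1:].mean(axis=0))
    for _ in range(max_iter):
        v = np.stack([log_map(c, p) for p in pts]).mean(axis=0)
        step = np.sqrt(max(minkowski_dot(v, v), 0.0))
        c = exp_map(c, v)
        if step < tol:
            return c
    raise RuntimeError("Karcher mean did not converge")


def hyperbolic_image(point: np.ndarray, a: np.ndarray, b: np.ndarray,
                     kappa: float = 1.0) -> tuple[float, float]:
    """Geodesic ImAge readout: project a point onto the geodesic through a, b.

    Returns ``(p, d_o)`` in physical units: ``p`` is the coordinate along
    the young->old geodesic with ``p(a) = 0`` and ``p(b) = d_H(a, b)``;
    ``d_o`` is the (convex-minimized) distance from the point to the
    geodesic.
    """
    d_ab = float(lorentz_distance(a, b, 1.0))
    if d_ab < _EPS:
        raise ValueError("degenerate geodesic: endpoints coincide")
    u = log_map(a, b) / d_ab

    def geo(t: float) -> np.ndarray:
        return exp_map(a, t * u)

    def dist(t: float) -> float:
        return float(lorentz_distance(geo(t), point, 1.0))

    span = max(d_ab, float(lorentz_distance(a, point, 1.0)) + d_ab)
    res = optimize.minimize_scalar(dist, bounds=(-2 * span, 2 * span), method="bounded",
                                   options={"xatol": 1e-10})
    scale = np.sqrt(kappa)
    return float(res.x) / scale, float(res.fun) / scale


def geodesic_variance_fraction(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of tangent-space variance along the a->b geodesic.

    All points are log-mapped to the tangent space at the geodesic midpoint;
    the fraction is Var(component along the geodesic direction) / total
    tangent variance.  Scale-invariant, so computed on the unit hyperboloid.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ValueError("need >= 2 points")
    d_ab = float(lorentz_distance(a, b, 1.0))
    mid = exp_map(a, 0.5 * log_map(a, b))
    u = log_map(mid, b)
    u = u / np.sqrt(max(minkowski_dot(u, u), _EPS))
    v = np.stack([log_map(mid, p) for p in pts])
    vbar = v.mean(axis=0)
    centered = v - vbar
    total = float(np.mean([minkowski_dot(c, c) for c in centered]))
    if total <= 0:
        return 1.0
    s = np.array([minkowski_dot(c, u) for c in centered])
    return float((s**2).mean() / total)
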