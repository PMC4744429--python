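"""Spatial weights, Moran's I, and proper-CAR precision matrices.

These primitives are shared by both modelling stages: rook adjacency defines
the neighbourhood graph of census tracts, Moran's I screens residuals and
slopes for spatial autocorrelation, and the conditional-autoregressive (CAR)
precision matrix tau^-2 (D - rho W) defines the spatial random field of the
tract-level model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "rook_adjacency",
    "lattice_rook_weights",
    "knn_weights",
    "morans_i",
    "car_rho_interval",
    "car_precision",
]


@dataclass
class SpatialWeights:
    """Symmetric binary adjacency with ids and neighbour counts.

    ``W`` is a sparse CSR 0/1 matrix with zero diagonal; ``D`` is the vector
    of neighbour counts (row sums of W); ``ids`` labels the areal units.
    """

    W: sparse.csr_matrix
    ids: np.ndarray
    style: str = "rook"

    def __post_init__(self) -> None:
        self.W = sparse.csr_matrix(self.W)
        self.ids = np.asarray(self.ids)
        if self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if (self.W != self.W.T).nnz != 0:
            raise ValueError("W must be symmetric")
        if self.W.diagonal().any():
            raise ValueError("W must have a zero diagonal")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def D(self) -> np.ndarray:
        return np.asarray(self.W.sum(axis=1)).ravel()

    def neighbour_lists(self) -> dict:
        """Neighbour-list form keyed by unit id (JSON-serialisable)."""
        out = {}
        indptr, indices = self.W.indptr, self.W.indices
        for i, uid in enumerate(self.ids):
            out[str(uid)] = [str(self.ids[j]) for j in indices[indptr[i]:indptr[i + 1]]]
        return out

    def subset(self, keep: np.ndarray) -> "SpatialWeights":
        """Weights restricted to the boolean/index mask ``keep``."""
        idx = np.arange(self.n)[keep] if np.asarray(keep).dtype == bool else np.asarray(keep)
        return SpatialWeights(self.W[np.ix_(idx, idx)], self.ids[idx], self.style)


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p: float


def rook_adjacency(geometries, ids=None) -> SpatialWeights:
    """Rook weights from polygons: neighbours share a boundary *segment*.

    Polygons touching only at a point (queen-but-not-rook contact) are not
    neighbours; the test is positive length of the boundary intersection.
    """
    from shapely.strtree import STRtree

    geoms = list(geometries)
    n = len(geoms)
    if ids is None:
        ids = np.arange(n)
    for g in geoms:
        if g is None or g.is_empty or g.area <= 0:
            raise ValueError("degenerate geometry in rook adjacency input")
    tree = STRtree(geoms)
    rows, cols = [], []
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            inter = g.boundary.intersection(geoms[j].boundary)
            if inter.length > 0:
                rows += [i, j]
                cols += [j, i]
    W = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return SpatialWeights(W, np.asarray(ids))


def lattice_rook_weights(rows: np.ndarray, cols: np.ndarray, ids=None) -> SpatialWeights:
    """Rook weights from integer lattice coordinates (|dr| + |dc| == 1)."""
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    n = rows.size
    if ids is None:
        ids = np.arange(n)
    index = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
    ri, ci = [], []
    for i, (r, c) in enumerate(zip(rows, cols)):
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            j = index.get((r + dr, c + dc))
            if j is not None:
                ri.append(i)
                ci.append(j)
    W = sparse.csr_matrix((np.ones(len(ri)), (ri, ci)), shape=(n, n))
    return SpatialWeights(W, np.asarray(ids))


def knn_weights(coords: np.ndarray, k: int = 8) -> SpatialWeights:
    """Symmetrised k-nearest-neighbour binary weights for point locations."""
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    k = min(k, n - 1)
    if k < 1:
        raise ValueError("need at least 2 points for knn weights")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    W = sparse.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    W = ((W + W.T) > 0).astype(float)  # symmetrise: union of directed links
    return SpatialWeights(W, np.arange(n), style="knn")


def morans_i(x: np.ndarray, weights: SpatialWeights, permutations: int = 0,
             rng: np.random.Generator | None = None) -> MoranResult:
    """Global Moran's I with significance under the normality null.

    I = (n/S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    Expectation under no autocorrelation is -1/(n-1). With ``permutations``
    > 0 the p-value is instead the two-sided pseudo p from random relabelling.
    """
    x = np.asarray(x, dtype=float)
    W = weights.W
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for Moran's I")
    z = x - x.mean()
    ss = float(z @ z)
    if ss == 0.0:
        raise ValueError("zero variance: Moran's I undefined for constant input")
    S0 = float(W.sum())

    def stat(v: np.ndarray) -> float:
        d = v - v.mean()
        return (n / S0) * float(d @ (W @ d)) / float(d @ d)

    I = (n / S0) * float(z @ (W @ z)) / ss
    EI = -1.0 / (n - 1)
    # normality-null moments (symmetric W: S1 = 2*sum w^2, S2 = sum (2 d_i)^2)
    Wd = W.toarray() if n <= 2000 else None
    if Wd is not None:
        S1 = 0.5 * float(((Wd + Wd.T) ** 2).sum())
        S2 = float(((Wd.sum(axis=0) + Wd.sum(axis=1)) ** 2).sum())
    else:
        S1 = 0.5 * float((W + W.T).power(2).sum())
        rsum = np.asarray(W.sum(axis=1)).ravel() + np.asarray(W.sum(axis=0)).ravel()
        S2 = float((rsum**2).sum())
    var = (n**2 * S1 - n * S2 + 3 * S0**2) / (S0**2 * (n**2 - 1)) - EI**2
    zscore = (I - EI) / np.sqrt(var)
    if permutations > 0:
        rng = np.random.default_rng() if rng is None else rng
        sims = np.empty(permutations)
        for b in range(permutations):
            sims[b] = stat(rng.permutation(x))
        extreme = np.sum(np.abs(sims - EI) >= abs(I - EI))
        p = (extreme + 1) / (permutations + 1)
    else:
        p = 2.0 * stats.norm.sf(abs(zscore))
    return MoranResult(I=I, expected=EI, variance=var, z=float(zscore), p=float(p))


def car_rho_interval(weights: SpatialWeights) -> tuple[float, float]:
    """Admissible rho interval (1/lambda_min, 1/lambda_max) for D - rho W.

    lambda are the eigenvalues of D^{-1/2} W D^{-1/2}; within the open
    interval the CAR precision is positive definite.
    """
    D = weights.D
    if (D == 0).any():
        raise ValueError("island (zero-neighbour) units have no CAR representation")
    s = 1.0 / np.sqrt(D)
    M = (weights.W.multiply(s[:, None])).multiply(s[None, :])
    lam = np.linalg.eigvalsh(M.toarray())
    return 1.0 / lam.min(), 1.0 / lam.max()


def car_precision(weights: SpatialWeights, rho: float, tau: float) -> sparse.csr_matrix:
    """Proper-CAR precision Q = tau^-2 (D - rho W) with binary W.

    The implied full conditional of unit c has mean (rho / d_c) * sum of the
    neighbours' deviations and variance tau^2 / d_c.
    """
    if not tau > 0:
        raise ValueError("tau must be > 0")
    lo, hi = car_rho_interval(weights)
    if not (lo < rho < hi):
        raise ValueError(
            f"rho={rho} outside the admissible interval ({lo:.6f}, {hi:.6f})"
        )
    D = sparse.diags(weights.D)
    return ((D - rho * weights.W) / tau**2).tocsr()
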