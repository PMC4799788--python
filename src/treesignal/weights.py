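"""Tip-by-tip distance, proximity and covariance matrices.

Every global and local statistic in this package is parametrized by one
of the matrices built here:

* patristic distances ``d_ij`` (sum of branch lengths on the tip-to-tip
  path) and node-count distances (number of internal nodes on that path);
* weight matrices ``w_ij``: inverse distance ``1/d_ij``, the Abouheif
  path-product proximity (product of node child counts along the path,
  inverted), and a normalized Gaussian kernel
  ``w_ij = exp(-(d_ij - mu)^2 / (2 sigma^2)) / (sigma sqrt(2 pi))``
  centred at distance ``mu`` with bandwidth ``sigma``;
* the Brownian-motion covariance ``V`` with ``V_ij`` the shared
  root-to-tip branch length (depth of the MRCA) and its Pagel lambda
  transform (off-diagonal entries scaled by lambda).

All matrices carry their tip labels and are returned as small frozen
wrappers around a plain ndarray.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .treedata import Tree

__all__ = [
    "DistanceMatrix",
    "WeightMatrix",
    "CovarianceMatrix",
    "patristic_distances",
    "nodecount_distances",
    "inverse_distance_weights",
    "abouheif_proximity",
    "gaussian_weights",
    "gaussian_kernel",
    "bm_covariance",
    "lambda_transform",
]


@dataclass(frozen=True)
class _LabelledMatrix:
    values: np.ndarray
    labels: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("matrix must be square with one label per row")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class DistanceMatrix(_LabelledMatrix):
    metric: str = "patristic"


@dataclass(frozen=True)
class WeightMatrix(_LabelledMatrix):
    scheme: str = "invdist"
    mu: float | None = None
    sigma: float | None = None

    @property
    def s0(self) -> float:
        """Total weight S0 = sum over all ordered pairs."""
        return float(self.values.sum())


@dataclass(frozen=True)
class CovarianceMatrix(_LabelledMatrix):
    pass


def patristic_distances(tree: Tree) -> DistanceMatrix:
    """Sum of branch lengths on the path between each pair of tips."""
    V = bm_covariance(tree).values
    depths = np.diag(V)
    D = depths[:, None] + depths[None, :] - 2.0 * V
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)  # guard float cancellation
    return DistanceMatrix(D, tuple(tree.tip_labels), metric="patristic")


def nodecount_distances(tree: Tree) -> DistanceMatrix:
    """Number of internal nodes strictly between each pair of tips.

    Both tips are excluded from the count, the MRCA is included: the two
    tips of a cherry are at distance 1.
    """
    e = tree.node_edge_depths()
    M = tree.mrca_matrix()
    ei = e[tree.tip_ids]
    D = ei[:, None] + ei[None, :] - 2 * e[M] - 1
    np.fill_diagonal(D, 0)
    return DistanceMatrix(D.astype(float), tuple(tree.tip_labels), metric="nNodes")


def inverse_distance_weights(D: DistanceMatrix) -> WeightMatrix:
    """w_ij = 1 / d_ij off-diagonal; the default Moran weighting."""
    d = D.values
    off = ~np.eye(D.n, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError(
            "zero off-diagonal distances: inverse-distance weights are undefined; "
            "use the node-count or Gaussian scheme, or merge duplicate tips"
        )
    W = np.zeros_like(d)
    W[off] = 1.0 / d[off]
    return WeightMatrix(W, D.labels, scheme="invdist")


def abouheif_proximity(tree: Tree) -> WeightMatrix:
    """Abouheif path-product proximity matrix.

    For tips i != j, ``w_ij = 1 / prod(dd_k)`` where the product runs
    over the internal nodes on the path between them (MRCA included,
    tips excluded) and ``dd_k`` is the number of children of node k.
    Branch lengths play no role.  The raw path product is returned
    without any global normalization; Moran's I divides by S0, which
    makes a global rescaling irrelevant.
    """
    children = tree.children()
    dd = np.array([len(c) for c in children], dtype=float)
    # B[i]: product of child counts over all strict ancestors of node i.
    B = np.ones(tree.n_nodes)
    for i in range(tree.n_nodes - 2, -1, -1):
        p = tree.parent[i]
        B[i] = B[p] * dd[p]
    M = tree.mrca_matrix()
    tips = tree.tip_ids
    Bi = B[tips]
    with np.errstate(divide="ignore", invalid="ignore"):
        path_prod = Bi[:, None] * Bi[None, :] / (B[M] * B[M] * dd[M])
        W = 1.0 / path_prod
    np.fill_diagonal(W, 0.0)
    return WeightMatrix(W, tuple(tree.tip_labels), scheme="abouheif")


def gaussian_kernel(d, mu: float, sigma: float):
    """Normalized Gaussian kernel of distance, centred at mu."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d = np.asarray(d, dtype=float)
    return np.exp(-((d - mu) ** 2) / (2.0 * sigma**2)) / (sigma * np.sqrt(2.0 * np.pi))


def gaussian_weights(D: DistanceMatrix, mu: float, sigma: float) -> WeightMatrix:
    """Gaussian phylogenetic weights: influence peaks at distance mu and
    decays with bandwidth sigma; diagonal forced to zero."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    W = gaussian_kernel(D.values, mu, sigma)
    np.fill_diagonal(W, 0.0)
    return WeightMatrix(W, D.labels, scheme="gaussian", mu=float(mu), sigma=float(sigma))


def bm_covariance(tree: Tree) -> CovarianceMatrix:
    """Brownian-motion covariance: V_ij = depth of MRCA(i, j)."""
    depths = tree.node_depths()
    M = tree.mrca_matrix()
    V = depths[M]
    return CovarianceMatrix(V, tuple(tree.tip_labels))


def lambda_transform(V: CovarianceMatrix, lam: float) -> CovarianceMatrix:
    """Multiply off-diagonal covariances by lambda in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    Vt = V.values * lam
    np.fill_diagonal(Vt, np.diag(V.values))
    return CovarianceMatrix(Vt, V.labels)
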