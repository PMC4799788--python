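"""Continuous phylogenetic correlograms with bootstrap envelopes.

Instead of binning tip pairs into discrete distance classes, the
autocorrelation is evaluated continuously: for every center distance mu
on a grid, Moran's I is computed with Gaussian-kernel weights
``w_ij = N(d_ij; mu, sigma)`` so each point of the curve reflects the
similarity of tip pairs whose patristic distance is near mu.  A
nonparametric bootstrap (resampling tips with replacement, recomputing
the whole curve on the induced trait/distance submatrices) yields a
pointwise percentile confidence envelope; each grid point is classified
as significantly positive, negative, or neither by comparing the
envelope with the no-signal reference value h0 = -1/(n-1).

With two or more traits the single-trait cross-product is replaced by
the standardized Mantel statistic between the tip-pair Euclidean trait
distance matrix and the Gaussian weight matrix (reference value 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treedata import TraitTree
from .weights import gaussian_kernel, patristic_distances

__all__ = ["CorrelogramResult", "phylo_correlogram", "mantel_correlogram"]


@dataclass
class CorrelogramResult:
    """An autocorrelation curve over a distance grid with envelope."""

    grid: np.ndarray  # center distances mu_k, strictly increasing
    stat: np.ndarray
    ci_lo: np.ndarray | None
    ci_hi: np.ndarray | None
    h0: float
    classes: np.ndarray  # "positive" | "none" | "negative" per point
    sigma: float
    n_boot: int
    conf: float
    seed: object
    kind: str = "moran"

    def to_frame(self) -> pd.DataFrame:
        data = {"stat": self.stat}
        if self.ci_lo is not None:
            data["ci_lo"] = self.ci_lo
            data["ci_hi"] = self.ci_hi
        data["class"] = self.classes
        return pd.DataFrame(data, index=pd.Index(self.grid, name="mu"))

    def metadata(self) -> dict:
        return {
            "h0": self.h0,
            "sigma": self.sigma,
            "n_boot": self.n_boot,
            "conf": self.conf,
            "seed": self.seed,
            "kind": self.kind,
        }


def _default_grid(dist_max: float, n_points: int) -> np.ndarray:
    # even grid over (0, dist_max]; mu = 0 is excluded (kernel would sit
    # on the empty diagonal)
    return np.linspace(dist_max / n_points, dist_max, n_points)


def _moran_curve(D: np.ndarray, y: np.ndarray, grid: np.ndarray, sigma: float) -> np.ndarray:
    n = len(y)
    z = y - y.mean()
    zz = float(z @ z)
    Wall = gaussian_kernel(D[None, :, :], grid[:, None, None], sigma)
    idx = np.arange(n)
    Wall[:, idx, idx] = 0.0
    s0 = Wall.sum(axis=(1, 2))
    num = np.einsum("kij,i,j->k", Wall, z, z, optimize=True)
    return n / s0 * num / zz


def _mantel_curve(D: np.ndarray, T: np.ndarray, grid: np.ndarray, sigma: float) -> np.ndarray:
    """Standardized Mantel correlation between the trait-distance matrix
    and the Gaussian weight matrix, per grid point."""
    n = D.shape[0]
    diffs = T[:, None, :] - T[None, :, :]
    TD = np.sqrt((diffs**2).sum(axis=2))
    off = ~np.eye(n, dtype=bool)
    td = TD[off]
    td = td - td.mean()
    td_norm = np.sqrt(float(td @ td))
    Wall = gaussian_kernel(D[None, :, :], grid[:, None, None], sigma)
    wd = Wall[:, off]
    wd = wd - wd.mean(axis=1, keepdims=True)
    w_norm = np.sqrt(np.einsum("ki,ki->k", wd, wd))
    return (wd @ td) / (w_norm * td_norm)


def _classify(lo: np.ndarray, hi: np.ndarray, h0: float) -> np.ndarray:
    classes = np.full(len(lo), "none", dtype=object)
    classes[lo > h0] = "positive"
    classes[hi < h0] = "negative"
    return classes.astype(str)


def _bootstrap_envelope(
    curve_fn, n: int, n_boot: int, conf: float, rng: np.random.Generator,
    degenerate_fn,
) -> tuple[np.ndarray, np.ndarray]:
    curves = []
    attempts = 0
    max_attempts = 10 * n_boot
    while len(curves) < n_boot:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not draw {n_boot} non-degenerate bootstrap samples "
                f"in {max_attempts} attempts"
            )
        attempts += 1
        idx = rng.integers(0, n, size=n)
        if degenerate_fn(idx):
            continue
        curves.append(curve_fn(idx))
    C = np.asarray(curves)
    alpha = (1.0 - conf) / 2.0
    lo = np.quantile(C, alpha, axis=0)
    hi = np.quantile(C, 1.0 - alpha, axis=0)
    return lo, hi


def phylo_correlogram(
    traittree: TraitTree,
    trait: str,
    n_points: int = 100,
    sigma: float | None = None,
    n_boot: int = 1000,
    conf: float = 0.95,
    dist_max: float | None = None,
    seed=None,
) -> CorrelogramResult:
    """Continuous Moran correlogram of one trait with bootstrap envelope.

    ``sigma`` defaults to five grid steps (``dist_max / n_points * 5``);
    ``dist_max`` defaults to the maximum patristic distance.  Pass
    ``n_boot=0`` for a curve without an envelope.
    """
    tree = traittree.tree
    n = tree.n_tips
    if n < 5:
        raise ValueError("correlogram needs at least 5 tips")
    y = traittree.trait(trait)
    if np.ptp(y) == 0:
        raise ValueError(f"trait {trait!r} is constant")
    D = patristic_distances(tree).values
    if dist_max is None:
        dist_max = float(D.max())
    if sigma is None:
        sigma = dist_max / n_points * 5.0
    grid = _default_grid(dist_max, n_points)
    stat = _moran_curve(D, y, grid, sigma)
    h0 = -1.0 / (n - 1)

    ci_lo = ci_hi = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)

        def degenerate(idx):
            return len(np.unique(idx)) < 3 or np.ptp(y[idx]) == 0

        def curve(idx):
            return _moran_curve(D[np.ix_(idx, idx)], y[idx], grid, sigma)

        ci_lo, ci_hi = _bootstrap_envelope(curve, n, n_boot, conf, rng, degenerate)
        if np.any((stat < ci_lo) | (stat > ci_hi)):
            warnings.warn(
                "observed curve falls outside its bootstrap envelope at some "
                "grid points (bootstrap noise); interpret classes cautiously",
                stacklevel=2,
            )
        classes = _classify(ci_lo, ci_hi, h0)
    else:
        classes = np.full(len(grid), "none", dtype=object).astype(str)

    return CorrelogramResult(
        grid=grid, stat=stat, ci_lo=ci_lo, ci_hi=ci_hi, h0=h0,
        classes=classes, sigma=float(sigma), n_boot=n_boot, conf=conf,
        seed=seed, kind="moran",
    )


def mantel_correlogram(
    traittree: TraitTree,
    traits=None,
    n_points: int = 100,
    sigma: float | None = None,
    n_boot: int = 1000,
    conf: float = 0.95,
    dist_max: float | None = None,
    seed=None,
) -> CorrelogramResult:
    """Multivariate Mantel correlogram over two or more traits.

    Traits are centered and scaled per column before the tip-pair
    Euclidean distance matrix is formed; the reference value is 0.
    """
    tree = traittree.tree
    n = tree.n_tips
    if traits is None:
        traits = traittree.trait_names
    traits = list(traits)
    if len(traits) < 2:
        raise ValueError("the Mantel correlogram needs at least 2 traits")
    T = np.column_stack([traittree.trait(t) for t in traits])
    sd = T.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [traits[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant traits cannot be scaled: {bad}")
    T = (T - T.mean(axis=0)) / sd
    D = patristic_distances(tree).values
    if dist_max is None:
        dist_max = float(D.max())
    if sigma is None:
        sigma = dist_max / n_points * 5.0
    grid = _default_grid(dist_max, n_points)
    stat = _mantel_curve(D, T, grid, sigma)
    h0 = 0.0

    ci_lo = ci_hi = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)

        def degenerate(idx):
            return len(np.unique(idx)) < 3 or np.all(np.ptp(T[idx], axis=0) == 0)

        def curve(idx):
            return _mantel_curve(D[np.ix_(idx, idx)], T[idx], grid, sigma)

        ci_lo, ci_hi = _bootstrap_envelope(curve, n, n_boot, conf, rng, degenerate)
        classes = _classify(ci_lo, ci_hi, h0)
    else:
        classes = np.full(len(grid), "none", dtype=object).astype(str)

    return CorrelogramResult(
        grid=grid, stat=stat, ci_lo=ci_lo, ci_hi=ci_hi, h0=h0,
        classes=classes, sigma=float(sigma), n_boot=n_boot, conf=conf,
        seed=seed, kind="mantel",
    )
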