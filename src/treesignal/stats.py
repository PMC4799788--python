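"""Statistic kernels for phylogenetic signal.

Autocorrelation statistics
--------------------------
Global Moran's I with an arbitrary phylogenetic weight matrix W,

    I = n / S0 * sum_ij w_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2,

with S0 the total weight; Abouheif's Cmean, which is exactly Moran's I
under the Abouheif path-product proximity matrix; and the local Moran's
I (LIPA) decomposition

    I_i = (y_i - ybar) / m2 * sum_j w_ij (y_j - ybar),   m2 = sum (y-ybar)^2 / n,

whose sum over tips equals I * S0.

Evolutionary-model indices
--------------------------
Blomberg's K and K* compare the observed ratio of tip variance to
phylogenetically corrected variance against its Brownian-motion
expectation under the tree covariance V; K uses the GLS estimate of the
ancestral mean, K* the arithmetic tip mean.  Pagel's lambda is estimated
by maximizing the Gaussian profile likelihood of the trait under
V(lambda), the covariance whose off-diagonal entries are shrunk by
lambda in [0, 1].

All kernels refuse constant traits (zero variance) rather than return
NaN.  Linear solves against V go through a Cholesky factorization; V is
never inverted explicitly.  Batch variants evaluate a statistic for many
trait vectors at once against fixed matrices; the permutation tests in
:mod:`treesignal.inference` rely on them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .treedata import Tree
from .weights import CovarianceMatrix, WeightMatrix, abouheif_proximity, lambda_transform

__all__ = [
    "morans_i",
    "morans_i_batch",
    "abouheif_cmean",
    "local_morans_i",
    "local_morans_i_batch",
    "blomberg_k",
    "blomberg_kstar",
    "blomberg_k_batch",
    "pagel_lambda_ml",
    "GlsCache",
]


def _as_weight_array(W) -> np.ndarray:
    return W.values if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)


def _check_trait(y: np.ndarray, n_min: int = 3) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < n_min:
        raise ValueError(f"need at least {n_min} tips, got {len(y)}")
    if not np.all(np.isfinite(y)):
        raise ValueError("trait vector contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("zero variance: trait is constant across tips")
    return y


def morans_i(y, W, _n_min: int = 3) -> float:
    """Global Moran's I of trait *y* under weight matrix *W*."""
    w = _as_weight_array(W)
    y = _check_trait(y, n_min=_n_min)
    n = len(y)
    if w.shape != (n, n):
        raise ValueError("weight matrix shape does not match trait length")
    s0 = w.sum()
    if s0 <= 0:
        raise ValueError("total weight S0 must be positive")
    z = y - y.mean()
    return float(n / s0 * (z @ w @ z) / (z @ z))


def morans_i_batch(Y: np.ndarray, W) -> np.ndarray:
    """Moran's I for each row of *Y* (m x n) under a fixed weight matrix."""
    w = _as_weight_array(W)
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[1]
    s0 = w.sum()
    Z = Y - Y.mean(axis=1, keepdims=True)
    num = np.einsum("ri,ij,rj->r", Z, w, Z, optimize=True)
    den = np.einsum("ri,ri->r", Z, Z)
    return n / s0 * num / den


def abouheif_cmean(tree: Tree, y) -> float:
    """Abouheif's Cmean: Moran's I under the path-product proximity."""
    return morans_i(y, abouheif_proximity(tree))


def local_morans_i(y, W) -> np.ndarray:
    """Per-tip local Moran's I (LIPA) values."""
    w = _as_weight_array(W)
    y = _check_trait(y)
    z = y - y.mean()
    m2 = float(z @ z) / len(y)
    return (z / m2) * (w @ z)


def local_morans_i_batch(Y: np.ndarray, W) -> np.ndarray:
    w = _as_weight_array(W)
    Z = np.asarray(Y, dtype=float)
    Z = Z - Z.mean(axis=1, keepdims=True)
    m2 = np.einsum("ri,ri->r", Z, Z) / Z.shape[1]
    return (Z / m2[:, None]) * (Z @ w.T)


# ---------------------------------------------------------------------------
# Blomberg's K / K*


@dataclass
class GlsCache:
    """Cholesky-based quantities of a tree covariance V reused across
    many trait vectors (observed statistic + its permutation null)."""

    cho: tuple
    vinv_one: np.ndarray
    one_vinv_one: float
    trace: float
    one_v_one: float
    n: int
    logdet: float

    @staticmethod
    def from_covariance(V) -> "GlsCache":
        v = V.values if isinstance(V, CovarianceMatrix) else np.asarray(V, dtype=float)
        n = v.shape[0]
        try:
            cho = linalg.cho_factor(v, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError(
                "tree covariance is singular (duplicate tips or zero-length "
                "branches); jitter zero-length branches or merge tips"
            ) from exc
        one = np.ones(n)
        vinv_one = linalg.cho_solve(cho, one)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        return GlsCache(
            cho=cho,
            vinv_one=vinv_one,
            one_vinv_one=float(one @ vinv_one),
            trace=float(np.trace(v)),
            one_v_one=float(one @ v @ one),
            n=n,
            logdet=logdet,
        )


def _k_ratio_batch(Y: np.ndarray, cache: GlsCache, star: bool) -> np.ndarray:
    n = cache.n
    S = linalg.cho_solve(cache.cho, Y.T)  # V^-1 y, one column per trait row
    cross = S.sum(axis=0)  # 1' V^-1 y
    quad = np.einsum("rn,nr->r", Y, S)  # y' V^-1 y
    a = cross / cache.one_vinv_one  # GLS ancestral mean
    mse = (quad - cross**2 / cache.one_vinv_one) / (n - 1)
    if star:
        center = Y.mean(axis=1)
        er = (cache.trace - cache.one_v_one / n) / (n - 1)
    else:
        center = a
        er = (cache.trace - n / cache.one_vinv_one) / (n - 1)
    Z0 = Y - center[:, None]
    mse0 = np.einsum("ri,ri->r", Z0, Z0) / (n - 1)
    return (mse0 / mse) / er


def blomberg_k_batch(Y: np.ndarray, cache: GlsCache, star: bool = False) -> np.ndarray:
    return _k_ratio_batch(np.asarray(Y, dtype=float), cache, star)


def blomberg_k(V, y) -> float:
    """Blomberg's K: observed/expected variance ratio under BM, with the
    GLS ancestral mean.  K = 1 in expectation under pure Brownian motion."""
    y = _check_trait(y)
    cache = GlsCache.from_covariance(V)
    if cache.n != len(y):
        raise ValueError("covariance size does not match trait length")
    return float(_k_ratio_batch(y[None, :], cache, star=False)[0])


def blomberg_kstar(V, y) -> float:
    """Blomberg's K*: as K but the observed mean square uses the
    arithmetic tip mean, with the matching BM expectation."""
    y = _check_trait(y)
    cache = GlsCache.from_covariance(V)
    if cache.n != len(y):
        raise ValueError("covariance size does not match trait length")
    return float(_k_ratio_batch(y[None, :], cache, star=True)[0])


# ---------------------------------------------------------------------------
# Pagel's lambda


def _profile_loglik(lam: float, V: CovarianceMatrix, y: np.ndarray) -> float:
    Vl = lambda_transform(V, lam)
    cache = GlsCache.from_covariance(Vl)
    n = cache.n
    mu = float(y @ cache.vinv_one) / cache.one_vinv_one
    r = y - mu
    rs = float(r @ linalg.cho_solve(cache.cho, r))
    sigma2 = rs / n
    if sigma2 <= 0 or not np.isfinite(sigma2):
        raise ValueError("non-finite likelihood: degenerate residual variance")
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + cache.logdet + n)


def pagel_lambda_ml(
    V, y, bounds: tuple = (0.0, 1.0), tol: float = 1e-8
) -> tuple[float, float, float]:
    """Maximum-likelihood Pagel's lambda.

    Profiles out the GLS mean and the rate sigma^2 analytically and
    maximizes the remaining 1-D Gaussian log-likelihood of lambda over
    ``bounds`` by bounded scalar search.

    Returns ``(lambda_hat, loglik_at_hat, loglik_at_zero)``.
    """
    y = _check_trait(y, n_min=4)
    if not isinstance(V, CovarianceMatrix):
        V = CovarianceMatrix(np.asarray(V, dtype=float), tuple(range(len(y))))
    lo, hi = bounds
    ll0 = _profile_loglik(lo, V, y)
    ll1 = _profile_loglik(hi, V, y)
    if abs(ll1 - ll0) < 1e-10:
        mid = _profile_loglik(0.5 * (lo + hi), V, y)
        if abs(mid - ll0) < 1e-10:
            warnings.warn(
                "flat likelihood profile (star-like covariance); returning lambda=0",
                stacklevel=2,
            )
            ll_zero = ll0 if lo == 0.0 else _profile_loglik(0.0, V, y)
            return 0.0, ll0, ll_zero

    res = optimize.minimize_scalar(
        lambda lam: -_profile_loglik(lam, V, y),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol},
    )
    candidates = [(float(res.x), -float(res.fun)), (lo, ll0), (hi, ll1)]
    lam_hat, ll_hat = max(candidates, key=lambda t: t[1])
    ll_zero = ll0 if lo == 0.0 else _profile_loglik(0.0, V, y)
    return float(lam_hat), float(ll_hat), float(ll_zero)
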