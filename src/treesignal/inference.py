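"""Hypothesis tests and user-facing signal tables.

The null hypothesis throughout is the absence of phylogenetic signal:
trait values are distributed over the tips independently of the tree.
For the autocorrelation statistics (Moran's I, Abouheif's Cmean) and the
variance-ratio statistics (Blomberg's K, K*) the null distribution is
built by uniformly permuting trait values across tips with the tree held
fixed; the permutation p-value is

    p = (1 + #{stat* >= stat_obs}) / (nrep + 1)

for the one-sided "greater" alternative (signal = excess similarity,
the default), mirrored for "less" and doubled-smaller-tail (capped at 1)
for "two-sided".  Pagel's lambda is tested by a likelihood-ratio test of
lambda-hat against lambda = 0 on a chi-square(1) reference.

Reproducibility: a single root seed spawns an independent substream per
(trait, method) pair, so adding a trait or a method never changes the
p-values of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as kernels
from .treedata import Tree, TraitTree
from .weights import (
    CovarianceMatrix,
    WeightMatrix,
    abouheif_proximity,
    bm_covariance,
    inverse_distance_weights,
    nodecount_distances,
    patristic_distances,
)

__all__ = [
    "METHODS",
    "SignalResult",
    "SignalTable",
    "LipaResult",
    "permutation_test",
    "lambda_lrt",
    "phylo_signal",
    "lipa",
    "make_method_context",
    "stat_and_test",
]

# canonical method order; substream indices derive from it
METHODS = ("Cmean", "I", "K", "Kstar", "Lambda")


@dataclass(frozen=True)
class SignalResult:
    """A single statistic value with its test."""

    method: str
    stat: float
    p_value: float | None
    nrep: int | None = None
    seed: object = None
    alternative: str | None = None
    loglik: tuple | None = None  # (at lambda-hat, at lambda=0) for Lambda

    def __post_init__(self):
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value must lie in (0, 1], got {self.p_value}")


@dataclass
class SignalTable:
    """Per (trait x method) statistic values and p-values."""

    stat: pd.DataFrame
    pvalue: pd.DataFrame
    nrep: int
    seed: object
    alternative: str
    errors: dict = field(default_factory=dict)  # (trait, method) -> message

    def to_frame(self) -> pd.DataFrame:
        s = self.stat.add_suffix(".stat")
        p = self.pvalue.add_suffix(".pvalue")
        cols = [c for pair in zip(s.columns, p.columns) for c in pair]
        return pd.concat([s, p], axis=1)[cols]

    def metadata(self) -> dict:
        return {
            "nrep": self.nrep,
            "seed": self.seed,
            "alternative": self.alternative,
            "methods": list(self.stat.columns),
            "errors": {f"{t}/{m}": msg for (t, m), msg in self.errors.items()},
        }


@dataclass
class LipaResult:
    """Per-tip local Moran's I with permutation p-values."""

    tip_labels: list
    local_i: np.ndarray
    p_value: np.ndarray
    m2: float
    scheme: str
    nrep: int
    seed: object
    alternative: str
    p_adjusted: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"local_i": self.local_i, "p_value": self.p_value}
        if self.p_adjusted is not None:
            data["p_bh"] = self.p_adjusted
        return pd.DataFrame(data, index=pd.Index(self.tip_labels, name="tip"))

    def metadata(self) -> dict:
        return {
            "m2": self.m2,
            "prox": self.scheme,
            "nrep": self.nrep,
            "seed": self.seed,
            "alternative": self.alternative,
        }


# ---------------------------------------------------------------------------
# shared precomputation


@dataclass
class MethodContext:
    """Per-tree matrices shared by the observed statistic and its null."""

    tree: Tree
    weights: dict
    gls: kernels.GlsCache | None
    V: CovarianceMatrix | None


def make_method_context(tree: Tree, methods=METHODS) -> MethodContext:
    weights = {}
    if "I" in methods:
        weights["I"] = inverse_distance_weights(patristic_distances(tree))
    if "Cmean" in methods:
        weights["Cmean"] = abouheif_proximity(tree)
    gls = V = None
    if {"K", "Kstar", "Lambda"} & set(methods):
        V = bm_covariance(tree)
        if {"K", "Kstar"} & set(methods):
            gls = kernels.GlsCache.from_covariance(V)
    return MethodContext(tree=tree, weights=weights, gls=gls, V=V)


def _null_matrix(y: np.ndarray, nrep: int, rng: np.random.Generator) -> np.ndarray:
    return rng.permuted(np.tile(y, (nrep, 1)), axis=1)


def _perm_pvalue(obs: float, null: np.ndarray, alternative: str) -> float:
    nrep = len(null)
    p_greater = (1 + int(np.sum(null >= obs))) / (nrep + 1)
    p_less = (1 + int(np.sum(null <= obs))) / (nrep + 1)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_greater, p_less))
    raise ValueError(f"unknown alternative {alternative!r}")


def stat_and_test(
    ctx: MethodContext,
    method: str,
    y: np.ndarray,
    nrep: int,
    seed,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Observed statistic and p-value for one trait under one method."""
    y = np.asarray(y, dtype=float)
    if method == "Lambda":
        lam, ll_hat, ll_zero = kernels.pagel_lambda_ml(ctx.V, y)
        lrt = max(0.0, 2.0 * (ll_hat - ll_zero))
        return lam, float(sps.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    if method in ("I", "Cmean"):
        W = ctx.weights[method]
        obs = kernels.morans_i(y, W)
        stat_fn = lambda Y: kernels.morans_i_batch(Y, W)
    elif method in ("K", "Kstar"):
        star = method == "Kstar"
        obs = float(kernels.blomberg_k_batch(y[None, :], ctx.gls, star=star)[0])
        kernels._check_trait(y)
        stat_fn = lambda Y: kernels.blomberg_k_batch(Y, ctx.gls, star=star)
    else:
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    null = stat_fn(_null_matrix(y, nrep, rng))
    return obs, _perm_pvalue(obs, null, alternative)


# ---------------------------------------------------------------------------
# public operations


def permutation_test(
    statistic: str,
    traittree: TraitTree,
    trait: str,
    nrep: int = 999,
    alternative: str = "greater",
    seed=None,
) -> SignalResult:
    """Randomization test of one statistic on one trait.

    ``statistic`` is one of I, Cmean, K, Kstar; the trait values are
    permuted across tips ``nrep`` times (tree fixed) to build the null.
    """
    if statistic not in ("I", "Cmean", "K", "Kstar"):
        raise ValueError(f"{statistic!r} is not a randomization-tested statistic")
    if nrep < 99:
        raise ValueError("nrep must be >= 99 for a usable p-value resolution")
    y = traittree.trait(trait)
    ctx = make_method_context(traittree.tree, (statistic,))
    try:
        stat, p = stat_and_test(ctx, statistic, y, nrep, seed, alternative)
    except ValueError as exc:
        raise ValueError(f"trait {trait!r}: {exc}") from exc
    return SignalResult(
        method=statistic, stat=stat, p_value=p, nrep=nrep, seed=seed,
        alternative=alternative,
    )


def lambda_lrt(V, y, seed=None) -> SignalResult:
    """Likelihood-ratio test of Pagel's lambda against lambda = 0."""
    lam, ll_hat, ll_zero = kernels.pagel_lambda_ml(V, y)
    lrt = max(0.0, 2.0 * (ll_hat - ll_zero))
    p = float(sps.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    return SignalResult(
        method="Lambda", stat=lam, p_value=p, seed=seed,
        loglik=(ll_hat, ll_zero),
    )


def phylo_signal(
    traittree: TraitTree,
    methods=METHODS,
    nrep: int = 999,
    seed=None,
    alternative: str = "greater",
) -> SignalTable:
    """Compute every requested signal index and its test for every trait.

    Moran's I uses inverse-patristic weights; Cmean the Abouheif
    proximity; K, K* and lambda the Brownian covariance of the tree.
    Failures on one (trait, method) cell are recorded and the rest of the
    table is still filled.
    """
    methods = list(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if not traittree.trait_names:
        raise ValueError("trait table has no trait columns")
    root = np.random.SeedSequence(seed)
    ctx = make_method_context(traittree.tree, methods)
    stat = pd.DataFrame(index=traittree.trait_names, columns=methods, dtype=float)
    pval = pd.DataFrame(index=traittree.trait_names, columns=methods, dtype=float)
    errors = {}
    for ti, trait in enumerate(traittree.trait_names):
        y = traittree.trait(trait)
        for m in methods:
            mi = METHODS.index(m)
            sub = np.random.SeedSequence(entropy=root.entropy, spawn_key=(ti, mi))
            try:
                s, p = stat_and_test(ctx, m, y, nrep, sub, alternative)
            except ValueError as exc:
                errors[(trait, m)] = str(exc)
                s, p = np.nan, np.nan
            stat.loc[trait, m] = s
            pval.loc[trait, m] = p
    return SignalTable(
        stat=stat, pvalue=pval, nrep=nrep, seed=seed,
        alternative=alternative, errors=errors,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return adj


def lipa(
    traittree: TraitTree,
    trait: str,
    prox="patristic",
    nrep: int = 999,
    alternative: str = "greater",
    seed=None,
    bh_adjust: bool = False,
) -> LipaResult:
    """Local Moran's I (LIPA) per tip, with per-tip permutation tests.

    ``prox`` selects the weights: "patristic" (w = 1/d, the default),
    "nNodes" (w = 1/node-count distance, emphasising clade membership
    over branch lengths), or any custom :class:`WeightMatrix`.
    """
    tree = traittree.tree
    if isinstance(prox, WeightMatrix):
        W, scheme = prox, f"custom:{prox.scheme}"
    elif prox == "patristic":
        try:
            W = inverse_distance_weights(patristic_distances(tree))
        except ValueError as exc:
            raise ValueError(f"{exc} (the nNodes proximity avoids zero distances)") from exc
        scheme = "patristic"
    elif prox == "nNodes":
        W = inverse_distance_weights(nodecount_distances(tree))
        scheme = "nNodes"
    else:
        raise ValueError(f"unknown proximity scheme {prox!r}")
    y = traittree.trait(trait)
    obs = kernels.local_morans_i(y, W)
    z = y - y.mean()
    m2 = float(z @ z) / len(y)
    rng = np.random.default_rng(seed)
    null = kernels.local_morans_i_batch(_null_matrix(y, nrep, rng), W)
    if alternative == "greater":
        count = np.sum(null >= obs[None, :], axis=0)
    elif alternative == "less":
        count = np.sum(null <= obs[None, :], axis=0)
    elif alternative == "two-sided":
        cg = np.sum(null >= obs[None, :], axis=0)
        cl = np.sum(null <= obs[None, :], axis=0)
        count = np.minimum(cg, cl)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + count) / (nrep + 1)
    if alternative == "two-sided":
        p = np.minimum(1.0, 2.0 * p)
    return LipaResult(
        tip_labels=tree.tip_labels,
        local_i=obs,
        p_value=p,
        m2=m2,
        scheme=scheme,
        nrep=nrep,
        seed=seed,
        alternative=alternative,
        p_adjusted=_bh_adjust(p) if bh_adjust else None,
    )
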