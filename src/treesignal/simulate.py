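"""Trait and tree simulation.

Brownian-motion traits evolve along branches by accumulating independent
Gaussian increments with variance ``sigma2 * branch_length``; lineages
become independent the moment they split.  Yule (pure-birth) trees with
unit birth rate serve as random fixtures.  The gradient benchmark mixes
a standardized BM trait with standardized white noise,

    y(alpha) = alpha * z_BM + (1 - alpha) * z_noise,

and records, per mixing weight alpha in [0, 1] and per statistic, the
sampled index values and the rejection rate of its test at the 5% level.
Standardizing both components before mixing means alpha moves only the
phylogenetic structure of the trait, not its scale, so rejection rates
are comparable across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .treedata import Tree

__all__ = ["simulate_bm", "simulate_yule_tree", "signal_gradient_sim", "GradientSimResult"]


def simulate_bm(tree: Tree, sigma2: float = 1.0, root_value: float = 0.0, seed=None,
                n_traits: int = 1) -> np.ndarray:
    """Simulate Brownian-motion trait values at the tips of *tree*.

    Returns a vector of length ``n_tips`` in canonical tip order, or an
    ``(n_tips, n_traits)`` matrix when ``n_traits > 1``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    rng = np.random.default_rng(seed)
    vals = np.empty((tree.n_nodes, n_traits))
    vals[tree.root] = root_value
    sd = np.sqrt(sigma2 * tree.brlen)
    # children have lower postorder indices than parents
    for i in range(tree.n_nodes - 2, -1, -1):
        vals[i] = vals[tree.parent[i]] + rng.normal(0.0, sd[i], size=n_traits)
    tips = vals[tree.tip_ids]
    return tips[:, 0] if n_traits == 1 else tips


def simulate_yule_tree(n_tips: int, seed=None, birth_rate: float = 1.0) -> Tree:
    """Simulate an ultrametric pure-birth (Yule) tree with *n_tips* tips.

    Waiting times between birth events are exponential with rate
    ``birth_rate * k`` for k extant lineages; the lineage that splits is
    chosen uniformly.  Tips are labelled ``t1 .. tn`` in canonical order.
    """
    if n_tips < 3:
        raise ValueError("need n_tips >= 3")
    rng = np.random.default_rng(seed)

    # grow node records: (children, birth_time); active = extant lineages
    children: list[list[int]] = [[]]
    birth = [0.0]
    active = [0]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        node = active.pop(idx)
        left, right = len(children), len(children) + 1
        children.append([])
        children.append([])
        birth += [t, t]
        children[node] = [left, right]
        active.insert(idx, left)
        active.append(right)
    # final waiting time so terminal branches have positive length
    t += rng.exponential(1.0 / (birth_rate * n_tips))

    parent_of = {}
    for u, ch in enumerate(children):
        for c in ch:
            parent_of[c] = u

    order: list[int] = []

    def post(u: int) -> None:
        for c in children[u]:
            post(c)
        order.append(u)

    post(0)
    remap = {old: new for new, old in enumerate(order)}
    n_nodes = len(order)
    parent = np.full(n_nodes, -1, dtype=np.intp)
    brlen = np.zeros(n_nodes)
    labels: list[str | None] = [None] * n_nodes
    tip_ids = []
    tip_no = 1
    for old in order:
        new = remap[old]
        if old in parent_of:
            p = parent_of[old]
            parent[new] = remap[p]
            end = t if not children[old] else birth[children[old][0]]
            brlen[new] = end - birth[old]
    for old in order:  # canonical (postorder) tip numbering
        if not children[old]:
            new = remap[old]
            labels[new] = f"t{tip_no}"
            tip_no += 1
            tip_ids.append(new)
    tree = Tree(parent, brlen, tuple(labels), np.asarray(sorted(tip_ids)))
    tree.validate()
    return tree


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    s = x.std(ddof=0)
    if s == 0:
        raise ValueError("cannot standardize a constant vector")
    return x / s


@dataclass
class GradientSimResult:
    """Per-alpha, per-method statistic samples and test rejection rates."""

    alpha_grid: np.ndarray
    methods: list
    samples: dict  # method -> (n_alpha, nsim) array of statistics
    pvalues: dict  # method -> (n_alpha, nsim) array of p-values
    nsim: int
    nrep: int
    seed: object
    alpha_level: float = 0.05

    @property
    def rejection_rates(self) -> pd.DataFrame:
        rows = {
            m: (self.pvalues[m] < self.alpha_level).mean(axis=1) for m in self.methods
        }
        return pd.DataFrame(rows, index=pd.Index(self.alpha_grid, name="alpha"))

    def to_frame(self) -> pd.DataFrame:
        rr = self.rejection_rates
        stat = pd.DataFrame(
            {m: self.samples[m].mean(axis=1) for m in self.methods},
            index=rr.index,
        )
        return pd.concat({"rejection_rate": rr, "mean_stat": stat}, axis=1)

    def metadata(self) -> dict:
        return {
            "nsim": self.nsim,
            "nrep": self.nrep,
            "seed": self.seed,
            "methods": list(self.methods),
            "alpha_level": self.alpha_level,
        }


def signal_gradient_sim(
    tree: Tree,
    alpha_grid=None,
    nsim: int = 99,
    methods=("I", "Cmean", "K", "Kstar", "Lambda"),
    nrep: int = 999,
    seed=None,
) -> GradientSimResult:
    """Benchmark signal statistics along a Brownian-motion-strength gradient.

    For each alpha and each of *nsim* replicates the simulated trait is
    ``alpha * z_BM + (1 - alpha) * z_noise`` (both components standardized),
    and every requested statistic is computed and tested on it.
    """
    from .inference import METHODS, make_method_context, stat_and_test

    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.0, 1.01, 0.1), 10)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if np.any((alpha_grid < 0) | (alpha_grid > 1)):
        raise ValueError("alpha grid must lie in [0, 1]")
    if nsim < 10:
        raise ValueError("need nsim >= 10 for usable rates")
    methods = list(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    root = np.random.SeedSequence(seed)
    n = tree.n_tips
    samples = {m: np.empty((len(alpha_grid), nsim)) for m in methods}
    pvalues = {m: np.empty((len(alpha_grid), nsim)) for m in methods}
    ctx = make_method_context(tree, methods)
    for ai, alpha in enumerate(alpha_grid):
        for s in range(nsim):
            ss = np.random.SeedSequence(entropy=root.entropy, spawn_key=(ai, s))
            rng = np.random.default_rng(ss)
            z_bm = _standardize(simulate_bm(tree, 1.0, 0.0, rng))
            z_noise = _standardize(rng.standard_normal(n))
            y = alpha * z_bm + (1.0 - alpha) * z_noise
            for m in methods:
                stat, p = stat_and_test(ctx, m, y, nrep, ss.spawn(1)[0])
                samples[m][ai, s] = stat
                pvalues[m][ai, s] = p
    return GradientSimResult(
        alpha_grid=alpha_grid,
        methods=methods,
        samples=samples,
        pvalues=pvalues,
        nsim=nsim,
        nrep=nrep,
        seed=seed,
    )
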