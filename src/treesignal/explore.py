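"""Signal exploration across the tree and across phylogenetic uncertainty.

``signal_by_node`` recomputes a signal statistic and its test inside the
clade below every internal node (with at least ``min_tips`` descendant
tips), which helps locate the region of the tree that carries the
signal.  ``signal_bootstrap`` recomputes statistic and test on each of a
set of bootstrap tree replicates sharing one trait table, summarizing
the spread induced by phylogenetic reconstruction uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import METHODS, make_method_context, stat_and_test
from .treedata import Tree, TraitTree, bind_tree_traits, extract_subtree

__all__ = ["NodeSignalTable", "BootstrapSignalResult", "signal_by_node", "signal_bootstrap"]


@dataclass
class NodeSignalTable:
    """Per-internal-node statistic, p-value and subtree size."""

    table: pd.DataFrame  # index: node id; columns: n_tips, stat, p_value
    method: str
    nrep: int
    seed: object
    failures: dict  # node id -> reason

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def metadata(self) -> dict:
        return {
            "method": self.method, "nrep": self.nrep, "seed": self.seed,
            "failures": {str(k): v for k, v in self.failures.items()},
        }


@dataclass
class BootstrapSignalResult:
    """Statistic/p-value distribution over bootstrap tree replicates."""

    stats: np.ndarray
    p_values: np.ndarray
    method: str
    nrep: int
    seed: object

    @property
    def n_trees(self) -> int:
        return len(self.stats)

    def summary(self) -> pd.Series:
        qs = [0.025, 0.25, 0.5, 0.75, 0.975]
        return pd.Series(
            np.quantile(self.stats, qs), index=[f"q{q * 100:g}" for q in qs]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stat": self.stats, "p_value": self.p_values},
            index=pd.Index(range(self.n_trees), name="replicate"),
        )

    def metadata(self) -> dict:
        return {"method": self.method, "nrep": self.nrep, "seed": self.seed,
                "n_trees": self.n_trees}


def signal_by_node(
    traittree: TraitTree,
    trait: str,
    method: str = "Cmean",
    min_tips: int = 5,
    nrep: int = 999,
    seed=None,
) -> NodeSignalTable:
    """Signal statistic and test per internal node with >= min_tips tips.

    The root row equals the whole-tree result under the same seed
    policy.  Per-node failures (e.g. a constant trait within a clade)
    are recorded and skipped.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if min_tips < 4:
        raise ValueError("min_tips must be >= 4")
    tree = traittree.tree
    desc = tree.descendant_tips()
    root_seq = np.random.SeedSequence(seed)
    rows = {}
    failures = {}
    for node in tree.internal_ids():
        tips = desc[node]
        if len(tips) < min_tips:
            continue
        if node == tree.root:
            sub_tt = traittree
        else:
            sub = extract_subtree(tree, node)
            sub_tt = bind_tree_traits(
                sub, traittree.traits.loc[sub.tip_labels], policy="strict"
            )
        sub_seed = np.random.SeedSequence(entropy=root_seq.entropy, spawn_key=(int(node),))
        ctx = make_method_context(sub_tt.tree, (method,))
        try:
            s, p = stat_and_test(ctx, method, sub_tt.trait(trait), nrep, sub_seed)
        except ValueError as exc:
            failures[int(node)] = str(exc)
            continue
        rows[int(node)] = {"n_tips": len(tips), "stat": s, "p_value": p}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "node"
    return NodeSignalTable(table=table, method=method, nrep=nrep, seed=seed,
                           failures=failures)


def signal_bootstrap(
    trees: list[Tree],
    traits: pd.DataFrame,
    trait: str,
    method: str = "Cmean",
    nrep: int = 999,
    seed=None,
) -> BootstrapSignalResult:
    """Signal statistic and test on each bootstrap replicate of a phylogeny.

    Every tree's tip set must match the trait table exactly; a mismatch
    raises an error naming the offending tree index.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if len(trees) < 2:
        raise ValueError("need at least 2 bootstrap trees")
    root_seq = np.random.SeedSequence(seed)
    stats = np.empty(len(trees))
    pvals = np.empty(len(trees))
    for k, tree in enumerate(trees):
        try:
            tt = bind_tree_traits(tree, traits, policy="strict")
        except ValueError as exc:
            raise ValueError(f"bootstrap tree {k}: {exc}") from exc
        ctx = make_method_context(tt.tree, (method,))
        sub_seed = np.random.SeedSequence(entropy=root_seq.entropy, spawn_key=(k,))
        stats[k], pvals[k] = stat_and_test(ctx, method, tt.trait(trait), nrep, sub_seed)
    return BootstrapSignalResult(stats=stats, p_values=pvals, method=method,
                                 nrep=nrep, seed=seed)
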