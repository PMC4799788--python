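"""Trees, trait tables, and the bound tree+traits object.

A :class:`Tree` is a rooted phylogeny with branch lengths stored in flat
postorder-indexed arrays; a :class:`TraitTree` binds it to a tip-aligned
matrix of continuous trait values, which is the input object every
statistic in this package consumes.  Newick reading/writing is delegated
to dendropy; the flat arrays exist because all downstream matrix
computations (patristic distances, Brownian covariances, proximity
products) are simple array traversals over them.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Tree",
    "TraitTree",
    "NewickParseError",
    "TreeInvariantError",
    "BindError",
    "read_newick",
    "read_newick_list",
    "write_newick",
    "read_trait_table",
    "bind_tree_traits",
    "extract_subtree",
    "write_table",
]


class NewickParseError(ValueError):
    """Raised when a Newick source cannot be parsed."""


class TreeInvariantError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


class BindError(ValueError):
    """Raised when a tree and a trait table cannot be bound."""


@dataclass(frozen=True)
class Tree:
    """Rooted phylogenetic tree with branch lengths.

    Nodes are indexed ``0 .. n_nodes-1`` in postorder; the root is the
    last node.  ``parent[i]`` is ``-1`` for the root.  ``brlen[i]`` is the
    length of the branch above node ``i`` (0.0 for the root).  Tips appear
    in *canonical order*: the order in which they are visited by the
    postorder traversal of the tree as parsed, which for a Newick string
    is simply left-to-right reading order.
    """

    parent: np.ndarray
    brlen: np.ndarray
    labels: tuple  # per-node label or None (tips always labelled)
    tip_ids: np.ndarray  # node indices of tips, canonical order

    def __post_init__(self):
        object.__setattr__(self, "parent", np.asarray(self.parent, dtype=np.intp))
        object.__setattr__(self, "brlen", np.asarray(self.brlen, dtype=float))
        object.__setattr__(self, "tip_ids", np.asarray(self.tip_ids, dtype=np.intp))

    # -- structure ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                out[p].append(i)
        return out

    def is_tip(self) -> np.ndarray:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.parent[self.parent >= 0]] = False
        return mask

    def internal_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.is_tip())

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length (sum of branch lengths), per node."""
        depth = np.zeros(self.n_nodes)
        # parents have higher postorder index, so iterate downward
        for i in range(self.n_nodes - 2, -1, -1):
            depth[i] = depth[self.parent[i]] + self.brlen[i]
        return depth

    def node_edge_depths(self) -> np.ndarray:
        """Number of edges from the root to each node."""
        depth = np.zeros(self.n_nodes, dtype=np.intp)
        for i in range(self.n_nodes - 2, -1, -1):
            depth[i] = depth[self.parent[i]] + 1
        return depth

    def descendant_tips(self) -> list[np.ndarray]:
        """Per node, the canonical tip positions (0..n_tips-1) below it."""
        sets: list[list[int]] = [[] for _ in range(self.n_nodes)]
        pos = {int(t): k for k, t in enumerate(self.tip_ids)}
        for i in range(self.n_nodes):
            if i in pos:
                sets[i].append(pos[i])
            p = self.parent[i]
            if p >= 0:
                sets[p].extend(sets[i])
        return [np.asarray(s, dtype=np.intp) for s in sets]

    def mrca_matrix(self) -> np.ndarray:
        """n_tips x n_tips matrix of MRCA node ids (diagonal: the tip)."""
        n = self.n_tips
        M = np.empty((n, n), dtype=np.intp)
        M[np.diag_indices(n)] = self.tip_ids
        children = self.children()
        desc = self.descendant_tips()
        for u in self.internal_ids():
            kids = children[u]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    sa, sb = desc[kids[a]], desc[kids[b]]
                    M[np.ix_(sa, sb)] = u
                    M[np.ix_(sb, sa)] = u
        return M

    def validate(self) -> None:
        if self.n_tips < 2:
            raise TreeInvariantError("a tree needs at least 2 tips")
        labels = self.tip_labels
        if any(not l for l in labels):
            raise TreeInvariantError("every tip must carry a non-empty label")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeInvariantError(f"duplicate tip labels: {sorted(dupes)}")
        if np.any(self.brlen[: self.root] < 0):
            raise TreeInvariantError("negative branch lengths are not allowed")
        term = self.brlen[self.tip_ids]
        if np.any(term == 0):
            warnings.warn(
                "tree has zero-length terminal branches; patristic distances "
                "between their tips may be zero (inverse-distance weights will "
                "refuse such pairs)",
                stacklevel=3,
            )

    # -- conversion --------------------------------------------------------
    def to_newick(self, precision: int = 17) -> str:
        children = self.children()

        def fmt(i: int) -> str:
            lab = self.labels[i] or ""
            if any(c in lab for c in " ():;,'[]"):
                lab = "'" + lab.replace("'", "''") + "'"
            if not children[i]:
                return f"{lab}:{self.brlen[i]:.{precision}g}"
            inner = ",".join(fmt(c) for c in children[i])
            if i == self.root:
                return f"({inner}){lab}"
            return f"({inner}){lab}:{self.brlen[i]:.{precision}g}"

        return fmt(self.root) + ";"

    @staticmethod
    def from_dendropy(dtree: dendropy.Tree, assume_unit_lengths: bool = False) -> "Tree":
        nodes = list(dtree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.intp)
        brlen = np.zeros(len(nodes))
        labels: list[str | None] = []
        tip_ids = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    if not assume_unit_lengths:
                        raise TreeInvariantError(
                            "tree has branches without lengths; pass "
                            "assume_unit_lengths=True (CLI: --assume-unit-lengths) "
                            "to substitute 1.0"
                        )
                    brlen[i] = 1.0
                else:
                    brlen[i] = float(nd.edge.length)
            if nd.is_leaf():
                tip_ids.append(i)
                labels.append(nd.taxon.label if nd.taxon is not None else None)
            else:
                labels.append(nd.label)
        tree = Tree(parent, brlen, tuple(labels), np.asarray(tip_ids))
        tree.validate()
        return tree


def _as_newick_text(source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    text = str(source)
    if "(" not in text and "\n" not in text:
        p = Path(text)
        if p.exists():
            return p.read_text()
    return text


def read_newick(source, assume_unit_lengths: bool = False) -> Tree:
    """Read a single rooted tree from a Newick file or string.

    Quoted labels and bracket comments are accepted; internal node labels
    are preserved for reporting but never used by any statistic.
    """
    text = _as_newick_text(source)
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various tokenizer errors
        if "Duplicate taxon labels" in str(exc):
            raise TreeInvariantError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return Tree.from_dendropy(dtree, assume_unit_lengths=assume_unit_lengths)


def read_newick_list(source, assume_unit_lengths: bool = False) -> list[Tree]:
    """Read a multi-tree Newick file (e.g. bootstrap replicates)."""
    text = _as_newick_text(source)
    try:
        tl = dendropy.TreeList.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    if len(tl) == 0:
        raise NewickParseError("no trees found in source")
    return [Tree.from_dendropy(t, assume_unit_lengths=assume_unit_lengths) for t in tl]


def write_newick(tree: Tree, path=None) -> str:
    """Serialize a tree to Newick; optionally write it to *path*."""
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# trait tables


def read_trait_table(
    source,
    delimiter: str = ",",
    label_column=0,
    ignore_non_numeric: bool = False,
) -> pd.DataFrame:
    """Read a delimited trait table into a DataFrame keyed by tip label.

    Every non-label column must parse as numeric unless
    ``ignore_non_numeric`` drops offenders.  Duplicate tip labels are an
    error.
    """
    df = pd.read_csv(source, sep=delimiter, header=0, dtype=str)
    if isinstance(label_column, int):
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise BindError(f"label column {label_column!r} not in header {list(df.columns)}")
        label_name = label_column
    labels = df[label_name].astype(str)
    if labels.duplicated().any():
        dupes = sorted(labels[labels.duplicated()].unique())
        raise BindError(f"duplicate tip labels in trait table: {dupes}")
    out = {}
    for col in df.columns:
        if col == label_name:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            if ignore_non_numeric:
                continue
            row = labels[bad].iloc[0]
            raise BindError(
                f"non-numeric value in trait column {col!r} at row {row!r}; "
                "pass ignore_non_numeric=True to drop the column"
            )
        out[col] = vals.to_numpy(dtype=float)
    table = pd.DataFrame(out, index=pd.Index(labels, name="tip"))
    if table.columns.duplicated().any():
        raise BindError("duplicate trait column names")
    return table


@dataclass(frozen=True)
class TraitTree:
    """A tree bound to a tip-aligned trait matrix.

    ``traits`` rows follow the tree's canonical tip order exactly; no
    missing values remain after binding.
    """

    tree: Tree
    traits: pd.DataFrame

    def __post_init__(self):
        if list(self.traits.index) != self.tree.tip_labels:
            raise BindError("trait rows are not aligned to canonical tip order")
        if self.traits.isna().any().any():
            raise BindError("trait matrix contains missing values after binding")

    @property
    def n_tips(self) -> int:
        return self.tree.n_tips

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def trait(self, name: str) -> np.ndarray:
        return self.traits[name].to_numpy(dtype=float)


def bind_tree_traits(tree: Tree, table: pd.DataFrame, policy: str = "strict") -> TraitTree:
    """Bind a tree and a trait table into a :class:`TraitTree`.

    ``policy="strict"`` requires the tip label sets to match exactly;
    ``policy="intersect"`` prunes both sides to the common labels (at
    least 3 tips must survive).
    """
    tree_set = set(tree.tip_labels)
    table_set = set(map(str, table.index))
    if policy == "strict":
        if tree_set != table_set:
            diff = sorted(tree_set.symmetric_difference(table_set))
            raise BindError(f"tip labels differ between tree and table: {diff}")
        pruned = tree
    elif policy == "intersect":
        common = tree_set & table_set
        if len(common) < 3:
            raise BindError(
                f"only {len(common)} tips shared between tree and table; need >= 3"
            )
        pruned = tree if common == tree_set else _prune_to(tree, common)
    else:
        raise ValueError(f"unknown bind policy {policy!r}")
    aligned = table.loc[pruned.tip_labels]
    if aligned.isna().any().any():
        bad = sorted(aligned.index[aligned.isna().any(axis=1)])
        raise BindError(f"missing trait values for tips {bad}")
    return TraitTree(pruned, aligned.astype(float))


def _prune_to(tree: Tree, keep: set) -> Tree:
    dtree = dendropy.Tree.get(
        data=tree.to_newick(), schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    taxa = [t for t in dtree.taxon_namespace if t.label in keep]
    dtree.retain_taxa(taxa)
    # collapse the root if pruning left a unifurcation there
    while dtree.seed_node.num_child_nodes() == 1:
        child = dtree.seed_node.child_nodes()[0]
        dtree.seed_node = child
        child.parent_node = None
        child.edge.length = None
    return Tree.from_dendropy(dtree, assume_unit_lengths=True)


def extract_subtree(tree: Tree, node: int) -> Tree:
    """Extract the clade rooted at internal node *node* as a new Tree.

    Branch lengths are preserved; the stem branch above *node* is dropped.
    """
    if node in set(map(int, tree.tip_ids)):
        raise ValueError(f"node {node} is a tip; subtree extraction needs an internal node")
    if not 0 <= node < tree.n_nodes:
        raise ValueError(f"node id {node} out of range")
    children = tree.children()

    keep = []  # old ids, postorder within the clade

    def visit(u: int) -> None:
        for c in children[u]:
            visit(c)
        keep.append(u)

    visit(node)
    remap = {old: new for new, old in enumerate(keep)}
    parent = np.full(len(keep), -1, dtype=np.intp)
    brlen = np.zeros(len(keep))
    labels = []
    tip_ids = []
    for old in keep:
        new = remap[old]
        labels.append(tree.labels[old])
        if old != node:
            parent[new] = remap[tree.parent[old]]
            brlen[new] = tree.brlen[old]
        if not children[old]:
            tip_ids.append(new)
    sub = Tree(parent, brlen, tuple(labels), np.asarray(sorted(tip_ids)))
    sub.validate()
    return sub


# ---------------------------------------------------------------------------
# result output


def write_table(result, path, format: str = "tsv") -> None:
    """Write a result object (anything exposing ``to_frame``/``metadata``)
    to TSV or JSON with full numeric precision."""
    frame = result.to_frame() if hasattr(result, "to_frame") else pd.DataFrame(result)
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "json":
        payload = {
            "data": json.loads(frame.to_json(orient="split")),
            "metadata": getattr(result, "metadata", lambda: {})(),
        }
        path.write_text(json.dumps(payload, indent=1, default=float) + "\n")
    else:
        raise ValueError(f"unknown output format {format!r}")
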