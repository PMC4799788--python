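import numpy as np
import pandas as pd
import pytest

import treesignal as ts


@pytest.fixture
def three_tip():
    return ts.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star4():
    return ts.read_newick("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def yule17():
    return ts.simulate_yule_tree(17, seed=170)


def random_tree(rng: np.random.Generator, n_tips: int, jitter: bool = True) -> ts.Tree:
    """Random binary tree; optionally non-ultrametric branch lengths."""
    tree = ts.simulate_yule_tree(n_tips, seed=rng)
    if jitter:
        brlen = tree.brlen.copy()
        brlen[: tree.root] *= rng.uniform(0.2, 2.0, size=tree.root)
        tree = ts.Tree(tree.parent, brlen, tree.labels, tree.tip_ids)
    return tree


def make_traittree(tree: ts.Tree, y: np.ndarray, name: str = "y") -> ts.TraitTree:
    table = pd.DataFrame({name: np.asarray(y, float)},
                         index=pd.Index(tree.tip_labels, name="tip"))
    return ts.bind_tree_traits(tree, table)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with the package)


def tip_ancestor_path(tree: ts.Tree, node: int) -> list[int]:
    path = [node]
    while tree.parent[path[-1]] >= 0:
        path.append(int(tree.parent[path[-1]]))
    return path


def path_nodes_between_tips(tree: ts.Tree, a: int, b: int) -> list[int]:
    """All nodes strictly between tips a and b (MRCA included)."""
    pa, pb = tip_ancestor_path(tree, a), tip_ancestor_path(tree, b)
    sa = set(pa)
    mrca = next(x for x in pb if x in sa)
    up = pa[1 : pa.index(mrca) + 1]
    down = pb[1 : pb.index(mrca)]
    return up + down


def oracle_patristic(tree: ts.Tree) -> np.ndarray:
    n = tree.n_tips
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ta, tb = int(tree.tip_ids[i]), int(tree.tip_ids[j])
            pa, pb = tip_ancestor_path(tree, ta), tip_ancestor_path(tree, tb)
            mrca = next(x for x in pb if x in set(pa))
            d = sum(tree.brlen[x] for x in pa[: pa.index(mrca)])
            d += sum(tree.brlen[x] for x in pb[: pb.index(mrca)])
            D[i, j] = D[j, i] = d
    return D


def oracle_nodecount(tree: ts.Tree) -> np.ndarray:
    n = tree.n_tips
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            k = len(path_nodes_between_tips(tree, int(tree.tip_ids[i]), int(tree.tip_ids[j])))
            D[i, j] = D[j, i] = k
    return D


def oracle_abouheif(tree: ts.Tree) -> np.ndarray:
    n = tree.n_tips
    children = tree.children()
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            prod = 1.0
            for u in path_nodes_between_tips(tree, int(tree.tip_ids[i]), int(tree.tip_ids[j])):
                prod *= len(children[u])
            W[i, j] = W[j, i] = 1.0 / prod
    return W


def oracle_mrca_depth(tree: ts.Tree) -> np.ndarray:
    n = tree.n_tips
    depth = tree.node_depths()
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                V[i, j] = depth[tree.tip_ids[i]]
            else:
                pa = tip_ancestor_path(tree, int(tree.tip_ids[i]))
                pb = tip_ancestor_path(tree, int(tree.tip_ids[j]))
                mrca = next(x for x in pb if x in set(pa))
                V[i, j] = depth[mrca]
    return V


def oracle_morans_i(y: np.ndarray, W: np.ndarray) -> float:
    """Literal double-loop transcription of the global Moran's I formula."""
    y = np.asarray(y, float)
    n = len(y)
    ybar = y.mean()
    s0 = sum(W[i, j] for i in range(n) for j in range(n))
    num = sum(W[i, j] * (y[i] - ybar) * (y[j] - ybar) for i in range(n) for j in range(n))
    den = sum((y[i] - ybar) ** 2 for i in range(n))
    return n / s0 * num / den
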