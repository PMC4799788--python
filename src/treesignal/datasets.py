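"""Packaged example data.

The shipped fixture is a *synthetic* 17-tip ultrametric Yule tree with
three traits: ``BM`` (Brownian motion on the tree), ``random`` (i.i.d.
noise) and ``clade`` (noise with one clade shifted upward).  It mirrors
the shape of a small real comparative dataset — a handful of species
with one structured and one unstructured trait — and is regenerable with
``treesignal simulate-fixture --n-tips 17 --seed 20160319``.
"""

from __future__ import annotations

from importlib import resources

from .treedata import TraitTree, bind_tree_traits, read_newick, read_trait_table

__all__ = ["load_synthetic_17tip"]


def load_synthetic_17tip() -> TraitTree:
    """Load the packaged synthetic 17-tip tree + trait table."""
    pkg = resources.files("treesignal") / "data"
    tree = read_newick((pkg / "synthetic_17tip.nwk").read_text())
    with resources.as_file(pkg / "synthetic_17tip_traits.csv") as p:
        table = read_trait_table(p)
    return bind_tree_traits(tree, table)
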