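"""Shared helpers for rooted trees and reproducible random streams.

Trees are held as :class:`dendropy.Tree` objects throughout the package.
A *chronogram* carries edge lengths in time units and is ultrametric; a
*phylogram* carries edge lengths in expected substitutions per site.  Every
non-root node defines one branch (the edge above it); branches are addressed
by a stable string id: the taxon label for a leaf edge, the internal node's
label (``n2``, ``n3``, ...) otherwise.  :func:`ensure_branch_labels` assigns
those labels deterministically in preorder.
"""

from __future__ import annotations

from typing import Iterable

import dendropy
import numpy as np

#: relative tolerance used when checking ultrametricity of chronograms
TIME_RTOL = 1e-9


# ---------------------------------------------------------------------------
# random-number contract
# ---------------------------------------------------------------------------

def rng_from(seed, *path: int) -> np.random.Generator:
    """Return a Generator for ``seed`` plus an optional derivation path.

    ``seed`` may already be a Generator (returned unchanged, path ignored) or
    an integer root seed.  With a path, the stream is seeded from
    ``SeedSequence([seed, *path])`` so that, e.g., replicate ``k`` of stage
    ``s`` of an experiment is reproducible in isolation as
    ``rng_from(root_seed, s, k)``.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, path)]))


# ---------------------------------------------------------------------------
# tree construction / labelling
# ---------------------------------------------------------------------------

def ensure_branch_labels(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign deterministic internal-node labels ``n<k>`` in preorder.

    Existing internal labels are overwritten so that ids are canonical for a
    given traversal order.  Leaf branches are addressed by their taxon label
    and are left untouched.  Returns the same tree for chaining.
    """
    k = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            k += 1
            node.label = f"n{k}"
    return tree


def branch_nodes(tree: dendropy.Tree) -> list[dendropy.Node]:
    """All non-root nodes in preorder; each owns the edge above it."""
    root = tree.seed_node
    return [nd for nd in tree.preorder_node_iter() if nd is not root]


def branch_id(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label is None:
        raise ValueError("internal node has no label; call ensure_branch_labels first")
    return node.label


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


# ---------------------------------------------------------------------------
# ages and validation
# ---------------------------------------------------------------------------

def node_ages(tree: dendropy.Tree, validate: bool = True) -> dict[dendropy.Node, float]:
    """Age (time before present) of every node of a chronogram.

    Ages are reconstructed from edge lengths assuming tips are contemporaneous
    at age 0; with ``validate`` the root-to-tip paths are checked to agree
    within :data:`TIME_RTOL`, i.e. the tree must be ultrametric.
    """
    ages: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            child_ages = [ages[c] + (c.edge.length or 0.0) for c in node.child_nodes()]
            ages[node] = max(child_ages)
            if validate:
                span = max(child_ages) - min(child_ages)
                if span > TIME_RTOL * max(max(child_ages), 1e-300):
                    raise ValueError(
                        "tree is not ultrametric: root-to-tip path lengths differ "
                        f"by {span:g} at node {node.label or '?'}"
                    )
    return ages


def crown_age(tree: dendropy.Tree) -> float:
    """Age of the root of a chronogram."""
    return node_ages(tree)[tree.seed_node]


def is_ultrametric(tree: dendropy.Tree, rtol: float = TIME_RTOL) -> bool:
    depths = []
    for leaf in tree.leaf_node_iter():
        d = 0.0
        nd = leaf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        depths.append(d)
    depths = np.asarray(depths)
    scale = max(depths.max(), 1e-300)
    return bool((depths.max() - depths.min()) <= rtol * scale)


def validate_chronogram(tree: dendropy.Tree) -> None:
    """Raise ValueError unless the tree is a valid binary chronogram."""
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    n_internal = sum(1 for nd in tree.preorder_node_iter() if not nd.is_leaf())
    if n_internal != n_tips - 1:
        raise ValueError(
            f"expected {n_tips - 1} internal nodes for {n_tips} tips, found {n_internal}"
        )
    ages = node_ages(tree, validate=True)
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            if not ages[node] > ages[child]:
                raise ValueError("parent node age does not exceed child node age")


# ---------------------------------------------------------------------------
# Newick IO
# ---------------------------------------------------------------------------

def to_newick(tree: dendropy.Tree, digits: int = 12) -> str:
    """One-line Newick string with branch lengths at ``digits`` significant digits."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=f".{digits}g",
    )
    return s.strip()


def from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def write_trees(trees: Iterable[dendropy.Tree], path, digits: int = 12) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(to_newick(t, digits=digits) + "\n")


def read_trees(path) -> list[dendropy.Tree]:
    with open(path) as fh:
        return [from_newick(line) for line in fh if line.strip()]


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]
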