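"""Phylogenetic correlation matrices from Newick trees with Grafen branch lengths.

The species-level random effect of the meta-analytic model needs a
species-by-species correlation matrix A.  Published topologies rarely come
with meaningful branch lengths, so lengths are assigned by Grafen's method:
each internal node is placed at a height proportional to (number of
descendant tips - 1), heights are scaled so the root sits at 1 and tips at 0,
and the branch length is the parent-child height difference.  The resulting
tree is ultrametric, and A[i, j] is the depth from the root to the most
recent common ancestor of tips i and j (equal to 1 - height(MRCA)), which is
the standard Brownian-motion correlation under a unit-depth tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd


class NewickParseError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate tips, ...)."""


def normalize_species(name: str) -> str:
    """Case/underscore-folded species label used for dataset-tree matching."""
    return name.strip().lower().replace(" ", "_")


@dataclass
class Phylogeny:
    """Rooted tree over species labels (thin wrapper around a dendropy tree)."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class PhyloCorrelation:
    """Species-by-species correlation matrix with unit diagonal."""

    species_order: list[str]
    matrix: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, dtype=float)
        if A.shape != (len(self.species_order), len(self.species_order)):
            raise ValueError("matrix shape does not match species list")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(A), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(A).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        self.matrix = A
        self._index = {normalize_species(s): i
                       for i, s in enumerate(self.species_order)}

    def submatrix(self, species: list[str]) -> np.ndarray:
        """Matrix restricted (with repetition) to the given species labels."""
        missing = sorted({s for s in species if normalize_species(s) not in self._index})
        if missing:
            raise KeyError(f"species missing from tree: {missing}")
        idx = [self._index[normalize_species(s)] for s in species]
        return self.matrix[np.ix_(idx, idx)]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.species_order,
                     columns=self.species_order).to_csv(path)


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a rooted :class:`Phylogeny`.

    Polytomies are allowed; existing branch lengths are retained (Grafen
    recomputation is a separate, explicit step).  Duplicate tip labels and
    malformed syntax raise :class:`NewickParseError`.
    """
    try:
        tree = dendropy.Tree.get(
            file=io.StringIO(text), schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"could not parse Newick input: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({x for x in labels if labels.count(x) > 1})
    if dupes:
        raise NewickParseError(f"duplicate tip labels: {dupes}")
    norm = [normalize_species(x) for x in labels]
    dupes = sorted({x for x in norm if norm.count(x) > 1})
    if dupes:
        raise NewickParseError(f"tip labels collide after normalization: {dupes}")
    if len(labels) == 0:
        raise NewickParseError("tree has no tips")
    tree.is_rooted = True
    return Phylogeny(tree)


def grafen_lengths(phy: Phylogeny, power: float = 1.0) -> Phylogeny:
    """Assign Grafen branch lengths (in place on a clone; returns a new tree).

    Node height = (number of descendant tips - 1) ** power, scaled so the
    root height is 1; each branch length is parent height minus child height.
    Tips end at height 0, so the tree is ultrametric with depth 1.
    """
    if power <= 0:
        raise ValueError("power must be positive")
    if phy.n_tips < 2:
        raise ValueError("no branches: tree has fewer than 2 tips")
    tree = phy.tree.clone(depth=1)
    heights: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            heights[id(node)] = 0.0
        else:
            n_desc = len([l for l in node.leaf_iter()])
            heights[id(node)] = float(n_desc - 1) ** power
    root_h = heights[id(tree.seed_node)]
    if root_h <= 0:
        raise ValueError("degenerate tree: root height is zero")
    for node in tree.preorder_node_iter():
        h = heights[id(node)] / root_h
        heights[id(node)] = h
        if node.parent_node is not None:
            node.edge.length = heights[id(node.parent_node)] - h
        else:
            node.edge.length = None
    return Phylogeny(tree)


def correlation_matrix(phy: Phylogeny) -> PhyloCorrelation:
    """Brownian correlation matrix from an ultrametric tree.

    Entry (i, j) is the root-to-MRCA depth shared by tips i and j divided by
    the total tip depth.  Non-ultrametric trees are handled by normalizing
    each pair by the geometric mean of the two tip depths (with a warning via
    ValueError only when depths are zero).
    """
    tree = phy.tree
    leaves = list(tree.leaf_node_iter())
    n = len(leaves)
    if n < 1:
        raise ValueError("empty tree")
    # depth of every node from the root
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            bl = node.edge.length if node.edge.length is not None else 0.0
            depth[id(node)] = depth[id(node.parent_node)] + bl
    tip_depths = np.array([depth[id(l)] for l in leaves])
    if np.any(tip_depths <= 0):
        raise ValueError("tip depths must be positive; assign branch lengths first")

    # postorder accumulation: for each internal node, pairs of tips whose MRCA
    # is that node get covariance = node depth
    A = np.zeros((n, n))
    tip_index = {id(l): i for i, l in enumerate(leaves)}
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [tip_index[id(node)]]
            continue
        children = node.child_nodes()
        groups = [below.pop(id(c)) for c in children]
        d = depth[id(node)]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    A[i, groups[b]] = d
                    A[np.ix_(groups[b], [i])] = d
        merged: list[int] = []
        for grp in groups:
            merged.extend(grp)
        below[id(node)] = merged
    np.fill_diagonal(A, tip_depths)
    # normalize to a correlation matrix
    scale = np.sqrt(tip_depths)
    A = A / np.outer(scale, scale)
    np.fill_diagonal(A, 1.0)
    return PhyloCorrelation([l.taxon.label for l in leaves], A)


def check_species_coverage(species: list[str], corr: PhyloCorrelation) -> None:
    """Hard error listing dataset species absent from the tree."""
    tree_set = {normalize_species(s) for s in corr.species_order}
    missing = sorted({s for s in species if normalize_species(s) not in tree_set})
    if missing:
        raise KeyError(f"species missing from tree: {missing}")
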