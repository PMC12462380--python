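"""Rooted phylogenies with branch lengths, backed by dendropy.

Branch lengths are in expected substitutions per site (matching the scaled
generator convention).  Newick round-trips are numerically exact: lengths
are written with a shortest-round-trip float format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy


class NewickError(ValueError):
    pass


@dataclass
class Phylogeny:
    """A rooted tree with uniquely named leaves and nonnegative branch lengths."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise NewickError("leaf names must be unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                warnings.warn("missing branch length; defaulting to 0", stacklevel=3)
                edge.length = 0.0
            if edge.length < 0:
                raise NewickError(f"negative branch length {edge.length}")

    def leaf_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaf_nodes())

    def total_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self.tree.preorder_edge_iter()
            if e.head_node is not self.tree.seed_node
        )

    def postorder(self):
        return self.tree.postorder_node_iter()

    def patristic_distances(self) -> tuple[list[str], "np.ndarray"]:
        """Leaf labels and the matrix of path-length distances between them."""
        import numpy as np

        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = sorted(self.tree.taxon_namespace, key=lambda t: t.label)
        labels = [t.label for t in taxa]
        n = len(labels)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        return labels, D


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths expected; missing ones become 0)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"could not parse Newick: {exc}") from None
    if not tree.leaf_nodes():
        raise NewickError("tree has no leaves")
    return Phylogeny(tree=tree)


def write_newick(phylo: Phylogeny) -> str:
    """Serialize with full-precision branch lengths; reparses exactly."""
    return phylo.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    ).strip() + "\n"
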