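"""Ultrametric dated trees.

All phylogenetic computation in this package runs on :class:`TimeTree`, a
thin wrapper around a :class:`dendropy.Tree` that enforces ultrametricity
and carries node ages in Myr before present (present = 0, root = crown
age).  Branch intervals are half-open ``(child age, parent age]``.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy
import numpy as np

__all__ = ["TimeTree", "UltrametricityError"]

#: default tolerance (Myr) for the ultrametricity check
ULTRAMETRIC_TOL = 1e-8


class UltrametricityError(ValueError):
    """Raised when a tree's extant tips are not all at age 0."""


def _assign_ages(tree: dendropy.Tree, tol: float) -> float:
    """Set ``node.age`` (Myr before present) on every node; return crown age."""
    root = tree.seed_node
    root.depth = 0.0
    max_depth = 0.0
    for node in tree.preorder_node_iter():
        if node is not root:
            el = node.edge.length if node.edge.length is not None else 0.0
            node.depth = node.parent_node.depth + el
            if node.is_leaf() and node.depth > max_depth:
                max_depth = node.depth
    for node in tree.preorder_node_iter():
        node.age = max_depth - node.depth
        if node.is_leaf():
            if abs(node.age) > tol:
                raise UltrametricityError(
                    f"tip {node.taxon.label if node.taxon else '?'} at age "
                    f"{node.age:.3g} Myr (tolerance {tol:g})"
                )
            node.age = 0.0
    return max_depth


class TimeTree:
    """A rooted ultrametric tree with ages in Myr before present.

    Parameters
    ----------
    tree:
        The underlying dendropy tree (edge lengths in Myr).  Consumed, not
        copied.
    tip_species:
        Optional mapping of tip label -> species label, recorded when
        intraspecific subtrees are grafted onto a species tree.
    tol:
        Ultrametricity tolerance in Myr.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        tip_species: Mapping[str, str] | None = None,
        tol: float = ULTRAMETRIC_TOL,
    ) -> None:
        self.tree = tree
        self.tree.is_rooted = True
        self.tip_species = dict(tip_species) if tip_species is not None else None
        self.crown_age = _assign_ages(tree, tol)
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels")

    # -- constructors -------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        source: str,
        tip_species: Mapping[str, str] | None = None,
        tol: float = 1e-6,
    ) -> "TimeTree":
        """Read a newick string or file path (branch lengths in Myr)."""
        if "(" in source:
            tree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                path=source, schema="newick", preserve_underscores=True
            )
        return cls(tree, tip_species=tip_species, tol=tol)

    def to_newick(self, path: str | None = None) -> str:
        s = self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    # -- basic queries ------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def branching_times(self) -> np.ndarray:
        """Ages of internal nodes, descending (crown age first)."""
        ages = [
            nd.age for nd in self.tree.preorder_node_iter() if not nd.is_leaf()
        ]
        return np.sort(np.asarray(ages))[::-1]

    def total_branch_length(self) -> float:
        return sum(
            nd.edge.length or 0.0
            for nd in self.tree.preorder_node_iter()
            if nd is not self.tree.seed_node
        )

    def pendant_lengths(self) -> dict[str, float]:
        """Terminal branch length per tip label."""
        return {
            lf.taxon.label: (lf.edge.length or 0.0)
            for lf in self.tree.leaf_node_iter()
        }

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> bool:
        try:
            _assign_ages(self.tree, tol)
        except UltrametricityError:
            return False
        return True

    # -- manipulation -------------------------------------------------

    def prune_to(self, labels: Iterable[str]) -> "TimeTree":
        """Subtree spanned by ``labels`` (unsampled lineages removed).

        Degree-2 nodes are suppressed with branch lengths summed, so the
        result stays dated; the new crown is the MRCA of the retained tips.
        """
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)[:5]}")
        sub = self.tree.extract_tree_with_taxa_labels(
            keep, suppress_unifurcations=True
        )
        # extract_tree may leave a root edge; crown age is recomputed anyway
        tip_species = None
        if self.tip_species is not None:
            tip_species = {t: self.tip_species[t] for t in keep}
        return TimeTree(sub, tip_species=tip_species)

    def brownian_vcv(self) -> "np.ndarray":
        """Brownian-motion covariance matrix among tips.

        ``V[i, j]`` = shared path length from the root = crown age minus
        the age of the MRCA of tips *i* and *j*; diagonal = crown age.
        Returned in ``tip_labels`` order.
        """
        labels = self.tip_labels
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        V = np.zeros((n, n))
        # postorder: record tip sets, fill cross-blocks at each MRCA
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node._tipidx = [idx[node.taxon.label]]
                V[node._tipidx[0], node._tipidx[0]] = self.crown_age
            else:
                kids = [c._tipidx for c in node.child_nodes()]
                shared = self.crown_age - node.age
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        ia = np.asarray(kids[a])
                        ib = np.asarray(kids[b])
                        V[np.ix_(ia, ib)] = shared
                        V[np.ix_(ib, ia)] = shared
                node._tipidx = [i for k in kids for i in k]
        return V

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree n_tips={self.n_tips} crown_age={self.crown_age:.4g} Myr>"


def set_edge_lengths_from_ages(tree: dendropy.Tree) -> None:
    """Derive edge lengths from ``node.age`` attributes (in place)."""
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
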