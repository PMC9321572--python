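"""Evolutionary-unit (EU) delineation on a dated marker tree.

Units are delineated by a root-to-tip traversal: at each node the mean
pairwise sequence dissimilarity among all tips descending from it is
compared with ``1 - tau``; when it falls strictly below, the whole clade
collapses into a single unit and is not descended further.  Every unit is
therefore monophyletic, and partitions refine monotonically as the
similarity threshold tau increases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import SequenceAlignment, N_BASES
from .trees import TimeTree

__all__ = [
    "SimilarityMatrix",
    "EUPartition",
    "pairwise_similarity",
    "delineate_eus",
    "partition_summary",
]


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity in [0, 1] with per-pair site counts."""

    names: list[str]
    values: np.ndarray
    compared_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")

    def index_of(self, labels) -> np.ndarray:
        pos = {n: i for i, n in enumerate(self.names)}
        out = []
        for lab in labels:
            if lab not in pos:
                raise KeyError(f"tip {lab!r} missing from similarity matrix")
            out.append(pos[lab])
        return np.asarray(out)


def pairwise_similarity(aln: SequenceAlignment) -> SimilarityMatrix:
    """p-distance-style similarity over comparable sites.

    similarity(i, j) = 1 - mismatches / compared sites, counted over
    columns where both symbols are unambiguous bases (A, C, G or T); gaps
    and Ns are excluded pairwise.  A pair with no comparable site has
    undefined similarity and is scored 0, with a warning.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least two sequences")
    codes = aln.codes
    valid = codes < N_BASES
    n = aln.n_sequences
    sim = np.ones((n, n))
    comp = np.full((n, n), aln.length, dtype=np.int64)
    undefined = 0
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        mism = ((codes[i] != codes[i + 1 :]) & both).sum(axis=1)
        nsites = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(nsites > 0, 1.0 - mism / np.maximum(nsites, 1), 0.0)
        undefined += int((nsites == 0).sum())
        sim[i, i + 1 :] = s
        sim[i + 1 :, i] = s
        comp[i, i + 1 :] = nsites
        comp[i + 1 :, i] = nsites
    np.fill_diagonal(comp, valid.sum(axis=1))
    if undefined:
        warnings.warn(
            f"{undefined} sequence pair(s) share no comparable site; "
            "similarity set to 0"
        )
    return SimilarityMatrix(list(aln.names), sim, comp)


@dataclass
class EUPartition:
    """Monophyletic partition of tips into units at threshold tau."""

    tau: float
    blocks: dict[str, list[str]]
    mrca_ages: dict[str, float] = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.blocks)

    def tip_to_unit(self) -> dict[str, str]:
        return {tip: eu for eu, tips in self.blocks.items() for tip in tips}

    def refines(self, coarser: "EUPartition") -> bool:
        """True if every block here lies inside one block of ``coarser``."""
        other = coarser.tip_to_unit()
        for tips in self.blocks.values():
            parents = {other[t] for t in tips}
            if len(parents) != 1:
                return False
        return True


def delineate_eus(
    tree: TimeTree, sim: SimilarityMatrix, tau: float
) -> EUPartition:
    """Root-to-tip delineation at similarity threshold ``tau``.

    Pre-order traversal; at each node the mean dissimilarity over all
    unordered tip pairs under it is compared with ``1 - tau`` (strict
    inequality collapses — exact ties split).  A tip reached without
    collapse becomes a singleton unit.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    idx = sim.index_of(tree.tip_labels)  # raises on missing tips
    dis = 1.0 - sim.values
    threshold = 1.0 - tau

    # bottom-up pass: tip-index array and pairwise-dissimilarity sum per node;
    # each tip pair is touched exactly once across the whole tree (O(n^2))
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            node._tips = np.asarray(
                [sim.index_of([node.taxon.label])[0]], dtype=np.intp
            )
            node._labels = [node.taxon.label]
            node._dsum = 0.0
        else:
            kids = node.child_nodes()
            cross = 0.0
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    cross += dis[np.ix_(kids[a]._tips, kids[b]._tips)].sum()
            node._tips = np.concatenate([k._tips for k in kids])
            node._labels = [lab for k in kids for lab in k._labels]
            node._dsum = cross + sum(k._dsum for k in kids)

    blocks: dict[str, list[str]] = {}
    mrca_ages: dict[str, float] = {}
    stack = [tree.tree.seed_node]
    while stack:
        node = stack.pop()
        m = len(node._labels)
        if m == 1:
            mean_dis = 0.0
        else:
            mean_dis = node._dsum / (m * (m - 1) / 2.0)
        if m == 1 or mean_dis < threshold:
            eu = f"EU{len(blocks) + 1:05d}"
            blocks[eu] = list(node._labels)
            mrca_ages[eu] = float(node.age)
        else:
            stack.extend(reversed(node.child_nodes()))
    return EUPartition(tau=tau, blocks=blocks, mrca_ages=mrca_ages)


def partition_summary(
    partition: EUPartition,
    members: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-unit summary table.

    ``members`` is the haplotype membership map (haplotype name -> source
    sequence names); omitted, every haplotype counts one sequence.  The
    representative is the most sequence-rich haplotype of the unit, ties
    broken by lexicographically smallest name.
    """
    rows = []
    for eu, tips in partition.blocks.items():
        counts = {t: (len(members[t]) if members else 1) for t in tips}
        rep = min(counts, key=lambda t: (-counts[t], t))
        rows.append(
            {
                "eu_id": eu,
                "n_haplotypes": len(tips),
                "n_sequences": sum(counts.values()),
                "representative": rep,
                "mrca_age": partition.mrca_ages.get(eu, np.nan),
            }
        )
    return pd.DataFrame(rows)
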