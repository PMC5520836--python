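"""Pairwise genotype distances between lines and a neighbor-joining tree.

The per-locus distance is an allele-sharing score over the union of loci
called in either line of a pair (reference imputed for no-call loci under
the default policy): 0 for identical allele sets, 0.5 for overlapping but
unequal sets (a het sharing one allele with a hom), 1 for disjoint sets.
The pair distance is the mean over loci.  ``strict`` mode scores any
unequal allele sets as 1.

Neighbor joining is the canonical Q-criterion agglomeration with the
standard branch-length formulas; it recovers any additive distance matrix
exactly.  Ties in the Q matrix are broken by the lowest (row, column)
index pair, negative branch lengths are clamped to zero and flagged, and
Newick output fixes branch lengths at six decimals, so results are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import SnpRecord

METRICS = ("allele_sharing", "strict")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over line labels."""

    labels: list
    matrix: np.ndarray  # (n, n) float, zero diagonal
    n_loci_used: np.ndarray  # (n, n) int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix is not symmetric")
        if (self.matrix < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(self.matrix), 0):
            raise ValueError("distance matrix diagonal is not zero")

    def to_tsv(self) -> str:
        lines = ["\t".join([""] + list(self.labels))]
        for label, row in zip(self.labels, self.matrix):
            lines.append("\t".join([label] + [f"{d:.6f}" for d in row]))
        return "\n".join(lines) + "\n"


class TreeNode:
    """Minimal tree node: leaves carry a label, edges a branch length."""

    __slots__ = ("label", "children")

    def __init__(self, label: Optional[str] = None):
        self.label = label
        self.children: list[tuple["TreeNode", float]] = []

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree (trifurcating root node) over the line labels."""

    root: TreeNode
    labels: list
    clamped_branches: int = 0  # negative NJ branch lengths clamped to zero


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _allele_sets(records: Sequence[SnpRecord], refs: dict) -> dict:
    table = {}
    for r in records:
        key = (r.chrom, r.pos)
        prev = refs.get(key)
        if prev is not None and prev != r.ref_base:
            raise ValueError(
                f"reference mismatch at {r.chrom}:{r.pos}: {prev} vs {r.ref_base}"
            )
        refs[key] = r.ref_base
        table[key] = r.alleles
    return table


def locus_distance(a: frozenset, b: frozenset, metric: str = "allele_sharing") -> float:
    if a == b:
        return 0.0
    if metric == "strict":
        return 1.0
    return 0.5 if a & b else 1.0


def pairwise_distance(
    tables: dict[str, Sequence[SnpRecord]],
    policy: str = "absent_as_reference",
    metric: str = "allele_sharing",
    min_quality: Optional[int] = None,
) -> DistanceMatrix:
    """Mean per-locus allele-sharing distance for every pair of lines.

    For each pair, the union of loci called in either line is scored, with
    the homozygous reference genotype imputed where one line has no call.
    ``min_quality`` optionally drops calls below a consensus quality
    threshold before comparison.  Raises when a pair shares zero usable
    loci.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if policy != "absent_as_reference":
        raise ValueError(f"unsupported policy {policy!r}")
    labels = list(tables)
    if len(labels) < 2:
        raise ValueError("need at least two lines")
    refs: dict = {}
    sets = {}
    for label in labels:
        recs = tables[label]
        if min_quality is not None:
            recs = [r for r in recs if r.quality >= min_quality]
        sets[label] = _allele_sets(recs, refs)

    n = len(labels)
    dm = np.zeros((n, n))
    n_loci = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = sets[labels[i]], sets[labels[j]]
            union = set(si) | set(sj)
            if not union:
                raise ValueError(
                    f"zero usable loci for pair ({labels[i]}, {labels[j]})"
                )
            total = 0.0
            for key in union:
                ref_set = frozenset({refs[key]})
                total += locus_distance(
                    si.get(key, ref_set), sj.get(key, ref_set), metric
                )
            dm[i, j] = dm[j, i] = total / len(union)
            n_loci[i, j] = n_loci[j, i] = len(union)
    return DistanceMatrix(labels=labels, matrix=dm, n_loci_used=n_loci)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Canonical neighbor joining on a distance matrix of >= 3 taxa."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(label) for label in dm.labels]
    d = dm.matrix.copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, column) pair among ties, by flat argmin scan order
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        parent.children = [(nodes[i], clamp(li)), (nodes[j], clamp(lj))]
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the final three branches in closed form
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    root = TreeNode()
    root.children = [
        (nodes[0], clamp(0.5 * (d01 + d02 - d12))),
        (nodes[1], clamp(0.5 * (d01 + d12 - d02))),
        (nodes[2], clamp(0.5 * (d02 + d12 - d01))),
    ]
    return PhyloTree(root=root, labels=list(dm.labels), clamped_branches=clamped)


def write_newick(tree: PhyloTree) -> str:
    """Serialize as Newick with branch lengths at fixed six decimals."""

    def render(node: TreeNode) -> str:
        if node.is_leaf():
            return node.label
        inner = ",".join(
            f"{render(child)}:{length:.6f}" for child, length in node.children
        )
        return f"({inner})"

    return render(tree.root) + ";\n"
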