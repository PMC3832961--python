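"""Partition a gene-family tree into primer-design groups.

The partition is a deterministic bottom-up rule: in post-order, a clade
becomes a single group iff its members satisfy the within-group
constraint (maximum pairwise patristic distance, or minimum pairwise
identity); otherwise the clade splits into its children's partitions.
Because clades are laminar, this greedy rule yields the minimum number
of constraint-satisfying clade groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from panelforge.seqio import (
    Alignment,
    PhyloTree,
    SequenceRecord,
    ValidationError,
)

__all__ = [
    "DistanceMatrix",
    "PrimerGroup",
    "extract_group_alignment",
    "identity_matrix",
    "partition_tree",
    "patristic_distances",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise matrix, either distances or percent identities.

    ``kind`` is ``"distance"`` (zero diagonal, patristic substitutions/site)
    or ``"identity"`` (100 diagonal, percent nucleotide identity).
    """

    labels: list[str]
    matrix: np.ndarray
    kind: str = "distance"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("matrix entries must be finite")
        if np.any(self.matrix < 0):
            raise ValidationError("matrix entries must be >= 0")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValidationError("matrix must be symmetric")
        diag = np.diag(self.matrix)
        expect = 0.0 if self.kind == "distance" else 100.0
        if not np.allclose(diag, expect):
            raise ValidationError(f"{self.kind} matrix diagonal must be {expect}")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self._index[a], self._index[b]])

    def submatrix(self, labels: list[str]) -> np.ndarray:
        idx = [self._index[l] for l in labels]
        return self.matrix[np.ix_(idx, idx)]


@dataclass
class PrimerGroup:
    """A clade of family members selected for joint primer design."""

    group_id: int
    member_ids: list[str]
    sub_alignment: Alignment | None = None
    flagged_small: bool = False

    def __len__(self) -> int:
        return len(self.member_ids)


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    """Pairwise path-length sums between leaves, in tree order."""
    dtree = tree.dendropy_tree
    leaves = list(dtree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    n = len(labels)
    # root-to-node distances via preorder accumulation
    depth: dict = {dtree.seed_node: 0.0}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    # LCA by ancestor sets (n is small: hundreds of leaves at most)
    ancestors: dict = {}
    for leaf in leaves:
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        ancestors[leaf] = chain
    mat = np.zeros((n, n))
    for i in range(n):
        set_i = set(map(id, ancestors[leaves[i]]))
        for j in range(i + 1, n):
            lca = next(nd for nd in ancestors[leaves[j]] if id(nd) in set_i)
            d = depth[leaves[i]] + depth[leaves[j]] - 2.0 * depth[lca]
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels=labels, matrix=mat, kind="distance")


def identity_matrix(aln: Alignment) -> DistanceMatrix:
    """Percent identity over columns where both rows are non-gap."""
    if any(r.alphabet != "dna" for r in aln.rows):
        raise ValidationError("identity_matrix requires a nucleotide alignment")
    labels = aln.ids
    arr = np.array([list(r.residues) for r in aln.rows])
    nongap = arr != "-"
    n = len(labels)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            total = int(both.sum())
            if total == 0:
                warnings.warn(
                    f"no overlapping columns for {labels[i]!r}/{labels[j]!r}; "
                    "identity set to 0",
                    stacklevel=2,
                )
                pid = 0.0
            else:
                pid = 100.0 * float((arr[i][both] == arr[j][both]).sum()) / total
            mat[i, j] = mat[j, i] = pid
    return DistanceMatrix(labels=labels, matrix=mat, kind="identity")


def _group_ok(labels: list[str], dist: DistanceMatrix, threshold: float) -> bool:
    sub = dist.submatrix(labels)
    if dist.kind == "distance":
        return bool(sub.max() <= threshold)
    off = sub[~np.eye(len(labels), dtype=bool)]
    return bool(off.size == 0 or off.min() >= threshold)


def partition_tree(
    tree: PhyloTree,
    dist: DistanceMatrix,
    max_within: float,
    min_group_size: int = 1,
) -> list[PrimerGroup]:
    """Partition tree leaves into the fewest constraint-satisfying clades.

    ``max_within`` is a maximum pairwise distance for ``kind="distance"``
    matrices and a minimum pairwise percent identity for
    ``kind="identity"`` matrices. Groups smaller than ``min_group_size``
    are merged into their sibling clade when the merged clade still
    satisfies the constraint; otherwise they are kept and flagged.
    """
    if max_within <= 0:
        raise ValidationError("threshold must be > 0")
    leaf_set = set(tree.leaf_labels)
    if leaf_set != set(dist.labels):
        raise ValidationError("distance-matrix labels do not match tree leaves")

    dtree = tree.dendropy_tree.clone(depth=1)
    if len(dtree.seed_node.child_nodes()) > 2:
        # unrooted input: midpoint-root so clades are well defined
        dtree.reroot_at_midpoint(update_bipartitions=False)
    work = PhyloTree(dtree)

    def recurse(node) -> list[list[str]]:
        if node.is_leaf():
            return [[node.taxon.label]]
        leaves = sorted(l.taxon.label for l in node.leaf_iter())
        if _group_ok(leaves, dist, max_within):
            return [leaves]
        parts: list[list[str]] = []
        children = sorted(
            node.child_nodes(),
            key=lambda c: min(l.taxon.label for l in c.leaf_iter()),
        )
        for child in children:
            parts.extend(recurse(child))
        return parts

    parts = recurse(dtree.seed_node)

    # merge undersized groups into a sibling clade when permitted
    if min_group_size > 1:
        parts = _merge_small(parts, dtree, dist, max_within, min_group_size)

    # deterministic group numbering: by tree order of the first member
    order = {lab: i for i, lab in enumerate(work.leaf_labels)}
    parts.sort(key=lambda p: min(order[x] for x in p))
    groups = []
    for gid, members in enumerate(parts, start=1):
        members_sorted = sorted(members, key=lambda x: order[x])
        groups.append(
            PrimerGroup(
                group_id=gid,
                member_ids=members_sorted,
                flagged_small=len(members) < min_group_size,
            )
        )
    _assert_partition(groups, leaf_set)
    return groups


def _merge_small(parts, dtree, dist, threshold, min_group_size):
    clade_of: dict[frozenset, object] = {}
    for node in dtree.preorder_node_iter():
        clade_of[frozenset(l.taxon.label for l in node.leaf_iter())] = node
    changed = True
    while changed:
        changed = False
        for i, p in enumerate(parts):
            if len(p) >= min_group_size:
                continue
            node = clade_of[frozenset(p)]
            parent = node.parent_node
            if parent is None:
                continue
            sibling_leaves = frozenset(
                l.taxon.label for l in parent.leaf_iter()
            ) - frozenset(p)
            for j, q in enumerate(parts):
                if j != i and frozenset(q) == sibling_leaves:
                    merged = sorted(p + q)
                    if _group_ok(merged, dist, threshold):
                        parts = [
                            x for k, x in enumerate(parts) if k not in (i, j)
                        ] + [merged]
                        changed = True
                    break
            if changed:
                break
    return parts


def _assert_partition(groups: list[PrimerGroup], leaf_set: set[str]) -> None:
    seen: set[str] = set()
    for g in groups:
        overlap = seen & set(g.member_ids)
        if overlap:
            raise AssertionError(f"groups overlap on {sorted(overlap)}")
        seen |= set(g.member_ids)
    if seen != leaf_set:
        raise AssertionError("groups do not cover the leaf set")


def extract_group_alignment(aln: Alignment, group: PrimerGroup) -> Alignment:
    """Rows restricted to group members, all-gap columns dropped.

    Row order follows ``group.member_ids`` (tree order).
    """
    missing = [m for m in group.member_ids if m not in set(aln.ids)]
    if missing:
        raise ValidationError(f"members missing from alignment: {missing}")
    rows = [aln.row(m) for m in group.member_ids]
    arr = np.array([list(r.residues) for r in rows])
    keep = ~(arr == "-").all(axis=0)
    sub_rows = [
        SequenceRecord(
            id=r.id,
            residues="".join(arr[i][keep]),
            alphabet=r.alphabet,
            description=r.description,
            allow_gap=True,
        )
        for i, r in enumerate(rows)
    ]
    return Alignment(rows=sub_rows)
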