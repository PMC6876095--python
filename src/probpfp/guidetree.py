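"""UPGMA guide tree and ClustalW-style sequence weights.

UPGMA repeatedly merges the closest pair of clusters; the distance from a
merged cluster k = i U j to any other cluster l is the size-weighted
average (|N_i| d_il + |N_j| d_jl) / (|N_i| + |N_j|), which equals the mean
distance over all cross pairs of leaves.  Merge height is half the merge
distance, so the tree is ultrametric.

A leaf's ClustalW-style weight is the sum, over the branches on its
root-to-leaf path, of branch length divided by the number of leaves
sharing that branch; weights are normalised to mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TreeNode:
    """Node of the rooted, binary, ultrametric guide tree."""

    height: float
    size: int
    children: tuple["TreeNode", ...] = ()
    index: int | None = None      # leaf: index of the sequence
    label: str | None = None

    def __post_init__(self) -> None:
        if self.children and len(self.children) != 2:
            raise ValueError("internal nodes must have exactly 2 children")
        if not self.children and self.size != 1:
            raise ValueError("leaves have size 1")

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lv for c in self.children for lv in c.leaves()]


@dataclass
class _Merge:
    """One agglomeration step, recorded for oracle checks."""

    members_a: frozenset
    members_b: frozenset
    distance: float


def upgma(D: np.ndarray, labels: list[str] | None = None,
          return_history: bool = False):
    """Build the UPGMA tree for a symmetric distance matrix.

    Ties on the minimum distance are broken toward the lowest
    (row, column) cluster-index pair, in cluster-creation order, so the
    output is deterministic.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if not np.allclose(D, D.T, atol=1e-12) or np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, size=1, index=i,
                    label=labels[i] if labels else f"seq{i + 1}")
        for i in range(n)
    }
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = list(range(n))
    next_id = n
    history: list[_Merge] = []

    while len(active) > 1:
        best = None
        best_d = np.inf
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = dist[(i, j)]
                if d < best_d:
                    best_d = d
                    best = (i, j)
        i, j = best
        merged = TreeNode(
            height=best_d / 2.0,
            size=nodes[i].size + nodes[j].size,
            children=(nodes[i], nodes[j]),
        )
        history.append(_Merge(members[i], members[j], best_d))
        k = next_id
        next_id += 1
        for l in active:
            if l in (i, j):
                continue
            dil = dist[tuple(sorted((i, l)))]
            djl = dist[tuple(sorted((j, l)))]
            dist[(min(k, l), max(k, l))] = (
                nodes[i].size * dil + nodes[j].size * djl
            ) / (nodes[i].size + nodes[j].size)
        nodes[k] = merged
        members[k] = members[i] | members[j]
        active = [l for l in active if l not in (i, j)] + [k]

    root = nodes[active[0]]
    if return_history:
        return root, history
    return root


def clustalw_weights(root: TreeNode) -> np.ndarray:
    """Per-sequence weights from the guide tree, normalised to mean 1.

    A tree with zero total branch length (all sequences identical) yields
    uniform weights.
    """
    n = root.size
    raw = np.zeros(n)

    def walk(node: TreeNode, acc: float) -> None:
        if node.is_leaf:
            raw[node.index] = acc
            return
        for child in node.children:
            branch = node.height - child.height
            walk(child, acc + branch / child.size)

    walk(root, 0.0)
    if raw.sum() <= 1e-12:
        return np.ones(n)
    return raw * n / raw.sum()


def to_newick(root: TreeNode) -> str:
    """Newick serialisation with branch lengths (heights differences)."""

    def emit(node: TreeNode, parent_height: float) -> str:
        branch = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{branch:.10g}"
        inner = ",".join(emit(c, node.height) for c in node.children)
        return f"({inner}):{branch:.10g}"

    if root.is_leaf:
        return f"{root.label}:0;"
    inner = ",".join(emit(c, root.height) for c in root.children)
    return f"({inner});"


def write_newick(root: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(root) + "\n")
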