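"""Consistency transformation, profile-profile alignment, and refinement.

Before progressive alignment, each pairwise posterior matrix is
re-estimated through every third sequence (the probabilistic consistency
transformation): P'_xy = sum_z w_z (P_xz P_zy) / sum_z w_z, with P_xx the
identity.  Profiles are then merged along the guide tree by a dynamic
program whose match term is the weighted mean transformed posterior over
all row pairs of the two profiles (gapped rows contribute zero to the
numerator but their weight still counts in the denominator, unless
`gap_renorm` is set).  Finally the alignment is polished by random
bipartition: split the rows in two, re-align the two sub-profiles, and
keep the result only if its sum-of-pairs score does not decrease.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .guidetree import TreeNode
from .pairwise import DEFAULT_CUTOFF, mea_align
from .scoring import GapPenalties, sop_score
from .seqio import GAP, MultipleAlignment, ProteinSequence

log = logging.getLogger(__name__)


@dataclass
class Profile:
    """A set of aligned rows, stored as residue-index maps.

    `pos[r, c]` is the index of the residue of row r shown in column c, or
    -1 where the row is gapped.  `indices` are family indices of the rows.
    """

    indices: list[int]
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.pos.ndim != 2 or self.pos.shape[0] != len(self.indices):
            raise ValueError("pos must be (n_rows, n_cols)")
        if self.pos.shape[1] and np.any((self.pos < 0).all(axis=0)):
            raise ValueError("profile contains an all-gap column")

    @classmethod
    def from_sequence(cls, index: int, length: int) -> "Profile":
        return cls([index], np.arange(length, dtype=np.int64)[None, :])

    @property
    def ncols(self) -> int:
        return self.pos.shape[1]


class ConsistencyLibrary:
    """All-pairs posterior matrices with orientation-aware access."""

    def __init__(self, matrices: dict[tuple[int, int], np.ndarray]):
        for (i, j), m in matrices.items():
            if i >= j:
                raise ValueError("library keys must satisfy i < j")
            if np.asarray(m).ndim != 2:
                raise ValueError("library entries must be 2-D matrices")
        self.matrices = {k: np.asarray(v, float) for k, v in matrices.items()}

    def get(self, i: int, j: int) -> np.ndarray:
        """Posterior matrix of sequence i against sequence j (rows are i)."""
        if i < j:
            return self.matrices[(i, j)]
        return self.matrices[(j, i)].T

    def pairs(self):
        return self.matrices.keys()


def consistency_transform(posteriors: dict[tuple[int, int], np.ndarray],
                          weights: np.ndarray,
                          passes: int = 1,
                          cutoff: float = DEFAULT_CUTOFF,
                          ) -> ConsistencyLibrary:
    """Weighted three-sequence re-estimation of all pairwise posteriors.

    With only two sequences the transform is the identity.  Entries below
    `cutoff` are zeroed after each pass.
    """
    lib = ConsistencyLibrary(posteriors)
    n = int(np.asarray(weights).shape[0])
    expect = set(itertools.combinations(range(n), 2))
    if set(lib.pairs()) != expect:
        missing = sorted(expect - set(lib.pairs()))
        raise ValueError(f"missing posterior matrices for pairs {missing}")
    w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    for _ in range(passes):
        new = {}
        for (i, j), P in lib.matrices.items():
            acc = (w[i] + w[j]) * P          # z = i and z = j terms (P_zz = I)
            for z in range(n):
                if z == i or z == j:
                    continue
                acc = acc + w[z] * (lib.get(i, z) @ lib.get(z, j))
            acc /= wsum
            acc[acc < cutoff] = 0.0
            new[(i, j)] = np.clip(acc, 0.0, 1.0)
        lib = ConsistencyLibrary(new)
    return lib


def _padded(P: np.ndarray) -> np.ndarray:
    """Pad with a zero row/column so residue index -1 reads as 0."""
    out = np.zeros((P.shape[0] + 1, P.shape[1] + 1))
    out[:-1, :-1] = P
    return out


def _score_matrix(X: Profile, Y: Profile, lib: ConsistencyLibrary,
                  weights: np.ndarray, gap_renorm: bool) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    num = np.zeros((X.ncols, Y.ncols))
    for a, ia in enumerate(X.indices):
        for b, ib in enumerate(Y.indices):
            Ppad = _padded(lib.get(ia, ib))
            num += w[ia] * w[ib] * Ppad[X.pos[a]][:, Y.pos[b]]
    if gap_renorm:
        wa = (w[X.indices][:, None] * (X.pos >= 0)).sum(axis=0)
        wb = (w[Y.indices][:, None] * (Y.pos >= 0)).sum(axis=0)
        den = np.outer(wa, wb)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / den, 0.0)
        return out
    den = w[X.indices].sum() * w[Y.indices].sum()
    return num / den


def profile_column_score(X: Profile, Y: Profile, i: int, j: int,
                         lib: ConsistencyLibrary, weights: np.ndarray,
                         gap_renorm: bool = False) -> float:
    """Weighted mean transformed posterior for columns i of X and j of Y."""
    if not (0 <= i < X.ncols and 0 <= j < Y.ncols):
        raise IndexError("column index out of range")
    w = np.asarray(weights, dtype=float)
    num = 0.0
    den = 0.0
    for a, ia in enumerate(X.indices):
        for b, ib in enumerate(Y.indices):
            ww = w[ia] * w[ib]
            pi, pj = X.pos[a, i], Y.pos[b, j]
            if pi >= 0 and pj >= 0:
                num += ww * lib.get(ia, ib)[pi, pj]
                den += ww
            elif not gap_renorm:
                den += ww
    return num / den if den > 0 else 0.0


def profile_align(X: Profile, Y: Profile, lib: ConsistencyLibrary,
                  weights: np.ndarray, gap_renorm: bool = False) -> Profile:
    """Merge two disjoint profiles by the MEA-style column DP.

    Gap moves score zero; traceback ties prefer the diagonal, then
    advancing X, then advancing Y.
    """
    if set(X.indices) & set(Y.indices):
        raise ValueError("profiles must have disjoint row sets")
    S = _score_matrix(X, Y, lib, weights, gap_renorm)
    moves = mea_align(S).moves
    cols = []
    for s, i, j in moves:
        if s == "M":
            cols.append(np.concatenate([X.pos[:, i], Y.pos[:, j]]))
        elif s == "X":
            cols.append(np.concatenate(
                [X.pos[:, i], np.full(len(Y.indices), -1, dtype=np.int64)]))
        else:
            cols.append(np.concatenate(
                [np.full(len(X.indices), -1, dtype=np.int64), Y.pos[:, j]]))
    pos = np.stack(cols, axis=1) if cols else np.empty(
        (len(X.indices) + len(Y.indices), 0), dtype=np.int64)
    return Profile(X.indices + Y.indices, pos)


def profile_to_alignment(profile: Profile,
                         family: list[ProteinSequence]) -> MultipleAlignment:
    """Materialise a profile as gapped rows, restored to input order."""
    order = np.argsort(profile.indices)
    rows = []
    for r in order:
        idx = profile.indices[r]
        res = family[idx].residues
        rows.append((family[idx].id,
                     "".join(res[p] if p >= 0 else GAP
                             for p in profile.pos[r])))
    return MultipleAlignment(rows)


def alignment_to_profile(aln: MultipleAlignment,
                         family: list[ProteinSequence]) -> Profile:
    by_id = {s.id: k for k, s in enumerate(family)}
    indices = [by_id[sid] for sid, _ in aln.rows]
    pos = np.full((len(aln), aln.length), -1, dtype=np.int64)
    for r, (_, gapped) in enumerate(aln.rows):
        k = 0
        for c, ch in enumerate(gapped):
            if ch != GAP:
                pos[r, c] = k
                k += 1
    return Profile(indices, pos)


def progressive_align(tree: TreeNode, lib: ConsistencyLibrary,
                      weights: np.ndarray,
                      family: list[ProteinSequence],
                      gap_renorm: bool = False) -> MultipleAlignment:
    """Post-order merge of single-sequence profiles along the guide tree."""

    def build(node: TreeNode) -> Profile:
        if node.is_leaf:
            return Profile.from_sequence(node.index, len(family[node.index]))
        left = build(node.children[0])
        right = build(node.children[1])
        return profile_align(left, right, lib, weights, gap_renorm)

    return profile_to_alignment(build(tree), family)


def _strip_gap_columns(pos: np.ndarray) -> np.ndarray:
    keep = (pos >= 0).any(axis=0)
    return pos[:, keep]


def iterative_refine(aln: MultipleAlignment,
                     lib: ConsistencyLibrary,
                     weights: np.ndarray,
                     family: list[ProteinSequence],
                     iters: int = 10,
                     rng: np.random.Generator | None = None,
                     matrix=None,
                     gaps: GapPenalties | None = None,
                     accept_all: bool = False,
                     gap_renorm: bool = False) -> MultipleAlignment:
    """Random-bipartition refinement.

    Each iteration splits the rows into two non-empty groups by fair
    coin flips (re-drawn until both groups are non-empty), strips all-gap
    columns from each sub-profile, re-aligns the two profiles, and keeps
    the result only if its sum-of-pairs score is at least the current one
    (always, with `accept_all`).
    """
    if len(aln) < 2:
        return aln
    rng = rng or np.random.default_rng()
    current = alignment_to_profile(aln, family)
    current_aln = aln
    current_sop = sop_score(aln, matrix, gaps)
    for _ in range(iters):
        while True:
            mask = rng.integers(0, 2, size=len(current.indices)).astype(bool)
            if mask.any() and not mask.all():
                break
        group_a = Profile(
            [current.indices[r] for r in np.flatnonzero(mask)],
            _strip_gap_columns(current.pos[mask]),
        )
        group_b = Profile(
            [current.indices[r] for r in np.flatnonzero(~mask)],
            _strip_gap_columns(current.pos[~mask]),
        )
        candidate = profile_align(group_a, group_b, lib, weights, gap_renorm)
        cand_aln = profile_to_alignment(candidate, family)
        cand_sop = sop_score(cand_aln, matrix, gaps)
        if accept_all or cand_sop >= current_sop:
            current, current_aln, current_sop = candidate, cand_aln, cand_sop
    return current_aln
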