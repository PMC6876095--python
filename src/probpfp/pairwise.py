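"""Posterior fusion, maximal-expected-accuracy alignment, and distances.

The two posterior estimates for a sequence pair — pair-HMM (P^a) and
partition function (P^b) — are fused entrywise by their root mean square,
sqrt((a^2 + b^2) / 2).  A fused matrix is turned into a pairwise alignment
by the MEA dynamic program

    A(i, j) = max(A(i-1, j-1) + P(i, j), A(i-1, j), A(i, j-1)),

whose terminal value GS = A(|x|, |y|) is the expected number of correctly
matched residues; the pair distance is 1 - GS / min(|x|, |y|).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import mea_kernel
from .seqio import GAP, MultipleAlignment, ProteinSequence

log = logging.getLogger(__name__)

#: Entries below this value are treated as exact zeros after fusion.
DEFAULT_CUTOFF = 0.01


@dataclass(frozen=True)
class PosteriorMatrix:
    """Match posteriors for one sequence pair; zeros are stored implicitly
    in the sense that entries below a cutoff are zeroed in place."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("posterior matrix must be 2-D")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("posterior entries must lie in [0, 1]")
        rowsums = v.sum(axis=1)
        if np.any(rowsums > 1 + 1e-6):
            log.warning("posterior row sum exceeds 1: max %g", rowsums.max())
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_cutoff(self, cutoff: float = DEFAULT_CUTOFF) -> "PosteriorMatrix":
        v = self.values.copy()
        v[v < cutoff] = 0.0
        return PosteriorMatrix(v)


def fuse_posteriors(a: np.ndarray | PosteriorMatrix,
                    b: np.ndarray | PosteriorMatrix) -> np.ndarray:
    """Root-mean-square fusion sqrt((a^2 + b^2) / 2), clamped to [0, 1]."""
    va = a.values if isinstance(a, PosteriorMatrix) else np.asarray(a, float)
    vb = b.values if isinstance(b, PosteriorMatrix) else np.asarray(b, float)
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch: {va.shape} vs {vb.shape}")
    fused = np.sqrt((va ** 2 + vb ** 2) / 2.0)
    return np.clip(fused, 0.0, 1.0)


@dataclass(frozen=True)
class MeaAlignment:
    """Result of the MEA dynamic program for one pair.

    `moves` is the traceback path: ('M', i, j) aligns x_{i+1} with y_{j+1},
    ('X', i, -1) puts x_{i+1} against a gap, ('Y', -1, j) puts y_{j+1}
    against a gap (all indices 0-based).  `gs` is A(|x|, |y|).
    """

    gs: float
    moves: tuple[tuple[str, int, int], ...]

    @property
    def matching(self) -> list[tuple[int, int]]:
        return [(i, j) for s, i, j in self.moves if s == "M"]


def mea_align(P: np.ndarray | PosteriorMatrix) -> MeaAlignment:
    """Run the MEA DP and recover one optimal monotone matching.

    Traceback ties prefer the diagonal move, then up (advance x), then
    left, so the alignment is deterministic.
    """
    V = P.values if isinstance(P, PosteriorMatrix) else np.asarray(P, float)
    A = mea_kernel(V)
    n, m = V.shape
    moves: list[tuple[str, int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and A[i, j] == A[i - 1, j - 1] + V[i - 1, j - 1]:
            moves.append(("M", i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and A[i, j] == A[i - 1, j]:
            moves.append(("X", i - 1, -1))
            i -= 1
        else:
            moves.append(("Y", -1, j - 1))
            j -= 1
    moves.reverse()
    return MeaAlignment(gs=float(A[n, m]), moves=tuple(moves))


def alignment_from_moves(x: ProteinSequence, y: ProteinSequence,
                         moves) -> MultipleAlignment:
    """Materialise a traceback path as a two-row gapped alignment."""
    row_x: list[str] = []
    row_y: list[str] = []
    for s, i, j in moves:
        if s == "M":
            row_x.append(x.residues[i])
            row_y.append(y.residues[j])
        elif s == "X":
            row_x.append(x.residues[i])
            row_y.append(GAP)
        else:
            row_x.append(GAP)
            row_y.append(y.residues[j])
    return MultipleAlignment([(x.id, "".join(row_x)), (y.id, "".join(row_y))])


def pair_distance(gs: float, len_x: int, len_y: int) -> float:
    """Distance 1 - GS / min(|x|, |y|), clamped into [0, 1]."""
    if len_x <= 0 or len_y <= 0:
        raise ValueError("sequence lengths must be positive")
    return float(np.clip(1.0 - gs / min(len_x, len_y), 0.0, 1.0))


def build_distance_matrix(family: list[ProteinSequence],
                          posteriors: dict[tuple[int, int], np.ndarray],
                          ) -> np.ndarray:
    """Symmetric pairwise distance matrix from all-pairs posteriors.

    `posteriors` maps each index pair (i, j) with i < j to the posterior
    matrix of family[i] versus family[j].
    """
    n = len(family)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        P = posteriors[(i, j)]
        P = P.values if isinstance(P, PosteriorMatrix) else P
        gs = mea_align(P).gs
        D[i, j] = D[j, i] = pair_distance(gs, len(family[i]), len(family[j]))
    return D
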