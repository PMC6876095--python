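"""Match posteriors from an affine-gap alignment partition function.

Every global alignment l of two sequences is given Boltzmann weight
e^{A(l)/T}, where A(l) is its score under a substitution matrix and affine
gap penalties and T is a temperature constant.  Summing the weights with a
three-state (match / gap-in-y / gap-in-x) forward recursion over prefixes,
and a mirror recursion over suffixes, yields the partition function Z and
the posterior probability that residues x_i and y_j are matched:

    P(i, j) = Z_prefix(i-1, j-1) * e^{s(x_i, y_j)/T} * Z_suffix(i+1, j+1) / Z

where the prefix/suffix factors are summed over their three end states.
Alignments with adjacent mutual gaps (a gap-in-x column next to a
gap-in-y column, in either order) are included; switching gap direction
re-opens a gap run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kernels import pf_forward_kernel
from .matrices import SubstitutionMatrix, blosum62, encode
from .scoring import GapPenalties
from .seqio import ProteinSequence

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartitionParams:
    """Temperature, matrix and gap penalties of the Boltzmann weighting."""

    T: float = 5.0
    matrix: SubstitutionMatrix = field(default_factory=blosum62)
    gaps: GapPenalties = field(default_factory=GapPenalties)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature T must be positive")


@dataclass
class PartitionMatrices:
    """Log-space partition matrices for one sequence pair.

    `forward[s][i, j]` sums alignments of x[1..i], y[1..j] ending in state
    s (0 = match, 1 = gap-in-y, 2 = gap-in-x); `reverse[s][i, j]` sums
    alignments of the suffixes starting at (i, j), stored on the same
    (n+1) x (m+1) grid shifted by one (entry [i, j] covers x[i+1..], y[j+1..]).
    `log_total` is log Z.
    """

    forward: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    reverse: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    log_total: float = np.nan

    @property
    def total(self) -> float:
        return float(np.exp(self.log_total))


def _scaled_scores(x: ProteinSequence, y: ProteinSequence,
                   p: PartitionParams) -> np.ndarray:
    xi = encode(x.residues)
    yi = encode(y.residues)
    return p.matrix.scores[np.ix_(xi, yi)] / p.T


def _all_states(M: np.ndarray, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return np.logaddexp(np.logaddexp(M, X), Y)


def pf_forward(x: ProteinSequence, y: ProteinSequence,
               p: PartitionParams | None = None) -> PartitionMatrices:
    """Forward (prefix) partition matrices and the total log Z."""
    p = p or PartitionParams()
    S = _scaled_scores(x, y, p)
    go = p.gaps.open / p.T
    ge = p.gaps.extend / p.T
    M, X, Y = pf_forward_kernel(S, go, ge)
    total = _all_states(M, X, Y)[len(x), len(y)]
    return PartitionMatrices(forward=(M, X, Y), log_total=float(total))


def pf_reverse(x: ProteinSequence, y: ProteinSequence,
               p: PartitionParams | None = None) -> PartitionMatrices:
    """Suffix partition matrices (the forward recursion on reversed inputs)."""
    p = p or PartitionParams()
    S = _scaled_scores(x, y, p)
    go = p.gaps.open / p.T
    ge = p.gaps.extend / p.T
    Mr, Xr, Yr = pf_forward_kernel(S[::-1, ::-1].copy(), go, ge)
    # flip back so entry [i, j] covers the suffixes x[i+1..], y[j+1..]
    rev = tuple(np.ascontiguousarray(A[::-1, ::-1]) for A in (Mr, Xr, Yr))
    total = _all_states(*rev)[0, 0]
    return PartitionMatrices(reverse=rev, log_total=float(total))


def pf_posterior(x: ProteinSequence, y: ProteinSequence,
                 p: PartitionParams | None = None) -> np.ndarray:
    """Match posterior matrix P[i-1, j-1] = P(x_i ~ y_j | x, y), in [0, 1]."""
    p = p or PartitionParams()
    fwd = pf_forward(x, y, p)
    rev = pf_reverse(x, y, p)
    if abs(fwd.log_total - rev.log_total) > 1e-6 * max(1.0, abs(fwd.log_total)):
        log.warning("forward/reverse partition totals disagree: %g vs %g",
                    fwd.log_total, rev.log_total)
    n, m = len(x), len(y)
    S = _scaled_scores(x, y, p)
    F = _all_states(*fwd.forward)[:n, :m]          # prefix ending before (i, j)
    R = _all_states(*rev.reverse)[1:, 1:]          # suffix starting after (i, j)
    logP = F + S + R - fwd.log_total
    P = np.exp(logP)
    np.clip(P, 0.0, 1.0, out=P)
    rowsums = P.sum(axis=1)
    if np.any(rowsums > 1 + 1e-6):
        log.warning("partition posterior row sum exceeds 1: max %g",
                    rowsums.max())
    return P
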