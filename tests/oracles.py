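"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit enumeration of global
alignments, pair-HMM state paths, monotone matchings and cluster-pair
averages — so the dynamic-programming implementations are checked against
code that shares none of their structure.
"""

from __future__ import annotations

import itertools
import math
from itertools import groupby

import numpy as np

from probpfp.matrices import INDEX, encode


# ---------------------------------------------------------------- alignments

def alignment_moves(n: int, m: int):
    """All global alignment column sequences over moves M/X/Y.

    X consumes a residue of x (gap in y), Y consumes a residue of y.
    Adjacent X/Y columns in either order are distinct alignments.
    """
    out = []

    def rec(i, j, acc):
        if i == n and j == m:
            out.append(tuple(acc))
            return
        if i < n and j < m:
            rec(i + 1, j + 1, acc + ["M"])
        if i < n:
            rec(i + 1, j, acc + ["X"])
        if j < m:
            rec(i, j + 1, acc + ["Y"])

    rec(0, 0, [])
    return out


def affine_score(moves, xi, yi, scores, gap_open, gap_extend):
    """Alignment score with affine gaps; switching gap direction re-opens."""
    total = 0.0
    i = j = 0
    prev = None
    for mv in moves:
        if mv == "M":
            total += scores[xi[i], yi[j]]
            i += 1
            j += 1
        elif mv == "X":
            total += gap_extend if prev == "X" else gap_open
            i += 1
        else:
            total += gap_extend if prev == "Y" else gap_open
            j += 1
        prev = mv
    return total


def pf_oracle(x, y, params):
    """Partition function and match posteriors by full enumeration."""
    xi = encode(x.residues)
    yi = encode(y.residues)
    n, m = len(xi), len(yi)
    Z = 0.0
    acc = np.zeros((n, m))
    for moves in alignment_moves(n, m):
        w = math.exp(
            affine_score(moves, xi, yi, params.matrix.scores,
                         params.gaps.open, params.gaps.extend) / params.T
        )
        Z += w
        i = j = 0
        for mv in moves:
            if mv == "M":
                acc[i, j] += w
                i += 1
                j += 1
            elif mv == "X":
                i += 1
            else:
                j += 1
    return Z, acc / Z


# ----------------------------------------------------------------- pair HMM

def hmm_paths(n: int, m: int):
    """All state paths emitting both sequences; X<->Y transitions forbidden."""
    out = []

    def rec(i, j, last, acc):
        if i == n and j == m:
            out.append(tuple(acc))
            return
        if i < n and j < m:
            rec(i + 1, j + 1, "M", acc + ["M"])
        if i < n and last != "Y":
            rec(i + 1, j, "X", acc + ["X"])
        if j < m and last != "X":
            rec(i, j + 1, "Y", acc + ["Y"])

    rec(0, 0, None, [])
    return out


def hmm_oracle(x, y, h):
    """Total likelihood, match posteriors and per-residue gap posteriors of
    x, by exhaustive state-path enumeration."""
    xi = encode(x.residues)
    yi = encode(y.residues)
    n, m = len(xi), len(yi)
    states = {"M": 0, "X": 1, "Y": 2}
    trans = h.transition_matrix()
    total = 0.0
    match_acc = np.zeros((n, m))
    gapx_acc = np.zeros(n)
    for path in hmm_paths(n, m):
        prob = h.pi[states[path[0]]]
        i = j = 0
        cells = []
        gapped = []
        for k, st in enumerate(path):
            if k > 0:
                prob *= trans[states[path[k - 1]], states[st]]
            if st == "M":
                prob *= h.emit_match[xi[i], yi[j]]
                cells.append((i, j))
                i += 1
                j += 1
            elif st == "X":
                prob *= h.emit_single[xi[i]]
                gapped.append(i)
                i += 1
            else:
                prob *= h.emit_single[yi[j]]
                j += 1
        total += prob
        for c in cells:
            match_acc[c] += prob
        for g in gapped:
            gapx_acc[g] += prob
    return total, match_acc / total, gapx_acc / total


# ----------------------------------------------------------------- MEA / SoP

def mea_bruteforce(P: np.ndarray) -> float:
    """Maximum posterior mass over all monotone matchings."""
    n, m = P.shape
    best = 0.0

    def rec(i, j, acc):
        nonlocal best
        if acc > best:
            best = acc
        for ii in range(i, n):
            for jj in range(j, m):
                rec(ii + 1, jj + 1, acc + P[ii, jj])

    rec(0, 0, 0.0)
    return best


def sop_bruteforce(rows, scores, gap_open, gap_extend) -> float:
    """Sum-of-pairs by explicit pairwise projection and gap-run grouping."""
    total = 0.0
    for a, b in itertools.combinations(rows, 2):
        proj = [(ca, cb) for ca, cb in zip(a, b)
                if not (ca == "-" and cb == "-")]
        for ca, cb in proj:
            if ca != "-" and cb != "-":
                total += scores[INDEX[ca], INDEX[cb]]
        for seq in ("".join(p[0] for p in proj), "".join(p[1] for p in proj)):
            for is_gap, run in groupby(seq, key=lambda c: c == "-"):
                if is_gap:
                    length = len(list(run))
                    total += gap_open + (length - 1) * gap_extend
    return total


# -------------------------------------------------------------------- UPGMA

def upgma_eq14_history(D: np.ndarray):
    """Agglomeration history with cluster distances recomputed each step as
    the direct mean over all cross pairs of leaves."""
    n = D.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    history = []

    def cdist(A, B):
        return float(np.mean([D[a, b] for a in A for b in B]))

    while len(clusters) > 1:
        best = None
        best_d = np.inf
        for ai in range(len(clusters)):
            for aj in range(ai + 1, len(clusters)):
                d = cdist(clusters[ai], clusters[aj])
                if d < best_d:
                    best_d = d
                    best = (ai, aj)
        ai, aj = best
        history.append((clusters[ai], clusters[aj], best_d))
        merged = clusters[ai] | clusters[aj]
        clusters = [c for k, c in enumerate(clusters)
                    if k not in (ai, aj)] + [merged]
    return history
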