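"""Sum-of-pairs scoring and SP/TC benchmark metrics.

The sum-of-pairs (SoP) score of a multiple alignment is the sum over all
row pairs of the substitution-matrix score of their projected pairwise
alignment: columns where both rows are gapped are deleted, residue-residue
columns add s(a,b), and a residue-gap column adds the gap-open score when
it starts a gap run in that pairwise projection and the gap-extend score
otherwise.  Terminal gaps are penalised like internal ones.

SP and TC compare a test alignment against a reference: SP is the fraction
of reference residue-residue pairs reproduced; TC the fraction of
fully gap-free reference columns reproduced as identical residue-index
columns.
"""

from __future__ import annotations

from dataclasses import dataclass

from .matrices import SubstitutionMatrix, blosum62
from .seqio import GAP, MultipleAlignment


@dataclass(frozen=True)
class GapPenalties:
    """Affine gap scores: `open` for the first column of a run, `extend` after."""

    open: int = -11
    extend: int = -1

    def __post_init__(self) -> None:
        if not (self.open <= self.extend <= 0):
            raise ValueError("gap penalties must satisfy open <= extend <= 0")


def _score_pair(a: str, b: str, scores, index, g: GapPenalties) -> float:
    """Score one pairwise projection (both-gap columns deleted)."""
    total = 0.0
    in_gap_a = False
    in_gap_b = False
    for ca, cb in zip(a, b):
        if ca == GAP and cb == GAP:
            continue
        if ca == GAP:
            total += g.extend if in_gap_a else g.open
            in_gap_a, in_gap_b = True, False
        elif cb == GAP:
            total += g.extend if in_gap_b else g.open
            in_gap_a, in_gap_b = False, True
        else:
            total += scores[index[ca], index[cb]]
            in_gap_a = in_gap_b = False
    return total


def sop_score(aln: MultipleAlignment,
              matrix: SubstitutionMatrix | None = None,
              gaps: GapPenalties | None = None) -> float:
    """Sum-of-pairs score of `aln` (defaults: BLOSUM62, open -11 / extend -1)."""
    if len(aln) < 2:
        raise ValueError("sum-of-pairs needs at least 2 rows")
    matrix = matrix or blosum62()
    gaps = gaps or GapPenalties()
    from .matrices import INDEX
    total = 0.0
    for i in range(len(aln)):
        for j in range(i + 1, len(aln)):
            total += _score_pair(aln.rows[i][1], aln.rows[j][1],
                                 matrix.scores, INDEX, gaps)
    return total


def _residue_positions(gapped: str) -> list[int]:
    """Per column: residue index within the ungapped sequence, or -1 for gaps."""
    out = []
    k = 0
    for ch in gapped:
        if ch == GAP:
            out.append(-1)
        else:
            out.append(k)
            k += 1
    return out


def _aligned_pairs(aln: MultipleAlignment) -> set[tuple[str, int, str, int]]:
    pos = {sid: _residue_positions(g) for sid, g in aln.rows}
    ids = aln.ids
    pairs: set[tuple[str, int, str, int]] = set()
    for col in range(aln.length):
        for i in range(len(ids)):
            pi = pos[ids[i]][col]
            if pi < 0:
                continue
            for j in range(i + 1, len(ids)):
                pj = pos[ids[j]][col]
                if pj < 0:
                    continue
                a, b = ids[i], ids[j]
                if a > b:
                    a, b, pi2, pj2 = b, a, pj, pi
                    pairs.add((a, pi2, b, pj2))
                else:
                    pairs.add((a, pi, b, pj))
    return pairs


def _gapfree_columns(aln: MultipleAlignment) -> set[tuple[int, ...]]:
    """Gap-free columns as residue-index tuples over id-sorted rows."""
    order = sorted(range(len(aln)), key=lambda k: aln.ids[k])
    pos = [_residue_positions(aln.rows[k][1]) for k in order]
    cols: set[tuple[int, ...]] = set()
    for col in range(aln.length):
        tup = tuple(p[col] for p in pos)
        if all(v >= 0 for v in tup):
            cols.add(tup)
    return cols


def sp_tc_scores(test: MultipleAlignment,
                 ref: MultipleAlignment) -> tuple[float, float]:
    """SP and TC of `test` against the reference alignment `ref`.

    Both alignments must contain the same sequences (matched by id, with
    identical ungapped residues).  Vacuous denominators — a reference with
    no residue-residue pairs, or no gap-free columns — score 1.0.
    """
    if set(test.ids) != set(ref.ids):
        raise ValueError("test and reference alignments have different ids")
    test_seq = {sid: g.replace(GAP, "") for sid, g in test.rows}
    for sid, g in ref.rows:
        if g.replace(GAP, "") != test_seq[sid]:
            raise ValueError(f"ungapped sequence mismatch for id {sid!r}")

    ref_pairs = _aligned_pairs(ref)
    if ref_pairs:
        sp = len(ref_pairs & _aligned_pairs(test)) / len(ref_pairs)
    else:
        sp = 1.0

    ref_cols = _gapfree_columns(ref)
    if ref_cols:
        tc = len(ref_cols & _gapfree_columns(test)) / len(ref_cols)
    else:
        tc = 1.0
    return sp, tc
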