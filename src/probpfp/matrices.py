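"""Residue alphabet, substitution matrices, and emission tables.

The scoring alphabet is the 20 canonical amino acids plus ``X``, the
placeholder every ambiguity code (B, Z, X, U, O, ``*``) is normalised to on
input.  BLOSUM62 is the default substitution matrix; pair-HMM match
emissions are obtained by inverting its log-odds relation
``s(a,b) = round(2 * log2(p(a,b) / (q(a) q(b))))`` against a published
background frequency set and renormalising.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

#: Scoring alphabet: 20 canonical residues plus the ambiguity placeholder X.
ALPHABET = "ARNDCQEGHILKMFPSTWYVX"
AA20 = ALPHABET[:20]
INDEX = {a: i for i, a in enumerate(ALPHABET)}
N_LETTERS = len(ALPHABET)

#: Characters normalised to X on input (plus a logged warning).
AMBIGUOUS = set("BZXUO*")

# Robinson & Robinson amino-acid background frequencies, the set commonly
# paired with BLOSUM62 log-odds scores.  X receives a small nominal mass and
# the whole vector is renormalised.
_BACKGROUND = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}
_X_MASS = 2e-4


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer log-odds score table over :data:`ALPHABET`."""

    name: str
    scores: np.ndarray  # (21, 21) int array

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s.shape != (N_LETTERS, N_LETTERS):
            raise ValueError(f"score table must be {N_LETTERS}x{N_LETTERS}")
        if not np.array_equal(s, s.T):
            raise ValueError("substitution matrix must be symmetric")
        object.__setattr__(self, "scores", s.astype(np.float64))

    def score(self, a: str, b: str) -> float:
        return float(self.scores[INDEX[a], INDEX[b]])


_REGISTRY: dict[str, SubstitutionMatrix] = {}


def register_matrix(matrix: SubstitutionMatrix) -> None:
    """Hook for registering alternative substitution matrices by name."""
    _REGISTRY[matrix.name] = matrix


def get_matrix(name: str) -> SubstitutionMatrix:
    if name == "BLOSUM62":
        return blosum62()
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown substitution matrix {name!r}") from None


@lru_cache(maxsize=1)
def blosum62() -> SubstitutionMatrix:
    """The BLOSUM62 matrix restricted to the 21-letter scoring alphabet."""
    raw = substitution_matrices.load("BLOSUM62")
    letters = raw.alphabet
    table = np.zeros((N_LETTERS, N_LETTERS))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            table[i, j] = raw[letters.index(a), letters.index(b)]
    return SubstitutionMatrix("BLOSUM62", table)


@lru_cache(maxsize=1)
def background_frequencies() -> np.ndarray:
    """Background residue frequencies q(a) over :data:`ALPHABET`, summing to 1."""
    q = np.array([_BACKGROUND[a] for a in AA20] + [_X_MASS])
    return q / q.sum()


@lru_cache(maxsize=4)
def match_emissions(matrix_name: str = "BLOSUM62") -> tuple[np.ndarray, np.ndarray]:
    """Joint match emission table p(a,b) and its marginal q(a).

    Inverts the log-odds relation of the named matrix against the background
    frequencies: p(a,b) is proportional to q(a) q(b) 2^{s(a,b)/2}, then
    normalised to sum to 1.  The single-residue emission is the marginal of
    p, so both tables are exactly consistent.
    """
    m = get_matrix(matrix_name)
    q = background_frequencies()
    p = np.outer(q, q) * np.exp2(m.scores / 2.0)
    p /= p.sum()
    return p, p.sum(axis=1)


def encode(residues: str) -> np.ndarray:
    """Map a residue string to integer indices into :data:`ALPHABET`."""
    try:
        return np.array([INDEX[c] for c in residues], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not in alphabet") from None
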