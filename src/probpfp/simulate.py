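"""Synthetic protein families with known true alignments.

An ancestor sequence is drawn from the background residue frequencies and
each descendant evolves from it independently: every surviving site is
substituted with probability `p_sub` (the replacement drawn from the
BLOSUM62-derived conditional p(b | a), excluding the original residue, so
the realised substitution fraction matches `p_sub`), and at each site an
indel event fires with probability `p_indel` — a coin chooses insertion or
deletion, and the length is geometric with the given mean.  The edit
histories imply a true multiple alignment: one column per surviving
ancestor site, plus insertion columns (insertions from different
descendants are not homologous and get separate columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import AA20, background_frequencies, match_emissions
from .seqio import GAP, MultipleAlignment, ProteinSequence


@dataclass(frozen=True)
class SyntheticFamily:
    ancestor: ProteinSequence
    descendants: list[ProteinSequence]
    true_alignment: MultipleAlignment
    params: dict


def _conditional_substitution(p: np.ndarray) -> np.ndarray:
    """p(b | a) with the diagonal removed and rows renormalised."""
    cond = p[:20, :20].copy()
    np.fill_diagonal(cond, 0.0)
    return cond / cond.sum(axis=1, keepdims=True)


def generate_family(n: int = 8, length: int = 120,
                    p_sub: float = 0.10, p_indel: float = 0.02,
                    mean_indel: float = 2.0, seed: int = 0,
                    id_prefix: str = "seq") -> SyntheticFamily:
    """Simulate `n` descendants of a random ancestor of the given length."""
    if not (0 <= p_sub <= 1 and 0 <= p_indel <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if length < 10:
        raise ValueError("ancestor length must be at least 10")
    if n < 2:
        raise ValueError("need at least 2 descendants")
    if mean_indel < 1:
        raise ValueError("mean indel length must be at least 1")

    rng = np.random.default_rng(seed)
    q20 = background_frequencies()[:20]
    q20 = q20 / q20.sum()
    cond = _conditional_substitution(match_emissions()[0])
    aa = np.array(list(AA20))

    anc_idx = rng.choice(20, size=length, p=q20)
    ancestor = ProteinSequence(f"{id_prefix}_ancestor", "".join(aa[anc_idx]))

    # per descendant: kept[site] -> residue char or None; ins[site] -> string
    # inserted after that site
    histories: list[tuple[list[str | None], dict[int, str]]] = []
    for _ in range(n):
        while True:
            kept: list[str | None] = [None] * length
            ins: dict[int, str] = {}
            skip = 0
            for s in range(length):
                if skip > 0:
                    skip -= 1
                    continue
                if p_indel > 0 and rng.random() < p_indel:
                    g = int(rng.geometric(1.0 / mean_indel))
                    if rng.random() < 0.5:      # deletion starting here
                        skip = g - 1
                        continue
                    ins[s] = "".join(aa[rng.choice(20, size=g, p=q20)])
                a = anc_idx[s]
                if p_sub > 0 and rng.random() < p_sub:
                    kept[s] = aa[rng.choice(20, p=cond[a])]
                else:
                    kept[s] = aa[a]
            if any(r is not None for r in kept) or ins:
                break
        histories.append((kept, ins))

    descendants = []
    for d, (kept, ins) in enumerate(histories):
        parts = []
        for s in range(length):
            if kept[s] is not None:
                parts.append(kept[s])
            parts.append(ins.get(s, ""))
        descendants.append(
            ProteinSequence(f"{id_prefix}{d + 1}", "".join(parts)))

    # true alignment: ancestor-site columns, then per-descendant insertion
    # blocks (each private to one row)
    columns: list[list[str]] = []
    for s in range(length):
        col = [kept[s] if kept[s] is not None else GAP
               for kept, _ in histories]
        if any(c != GAP for c in col):
            columns.append(col)
        for d, (_, ins) in enumerate(histories):
            for ch in ins.get(s, ""):
                col = [GAP] * n
                col[d] = ch
                columns.append(col)
    rows = [
        (descendants[d].id, "".join(col[d] for col in columns))
        for d in range(n)
    ]
    truth = MultipleAlignment(rows)
    for d in range(n):
        assert truth.ungapped(d) == descendants[d].residues

    return SyntheticFamily(
        ancestor=ancestor,
        descendants=descendants,
        true_alignment=truth,
        params={"n": n, "length": length, "p_sub": p_sub,
                "p_indel": p_indel, "mean_indel": mean_indel, "seed": seed},
    )
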