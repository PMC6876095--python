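import numpy as np
import pytest

from probpfp.matrices import AA20
from probpfp.seqio import ProteinSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, length, label="x"):
    letters = rng.choice(list(AA20), size=length)
    return ProteinSequence(label, "".join(letters))


def random_pair(rng, max_len=4, min_len=1):
    la = int(rng.integers(min_len, max_len + 1))
    lb = int(rng.integers(min_len, max_len + 1))
    return random_protein(rng, la, "x"), random_protein(rng, lb, "y")


def random_alignment(rng, n_rows=3, n_cols=6):
    """Random gapped alignment with no all-gap columns and non-empty rows."""
    while True:
        rows = []
        grid = rng.random((n_rows, n_cols)) < 0.3   # True = gap
        # forbid all-gap columns and all-gap rows
        if grid.all(axis=0).any() or grid.all(axis=1).any():
            continue
        for r in range(n_rows):
            chars = [
                "-" if grid[r, c] else str(rng.choice(list(AA20)))
                for c in range(n_cols)
            ]
            rows.append((f"s{r + 1}", "".join(chars)))
        return rows


@pytest.fixture
def tiny_family():
    return [
        ProteinSequence("s1", "ARNDCQE"),
        ProteinSequence("s2", "ARNDCQE"),
        ProteinSequence("s3", "ARNECQE"),
        ProteinSequence("s4", "ARNDCE"),
    ]
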