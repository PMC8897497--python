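import numpy as np
import pytest

from mvapipe.io import CohortTable, SubjectRecord
from mvapipe.patterns import AMINO_ACIDS


def random_pattern_string(rng: np.random.Generator, min_len: int = 4, max_len: int = 10) -> str:
    """Random trimmed pattern with fixed residues, classes and wildcards."""
    while True:
        n = int(rng.integers(min_len, max_len + 1))
        toks = []
        for i in range(n):
            kind = rng.random()
            if i in (0, n - 1) or kind < 0.55:
                toks.append(AMINO_ACIDS[rng.integers(0, 20)])
            elif kind < 0.85:
                toks.append(".")
            else:
                k = int(rng.integers(2, 4))
                cls = sorted(rng.choice(list(AMINO_ACIDS), size=k, replace=False))
                toks.append("[" + "".join(cls) + "]")
        s = "".join(toks)
        if any(t in AMINO_ACIDS for t in toks):
            return s


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture
def toy_cohort() -> CohortTable:
    """Two H and two P subjects with a handful of peptides."""
    subjects = [
        SubjectRecord("s1", "noCAD", "H"),
        SubjectRecord("s2", "ACS", "H"),
        SubjectRecord("s3", "noCAD", "P"),
        SubjectRecord("s4", "ACS", "P"),
    ]
    counts = {
        ("s1", "TLPMDTSPRAHW"): 12,
        ("s1", "AAAAAAAAAAAA"): 3,
        ("s2", "TLPMDTSPRAHW"): 5,
        ("s3", "TLPMDTSPRAHW"): 40,
        ("s3", "KPALFWRDCEHG"): 15,
        ("s4", "KPALFWRDCEHG"): 7,
    }
    return CohortTable(counts=counts, subjects=subjects)
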