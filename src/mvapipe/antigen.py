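"""Per-subject peptide alignment profiles along a target antigen.

A subject's 12-mer peptides are aligned ungapped to a target protein; a
peptide aligns at an offset when at least ``min_match`` of its 12 positions
equal the protein residues.  Each unique peptide contributes 1 to every
position of its best-scoring span (all best-scoring offsets are counted when
tied).  A paired null track is built by residue-scrambling each peptide and
aligning the scrambled set the same way; the per-position signal-to-random
ratio is (signal + eps) / (random + eps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortTable
from .patterns import Pattern
from .synthetic import scramble_peptides


@dataclass
class PositionProfile:
    """Per-position signal/random coverage and their ratio along one protein."""

    accession: str
    signal: np.ndarray
    random: np.ndarray
    ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": np.arange(len(self.signal)), "signal": self.signal,
             "random": self.random, "ratio": self.ratio}
        )


def align_peptides_to_protein(peptides, protein: str, min_match: int = 6,
                              mode: str = "best") -> np.ndarray:
    """Per-position count of distinct aligned peptides covering the position.

    ``mode='best'`` (default) credits only the best-scoring offset(s) of each
    peptide; ``mode='all'`` credits every offset with >= ``min_match``
    matches.
    """
    if mode not in ("best", "all"):
        raise ValueError("mode must be 'best' or 'all'")
    L = len(protein)
    cov = np.zeros(L, dtype=float)
    peps = sorted(set(peptides))
    if not peps or L < 12:
        return cov
    prot = np.frombuffer(protein.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(prot, 12)
    for pep in peps:
        arr = np.frombuffer(pep.encode(), dtype=np.uint8)
        scores = (windows == arr).sum(axis=1)
        best = int(scores.max())
        if best < min_match:
            continue
        offs = np.nonzero(scores == best)[0] if mode == "best" else np.nonzero(scores >= min_match)[0]
        for o in offs:
            cov[o : o + 12] += 1
    return cov


def signal_to_random_profile(peptides, protein: str, seed: int, eps: float = 1.0,
                             min_match: int = 6, accession: str = "target",
                             mode: str = "best") -> PositionProfile:
    """Signal and scrambled-peptide random tracks plus their ratio."""
    peps = sorted(set(peptides))
    signal = align_peptides_to_protein(peps, protein, min_match=min_match, mode=mode)
    random_track = align_peptides_to_protein(
        scramble_peptides(peps, seed), protein, min_match=min_match, mode=mode
    )
    ratio = (signal + eps) / (random_track + eps)
    return PositionProfile(accession=accession, signal=signal, random=random_track, ratio=ratio)


def epitope_containing_abundance(cohort: CohortTable, pattern: Pattern | str,
                                 threshold: float | None = None):
    """Per subject, the summed counts of peptides containing ``pattern``.

    With ``threshold`` set, also returns the binary seropositivity call
    (positive iff abundance > threshold), e.g. the MVA+ rule at 1200 for
    P.DT.PR-containing peptides.
    """
    if isinstance(pattern, str):
        pattern = Pattern.parse(pattern)
    rg = pattern.compiled()
    by_subject = cohort.by_subject()
    abund = pd.Series(
        {sid: float(sum(c for pep, c in prof.items() if rg.search(pep)))
         for sid, prof in by_subject.items()}
    ).reindex(cohort.subject_ids)
    if threshold is None:
        return abund
    return abund, abund > threshold
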