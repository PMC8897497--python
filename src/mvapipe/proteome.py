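"""Proteome antigen scanning.

Motifs are aligned to proteomes (every offset where all fixed positions
match), proteins are tiled into 20-aa fragments in two frameshifts (0 and
-10, giving 10-aa overlaps between the two tilings), and each fragment is
scored by its alignment load::

    load(fragment) = sum of abundance of distinct motifs aligned
                     -----------------------------------------
                           count of distinct motifs aligned

The top-k fragments per proteome are reported; when two selected fragments
from different frameshifts overlap by 10 aa they are merged into one 30-aa
fragment and the load is recomputed over the merged span.  Finally, target
types are derived: the 12-mer protein substrings around motif hits inside top
fragments are clustered (greedy agglomeration on Hamming distance) and each
cluster is summarised by a position-weight matrix and its consensus pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Proteome
from .patterns import AMINO_ACIDS, Pattern, consensus_from_pwm

FRAGMENT_LENGTH = 20
FRAMESHIFTS = (0, -10)


@dataclass(frozen=True)
class Fragment:
    """A tiled (20 aa) or merged (30 aa) proteome window, end-exclusive."""

    accession: str
    start: int
    end: int
    frameshift: int | None  # None for merged 30-aa fragments

    def __post_init__(self):
        if self.end - self.start not in (20, 30):
            raise ValueError(f"fragment length must be 20 or 30, got {self.end - self.start}")

    @property
    def key(self) -> str:
        fs = "m" if self.frameshift is None else str(self.frameshift)
        return f"{self.accession}:{self.start}-{self.end}|fs{fs}"


@dataclass(frozen=True)
class AlignmentHit:
    """One exact motif placement on a protein (all fixed positions match)."""

    pattern: Pattern
    accession: str
    offset: int

    @property
    def span(self) -> tuple[int, int]:
        return self.offset, self.offset + len(self.pattern)


@dataclass
class LoadMatrix:
    """Per-subject and total alignment loads over a fragment list."""

    fragments: list[Fragment]
    per_subject: pd.DataFrame  # index = fragment key, columns = subjects
    total: pd.Series  # index = fragment key
    fragment_motifs: dict[str, frozenset] = field(default_factory=dict)


def tile_fragments(proteome: Proteome) -> list[Fragment]:
    """Complete 20-aa windows in both frameshifts for every protein."""
    frags: list[Fragment] = []
    for acc in sorted(proteome.entries):
        L = len(proteome.entries[acc])
        for start in range(0, L - FRAGMENT_LENGTH + 1, FRAGMENT_LENGTH):
            frags.append(Fragment(acc, start, start + FRAGMENT_LENGTH, frameshift=0))
        for start in range(10, L - FRAGMENT_LENGTH + 1, FRAGMENT_LENGTH):
            frags.append(Fragment(acc, start, start + FRAGMENT_LENGTH, frameshift=-10))
    return frags


def align_motifs_to_proteome(motifs, proteome: Proteome, min_fixed: int = 4) -> list[AlignmentHit]:
    """Every (motif, protein, offset) where all fixed positions match."""
    pats = [m if isinstance(m, Pattern) else Pattern.parse(str(m)) for m in motifs]
    for p in pats:
        if p.n_fixed < min_fixed:
            raise ValueError(f"motif {p} has {p.n_fixed} fixed positions, need >= {min_fixed}")
    import re

    hits: list[AlignmentHit] = []
    for acc in sorted(proteome.entries):
        seq = proteome.entries[acc]
        for p in pats:
            rg = re.compile("(?=" + p.to_regex() + ")")
            for m in rg.finditer(seq):
                hits.append(AlignmentHit(pattern=p, accession=acc, offset=m.start()))
    return hits


def _containing_fragment_starts(offset: int, end: int) -> list[tuple[int, int]]:
    """(frameshift, start) of the tiled fragments fully containing [offset, end)."""
    out = []
    s0 = (offset // 20) * 20
    if end <= s0 + 20:
        out.append((0, s0))
    if offset >= 10:
        s1 = ((offset - 10) // 20) * 20 + 10
        if end <= s1 + 20:
            out.append((-10, s1))
    return out


def fragment_alignment_load(hits: list[AlignmentHit], fragments: list[Fragment],
                            abundance: pd.DataFrame, subject: str = "ALL") -> LoadMatrix:
    """Alignment load per fragment: mean abundance of the distinct motifs whose
    span lies fully inside the fragment.  Fragments with no hits score 0."""
    for h in hits:
        if str(h.pattern) not in abundance.index:
            raise ValueError(f"no abundance row for motif {h.pattern}")
    lookup = {(f.accession, f.frameshift, f.start): f for f in fragments}
    frag_motifs: dict[str, set] = {f.key: set() for f in fragments}
    for h in hits:
        o, e = h.span
        for fs, s in _containing_fragment_starts(o, e):
            f = lookup.get((h.accession, fs, s))
            if f is not None:
                frag_motifs[f.key].add(str(h.pattern))
    cols = list(abundance.columns) if subject == "ALL" else [subject]
    mat = np.zeros((len(fragments), len(cols)))
    for i, f in enumerate(fragments):
        motifs = sorted(frag_motifs[f.key])
        if motifs:
            mat[i] = abundance.loc[motifs, cols].to_numpy().sum(axis=0) / len(motifs)
    per_subject = pd.DataFrame(mat, index=[f.key for f in fragments], columns=cols)
    return LoadMatrix(
        fragments=list(fragments),
        per_subject=per_subject,
        total=per_subject.sum(axis=1),
        fragment_motifs={k: frozenset(v) for k, v in frag_motifs.items()},
    )


def _span_load(accession: str, start: int, end: int, hits: list[AlignmentHit],
               abundance: pd.DataFrame) -> tuple[float, frozenset]:
    motifs = sorted(
        {str(h.pattern) for h in hits
         if h.accession == accession and h.offset >= start and h.span[1] <= end}
    )
    if not motifs:
        return 0.0, frozenset()
    load = float(abundance.loc[motifs].to_numpy().sum() / len(motifs))
    return load, frozenset(motifs)


def select_top_fragments(loads: LoadMatrix, k: int = 40, *, hits: list[AlignmentHit],
                         abundance: pd.DataFrame) -> tuple[list[Fragment], pd.Series]:
    """Top-k fragments by total load, with the 30-aa merge rule applied.

    Ties break by (accession, start) ascending.  When two selected fragments
    from different frameshifts overlap by 10 aa, they are replaced by a
    single 30-aa fragment whose load is recomputed over the merged span.
    Returns the fragments and their total loads.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(
        loads.fragments,
        key=lambda f: (-float(loads.total[f.key]), f.accession, f.start),
    )
    selected = [f for f in order[:k] if True]
    selected_sorted = sorted(selected, key=lambda f: (f.accession, f.start))
    merged: list[Fragment] = []
    consumed = set()
    for i, f in enumerate(selected_sorted):
        if f.key in consumed:
            continue
        partner = None
        if i + 1 < len(selected_sorted):
            g = selected_sorted[i + 1]
            if (g.key not in consumed and g.accession == f.accession
                    and g.frameshift != f.frameshift and g.start - f.start == 10):
                partner = g
        if partner is not None:
            merged.append(Fragment(f.accession, f.start, partner.end, frameshift=None))
            consumed.add(f.key)
            consumed.add(partner.key)
        else:
            merged.append(f)
            consumed.add(f.key)
    out_loads = {}
    for f in merged:
        if f.frameshift is None:
            load, _ = _span_load(f.accession, f.start, f.end, hits, abundance)
        else:
            load = float(loads.total[f.key])
        out_loads[f.key] = load
    merged.sort(key=lambda f: (-out_loads[f.key], f.accession, f.start))
    return merged, pd.Series({f.key: out_loads[f.key] for f in merged})


@dataclass
class TargetType:
    """A PWM-consensus cluster of 12-mer substrings hit inside top fragments."""

    member_substrings: frozenset
    pwm: np.ndarray  # 20 x 12 residue frequencies, columns sum to 1
    consensus: str


def extract_hit_substrings(top_fragments: list[Fragment], hits: list[AlignmentHit],
                           proteome: Proteome) -> list[str]:
    """Unique 12-aa protein substrings containing each hit span inside a top
    fragment, centred on the span and shifted inward at fragment edges."""
    subs = set()
    by_acc: dict[str, list[Fragment]] = {}
    for f in top_fragments:
        by_acc.setdefault(f.accession, []).append(f)
    for h in hits:
        o, e = h.span
        if e - o > 12:
            continue  # a full 12-mer cannot contain the span
        for f in by_acc.get(h.accession, []):
            if o >= f.start and e <= f.end:
                seq = proteome.entries[h.accession]
                w = o - (12 - (e - o)) // 2
                lo = max(f.start, e - 12)
                hi = min(f.end - 12, o)
                if lo > hi:
                    continue
                w = min(max(w, lo), hi)
                subs.add(seq[w : w + 12])
    return sorted(subs)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def cluster_target_types(top_fragments: list[Fragment], hits: list[AlignmentHit],
                         proteome: Proteome, min_cluster: int = 10,
                         distance_cutoff: int = 9) -> list[TargetType]:
    """Cluster unique hit substrings into target types.

    Greedy agglomeration over unique substrings ("no counts"): a substring
    joins the first cluster holding a member within ``distance_cutoff``
    Hamming distance (cutoff 9 over 12 positions = at least 3 identities);
    clusters with fewer than ``min_cluster`` unique members are discarded.
    """
    subs = extract_hit_substrings(top_fragments, hits, proteome)
    clusters: list[list[str]] = []
    for s in subs:
        placed = False
        for cl in clusters:
            if min(_hamming(s, m) for m in cl) <= distance_cutoff:
                cl.append(s)
                placed = True
                break
        if not placed:
            clusters.append([s])
    kept = [cl for cl in clusters if len(cl) >= min_cluster]
    kept.sort(key=lambda cl: (-len(cl), cl[0]))
    out = []
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for cl in kept:
        pwm = np.zeros((20, 12))
        for s in cl:
            for j, ch in enumerate(s):
                pwm[aa_index[ch], j] += 1
        pwm /= pwm.sum(axis=0, keepdims=True)
        cols = [{a: pwm[aa_index[a], j] for a in AMINO_ACIDS if pwm[aa_index[a], j] > 0}
                for j in range(12)]
        out.append(TargetType(
            member_substrings=frozenset(cl),
            pwm=pwm,
            consensus=consensus_from_pwm(cols),
        ))
    return out
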