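import re

import numpy as np
import pandas as pd
import pytest

from mvapipe.io import Proteome
from mvapipe.patterns import Pattern
from mvapipe.proteome import (
    AlignmentHit,
    Fragment,
    align_motifs_to_proteome,
    cluster_target_types,
    extract_hit_substrings,
    fragment_alignment_load,
    select_top_fragments,
    tile_fragments,
)

from conftest import random_sequence


def proteome_of(**entries):
    return Proteome(entries=dict(entries))


class TestTiling:
    def test_length_60_yields_five_fragments(self):
        prot = proteome_of(p1=random_sequence(np.random.default_rng(0), 60))
        frags = tile_fragments(prot)
        fs0 = sorted(f.start for f in frags if f.frameshift == 0)
        fs1 = sorted(f.start for f in frags if f.frameshift == -10)
        assert fs0 == [0, 20, 40]
        assert fs1 == [10, 30]

    def test_protein_shorter_than_window_yields_nothing(self):
        prot = proteome_of(p1=random_sequence(np.random.default_rng(0), 19))
        assert tile_fragments(prot) == []

    def test_total_count_matches_brute_force(self):
        rng = np.random.default_rng(1)
        entries = {f"p{i}": random_sequence(rng, int(rng.integers(15, 300))) for i in range(30)}
        prot = Proteome(entries=entries)
        frags = tile_fragments(prot)
        expected = sum(
            len(range(0, len(s) - 19, 20)) + len(range(10, len(s) - 19, 20))
            for s in entries.values()
        )
        assert len(frags) == expected

    def test_each_tiling_partitions_covered_residues(self):
        prot = proteome_of(p1=random_sequence(np.random.default_rng(2), 97))
        frags = tile_fragments(prot)
        for fs in (0, -10):
            covered = []
            for f in (f for f in frags if f.frameshift == fs):
                covered.extend(range(f.start, f.end))
            assert len(covered) == len(set(covered))  # no overlap within a tiling


class TestAlignment:
    def test_epitope_motif_hits_at_proline(self):
        seq = "GG" + "TLPMDTSPRAHW" + "GG"
        hits = align_motifs_to_proteome(["P..T.PR"], proteome_of(p1=seq))
        assert [(h.accession, h.offset) for h in hits] == [("p1", 4)]

    def test_disjoint_alphabet_no_hits(self):
        hits = align_motifs_to_proteome(["W.W.W.W"], proteome_of(p1="ACDEACDEACDEACDEACDE"))
        assert hits == []

    def test_too_few_fixed_positions_rejected(self):
        with pytest.raises(ValueError, match="fixed positions"):
            align_motifs_to_proteome(["A.B" .replace("B", "C")], proteome_of(p1="ACDEACDE"))

    def test_matches_regex_oracle_on_random_proteins(self):
        rng = np.random.default_rng(3)
        entries = {f"p{i}": random_sequence(rng, 120) for i in range(50)}
        prot = Proteome(entries=entries)
        motifs = []
        while len(motifs) < 20:
            toks = [
                "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)] if rng.random() < 0.6 else "."
                for _ in range(int(rng.integers(4, 9)))
            ]
            s = "".join(toks).strip(".")
            if sum(1 for t in s if t != ".") >= 4:
                motifs.append(s)
        hits = align_motifs_to_proteome(motifs, prot)
        expected = set()
        for acc, seq in entries.items():
            for m in motifs:
                rx = re.compile("(?=" + m + ")")
                for mt in rx.finditer(seq):
                    expected.add((m, acc, mt.start()))
        assert {(str(h.pattern), h.accession, h.offset) for h in hits} == expected


def _simple_load_setup():
    rng = np.random.default_rng(4)
    seq = random_sequence(rng, 40)
    seq = "PAATAPR" + seq[7:20] + "KPQLFGR" + seq[27:]
    prot = proteome_of(p1=seq)
    frags = tile_fragments(prot)
    motifs = ["P..T.PR", "KP.LF.R"]
    abund = pd.DataFrame([[100.0, 20.0], [50.0, 30.0]], index=motifs, columns=["s1", "s2"])
    hits = align_motifs_to_proteome(motifs, prot)
    return prot, frags, motifs, abund, hits


class TestAlignmentLoad:
    def test_mean_of_distinct_motif_abundances(self):
        prot, frags, motifs, abund, hits = _simple_load_setup()
        lm = fragment_alignment_load(hits, frags, abund)
        # fragment [0,20) holds P..T.PR (offset 0) and KP.LF.R (offset 20? no: 20 is outside)
        key0 = [f.key for f in frags if f.frameshift == 0 and f.start == 0][0]
        assert lm.per_subject.loc[key0, "s1"] == pytest.approx(100.0)
        assert lm.total[key0] == pytest.approx(120.0)

    def test_fragment_with_three_motifs_mean(self):
        frag = Fragment("p1", 0, 20, 0)
        hits = [AlignmentHit(Pattern.parse(m), "p1", o) for m, o in
                [("AACA", 0), ("CCGC", 5), ("GGTG", 10)]]
        abund = pd.DataFrame([[100.0], [50.0], [30.0]],
                             index=["AACA", "CCGC", "GGTG"], columns=["s1"])
        lm = fragment_alignment_load(hits, [frag], abund)
        assert lm.total[frag.key] == pytest.approx(60.0)

    def test_zero_abundance_motif_gives_zero_load(self):
        frag = Fragment("p1", 0, 20, 0)
        hits = [AlignmentHit(Pattern.parse("AACA"), "p1", 2)]
        abund = pd.DataFrame([[0.0]], index=["AACA"], columns=["s1"])
        lm = fragment_alignment_load(hits, [frag], abund)
        assert lm.total[frag.key] == 0.0

    def test_missing_abundance_row_rejected(self):
        frag = Fragment("p1", 0, 20, 0)
        hits = [AlignmentHit(Pattern.parse("AACA"), "p1", 2)]
        abund = pd.DataFrame([[1.0]], index=["CCGC"], columns=["s1"])
        with pytest.raises(ValueError, match="no abundance row"):
            fragment_alignment_load(hits, [frag], abund)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(5)
        entries = {f"p{i}": random_sequence(rng, 200) for i in range(10)}
        prot = Proteome(entries=entries)
        motifs = ["A..A", "C.D.E", "K...L", "P..T.PR", "G.G", "W.Y.A", "M..N", "R..R", "S.T.S", "F.F"]
        abund = pd.DataFrame(
            rng.integers(0, 200, size=(10, 3)).astype(float), index=motifs,
            columns=["s1", "s2", "s3"],
        )
        frags = tile_fragments(prot)
        hits = align_motifs_to_proteome(motifs, prot, min_fixed=2)
        lm = fragment_alignment_load(hits, frags, abund)
        for f in frags:
            seq = entries[f.accession][f.start : f.end]
            present = sorted({
                m for m in motifs
                if any(f.start <= o and o + len(Pattern.parse(m)) <= f.end
                       for o in Pattern.parse(m).match(entries[f.accession]))
            })
            for s in ("s1", "s2", "s3"):
                expected = sum(abund.loc[m, s] for m in present) / len(present) if present else 0.0
                assert lm.per_subject.loc[f.key, s] == pytest.approx(expected)

    def test_load_scales_with_abundance(self):
        prot, frags, motifs, abund, hits = _simple_load_setup()
        lm1 = fragment_alignment_load(hits, frags, abund)
        lm2 = fragment_alignment_load(hits, frags, abund * 3.0)
        assert np.allclose(lm2.per_subject.to_numpy(), 3.0 * lm1.per_subject.to_numpy())


class TestTopFragments:
    def test_overlapping_frameshift_pair_merged_to_30aa(self):
        rng = np.random.default_rng(6)
        seq = random_sequence(rng, 140)
        seq = seq[:100] + "PAATAPRAAA" + "KPQLFGRAAA" + seq[120:]
        prot = proteome_of(p1=seq)
        frags = tile_fragments(prot)
        motifs = ["P..T.PR", "KP.LF.R"]
        abund = pd.DataFrame([[100.0], [90.0]], index=motifs, columns=["s1"])
        hits = align_motifs_to_proteome(motifs, prot)
        lm = fragment_alignment_load(hits, frags, abund)
        top, top_loads = select_top_fragments(lm, k=2, hits=hits, abundance=abund)
        merged = [f for f in top if f.frameshift is None]
        # the top-2 fragments are [90,110) (fs -10, load 100) and [100,120)
        # (fs 0, load 95): 10-aa overlap -> one 30-aa fragment [90,120) whose
        # load is recomputed over the merged span (both motifs: (100+90)/2)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (90, 120)
        assert top_loads[merged[0].key] == pytest.approx(95.0)

    def test_k_larger_than_fragment_count_returns_all(self):
        prot, frags, motifs, abund, hits = _simple_load_setup()
        lm = fragment_alignment_load(hits, frags, abund)
        top, _ = select_top_fragments(lm, k=1000, hits=hits, abundance=abund)
        assert len(top) <= len(frags)
        assert len({f.key for f in top}) == len(top)


class TestTargetTypes:
    def test_repeated_substring_counts_once(self):
        # 15 hits on the same site yield one unique substring -> below min_cluster
        rng = np.random.default_rng(7)
        seq = random_sequence(rng, 40)
        seq = seq[:10] + "PAATAPRAAAGG" + seq[22:]
        prot = proteome_of(p1=seq)
        frag = Fragment("p1", 0, 20, 0)
        hits = [AlignmentHit(Pattern.parse("P..T.PR"), "p1", 10)] * 15
        types = cluster_target_types([frag], hits, prot, min_cluster=2)
        assert types == []

    def test_similar_substrings_form_one_type_with_consensus(self):
        rng = np.random.default_rng(8)
        base = "PAATAPRAAAGG"
        prot_entries = {}
        frags, hits = [], []
        for i in range(12):
            mutated = list(base)
            # mutate up to 2 non-fixed positions
            for j in rng.choice([1, 2, 8, 9, 10, 11], size=2, replace=False):
                mutated[j] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
            seq = "".join(mutated) + random_sequence(rng, 28)
            acc = f"p{i}"
            prot_entries[acc] = seq
            frags.append(Fragment(acc, 0, 20, 0))
            hits.append(AlignmentHit(Pattern.parse("P..T.PR"), acc, 0))
        prot = Proteome(entries=prot_entries)
        types = cluster_target_types(frags, hits, prot, min_cluster=10)
        assert len(types) == 1
        t = types[0]
        assert len(t.member_substrings) >= 10
        # fixed positions of the planted pattern survive in the consensus
        assert re.fullmatch(r"P..T.PR.*", t.consensus.replace("[", "").replace("]", "")) or \
            "P" == t.consensus[0]

    def test_pwm_columns_sum_to_one(self):
        rng = np.random.default_rng(9)
        entries = {f"p{i}": random_sequence(rng, 60) for i in range(15)}
        prot = Proteome(entries=entries)
        frags = [Fragment(acc, 0, 20, 0) for acc in entries]
        hits = [AlignmentHit(Pattern.parse("A..A"), acc, 4) for acc in entries]
        types = cluster_target_types(frags, hits, prot, min_cluster=2, distance_cutoff=12)
        assert types
        for t in types:
            assert np.allclose(t.pwm.sum(axis=0), 1.0)

    def test_substring_extraction_clips_to_fragment(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        prot = proteome_of(p1=seq)
        frag = Fragment("p1", 0, 20, 0)
        # span [16, 20): centred window would overrun the fragment, so it is
        # shifted inward to [8, 20)
        hit = AlignmentHit(Pattern.parse("Q..T"), "p1", 16)
        assert extract_hit_substrings([frag], [hit], prot) == [seq[8:20]]
        # a hit whose span leaves the fragment is not extracted
        outside = AlignmentHit(Pattern.parse("Q..TV"), "p1", 16)
        assert extract_hit_substrings([frag], [outside], prot) == []
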