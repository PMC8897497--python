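import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from mvapipe.discovery import (
    discover_motifs,
    hypergeometric_enrichment,
    motif_abundance,
    select_group_differential,
    select_group_peptides,
    select_top_motifs,
    MotifRecord,
)
from mvapipe.io import CohortTable, SubjectRecord
from mvapipe.patterns import Pattern
from mvapipe.synthetic import labelled_peptide_set, random_peptides


def exact_hypergeom_tail(k, K, n, N) -> Fraction:
    """Independent rational-arithmetic oracle for the upper tail."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return total


class TestHypergeometric:
    def test_zero_matches_gives_one(self):
        assert hypergeometric_enrichment(0, 5, 10, 20) == 1.0

    def test_worked_example(self):
        # all 5 carriers drawn into a 10-of-20 sample: C(15,5)/C(20,10)
        assert hypergeometric_enrichment(5, 5, 10, 20) == pytest.approx(3003 / 184756, abs=1e-15)

    def test_matches_rational_oracle_small_sweep(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        p = hypergeometric_enrichment(k, K, n, N)
                        assert abs(p - float(exact_hypergeom_tail(k, K, n, N))) <= 1e-12

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(6, 5, 10, 20)
        with pytest.raises(ValueError):
            hypergeometric_enrichment(1, 25, 10, 20)


def _cohort(rows):
    """rows: (subject_id, perio_group, {peptide: count})"""
    subjects = [SubjectRecord(sid, "noCAD", per) for sid, per, _ in rows]
    counts = {(sid, pep): c for sid, _, prof in rows for pep, c in prof.items()}
    return CohortTable(counts=counts, subjects=subjects)


PEP = "TLPMDTSPRAHW"
PEP2 = "KPALFWRDCEHG"


class TestSelectGroupPeptides:
    def test_single_carrier_with_high_count_included(self):
        rows = [(f"s{i}", "P", {PEP: 12} if i == 0 else {PEP2: 1}) for i in range(10)]
        assert PEP in select_group_peptides(_cohort(rows), "P")

    def test_low_max_count_excluded(self):
        rows = [(f"s{i}", "P", {PEP: 9} if i < 2 else {PEP2: 1}) for i in range(10)]
        assert PEP not in select_group_peptides(_cohort(rows), "P")

    def test_presence_below_ten_percent_excluded(self):
        rows = [(f"s{i}", "P", {PEP: 50} if i == 0 else {PEP2: 1}) for i in range(11)]
        # 1 of 11 subjects < ceil(1.1) = 2
        assert PEP not in select_group_peptides(_cohort(rows), "P")

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            select_group_peptides(_cohort([("s1", "P", {PEP: 1})]), "X")

    def test_group_without_counts_gives_empty_set(self):
        rows = [("s1", "P", {PEP: 5}), ("s2", "H", {})]
        assert select_group_peptides(_cohort(rows), "H") == set()


class TestDiscoverMotifs:
    def test_recovers_planted_pattern(self):
        q, qflags = labelled_peptide_set(2000, "P..T.PR", 0.08, seed=1)
        r, _ = labelled_peptide_set(2000, "P..T.PR", 0.005, seed=2)
        recs = discover_motifs(q, r)
        carriers = {p for p, f in zip(q, qflags) if f}
        best = max(recs, key=lambda m: len(m.query_peptides & carriers))
        assert best.p_hyper < 1e-5
        assert len(best.query_peptides & carriers) >= 0.9 * len(carriers)

    def test_identical_query_and_reference_emit_nothing(self):
        rng = np.random.default_rng(5)
        peps = random_peptides(500, rng)
        assert discover_motifs(peps, peps) == []

    def test_three_fixed_positions_never_emitted(self):
        # an extremely enriched 3-fixed pattern must still be withheld
        q, _ = labelled_peptide_set(400, "W.W.W", 0.5, seed=3)
        rng = np.random.default_rng(4)
        r = random_peptides(400, rng)
        recs = discover_motifs(q, r)
        assert all(m.pattern.n_fixed >= 4 for m in recs)

    def test_invariant_to_input_order(self):
        q, _ = labelled_peptide_set(600, "P..T.PR", 0.1, seed=6)
        rng = np.random.default_rng(7)
        r = random_peptides(600, rng)
        recs1 = discover_motifs(q, r)
        recs2 = discover_motifs(list(reversed(q)), list(reversed(r)))
        assert [(str(m.pattern), m.query_coverage, m.p_hyper) for m in recs1] == [
            (str(m.pattern), m.query_coverage, m.p_hyper) for m in recs2
        ]

    def test_iterative_runs_cover_disjoint_peptides(self):
        q, _ = labelled_peptide_set(1500, "P..T.PR", 0.06, seed=8)
        q2, _ = labelled_peptide_set(1500, "KP.LF.R", 0.06, seed=9)
        query = q[:750] + q2[750:]
        rng = np.random.default_rng(10)
        ref = random_peptides(1500, rng)
        recs = discover_motifs(query, ref, n_iterations=2)
        # every emitted motif's covered query set was removed before later runs,
        # so identical patterns never recur
        pats = [str(m.pattern) for m in recs]
        assert len(pats) == len(set(pats))

    def test_empty_query_gives_empty_result(self):
        assert discover_motifs([], ["A" * 12]) == []


class TestSelectTopMotifs:
    def _rec(self, p, ratio):
        return MotifRecord(Pattern.parse("P..T.PR"), 10, 1, p, ratio)

    def test_low_p_kept_despite_low_ratio(self):
        assert select_top_motifs([self._rec(1e-9, 2.0)])

    def test_high_ratio_kept_despite_moderate_p(self):
        assert select_top_motifs([self._rec(1e-6, 12.0)])

    def test_neither_arm_dropped(self):
        assert select_top_motifs([self._rec(1e-6, 3.0)]) == []


class TestMotifAbundance:
    def test_sum_of_matching_peptide_counts(self):
        rows = [("s1", "P", {PEP: 5, "TLPADTSPRAHW": 7, PEP2: 100})]
        ab = motif_abundance(["P..T.PR"], _cohort(rows))
        assert ab.loc["P..T.PR", "s1"] == 12.0

    def test_non_matching_motif_zero_everywhere(self):
        rows = [("s1", "P", {PEP: 5}), ("s2", "H", {PEP2: 3})]
        ab = motif_abundance(["WWWW"], _cohort(rows))
        assert (ab.to_numpy() == 0).all()

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(12)
        peps = random_peptides(200, rng)
        rows = []
        for i in range(5):
            prof = {p: int(rng.integers(1, 50)) for p in peps if rng.random() < 0.3}
            rows.append((f"s{i}", "P", prof))
        cohort = _cohort(rows)
        pats = [Pattern.parse(s) for s in
                ["A..A", "C.D.E", "K...L", "P..T.PR", "GG", "W.Y", "M..N", "R.R", "ST", "FF.A"]]
        ab = motif_abundance([str(p) for p in pats], cohort)
        for pat in pats:
            for sid, _, prof in rows:
                expected = sum(c for pep, c in prof.items() if pat.matches(pep))
                assert ab.loc[str(pat), sid] == expected


class TestGroupDifferential:
    def _abundance(self, a_vals, b_vals):
        subjects = [SubjectRecord(f"a{i}", "noCAD", "P") for i in range(len(a_vals))] + [
            SubjectRecord(f"b{i}", "noCAD", "H") for i in range(len(b_vals))
        ]
        cols = [f"a{i}" for i in range(len(a_vals))] + [f"b{i}" for i in range(len(b_vals))]
        ab = pd.DataFrame([list(a_vals) + list(b_vals)], index=["P..T.PR"], columns=cols)
        return ab, subjects

    def test_perfectly_separated_toy_passes_all_criteria(self):
        ab, subjects = self._abundance([100, 100, 100, 100], [10, 10, 10, 10])
        sel, table = select_group_differential(ab, subjects, ("P", "H"), return_table=True)
        assert [str(p) for p in sel] == ["P..T.PR"]
        row = table.iloc[0]
        assert row["fold_pass"] and row["sens_spec_pass"] and row["mwu_pass"]
        # exact two-sided MWU p over the C(8,4) splits
        assert row["mwu_p"] == pytest.approx(2 / 70)

    def test_identical_distributions_dropped(self):
        ab, subjects = self._abundance([5, 9, 7, 8], [9, 7, 5, 8])
        assert select_group_differential(ab, subjects, ("P", "H")) == []

    def test_interleaved_values_fail_sens_spec_criterion(self):
        # fold >> 3 but best achievable is (sens 1.0, spec 0.5): any threshold
        # with spec >= 0.7 leaves sens at 0.25
        ab, subjects = self._abundance([100, 1, 1, 2], [0.5, 0.6, 3, 3.5])
        sel, table = select_group_differential(ab, subjects, ("P", "H"), return_table=True)
        row = table.iloc[0]
        assert row["fold_pass"]
        assert not row["sens_spec_pass"]
        assert sel == []

    def test_small_group_rejected(self):
        ab, subjects = self._abundance([1, 2, 3], [])
        with pytest.raises(ValueError):
            select_group_differential(ab, subjects, ("P", "H"))

    def test_exact_mwu_matches_enumeration_with_ties(self):
        from mvapipe.discovery import _mwu_two_sided

        x = np.array([3.0, 3.0, 5.0, 7.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        # enumerate all C(8,4) group assignments of the pooled values
        pooled = np.concatenate([x, y])
        u_obs = np.sum(x[:, None] > y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :])
        dev = abs(u_obs - 8.0)
        hits = total = 0
        for sel in itertools.combinations(range(8), 4):
            xs = pooled[list(sel)]
            ys = np.delete(pooled, list(sel))
            u = np.sum(xs[:, None] > ys[None, :]) + 0.5 * np.sum(xs[:, None] == ys[None, :])
            total += 1
            hits += abs(u - 8.0) >= dev - 1e-9
        assert _mwu_two_sided(x, y) == pytest.approx(hits / total)
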