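"""Exhaustive wildcard-motif discovery and the motif selection funnel.

The discovery stage re-implements an exhaustive SPEXS-style pattern search:
patterns made of fixed residues and single-position wildcards are grown left
to right over a trie, pruning on query coverage (which is anti-monotone under
extension), and scored by the hypergeometric upper-tail probability of their
query-vs-reference coverage.  The funnel around it mirrors the study design:

1. ``select_group_peptides`` — group-enriched "TopPeptide" sets: present in
   >=10% of the group's subjects with >=10 reads in at least one sample.
2. ``discover_motifs`` — motifs with >=4 fixed positions, query coverage >=4
   and hypergeometric p < 1e-5, in iterative runs that remove covered query
   peptides between runs.
3. ``select_top_motifs`` — the strict "TopMotif" filter: p < 1e-8 OR
   query/reference ratio >= 10.
4. ``select_group_differential`` — motifs whose per-subject abundance
   separates a clinical contrast: >3-fold mean difference, a threshold with
   >=50% sensitivity and >=70% specificity, and two-sided Mann-Whitney U
   p < 0.05.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .io import CohortTable, SubjectRecord
from .patterns import AMINO_ACIDS, Pattern

__all__ = [
    "MotifRecord",
    "SearchParams",
    "select_group_peptides",
    "hypergeometric_enrichment",
    "discover_motifs",
    "select_top_motifs",
    "motif_abundance",
    "select_group_differential",
    "DifferentialCriteria",
]


@dataclass(frozen=True)
class MotifRecord:
    """An emitted motif with its enrichment statistics."""

    pattern: Pattern
    query_coverage: int
    ref_coverage: int
    p_hyper: float
    enrichment_ratio: float
    query_peptides: frozenset = field(default=frozenset(), repr=False, compare=False)


def select_group_peptides(cohort: CohortTable, group: str) -> set[str]:
    """Group-enriched peptides (the TopPeptide set) for one clinical label.

    A peptide qualifies when it is present (count > 0) in at least 10% of the
    group's subjects (ceiling) and reaches >= 10 reads in at least one of
    them.
    """
    members = cohort.group_subjects(group)  # raises on unknown label
    if not members:
        raise ValueError(f"group {group!r} has no subjects")
    need = math.ceil(0.1 * len(members))
    presence: dict[str, int] = {}
    maxcount: dict[str, int] = {}
    by_subject = cohort.by_subject()
    for sid in members:
        for pep, c in by_subject[sid].items():
            if c > 0:
                presence[pep] = presence.get(pep, 0) + 1
                if c > maxcount.get(pep, 0):
                    maxcount[pep] = c
    return {p for p, n in presence.items() if n >= need and maxcount[p] >= 10}


def hypergeometric_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    ``k`` query matches out of ``n`` query peptides, ``K`` total matches out
    of ``N`` total peptides.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if K > N or n > N or k > min(K, n):
        raise ValueError(f"inconsistent margins k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    ks = np.arange(k, min(K, n) + 1)
    logp = stats.hypergeom.logpmf(ks, N, K, n)
    return float(min(1.0, math.exp(logsumexp(logp))))


@dataclass
class SearchParams:
    """Tuning knobs of the exhaustive pattern search."""

    min_query_coverage: int = 4
    min_fixed_positions: int = 4
    p_threshold: float = 1e-5
    max_consecutive_wildcards: int = 3
    max_pattern_length: int = 12


def _root_occurrences(peps: list[str]) -> dict[str, list[tuple[int, int]]]:
    occ: dict[str, list[tuple[int, int]]] = {c: [] for c in AMINO_ACIDS}
    for i, pep in enumerate(peps):
        for j, ch in enumerate(pep):
            occ[ch].append((i, j))
    return occ


def _coverage(occ: list[tuple[int, int]]) -> int:
    return len({i for i, _ in occ})


def _search_once(qpeps: list[str], rpeps: list[str], params: SearchParams,
                 n_query_total: int, n_ref_total: int) -> list[MotifRecord]:
    nq, nr = len(qpeps), len(rpeps)
    if nq == 0:
        return []
    qlen = [len(p) for p in qpeps]
    rlen = [len(p) for p in rpeps]
    minq = params.min_query_coverage
    maxg = params.max_consecutive_wildcards
    maxlen = params.max_pattern_length

    qroot = _root_occurrences(qpeps)
    rroot = _root_occurrences(rpeps)
    queue: deque = deque()
    for c in AMINO_ACIDS:
        qocc = qroot[c]
        if _coverage(qocc) >= minq:
            queue.append((c, 1, qocc, rroot[c]))

    emitted: list[MotifRecord] = []
    N = n_query_total + n_ref_total
    while queue:
        pat, nfixed, qocc, rocc = queue.popleft()
        L = len(pat)
        qcov = _coverage(qocc)
        # coverage is anti-monotone: every node was admitted at >= minq and
        # children below can only shrink its occurrence list
        if nfixed >= params.min_fixed_positions:
            rcov = _coverage(rocc)
            p = hypergeometric_enrichment(qcov, qcov + rcov, n_query_total, N)
            if p < params.p_threshold:
                ratio = (qcov / n_query_total) / (max(rcov, 1) / max(n_ref_total, 1))
                emitted.append(
                    MotifRecord(
                        pattern=Pattern.parse(pat),
                        query_coverage=qcov,
                        ref_coverage=rcov,
                        p_hyper=p,
                        enrichment_ratio=ratio,
                        query_peptides=frozenset(qpeps[i] for i, _ in qocc),
                    )
                )
        for g in range(0, maxg + 1):
            if L + g + 1 > maxlen:
                break
            children: dict[str, list[tuple[int, int]]] = {}
            for pi, st in qocc:
                pos = st + L + g
                if pos < qlen[pi]:
                    children.setdefault(qpeps[pi][pos], []).append((pi, st))
            surviving = {c: o for c, o in children.items() if _coverage(o) >= minq}
            if not surviving:
                continue
            rchildren: dict[str, list[tuple[int, int]]] = {c: [] for c in surviving}
            for pi, st in rocc:
                pos = st + L + g
                if pos < rlen[pi]:
                    c = rpeps[pi][pos]
                    if c in rchildren:
                        rchildren[c].append((pi, st))
            gap = "." * g
            for c in sorted(surviving):
                child_occ = surviving[c]
                assert _coverage(child_occ) <= qcov
                queue.append((pat + gap + c, nfixed + 1, child_occ, rchildren[c]))
    return emitted


def _deduplicate(emitted: list[MotifRecord]) -> list[MotifRecord]:
    """Keep, per identical query match set, only the most specific patterns."""
    groups: dict[frozenset, list[MotifRecord]] = {}
    for rec in emitted:
        groups.setdefault(rec.query_peptides, []).append(rec)
    kept: list[MotifRecord] = []
    for recs in groups.values():
        top = max(r.pattern.n_fixed for r in recs)
        best = [r for r in recs if r.pattern.n_fixed == top]
        best.sort(key=lambda r: (-len(r.pattern), str(r.pattern)))
        kept.append(best[0])
    kept.sort(key=lambda r: (r.p_hyper, -r.query_coverage, str(r.pattern)))
    return kept


def discover_motifs(query, reference, params: SearchParams | None = None,
                    n_iterations: int = 2) -> list[MotifRecord]:
    """Exhaustive pattern search of ``query`` against ``reference`` peptides.

    Runs ``n_iterations`` passes; after each pass, query peptides covered by
    any emitted motif are removed and the search restarts on the remainder.
    Deterministic regardless of input order (peptides are canonically
    sorted).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    params = params or SearchParams()
    qpeps = sorted(set(query))
    rpeps = sorted(set(reference))
    results: list[MotifRecord] = []
    for _ in range(n_iterations):
        if not qpeps:
            break
        emitted = _search_once(qpeps, rpeps, params, len(qpeps), len(rpeps))
        emitted = _deduplicate(emitted)
        if not emitted:
            break
        results.extend(emitted)
        covered = set().union(*(r.query_peptides for r in emitted))
        qpeps = [p for p in qpeps if p not in covered]
    return results


def select_top_motifs(motifs: list[MotifRecord], p_threshold: float = 1e-8,
                      ratio_threshold: float = 10.0) -> list[MotifRecord]:
    """The strict TopMotif filter: p < 1e-8 OR query/reference ratio >= 10."""
    return [m for m in motifs if m.p_hyper < p_threshold or m.enrichment_ratio >= ratio_threshold]


def motif_abundance(motifs, cohort: CohortTable) -> pd.DataFrame:
    """Motif x subject abundance: sum of counts of peptides containing the motif.

    Returns a DataFrame indexed by pattern string, one column per subject.
    """
    pats = [m if isinstance(m, Pattern) else Pattern.parse(str(m)) for m in motifs]
    keys = [str(p) for p in pats]
    regs = [p.compiled() for p in pats]
    subjects = cohort.subject_ids
    mat = np.zeros((len(pats), len(subjects)), dtype=float)
    match_cache: dict[str, list[int]] = {}
    by_subject = cohort.by_subject()
    for j, sid in enumerate(subjects):
        for pep, c in by_subject[sid].items():
            hit = match_cache.get(pep)
            if hit is None:
                hit = [i for i, rg in enumerate(regs) if rg.search(pep)]
                match_cache[pep] = hit
            for i in hit:
                mat[i, j] += c
    return pd.DataFrame(mat, index=keys, columns=subjects)


@dataclass
class DifferentialCriteria:
    """Criteria for calling a motif group-differential."""

    fold: float = 3.0
    min_sens: float = 0.5
    min_spec: float = 0.7
    alpha: float = 0.05


def _mwu_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p: exact enumeration when both groups <= 8,
    tie-corrected normal approximation otherwise."""
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("Mann-Whitney U needs >= 2 subjects per group")
    if n1 <= 8 and n2 <= 8:
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)

        def ustat(sel: tuple) -> float:
            xs = pooled[list(sel)]
            ys = np.delete(pooled, list(sel))
            return float(np.sum(xs[:, None] > ys[None, :]) + 0.5 * np.sum(xs[:, None] == ys[None, :]))

        u_obs = float(np.sum(x[:, None] > y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :]))
        center = n1 * n2 / 2.0
        dev = abs(u_obs - center)
        hits = total = 0
        for sel in itertools.combinations(idx, n1):
            total += 1
            if abs(ustat(sel) - center) >= dev - 1e-9:
                hits += 1
        return hits / total
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def _best_sens_spec(pos: np.ndarray, neg: np.ndarray) -> list[tuple[float, float]]:
    """(sensitivity, specificity) at every candidate '>= threshold' cut, where
    positives are expected high."""
    out = []
    for t in np.unique(np.concatenate([pos, neg])):
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        out.append((sens, spec))
    return out


def select_group_differential(abundance: pd.DataFrame, subjects: list[SubjectRecord],
                              contrast: tuple[str, str],
                              criteria: DifferentialCriteria | None = None,
                              return_table: bool = False):
    """Motifs whose abundance separates the two contrast groups.

    A motif is kept iff (i) its mean abundance in one group is more than
    ``fold`` times the other's, (ii) some abundance threshold separates the
    groups with sensitivity >= ``min_sens`` and specificity >= ``min_spec``
    (">= threshold" calls the higher-mean group), and (iii) the two-sided
    Mann-Whitney U p-value is below ``alpha``.
    """
    criteria = criteria or DifferentialCriteria()
    by_id = {s.subject_id: s for s in subjects}
    ga, gb = contrast

    def members(g):
        if g in ("noCAD", "sCAD", "ACS", "no-CAD", "s-CAD"):
            return [sid for sid, s in by_id.items() if s.cad_group == g.replace("-", "")]
        return [sid for sid, s in by_id.items() if s.perio_group == g]

    ids_a = [s for s in members(ga) if s in abundance.columns]
    ids_b = [s for s in members(gb) if s in abundance.columns]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each contrast group needs >= 2 subjects with abundance data")

    rows = []
    selected: list[Pattern] = []
    for pat_str, row in abundance.iterrows():
        a = row[ids_a].to_numpy(dtype=float)
        b = row[ids_b].to_numpy(dtype=float)
        ma, mb = a.mean(), b.mean()
        if ma >= mb:
            fold_pass = mb == 0 and ma > 0 or (mb > 0 and ma / mb > criteria.fold)
            pos, neg = a, b
        else:
            fold_pass = ma == 0 and mb > 0 or (ma > 0 and mb / ma > criteria.fold)
            pos, neg = b, a
        ss_pass = any(
            s >= criteria.min_sens and sp >= criteria.min_spec for s, sp in _best_sens_spec(pos, neg)
        )
        if ma == mb == 0:
            fold_pass = ss_pass = False
            p = 1.0
        else:
            p = _mwu_two_sided(a, b)
        mwu_pass = p < criteria.alpha
        keep = fold_pass and ss_pass and mwu_pass
        rows.append((pat_str, ma, mb, fold_pass, ss_pass, p, mwu_pass, keep))
        if keep:
            selected.append(Pattern.parse(pat_str))
    table = pd.DataFrame(
        rows,
        columns=["pattern", f"mean_{ga}", f"mean_{gb}", "fold_pass", "sens_spec_pass",
                 "mwu_p", "mwu_pass", "selected"],
    ).set_index("pattern")
    if return_table:
        return selected, table
    return selected
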