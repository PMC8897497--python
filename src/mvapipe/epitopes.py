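"""Epitope clustering.

Group-differential motifs are first clustered by sequence homology: two
motifs belong together when, at some ungapped relative offset, they share at
least 3 identical fixed residues (single-linkage components; components with
fewer than 3 motifs are set aside as unclustered).  Cluster abundances per
subject count each peptide once even when several member motifs match it.

Cluster-level summaries follow the study's two views:

* a group-normalised abundance matrix (each cluster's mean abundance per
  clinical stratum, divided by the cluster's cross-group mean; clusters with
  cross-group mean below ``min_mean`` are dropped), and
* correlation-defined epitope groups: per-subject cluster abundances on a
  log10(x+1) scale, pairwise Pearson R, distance 1 - R, Ward-D2
  agglomeration cut at ``k`` groups, labelled A, B, ... in descending total
  abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import CohortTable
from .patterns import Pattern, consensus_from_pwm


@dataclass
class MotifCluster:
    """A homology cluster of motifs sharing >= 3 identical fixed residues."""

    cluster_id: int
    members: list[Pattern]
    consensus: str
    per_subject_abundance: pd.Series | None = None


@dataclass
class EpitopeGroup:
    """A correlation-defined super-group of motif clusters (epitope A, B, ...)."""

    label: str
    cluster_ids: frozenset
    core_consensus: str
    per_subject_abundance: pd.Series = field(default=None)


def pattern_similarity(a: Pattern, b: Pattern) -> int:
    """Max over ungapped offsets of the number of positions where both
    patterns carry the same fixed residue."""
    ea, eb = a.elements, b.elements
    best = 0
    for off in range(-(len(eb) - 1), len(ea)):
        shared = 0
        for j in range(len(eb)):
            i = off + j
            if 0 <= i < len(ea):
                x, y = ea[i], eb[j]
                if x is not None and y is not None and len(x) == 1 and x == y:
                    shared += 1
        best = max(best, shared)
    return best


def _pattern_pwm(patterns: list[Pattern]) -> list[dict[str, float]]:
    """Position-frequency columns from member patterns aligned (ungapped) to
    the longest member at their best-matching offset.  Fixed residues count
    1, class residues 1/|class|, wildcards nothing."""
    ref = max(patterns, key=lambda p: (len(p), str(p)))
    placements = []
    lo, hi = 0, len(ref)
    for p in patterns:
        best_off, best_sim = 0, -1
        for off in range(-(len(p) - 1), len(ref)):
            sim = 0
            for j, e in enumerate(p.elements):
                i = off + j
                if 0 <= i < len(ref) and e is not None and ref.elements[i] is not None \
                        and len(e) == 1 and e == ref.elements[i]:
                    sim += 1
            if sim > best_sim or (sim == best_sim and abs(off) < abs(best_off)):
                best_off, best_sim = off, sim
        placements.append((p, best_off))
        lo = min(lo, best_off)
        hi = max(hi, best_off + len(p))
    counts: list[dict[str, float]] = [{} for _ in range(hi - lo)]
    for p, off in placements:
        for j, e in enumerate(p.elements):
            if e is None:
                continue
            col = counts[off - lo + j]
            w = 1.0 / len(e)
            for r in e:
                col[r] = col.get(r, 0.0) + w
    pwm = []
    for col in counts:
        tot = sum(col.values())
        pwm.append({r: v / tot for r, v in col.items()} if tot > 0 else {})
    return pwm


def cluster_motifs_by_homology(motifs: list[Pattern], min_shared: int = 3,
                               min_cluster: int = 3) -> tuple[list[MotifCluster], list[Pattern]]:
    """Single-linkage homology components over motif pairs sharing
    >= ``min_shared`` identical fixed residues; components smaller than
    ``min_cluster`` are returned separately as unclustered."""
    pats = sorted(set(motifs), key=str)
    n = len(pats)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if pattern_similarity(pats[i], pats[j]) >= min_shared:
                parent[find(i)] = find(j)
    comps: dict[int, list[Pattern]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(pats[i])
    groups = sorted(comps.values(), key=lambda g: (-len(g), str(g[0])))
    clusters: list[MotifCluster] = []
    unclustered: list[Pattern] = []
    cid = 0
    for g in groups:
        if len(g) >= min_cluster:
            cid += 1
            clusters.append(MotifCluster(
                cluster_id=cid,
                members=sorted(g, key=str),
                consensus=consensus_from_pwm(_pattern_pwm(g), columns=None),
            ))
        else:
            unclustered.extend(g)
    return clusters, sorted(unclustered, key=str)


def attach_cluster_abundance(clusters: list[MotifCluster], cohort: CohortTable) -> pd.DataFrame:
    """Per-subject abundance per cluster: sum of counts of peptides matched by
    at least one member motif (each peptide counted once).  Fills each
    cluster's ``per_subject_abundance`` and returns the cluster x subject
    DataFrame."""
    subjects = cohort.subject_ids
    regs = [[m.compiled() for m in cl.members] for cl in clusters]
    mat = np.zeros((len(clusters), len(subjects)))
    cache: dict[str, list[int]] = {}
    by_subject = cohort.by_subject()
    for j, sid in enumerate(subjects):
        for pep, c in by_subject[sid].items():
            hit = cache.get(pep)
            if hit is None:
                hit = [i for i, rgs in enumerate(regs) if any(r.search(pep) for r in rgs)]
                cache[pep] = hit
            for i in hit:
                mat[i, j] += c
    df = pd.DataFrame(mat, index=[cl.cluster_id for cl in clusters], columns=subjects)
    for cl in clusters:
        cl.per_subject_abundance = df.loc[cl.cluster_id]
    return df


def default_grouping(cohort: CohortTable) -> dict[str, list[str]]:
    """The study's presentation strata: 3 CAD groups, 3 periodontal groups,
    smoking -/+ (never vs any exposure), diabetes -/+."""
    g: dict[str, list[str]] = {
        "noCAD": [], "sCAD": [], "ACS": [], "H": [], "G": [], "P": [],
        "smoking-": [], "smoking+": [], "DM-": [], "DM+": [],
    }
    for s in cohort.subjects:
        g[s.cad_group].append(s.subject_id)
        g[s.perio_group].append(s.subject_id)
        g["smoking+" if s.smoking_exposed else "smoking-"].append(s.subject_id)
        g["DM+" if s.diabetes else "DM-"].append(s.subject_id)
    return g


def group_abundance_matrix(clusters: list[MotifCluster], cohort: CohortTable,
                           grouping: dict[str, list[str]] | None = None,
                           min_mean: float = 150.0) -> pd.DataFrame:
    """Group-normalised cluster abundance matrix (clusters x strata).

    cell(c, g) = mean cluster abundance over the stratum's subjects, divided
    by the cluster's mean cell value across strata.  Clusters whose
    cross-group mean is below ``min_mean`` are dropped before normalisation.
    Row and column orderings for presentation (Ward-D2 on Pearson-correlation
    distance) are attached as ``df.attrs['row_order']``/``['col_order']``.
    """
    grouping = grouping or default_grouping(cohort)
    for name, members in grouping.items():
        if not members:
            raise ValueError(f"stratum {name!r} is empty")
    if any(cl.per_subject_abundance is None for cl in clusters):
        attach_cluster_abundance(clusters, cohort)
    raw = pd.DataFrame(
        {
            name: [float(cl.per_subject_abundance[members].mean()) for cl in clusters]
            for name, members in grouping.items()
        },
        index=[cl.cluster_id for cl in clusters],
    )
    cross_mean = raw.mean(axis=1)
    raw = raw.loc[cross_mean >= min_mean]
    norm = raw.div(raw.mean(axis=1), axis=0)
    for axis_name, data in (("row_order", norm.to_numpy()), ("col_order", norm.to_numpy().T)):
        order = list(range(data.shape[0]))
        if data.shape[0] > 2 and data.shape[1] > 1:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                corr = np.corrcoef(data)
            corr = np.nan_to_num(corr, nan=0.0)
            np.fill_diagonal(corr, 1.0)
            dist = np.clip(1.0 - corr, 0.0, 2.0)
            link = hierarchy.linkage(squareform(dist, checks=False), method="ward")
            order = list(hierarchy.leaves_list(link))
        norm.attrs[axis_name] = order
    return norm


def define_epitopes(clusters: list[MotifCluster], cohort: CohortTable,
                    k: int = 5) -> tuple[list[EpitopeGroup], pd.DataFrame]:
    """Unite motif clusters into ``k`` correlation-defined epitope groups.

    Per-subject cluster abundances on log10(x+1) scale; pairwise Pearson R;
    distance 1 - R; Ward-D2 tree cut at ``k``.  Groups are labelled A, B, ...
    in descending total abundance.  Returns the groups and the full
    correlation matrix (clusters x clusters).
    """
    if len(clusters) < k:
        raise ValueError(f"need >= k={k} clusters, got {len(clusters)}")
    if any(cl.per_subject_abundance is None for cl in clusters):
        attach_cluster_abundance(clusters, cohort)
    ids = [cl.cluster_id for cl in clusters]
    X = np.log10(np.vstack([cl.per_subject_abundance.to_numpy(dtype=float) for cl in clusters]) + 1.0)
    sd = X.std(axis=1)
    flat_mask = sd < 1e-10
    if np.any(flat_mask):
        flat = [ids[i] for i in np.nonzero(flat_mask)[0]]
        warnings.warn(f"constant abundance vector for cluster(s) {flat}; correlation set to 0")
    with np.errstate(all="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[flat_mask, :] = 0.0
    corr[:, flat_mask] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=ids, columns=ids)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    assignment = hierarchy.fcluster(link, t=k, criterion="maxclust")
    by_id = {cl.cluster_id: cl for cl in clusters}
    groups: dict[int, list[int]] = {}
    for cid, a in zip(ids, assignment):
        groups.setdefault(int(a), []).append(cid)
    totals = {
        a: sum(float(by_id[c].per_subject_abundance.sum()) for c in members)
        for a, members in groups.items()
    }
    order = sorted(groups, key=lambda a: (-totals[a], min(groups[a])))
    out: list[EpitopeGroup] = []
    for rank, a in enumerate(order):
        label = chr(ord("A") + rank)
        member_ids = sorted(groups[a])
        member_patterns = []
        for c in member_ids:
            try:
                member_patterns.append(Pattern.parse(by_id[c].consensus))
            except ValueError:
                continue  # consensus degenerated to classes/wildcards only
        core = consensus_from_pwm(_pattern_pwm(member_patterns)) if member_patterns else ""
        abund = sum(by_id[c].per_subject_abundance for c in member_ids)
        out.append(EpitopeGroup(
            label=label,
            cluster_ids=frozenset(member_ids),
            core_consensus=core,
            per_subject_abundance=abund,
        ))
    return out, corr_df
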