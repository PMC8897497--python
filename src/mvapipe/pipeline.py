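"""End-to-end pipeline on a synthetic study.

Chains every stage — cohort generation, TopPeptide selection, motif
discovery, the TopMotif and group-differential filters, homology/epitope
clustering, proteome scanning, the target-antigen profile and the two-step
biomarker model — into a single deterministic run.  Problem sizes default to
a desk-scale study (full 96-subject design, ~1200 distinct peptides per
subject) so a complete run takes well under a minute; all sizes are config.

The biomarker features A..E are the per-subject abundances of peptides
containing each planted core pattern, so the model stage is well-defined
even when a scaled-down discovery run recovers only part of the plants.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import pandas as pd

from . import antigen, biomarker, discovery, epitopes, proteome as proteome_mod, synthetic
from .io import CohortTable, Proteome
from .patterns import Pattern

DEFAULT_EPITOPE_SEQUENCE_LENGTH = 24


def default_plants(seed: int = 0) -> list[synthetic.PlantSpec]:
    """Five planted effects mirroring the epitope A..E sign structure."""
    import numpy as np

    rng = np.random.default_rng(seed)
    pat_a = Pattern.parse("P..T.PR")
    epi = synthetic.instantiate_pattern(pat_a, rng, length=DEFAULT_EPITOPE_SEQUENCE_LENGTH)
    return [
        synthetic.PlantSpec(pat_a, {"P": 0.02, "H": 0.002, "P:noCAD": 0.05, "G:ACS": 0.04},
                            abundance_boost=8.0, responder_subject_fraction=0.9,
                            source_sequence=epi),
        synthetic.PlantSpec(Pattern.parse("KP.LF.R"), {"P": 0.015, "H": 0.002},
                            abundance_boost=6.0, responder_subject_fraction=0.9),
        synthetic.PlantSpec(Pattern.parse("N.SF.KL"), {"H": 0.015, "P": 0.002, "H:ACS": 0.04},
                            abundance_boost=6.0, responder_subject_fraction=0.9),
        synthetic.PlantSpec(Pattern.parse("GQ.W.DA"), {"G": 0.015}, abundance_boost=6.0,
                            responder_subject_fraction=0.9),
        synthetic.PlantSpec(Pattern.parse("W.RD.EH"), {"P:noCAD": 0.03}, abundance_boost=6.0,
                            responder_subject_fraction=0.9),
    ]


@dataclass
class PipelineConfig:
    cohort: synthetic.CohortConfig = field(default_factory=lambda: synthetic.CohortConfig(
        library_size=1200, universe_size=12_000, shared_fraction=0.5, plant_pool_size=150,
    ))
    proteome: synthetic.ProteomeConfig = field(default_factory=lambda: synthetic.ProteomeConfig(
        n_proteins=30, mean_length=250,
    ))
    discovery_groups: tuple = ("H", "G", "P")
    search: discovery.SearchParams = field(default_factory=discovery.SearchParams)
    n_iterations: int = 2
    contrast: tuple = ("P", "H")
    top_k_fragments: int = 40
    epitope_k: int = 5
    target_type_min_cluster: int = 10


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0) -> dict:
    """Run the full synthetic-study pipeline; returns a dict of results."""
    config = config or PipelineConfig()
    plants = default_plants(seed)
    cohort, truth = synthetic.generate_cohort(config.cohort, plants, seed)
    prot = synthetic.plant_proteome(config.proteome, truth, seed + 1)

    top_peptides = {g: discovery.select_group_peptides(cohort, g) for g in config.discovery_groups}
    motifs: list[discovery.MotifRecord] = []
    per_group_counts = {}
    for g in config.discovery_groups:
        ref = set().union(*(top_peptides[h] for h in config.discovery_groups if h != g))
        recs = discovery.discover_motifs(top_peptides[g], ref, config.search, config.n_iterations)
        per_group_counts[g] = len(recs)
        motifs.extend(recs)
    top_motifs = discovery.select_top_motifs(motifs)
    unique_patterns = sorted({str(m.pattern) for m in top_motifs})

    abundance = discovery.motif_abundance(unique_patterns, cohort)
    differential, diff_table = discovery.select_group_differential(
        abundance, cohort.subjects, config.contrast, return_table=True
    )

    clusters, unclustered = epitopes.cluster_motifs_by_homology(differential)
    epitope_groups, corr = [], pd.DataFrame()
    if len(clusters) >= config.epitope_k:
        epitopes.attach_cluster_abundance(clusters, cohort)
        epitope_groups, corr = epitopes.define_epitopes(clusters, cohort, k=config.epitope_k)

    fragments = proteome_mod.tile_fragments(prot)
    scan_patterns = unique_patterns or [str(p.pattern) for p in plants]
    scan_abund = discovery.motif_abundance(scan_patterns, cohort)
    hits = proteome_mod.align_motifs_to_proteome(scan_patterns, prot)
    loads = proteome_mod.fragment_alignment_load(hits, fragments, scan_abund)
    top_frags, top_loads = proteome_mod.select_top_fragments(
        loads, k=config.top_k_fragments, hits=hits, abundance=scan_abund
    )
    target_types = proteome_mod.cluster_target_types(
        top_frags, hits, prot, min_cluster=config.target_type_min_cluster
    )

    target_seq = prot.entries[truth.target_accession]
    pooled = cohort.peptides()
    pooled_profile = antigen.signal_to_random_profile(pooled, target_seq, seed + 2)
    lo, hi = truth.planted_target_epitope
    by_subject = cohort.by_subject()
    subj_ratio = {
        sid: float(antigen.signal_to_random_profile(
            set(by_subject[sid]), target_seq, seed + 3).ratio[lo:hi].mean())
        for sid in cohort.subject_ids
    }

    features = pd.DataFrame({
        label: antigen.epitope_containing_abundance(cohort, spec.pattern)
        for label, spec in zip("ABCDE", plants)
    })
    capped = biomarker.cap_normalize_features(features)
    perio = pd.Series({s.subject_id: s.perio_group for s in cohort.subjects})
    cad = pd.Series({s.subject_id: s.cad_group for s in cohort.subjects})
    model = biomarker.fit_two_step(capped, perio, cad, seed=seed, n_bootstrap=500)

    return {
        "cohort": cohort,
        "truth": truth,
        "proteome": prot,
        "top_peptides": top_peptides,
        "motifs": motifs,
        "per_group_motif_counts": per_group_counts,
        "top_motifs": top_motifs,
        "abundance": abundance,
        "differential": differential,
        "differential_table": diff_table,
        "clusters": clusters,
        "unclustered": unclustered,
        "epitope_groups": epitope_groups,
        "epitope_correlation": corr,
        "top_fragments": top_frags,
        "top_fragment_loads": top_loads,
        "target_types": target_types,
        "pooled_profile": pooled_profile,
        "subject_epitope_ratio": subj_ratio,
        "features": features,
        "model": model,
    }


def serialize_results(result: dict) -> dict[str, str]:
    """Canonical TSV/text renderings of the pipeline outputs (used both for
    writing files and for byte-level determinism checks)."""

    def tsv(df: pd.DataFrame) -> str:
        buf = _io.StringIO()
        df.to_csv(buf, sep="\t", float_format="%.10g")
        return buf.getvalue()

    cohort: CohortTable = result["cohort"]
    counts_df, meta_df = cohort.to_frames()
    model = result["model"]
    model_lines = [
        "feature\tcoef",
        *(f"{f}\t{c:.10g}" for f, c in zip(model.step1.feature_names, model.step1.coef)),
        f"intercept\t{model.step1.intercept:.10g}",
        f"threshold\t{model.step1.threshold:.10g}",
        f"train_balanced_accuracy\t{model.step1.train_balanced_accuracy:.10g}",
        f"validation_balanced_accuracy\t{model.step1.validation_balanced_accuracy:.10g}",
        f"auroc\t{model.step1.auroc:.10g}",
        f"auroc_ci\t{model.step1.auroc_ci[0]:.10g},{model.step1.auroc_ci[1]:.10g}",
    ]
    for stratum, rules in sorted(model.step2.items()):
        for r in rules:
            model_lines.append(
                f"step2:{stratum}:{r.feature}\t{r.call_if_positive} if {r.direction} "
                f"{r.threshold:.10g} (sens {r.sensitivity:.3f}, spec {r.specificity:.3f})"
            )
    out = {
        "counts.tsv": tsv(counts_df.set_index("subject_id")),
        "metadata.tsv": tsv(meta_df.set_index("subject_id")),
        "motifs.tsv": tsv(pd.DataFrame(
            [(str(m.pattern), m.query_coverage, m.ref_coverage, m.p_hyper, m.enrichment_ratio)
             for m in result["top_motifs"]],
            columns=["pattern", "query_coverage", "ref_coverage", "p_hyper", "enrichment_ratio"],
        ).set_index("pattern")),
        "differential.tsv": tsv(result["differential_table"]),
        "clusters.tsv": tsv(pd.DataFrame(
            [(cl.cluster_id, ",".join(str(m) for m in cl.members), cl.consensus)
             for cl in result["clusters"]],
            columns=["cluster_id", "members", "consensus"],
        ).set_index("cluster_id")),
        "epitopes.tsv": tsv(pd.DataFrame(
            [(e.label, ",".join(str(c) for c in sorted(e.cluster_ids)), e.core_consensus)
             for e in result["epitope_groups"]],
            columns=["epitope", "cluster_ids", "core_consensus"],
        ).set_index("epitope")),
        "top_fragments.tsv": tsv(pd.DataFrame(
            [(f.accession, f.start, f.end,
              "merged" if f.frameshift is None else f.frameshift,
              result["top_fragment_loads"][f.key]) for f in result["top_fragments"]],
            columns=["accession", "start", "end", "frameshift", "total_load"],
        ).set_index("accession")),
        "target_types.tsv": tsv(pd.DataFrame(
            [(i + 1, t.consensus, len(t.member_substrings))
             for i, t in enumerate(result["target_types"])],
            columns=["target_type", "consensus", "n_substrings"],
        ).set_index("target_type")),
        "profile.tsv": tsv(result["pooled_profile"].to_frame().set_index("position")),
        "features.tsv": tsv(result["features"]),
        "model.tsv": "\n".join(model_lines) + "\n",
    }
    return out


def write_outputs(result: dict, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, text in serialize_results(result).items():
        (out / name).write_text(text)
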