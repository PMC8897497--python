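# Methods

This note documents the models, parameter choices and numerical conventions
behind `mvapipe`, and what the synthetic-data validation does and does not
establish.

## Data model

The pipeline's raw unit is the raw sequencing read count of a 12-mer peptide
in one subject's immunoprofile. Counts are kept raw throughout: the selection
thresholds of the workflow (≥10 reads, abundance sums, the >3-fold rule) are
defined on raw counts, and no library-size normalisation is applied. Count
tables are TSV (`subject_id`, `peptide`, `count`); proteomes are standard
FASTA, with UniProt `sp|ACC|NAME` headers reduced to the accession and other
headers to their first token. Validation is strict: peptides must be 12
residues over the 20-letter alphabet, counts non-negative integers,
(subject, peptide) pairs unique, and every counted subject present in the
metadata; non-standard proteome residues are flagged and kept, never dropped.

Replicate QC computes Pearson *R* on log10(count+1) over the union of two
replicate profiles (absent peptide = 0). The log scale matches the
heavy-tailed count distribution; with the default count model below, two
Poisson observations of the same latent profile at a 10⁵-peptide library
give *R* ≈ 0.84–0.87.

## Synthetic cohorts

The generator emulates the statistical structure a phage-display
immunoprofiling study presents to the analysis, not the biophysics of
selection:

* **Counts.** Each peptide carries a latent log-normal abundance
  (`log_mu = 1.0`, `log_sigma = 1.5`, natural log), observed through Poisson
  sampling; a per-subject log-normal factor (`subject_log_sigma = 0.3`)
  models titer differences. This reproduces the heavy tail (most peptides at
  1–5 reads, a long tail into the hundreds) and supports technical-replicate
  simulation.
* **Sharing.** A fraction (`shared_fraction`, default 0.3) of each subject's
  peptides is drawn from a common background pool, the rest are private;
  only shared peptides can pass the ≥10%-of-subjects presence rule, as in
  real repertoires where public mimotopes carry the group signal.
* **Design.** The default cohort is the 3×3 design with 32 subjects per CAD
  group and periodontal strata of 21/27/48 (7/9/16 per cell, 96 subjects).
  The per-subject library size defaults to 10⁵ distinct peptides — a free
  parameter of the emulation, not an empirical claim; validation runs use
  600–2000 peptides per subject, which preserves every selection rule's
  behaviour at proportionally smaller absolute abundances.
* **Planted effects.** A `PlantSpec` plants a wildcard pattern into a
  fraction of the peptides of responder subjects (fractions addressable per
  CAD group, periodontal group, or perio×CAD cell), with a multiplicative
  latent-abundance boost. Planted peptides come from a shared pool so they
  recur across subjects; when a `source_sequence` is given the pool is the
  set of its 12-mer windows, tying the cohort signal to a target-antigen
  region. The proteome generator writes pattern realisations at recorded
  sites in i.i.d.-uniform random proteins and always embeds one epitope
  segment in the C-terminal third of a dedicated target protein.

All generators are pure functions of (config, seed) and return a
`TruthRecord` sufficient to score recovery. What passing recovery tests show
is that each stage detects the structure it is designed for at realistic
effect sizes; they do not show robustness to selection-round artefacts, PCR
or sequencing error, or cross-reactive repertoire structure, none of which
the generator models.

## Motif discovery

The search enumerates patterns of fixed residues and single-position
wildcards only; residue classes (e.g. `[ST]`) arise downstream from PWM
consensus building, never during search. Patterns grow rightward as
(gap of 0–3 wildcards + fixed residue), so every node is in trimmed form and
each pattern has a unique construction path; occurrence lists (peptide,
offset) make child coverage a filter of the parent's, and the anti-monotone
query-coverage bound (default ≥4) prunes the trie. Limits: pattern length
≤12 (the peptide frame), ≤3 consecutive wildcards.

The hypergeometric tail *P*(X ≥ k) is computed by `logsumexp` over log-pmf
terms; it matches exact rational enumeration to <10⁻¹² for all margins
N ≤ 30. The enrichment ratio is
(query_coverage/|query|)/(max(ref_coverage, 1)/|reference|), the reference
coverage floored at 1 to keep the ratio finite. Emitted motifs are
de-duplicated per identical query match set, keeping the most specific
pattern (most fixed positions; ties broken by length then lexicographic
order), and the search re-runs after removing covered query peptides
(default 2 iterations). Output order — (p, coverage, pattern) — and the
internal canonical sorting make results independent of input order.

The reference set for a group's search is the union of the other groups'
TopPeptide sets on the same clinical axis; query/reference overlap is
allowed. The differential filter uses group means (not medians) for the
>3-fold rule, sweeps observed abundances as "≥ threshold calls the
higher-mean group" cuts for the sensitivity/specificity rule, and uses a
two-sided Mann–Whitney *U* test: exact enumeration over all
C(n₁+n₂, n₁) assignments when both groups have ≤8 subjects (ties handled by
the ½-count convention), otherwise the tie-corrected normal approximation.

## Proteome scanning

Fragments are complete 20-aa windows at starts 0, 20, 40, … and 10, 30, 50,
…; a hit is assigned to a fragment only when its span lies fully inside it,
so a hit straddling one tiling's boundary is caught by the other tiling.
A motif aligned several times within one fragment counts once (the load
formula divides by the number of distinct motifs). Top-*k* selection ranks
by total load with (accession, start) tie-breaks; two selected fragments
from different frameshifts overlapping by 10 aa merge into one 30-aa
fragment whose load is recomputed over the merged span. Loads are
scale-equivariant in the abundances.

Target types: for each hit inside a top fragment, the 12-mer protein
substring centred on the hit span (shifted inward at fragment edges, and
required to contain the span) is extracted; unique substrings are clustered
greedily — a substring joins the first cluster with any member within
Hamming distance 9 (i.e. ≥3 identities over 12 positions) — and clusters
need ≥10 unique members ("no counts": uniqueness, not multiplicity). The
similarity-index parameter of the original tooling has no recoverable
semantics and is not implemented as a constraint. Each cluster is summarised
by a 20×12 column-stochastic PWM and a consensus string (fixed residue at
frequency ≥0.5; class of residues each ≥0.2; wildcard otherwise).

## Epitope clustering

Motif homology uses the maximum, over ungapped relative offsets, of the
number of positions where two patterns carry the same fixed residue;
single-linkage components at ≥3 shared residues form clusters, and
components of <3 motifs are reported unclustered. Cluster abundance counts
a peptide once even when several member motifs match it. The group matrix
divides each cluster's per-stratum mean abundance by its cross-stratum mean
(rows average to 1 by construction); clusters with cross-stratum mean below
150 are dropped first. Epitope groups come from Ward clustering of 1−R
distances over log10(x+1) per-subject abundances, cut at *k* = 5 (the
number of epitope groups is a free parameter; 5 mirrors the standard
presentation). scipy's `linkage(method="ward")` on the condensed 1−R matrix
plays the role of R's `ward.D2` (the same Lance–Williams recurrence applied
to the supplied dissimilarities). Constant abundance vectors get
correlation 0 by convention, with a warning. Labels A, B, … are assigned in
descending total abundance, making the labelling deterministic.

## Target-antigen profiles

A peptide aligns at the offset(s) maximising its match count, provided ≥6 of
12 positions match; ties credit every best offset once. Best-offset (rather
than all-offsets ≥6) assignment avoids smearing coverage along repetitive
regions; an all-offsets mode exists behind a flag. The null track scrambles
each peptide's residues once (paired null, preserving per-peptide
composition exactly) and aligns identically; the ratio uses a pseudocount
ε = 1 on both tracks, so positions with no coverage in either track sit at
exactly 1 and changing ε moves every ratio monotonically toward 1.

## Two-step biomarker model

Features are per-subject epitope abundances normalised by the per-feature
97.5th percentile (linear-interpolation quantile; a zero percentile falls
back to the maximum) and capped at 1. Step 1 is an unpenalised logistic
regression ("generalized linear model" read as binomial GLM) of
periodontitis vs healthy on features A, B, C: stratified 80/20 split; 5-fold
out-of-fold probabilities on the training part choose the decision threshold
maximising balanced accuracy (ties prefer the higher threshold); the final
model refits on the full training part; AUROC is reported on training
predictions with a seeded 2000-resample bootstrap percentile 95% CI. For
null calibration the package exposes the cross-validated (out-of-fold)
AUROC, which unlike the training AUROC is not optimistically biased.

Step 2 sweeps observed feature values as thresholds and picks the Youden-J
maximiser, with ties resolved toward higher specificity and then the more
stringent threshold. The stratum rules are: C high → ACS in H; A high → ACS
in G; A or E high → no-CAD in P (the two P-stratum markers combine by OR by
default; AND is a config option). Classification of a new subject uses the
step-1 call to pick the stratum unless the true periodontal group is
supplied.

## Problem sizes used in validation

The automated checks run at desk scale, chosen so the full suite and the
acceptance script each finish in about a minute: motif recovery on
2000-vs-2000 peptide sets (20 seeds), fragment recovery on 18-subject
cohorts with 800-peptide libraries against 50×300-aa proteomes (20 seeds),
profile calibration on a 210-aa target (20 seeds), epitope-block recovery on
20-cluster × 60-subject matrices (20 seeds), and the biomarker model on the
full 96-subject design (50 seeds). The end-to-end pipeline default uses the
96-subject design with 1200-peptide libraries.

## Known limitations

* The search alphabet excludes residue classes; a class-bearing motif is
  found as its best fixed-residue specialisations and only regains classes
  at consensus time.
* Greedy target-type clustering depends on the (deterministic, sorted)
  insertion order near the distance cutoff; it is not a global optimum.
* The exact Mann–Whitney enumeration is used only up to group size 8;
  larger groups rely on the normal approximation.
* The generator does not model phage-selection rounds, sequencing error,
  antibody cross-reactivity between unrelated motifs, or covariate effects
  (age, sex, smoking) on the planted signals; covariates are emitted for
  stratification only.
* Step-1 performance on synthetic cohorts reflects the planted effect size
  (4-fold median shifts) and should not be read as an expected clinical
  accuracy.
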