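"""Synthetic cohorts, proteomes and target antigens with known ground truth.

The generator emulates the structure of a phage-display immunoprofiling
study so every downstream stage can be tested without the original serum
data:

* heavy-tailed peptide counts: a log-normal latent abundance per peptide,
  observed through Poisson sampling (which also yields technical-replicate
  pairs for the correlation QC);
* a background peptide universe partially shared across subjects;
* planted group-differential motifs: a ``PlantSpec`` names a wildcard
  pattern, the fraction of peptides carrying it per clinical group, an
  abundance boost, and the fraction of responder subjects;
* proteomes with embedded motif-mimicking segments and one target protein
  with a planted C-terminal epitope.

Everything is a pure function of (config, seed); the returned ``TruthRecord``
is sufficient to score recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CAD_GROUPS, PERIO_GROUPS, CohortTable, Proteome, SubjectRecord
from .patterns import AMINO_ACIDS, Pattern

_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


def random_peptides(n: int, rng: np.random.Generator, length: int = 12) -> list[str]:
    codes = _AA_BYTES[rng.integers(0, 20, size=(n, length))]
    return [bytes(row).decode() for row in codes]


def random_protein(length: int, rng: np.random.Generator) -> str:
    return bytes(_AA_BYTES[rng.integers(0, 20, size=length)]).decode()


def instantiate_pattern(pattern: Pattern, rng: np.random.Generator, length: int = 12) -> str:
    """A random sequence of ``length`` containing one realisation of the
    pattern at a random offset (wildcards and free positions drawn uniformly)."""
    L = len(pattern)
    if L > length:
        raise ValueError(f"pattern length {L} exceeds sequence length {length}")
    seq = list(bytes(_AA_BYTES[rng.integers(0, 20, size=length)]).decode())
    off = int(rng.integers(0, length - L + 1))
    for i, e in enumerate(pattern.elements):
        if e is not None:
            choices = sorted(e)
            seq[off + i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(seq)


def scramble_peptides(peptides, seed: int) -> list[str]:
    """Per-peptide residue scrambling (uniform random permutation each)."""
    rng = np.random.default_rng(seed)
    out = []
    for pep in peptides:
        perm = rng.permutation(len(pep))
        out.append("".join(pep[i] for i in perm))
    return out


@dataclass
class PlantSpec:
    """A planted group-differential motif effect.

    Keys of ``carrier_fraction_per_group`` may be a CAD label (``ACS``), a
    periodontal label (``P``), or a ``perio:cad`` cell (``P:noCAD``); a
    subject matching several keys uses the largest fraction.
    """

    pattern: Pattern
    carrier_fraction_per_group: dict[str, float]
    abundance_boost: float = 10.0
    responder_subject_fraction: float = 1.0
    source_sequence: str | None = None  # plant 12-mer windows of this sequence instead

    def __post_init__(self):
        if isinstance(self.pattern, str):
            self.pattern = Pattern.parse(self.pattern)
        if not any(f > 0 for f in self.carrier_fraction_per_group.values()):
            raise ValueError("at least one group fraction must be > 0")
        for g, f in self.carrier_fraction_per_group.items():
            if not 0 <= f <= 1:
                raise ValueError(f"carrier fraction for {g!r} out of [0,1]: {f}")
        if self.abundance_boost < 1:
            raise ValueError("abundance_boost must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth of a synthetic study."""

    planted_patterns: list[PlantSpec]
    planted_proteome_sites: list[tuple[str, int, str]] = field(default_factory=list)
    planted_target_epitope: tuple[int, int] | None = None
    target_accession: str | None = None
    subject_effect_assignments: dict[str, dict[str, bool]] = field(default_factory=dict)
    planted_peptide_pools: dict[str, list[str]] = field(default_factory=dict)


def default_design() -> dict[tuple[str, str], int]:
    """The 3x3 study design: 32 subjects per CAD group, periodontal strata
    H/G/P of 21/27/48 split evenly across CAD groups (7/9/16 per cell)."""
    per_perio = {"H": 7, "G": 9, "P": 16}
    return {(cad, per): per_perio[per] for cad in CAD_GROUPS for per in PERIO_GROUPS}


@dataclass
class CohortConfig:
    """Design of a synthetic cohort.

    ``library_size`` is the number of distinct peptides observed per subject
    (default 1e5, a free parameter of the emulation); ``universe_size`` the
    size of the shared background peptide pool; ``shared_fraction`` the
    fraction of each subject's peptides drawn from that pool.  Latent
    abundances are log-normal (``log_mu``, ``log_sigma``) and counts Poisson.
    """

    n_per_cell: dict[tuple[str, str], int] = field(default_factory=default_design)
    library_size: int = 100_000
    universe_size: int = 500_000
    shared_fraction: float = 0.3
    log_mu: float = 1.0
    log_sigma: float = 1.5
    subject_log_sigma: float = 0.3
    plant_pool_size: int = 300
    smoking_rate: float = 0.45
    diabetes_rate: float = 0.19

    def __post_init__(self):
        missing = [c for c in itertools.product(CAD_GROUPS, PERIO_GROUPS) if c not in self.n_per_cell]
        if missing:
            raise ValueError(f"design does not cover cells {missing}")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction out of [0,1]")


def _make_subjects(config: CohortConfig, rng: np.random.Generator) -> list[SubjectRecord]:
    subjects = []
    i = 0
    for cad in CAD_GROUPS:
        for per in PERIO_GROUPS:
            for _ in range(config.n_per_cell[(cad, per)]):
                i += 1
                smoking = "never"
                if rng.random() < config.smoking_rate:
                    smoking = "ex" if rng.random() < 0.5 else "active"
                subjects.append(SubjectRecord(
                    subject_id=f"S{i:03d}",
                    cad_group=cad,
                    perio_group=per,
                    smoking=smoking,
                    diabetes=bool(rng.random() < config.diabetes_rate),
                    age=float(np.round(rng.normal(63, 9), 1)),
                    sex="F" if rng.random() < 0.5 else "M",
                    ebv_ca_seropositive=bool(rng.random() < 0.9),
                ))
    return subjects


def _plant_pool(spec: PlantSpec, rng: np.random.Generator, size: int) -> list[str]:
    if spec.source_sequence is not None:
        seq = spec.source_sequence
        return [seq[i : i + 12] for i in range(len(seq) - 11)]
    return [instantiate_pattern(spec.pattern, rng) for _ in range(size)]


def generate_cohort(config: CohortConfig, plants: list[PlantSpec],
                    seed: int) -> tuple[CohortTable, TruthRecord]:
    """Generate a synthetic cohort and its ground truth, deterministically."""
    rng = np.random.default_rng(seed)
    subjects = _make_subjects(config, rng)
    truth = TruthRecord(planted_patterns=list(plants))

    universe = random_peptides(config.universe_size, rng)
    universe_latent = rng.normal(config.log_mu, config.log_sigma, size=config.universe_size)

    pools: list[list[str]] = []
    pool_latents: list[np.ndarray] = []
    for spec in plants:
        pool = _plant_pool(spec, rng, config.plant_pool_size)
        pools.append(pool)
        pool_latents.append(
            rng.normal(config.log_mu, config.log_sigma, size=len(pool)) + np.log(spec.abundance_boost)
        )
        truth.planted_peptide_pools[str(spec.pattern)] = pool
        truth.subject_effect_assignments[str(spec.pattern)] = {}

    n_shared = int(round(config.shared_fraction * config.library_size))
    counts: dict[tuple[str, str], int] = {}
    for subj in subjects:
        noise = rng.normal(0.0, config.subject_log_sigma)
        idx = rng.choice(config.universe_size, size=n_shared, replace=False)
        peps = [universe[i] for i in idx]
        latent = universe_latent[idx] + noise
        n_private = config.library_size - n_shared
        if n_private > 0:
            peps += random_peptides(n_private, rng)
            latent = np.concatenate([latent, rng.normal(config.log_mu, config.log_sigma, n_private) + noise])
        for spec, pool, pool_latent in zip(plants, pools, pool_latents):
            labels = (subj.cad_group, subj.perio_group, f"{subj.perio_group}:{subj.cad_group}")
            frac = max(
                (f for g, f in spec.carrier_fraction_per_group.items() if g in labels),
                default=0.0,
            )
            responder = frac > 0 and rng.random() < spec.responder_subject_fraction
            truth.subject_effect_assignments[str(spec.pattern)][subj.subject_id] = bool(responder)
            if not responder:
                continue
            n_plant = rng.binomial(config.library_size, frac)
            if n_plant == 0:
                continue
            take = rng.choice(len(pool), size=min(n_plant, len(pool)), replace=False)
            peps += [pool[i] for i in take]
            latent = np.concatenate([latent, pool_latent[take] + noise])
        c = rng.poisson(np.exp(latent))
        for pep, ci in zip(peps, c):
            if ci > 0:
                key = (subj.subject_id, pep)
                counts[key] = counts.get(key, 0) + int(ci)
    return CohortTable(counts=counts, subjects=subjects), truth


@dataclass
class ProteomeConfig:
    n_proteins: int = 50
    mean_length: int = 300
    length_sd: int = 80
    min_length: int = 60
    sites_per_pattern: int = 3
    target_accession: str = "TARGET01"
    target_length: int = 210


def plant_proteome(config: ProteomeConfig, truth: TruthRecord, seed: int) -> Proteome:
    """Random proteome with the truth's patterns planted at recorded sites and
    a target protein carrying a planted epitope in its C-terminal third."""
    rng = np.random.default_rng(seed)
    entries: dict[str, str] = {}
    lengths = np.maximum(
        rng.normal(config.mean_length, config.length_sd, size=config.n_proteins).astype(int),
        config.min_length,
    )
    for i, L in enumerate(lengths):
        entries[f"SYN{i + 1:04d}"] = random_protein(int(L), rng)

    occupied: dict[str, list[tuple[int, int]]] = {acc: [] for acc in entries}
    accs = sorted(entries)

    def place(acc: str, segment: str, lo: int, hi: int) -> int:
        """Overwrite ``segment`` at a random non-colliding offset in [lo, hi]."""
        for _ in range(100):
            off = int(rng.integers(lo, hi + 1))
            span = (off, off + len(segment))
            if all(span[1] <= s or span[0] >= e for s, e in occupied[acc]):
                seq = entries[acc]
                entries[acc] = seq[: span[0]] + segment + seq[span[1] :]
                occupied[acc].append(span)
                return off
        raise RuntimeError(f"could not place a planted site on {acc} after 100 attempts")

    for spec in truth.planted_patterns:
        for _ in range(config.sites_per_pattern):
            acc = accs[int(rng.integers(0, len(accs)))]
            seg = instantiate_pattern(spec.pattern, rng, length=len(spec.pattern))
            off = place(acc, seg, 0, len(entries[acc]) - len(seg))
            truth.planted_proteome_sites.append((acc, off, str(spec.pattern)))

    target = config.target_accession
    entries[target] = random_protein(config.target_length, rng)
    occupied[target] = []
    if truth.planted_patterns:
        # the target epitope: the first plant's source sequence when given,
        # otherwise a fresh realisation of the first planted pattern
        first = truth.planted_patterns[0]
        source_specs = [s for s in truth.planted_patterns if s.source_sequence is not None]
        if source_specs:
            first = source_specs[0]
            epi = first.source_sequence
        else:
            epi = instantiate_pattern(first.pattern, rng, length=24)
        lo = max(0, (2 * config.target_length) // 3)
        hi = config.target_length - len(epi)
        if hi < lo:
            raise ValueError("target protein too short for the epitope")
        off = place(target, epi, lo, hi)
        truth.planted_target_epitope = (off, off + len(epi))
        truth.target_accession = target
        inside = first.pattern.match(epi)
        if inside:
            truth.planted_proteome_sites.append((target, off + inside[0], str(first.pattern)))
    return Proteome(entries=entries)


def labelled_peptide_set(n: int, pattern: Pattern | str, carrier_fraction: float,
                         seed: int) -> tuple[list[str], list[bool]]:
    """``n`` random 12-mers of which a Bernoulli(``carrier_fraction``) subset
    carries ``pattern`` at a random offset.  Returns peptides and carrier flags."""
    if isinstance(pattern, str):
        pattern = Pattern.parse(pattern)
    rng = np.random.default_rng(seed)
    flags = rng.random(n) < carrier_fraction
    peps = []
    for is_carrier in flags:
        if is_carrier:
            peps.append(instantiate_pattern(pattern, rng))
        else:
            peps.append(random_peptides(1, rng)[0])
    return peps, [bool(f) for f in flags]


def simulate_technical_replicates(n_peptides: int = 100_000, seed: int = 0,
                                  log_mu: float = 1.0, log_sigma: float = 1.5
                                  ) -> tuple[dict[str, int], dict[str, int]]:
    """Two Poisson observations of the same latent log-normal profile."""
    rng = np.random.default_rng(seed)
    peps = random_peptides(n_peptides, rng)
    latent = np.exp(rng.normal(log_mu, log_sigma, size=n_peptides))
    a = rng.poisson(latent)
    b = rng.poisson(latent)
    rep_a = {p: int(c) for p, c in zip(peps, a) if c > 0}
    rep_b = {p: int(c) for p, c in zip(peps, b) if c > 0}
    return rep_a, rep_b


# ---------------------------------------------------------------------------
# Feature-level generators for the clustering and biomarker stages


def generate_block_cluster_abundance(n_blocks: int = 5, clusters_per_block: int = 4,
                                     n_subjects: int = 60, seed: int = 0,
                                     noise_sd: float = 0.3) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster x subject abundances with ``n_blocks`` independent responder
    blocks: clusters of one block share a latent per-subject response and are
    uncorrelated with other blocks.  Returns the matrix and true block labels."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b in range(n_blocks):
        latent = rng.normal(0.0, 1.0, size=n_subjects)
        for _ in range(clusters_per_block):
            logv = 2.0 + latent + rng.normal(0.0, noise_sd, size=n_subjects)
            rows.append(10.0 ** logv)
            labels.append(b)
    df = pd.DataFrame(
        np.vstack(rows),
        index=np.arange(1, len(rows) + 1),
        columns=[f"S{j + 1:03d}" for j in range(n_subjects)],
    )
    return df, np.array(labels)


#: multiplicative effects mirroring the study's sign structure: epitopes A
#: and B high in periodontitis, C high in periodontally healthy; within P,
#: A and E high in no-CAD; within G, A high in ACS; within H, C high in ACS.
DEFAULT_FEATURE_EFFECTS = {
    ("perio", "P"): {"A": 4.0, "B": 4.0},
    ("perio", "H"): {"C": 4.0},
    ("perio:P", "noCAD"): {"A": 3.0, "E": 4.0},
    ("perio:G", "ACS"): {"A": 4.0},
    ("perio:H", "ACS"): {"C": 3.0},
}


def generate_epitope_features(seed: int, n_per_cell: dict | None = None,
                              base_mean: float = 100.0, log_sigma: float = 0.6,
                              effects: dict | None = None
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject epitope abundances (features A..E) with planted effects.

    Returns (features, metadata) where metadata has ``perio_group`` and
    ``cad_group`` columns.  Effects are multiplicative on the log-normal base
    abundance; keys address either a periodontal stratum (``("perio", "P")``)
    or a CAD group within one (``("perio:P", "noCAD")``).
    """
    rng = np.random.default_rng(seed)
    n_per_cell = n_per_cell or default_design()
    effects = effects if effects is not None else DEFAULT_FEATURE_EFFECTS
    feats = list("ABCDE")
    rows, meta = [], []
    i = 0
    for cad in CAD_GROUPS:
        for per in PERIO_GROUPS:
            for _ in range(n_per_cell[(cad, per)]):
                i += 1
                mult = {f: 1.0 for f in feats}
                for (scope, label), eff in effects.items():
                    hit = (scope == "perio" and per == label) or \
                          (scope == f"perio:{per}" and cad == label)
                    if hit:
                        for f, m in eff.items():
                            mult[f] *= m
                vals = {
                    f: base_mean * mult[f] * float(np.exp(rng.normal(0.0, log_sigma)))
                    for f in feats
                }
                rows.append(vals)
                meta.append({"subject_id": f"S{i:03d}", "perio_group": per, "cad_group": cad})
    meta_df = pd.DataFrame(meta).set_index("subject_id")
    feat_df = pd.DataFrame(rows, index=meta_df.index)
    return feat_df, meta_df
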