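"""Cohort data model, file I/O, and replicate QC.

The raw input of the pipeline is a per-subject table of 12-mer peptide read
counts from phage-display immunoprofiling, plus a subject metadata table with
the clinical labels (coronary-artery-disease group, periodontal group,
smoking, diabetes, age, sex, EBV-CA serostatus).  Proteomes are plain FASTA.

Count tables are tab-delimited (columns ``subject_id``, ``peptide``,
``count``); metadata is one TSV row per subject.  Validation is total: any
malformed peptide, count or unknown subject raises with the offending line.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .patterns import _AA_SET

logger = logging.getLogger(__name__)

PEPTIDE_LENGTH = 12
CAD_GROUPS = ("noCAD", "sCAD", "ACS")
PERIO_GROUPS = ("H", "G", "P")
SMOKING_LEVELS = ("never", "ex", "active")
SEXES = ("F", "M")

_CAD_ALIASES = {"no-CAD": "noCAD", "s-CAD": "sCAD", "stable-CAD": "sCAD"}


@dataclass
class SubjectRecord:
    """Clinical labels for one study subject."""

    subject_id: str
    cad_group: str
    perio_group: str
    smoking: str = "never"
    diabetes: bool = False
    age: float = 60.0
    sex: str = "F"
    ebv_ca_seropositive: bool = True

    def __post_init__(self):
        self.cad_group = _CAD_ALIASES.get(self.cad_group, self.cad_group)
        if self.cad_group not in CAD_GROUPS:
            raise ValueError(f"unknown CAD group {self.cad_group!r}")
        if self.perio_group not in PERIO_GROUPS:
            raise ValueError(f"unknown periodontal group {self.perio_group!r}")
        if self.smoking not in SMOKING_LEVELS:
            raise ValueError(f"unknown smoking level {self.smoking!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")

    @property
    def smoking_exposed(self) -> bool:
        """True for any smoking history (ex- or active), the '+' stratum."""
        return self.smoking != "never"


def validate_peptide(peptide: str, line: int | None = None) -> str:
    where = "" if line is None else f" (line {line})"
    pep = peptide.upper()
    if len(pep) != PEPTIDE_LENGTH:
        raise ValueError(f"peptide {peptide!r} has length {len(pep)}, expected {PEPTIDE_LENGTH}{where}")
    if not set(pep) <= _AA_SET:
        raise ValueError(f"peptide {peptide!r} contains non amino-acid letters{where}")
    return pep


@dataclass
class CohortTable:
    """Per-subject peptide count table plus subject records."""

    counts: dict[tuple[str, str], int]
    subjects: list[SubjectRecord]

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in cohort")
        known = set(ids)
        for (sid, pep), c in self.counts.items():
            if sid not in known:
                raise ValueError(f"count entry for unknown subject {sid!r}")
            validate_peptide(pep)
            if not isinstance(c, (int, np.integer)) or c < 0:
                raise ValueError(f"count for ({sid}, {pep}) must be a non-negative integer, got {c!r}")

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def by_subject(self) -> dict[str, dict[str, int]]:
        """Subject -> (peptide -> count) index, built lazily once."""
        cached = getattr(self, "_by_subject", None)
        if cached is None:
            cached = {sid: {} for sid in self.subject_ids}
            for (sid, pep), c in self.counts.items():
                cached[sid][pep] = c
            object.__setattr__(self, "_by_subject", cached)
        return cached

    def profile(self, subject_id: str) -> dict[str, int]:
        """Peptide -> count mapping for one subject."""
        if subject_id not in set(self.subject_ids):
            raise KeyError(subject_id)
        return dict(self.by_subject()[subject_id])

    def group_subjects(self, group: str) -> list[str]:
        """Subject ids carrying a clinical label on either the CAD or periodontal axis."""
        group = _CAD_ALIASES.get(group, group)
        if group in CAD_GROUPS:
            return [s.subject_id for s in self.subjects if s.cad_group == group]
        if group in PERIO_GROUPS:
            return [s.subject_id for s in self.subjects if s.perio_group == group]
        raise ValueError(f"unknown clinical group {group!r}")

    def peptides(self) -> set[str]:
        return {pep for (_, pep) in self.counts}

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        rows = sorted((sid, pep, c) for (sid, pep), c in self.counts.items())
        counts = pd.DataFrame(rows, columns=["subject_id", "peptide", "count"])
        meta = pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "cad_group": s.cad_group,
                    "perio_group": s.perio_group,
                    "smoking": s.smoking,
                    "diabetes": s.diabetes,
                    "age": s.age,
                    "sex": s.sex,
                    "ebv_ca_seropositive": s.ebv_ca_seropositive,
                }
                for s in sorted(self.subjects, key=lambda s: s.subject_id)
            ]
        )
        return counts, meta


def load_cohort(counts_path, metadata_path) -> CohortTable:
    """Load and validate a cohort from a counts TSV and a metadata TSV."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "cad_group", "perio_group"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata file misses columns {sorted(required - set(meta.columns))}")
    subjects = [
        SubjectRecord(
            subject_id=row["subject_id"],
            cad_group=str(row["cad_group"]),
            perio_group=str(row["perio_group"]),
            smoking=str(row.get("smoking", "never")),
            diabetes=bool(row.get("diabetes", False)),
            age=float(row.get("age", 60.0)),
            sex=str(row.get("sex", "F")),
            ebv_ca_seropositive=bool(row.get("ebv_ca_seropositive", True)),
        )
        for _, row in meta.iterrows()
    ]
    known = {s.subject_id for s in subjects}

    df = pd.read_csv(counts_path, sep="\t", dtype={"subject_id": str, "peptide": str})
    if list(df.columns[:3]) != ["subject_id", "peptide", "count"]:
        raise ValueError("counts file must have columns subject_id, peptide, count")
    counts: dict[tuple[str, str], int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        sid = row.subject_id
        if sid not in known:
            raise ValueError(f"unknown subject {sid!r} in counts file (line {line})")
        pep = validate_peptide(str(row.peptide), line=line)
        try:
            c = int(row.count)
        except (TypeError, ValueError):
            raise ValueError(f"malformed count {row.count!r} (line {line})") from None
        if c < 0:
            raise ValueError(f"negative count {c} (line {line})")
        key = (sid, pep)
        if key in counts:
            raise ValueError(f"duplicate (subject, peptide) row for {key} (line {line})")
        counts[key] = c
    return CohortTable(counts=counts, subjects=subjects)


def write_cohort(cohort: CohortTable, counts_path, metadata_path) -> None:
    """Write the canonical (sorted) TSV representation; inverse of load_cohort."""
    counts, meta = cohort.to_frames()
    counts.to_csv(counts_path, sep="\t", index=False)
    meta.to_csv(metadata_path, sep="\t", index=False)


@dataclass
class Proteome:
    """Accession -> amino-acid sequence mapping."""

    entries: dict[str, str]
    nonstandard: dict[str, set] = field(default_factory=dict)

    def __post_init__(self):
        for acc, seq in self.entries.items():
            if not seq:
                raise ValueError(f"empty sequence for {acc!r}")
            if not seq.isupper():
                raise ValueError(f"sequence for {acc!r} is not upper-case")

    def __len__(self) -> int:
        return len(self.entries)

    def total_residues(self) -> int:
        return sum(len(s) for s in self.entries.values())


def _fasta_accession(header: str) -> str:
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return token


def read_fasta_proteome(path) -> Proteome:
    """Read a FASTA proteome; UniProt ``sp|ACC|NAME`` headers yield ``ACC``.

    Non-standard residues (outside the 20-letter alphabet) are flagged on the
    returned object and warned about, never silently dropped.
    """
    entries: dict[str, str] = {}
    nonstandard: dict[str, set] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _fasta_accession(rec.description or rec.id)
        seq = str(rec.seq).upper()
        if acc in entries:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        odd = set(seq) - _AA_SET
        if odd:
            nonstandard[acc] = odd
            warnings.warn(f"{acc}: non-standard residues {sorted(odd)}", stacklevel=2)
        entries[acc] = seq
    if not entries:
        raise ValueError(f"no FASTA records in {path}")
    return Proteome(entries=entries, nonstandard=nonstandard)


def write_fasta_proteome(proteome: Proteome, path) -> None:
    with open(path, "w") as fh:
        for acc in sorted(proteome.entries):
            fh.write(f">{acc}\n")
            seq = proteome.entries[acc]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def replicate_correlation(profile_a: dict[str, int], profile_b: dict[str, int]) -> tuple[float, float]:
    """Pearson R (and two-sided p) between two replicate count profiles.

    Computed on log10(count + 1) over the union of peptides; a peptide absent
    from one replicate counts 0 there.  Used as the technical-replicate QC
    (the assay is considered reproducible around R ~ 0.87).
    """
    if not profile_a or not profile_b:
        raise ValueError("replicate profiles must be non-empty")
    union = sorted(set(profile_a) | set(profile_b))
    if len(union) < 3:
        raise ValueError("fewer than 3 peptides in the union; correlation undefined")
    a = np.log10(np.array([profile_a.get(p, 0) for p in union], dtype=float) + 1.0)
    b = np.log10(np.array([profile_b.get(p, 0) for p in union], dtype=float) + 1.0)
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
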