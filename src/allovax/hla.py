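"""HLA nomenclature, subject typings, and cell-line reference augmentation.

HLA alleles are named by colon-separated numeric fields (e.g.
``HLA-A*24:02:01:01``).  The first three fields determine the coding
sequence (the "CDS level"); a fourth field distinguishes variants that
differ only in non-coding sequence.  This module parses and manipulates
allele names at 1-4 field resolution, holds per-subject typings, and
builds the cell-line-specific augmented transcriptome in which generic
HLA reference transcripts are removed and replaced with the coding
sequences of the alleles the line actually carries, so that a
pseudoalignment quantifier can resolve expression per allele despite the
very high (>90%) sequence identity between alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CLASS_I_LOCI",
    "CLASS_II_LOCI",
    "SUPPORTED_LOCI",
    "HlaError",
    "AlleleParseError",
    "UnsupportedLocusError",
    "ResolutionError",
    "TypingValidationError",
    "HlaAllele",
    "HlaTyping",
    "TranscriptRecord",
    "AugmentationPlan",
    "parse_allele",
    "truncate_allele",
    "alleles_match_at",
    "build_augmented_transcriptome",
    "load_typing_table",
    "load_removal_list",
    "read_fasta",
    "write_fasta",
]

CLASS_I_LOCI = ("HLA-A", "HLA-B", "HLA-C")
CLASS_II_LOCI = (
    "HLA-DRA",
    "HLA-DRB1",
    "HLA-DRB3",
    "HLA-DRB4",
    "HLA-DRB5",
    "HLA-DQA1",
    "HLA-DQB1",
    "HLA-DPA1",
    "HLA-DPB1",
)
SUPPORTED_LOCI = CLASS_I_LOCI + CLASS_II_LOCI

_NUCLEOTIDES = frozenset("ACGTN")


class HlaError(ValueError):
    """Base class for HLA-related errors."""


class AlleleParseError(HlaError):
    """Allele text could not be parsed into numeric fields."""


class UnsupportedLocusError(HlaError):
    """Allele names a locus outside the supported HLA loci."""


class ResolutionError(HlaError):
    """Requested resolution exceeds the allele's typed resolution."""


class TypingValidationError(HlaError):
    """A typing table violates structural constraints."""


@dataclass(frozen=True)
class HlaAllele:
    """A single HLA allele at 1-4 field resolution.

    ``fields`` keeps the original zero-padded digit strings so that
    formatting round-trips (``02`` stays ``02``).
    """

    gene: str
    fields: tuple[str, ...]
    raw: str = ""

    def __post_init__(self) -> None:
        if self.gene not in SUPPORTED_LOCI:
            raise UnsupportedLocusError(f"unsupported HLA locus: {self.gene!r}")
        if not 1 <= len(self.fields) <= 4:
            raise AlleleParseError(
                f"allele must have 1-4 fields, got {len(self.fields)}"
            )
        for f in self.fields:
            if not f.isdigit():
                raise AlleleParseError(f"non-numeric allele field: {f!r}")

    @property
    def resolution(self) -> int:
        return len(self.fields)

    @property
    def name(self) -> str:
        """Canonical allele string, e.g. ``HLA-A*24:02:01:01``."""
        return f"{self.gene}*{':'.join(self.fields)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def parse_allele(text: str) -> HlaAllele:
    """Parse an allele string into an :class:`HlaAllele`.

    Tolerates a missing ``HLA-`` prefix and internal whitespace
    (typography such as ``HLA-B*35: 08:01`` occurs in printed tables).
    """
    raw = text
    cleaned = "".join(text.split())
    if "*" not in cleaned:
        raise AlleleParseError(f"allele string lacks '*': {text!r}")
    gene_part, _, allele_part = cleaned.partition("*")
    gene = gene_part.upper()
    if not gene.startswith("HLA-"):
        gene = "HLA-" + gene
    if gene not in SUPPORTED_LOCI:
        raise UnsupportedLocusError(f"unsupported HLA locus: {gene_part!r}")
    if allele_part == "":
        raise AlleleParseError(f"allele string has no fields: {text!r}")
    fields = tuple(allele_part.split(":"))
    if len(fields) > 4:
        raise AlleleParseError(
            f"allele string has {len(fields)} fields (max 4): {text!r}"
        )
    for f in fields:
        if not f.isdigit():
            raise AlleleParseError(f"non-numeric field {f!r} in {text!r}")
    return HlaAllele(gene=gene, fields=fields, raw=raw)


def truncate_allele(allele: HlaAllele, n: int) -> HlaAllele:
    """Return the allele restricted to its first ``n`` fields.

    Truncating to the current resolution is the identity; asking for
    more fields than are typed raises :class:`ResolutionError` (never
    silently pads).
    """
    if n < 1:
        raise ResolutionError(f"resolution must be >= 1, got {n}")
    if n > allele.resolution:
        raise ResolutionError(
            f"cannot truncate {allele.name} to {n} fields "
            f"(has {allele.resolution})"
        )
    if n == allele.resolution:
        return allele
    return HlaAllele(gene=allele.gene, fields=allele.fields[:n], raw=allele.raw)


def alleles_match_at(
    a: HlaAllele, b: HlaAllele, n: int, *, strict: bool = True
) -> bool:
    """Do two alleles agree over their first ``n`` fields?

    In strict mode (default) both alleles must carry at least ``n``
    fields; a 3-field (CDS-level) comparison then never succeeds against
    a 2-field typing.  In lenient mode the comparison uses
    ``min(n, res(a), res(b))`` fields.  Different genes never match.
    """
    if n < 1:
        raise ResolutionError(f"resolution must be >= 1, got {n}")
    if a.gene != b.gene:
        return False
    if strict:
        if a.resolution < n or b.resolution < n:
            return False
        m = n
    else:
        m = min(n, a.resolution, b.resolution)
    return a.fields[:m] == b.fields[:m]


@dataclass
class HlaTyping:
    """Per-subject mapping locus -> 0-2 alleles.

    An empty list records a locus known to be absent (secondary DRB loci
    such as HLA-DRB3 exist only on some haplotypes); a locus missing
    from the mapping altogether is untyped.
    """

    subject_id: str
    alleles: dict[str, list[HlaAllele]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, allele_list in self.alleles.items():
            if locus not in SUPPORTED_LOCI:
                raise UnsupportedLocusError(
                    f"unsupported locus {locus!r} in typing for "
                    f"{self.subject_id}"
                )
            if len(allele_list) > 2:
                raise TypingValidationError(
                    f"{self.subject_id}: more than 2 alleles at {locus}"
                )
            for a in allele_list:
                if a.gene != locus:
                    raise TypingValidationError(
                        f"{self.subject_id}: allele {a.name} filed under "
                        f"{locus}"
                    )

    def loci(self) -> list[str]:
        return [l for l in SUPPORTED_LOCI if l in self.alleles]


@dataclass
class TranscriptRecord:
    """A transcript sequence destined for the quantification index."""

    id: str
    sequence: str
    source: str = "reference"  # "reference" | "hla_allele"
    allele: Optional[HlaAllele] = None

    def __post_init__(self) -> None:
        if self.source not in ("reference", "hla_allele"):
            raise ValueError(f"invalid source {self.source!r}")
        seq = self.sequence.upper()
        bad = set(seq) - _NUCLEOTIDES
        if bad:
            raise ValueError(
                f"transcript {self.id}: invalid characters {sorted(bad)}"
            )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AugmentationPlan:
    """Which reference transcripts to drop and which allele sequences to add.

    ``sequence_kind`` records whether the inserted allele sequences are
    bare coding sequences or carry untranslated regions as well; the two
    variants of the index are compared by the UTR experiment in the
    quantification module.
    """

    removal_ids: list[str]
    insertions: list[TranscriptRecord]
    sequence_kind: str = "CDS"  # "CDS" | "CDS_plus_UTR"

    def __post_init__(self) -> None:
        if self.sequence_kind not in ("CDS", "CDS_plus_UTR"):
            raise ValueError(f"invalid sequence_kind {self.sequence_kind!r}")
        if len(set(self.removal_ids)) != len(self.removal_ids):
            raise ValueError("duplicate ids in removal list")
        ins_ids = [r.id for r in self.insertions]
        if len(set(ins_ids)) != len(ins_ids):
            raise ValueError("duplicate insertion ids")
        for r in self.insertions:
            if r.source != "hla_allele":
                raise ValueError(
                    f"insertion {r.id} must have source='hla_allele'"
                )


def build_augmented_transcriptome(
    reference: Sequence[TranscriptRecord], plan: AugmentationPlan
) -> list[TranscriptRecord]:
    """Remove the planned transcripts and append the allele sequences.

    Output preserves surviving reference order, then insertions.  A
    removal id absent from the reference is an error (it signals a stale
    removal list), as is an insertion id colliding with a surviving
    reference id.
    """
    ref_ids = {r.id for r in reference}
    missing = [i for i in plan.removal_ids if i not in ref_ids]
    if missing:
        raise KeyError(f"removal ids not found in reference: {missing}")
    for rec in plan.insertions:
        if not rec.sequence:
            raise ValueError(f"insertion {rec.id} has empty sequence")
    removals = set(plan.removal_ids)
    surviving = [r for r in reference if r.id not in removals]
    surviving_ids = {r.id for r in surviving}
    clash = [r.id for r in plan.insertions if r.id in surviving_ids]
    if clash:
        raise ValueError(f"insertion ids collide with reference ids: {clash}")
    return list(surviving) + list(plan.insertions)


def load_typing_table(path: str | Path) -> list[HlaTyping]:
    """Read a typing CSV with columns subject_id, locus, allele.

    One row per allele.  An allele value of ``-`` (or empty) registers
    the locus as typed-but-absent, yielding an empty allele list;
    untyped loci simply have no rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"subject_id", "locus", "allele"}
    if not required.issubset(df.columns):
        raise TypingValidationError(
            f"typing table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    typings: dict[str, dict[str, list[HlaAllele]]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        subject = row.subject_id.strip()
        locus = row.locus.strip().upper()
        if not locus.startswith("HLA-"):
            locus = "HLA-" + locus
        if locus not in SUPPORTED_LOCI:
            raise UnsupportedLocusError(
                f"row {i + 2}: unsupported locus {row.locus!r}"
            )
        per_subject = typings.setdefault(subject, {})
        allele_text = row.allele.strip()
        if allele_text in ("", "-"):
            per_subject.setdefault(locus, [])
            continue
        if "*" not in allele_text:
            # bare field lists ("11:01:01:01") inherit the locus column
            allele_text = f"{locus}*{allele_text}"
        try:
            allele = parse_allele(allele_text)
        except HlaError as exc:
            raise type(exc)(f"row {i + 2}: {exc}") from exc
        if allele.gene != locus:
            raise TypingValidationError(
                f"row {i + 2}: allele {allele.name} does not belong to "
                f"locus {locus}"
            )
        alleles = per_subject.setdefault(locus, [])
        if len(alleles) >= 2:
            raise TypingValidationError(
                f"row {i + 2}: more than 2 alleles at {locus} for {subject}"
            )
        alleles.append(allele)
    return [HlaTyping(subject_id=s, alleles=a) for s, a in typings.items()]


def load_removal_list(path: str | Path) -> list[str]:
    """Read a removal list: one transcript id per line, '#' comments allowed."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return ids


def read_fasta(path: str | Path, source: str = "reference") -> list[TranscriptRecord]:
    """Read transcripts from FASTA; the header token before whitespace is the id."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(TranscriptRecord(id=rec.id, sequence=str(rec.seq), source=source))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate transcript ids in {path}: {dupes}")
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcripts as 60-column wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
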