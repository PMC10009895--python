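"""Seeded generators for every input the pipeline consumes.

The generators emulate the structural features the analysis has to cope
with: HLA allele pairs of >90% sequence identity (which force ambiguous
read assignment), reference transcriptomes carrying decoy HLA
transcripts slated for removal, short single-end reads drawn from known
TPM abundances with substitution errors, multi-study grade-labelled
expression matrices with planted fold changes, and cohort typings with
a controlled match structure against a cell-line typing.  Every
generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .hla import (
    HlaAllele,
    HlaTyping,
    TranscriptRecord,
    parse_allele,
    truncate_allele,
)
from .signature import StudyMatrix

__all__ = [
    "StudyParams",
    "SimulationConfig",
    "make_allele_pair",
    "make_transcriptome",
    "simulate_reads",
    "simulate_grade_studies",
    "make_cohort_typings",
    "UnsatisfiableMatchSpec",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class UnsatisfiableMatchSpec(ValueError):
    """A requested cohort match level cannot be generated."""


@dataclass
class StudyParams:
    """Shape of the simulated grade meta-analysis inputs."""

    n_studies: int = 7
    n_genes: int = 2000
    samples_per_group: int = 40
    planted_genes: int = 30
    planted_log2_fc: float = 2.0
    noise_sd: float = 0.5


@dataclass
class SimulationConfig:
    """Shared knobs for sequence and study simulation.

    ``read_length`` mirrors the 150-base short-read libraries the
    quantification targets; ``allele_identity`` targets the 91-93%
    pairwise identity typical of confusable HLA allele pairs.
    """

    seed: int = 0
    read_length: int = 150
    n_reads: int = 200_000
    error_rate: float = 0.005
    k: int = 21
    allele_identity: float = 0.92
    study_params: StudyParams = field(default_factory=StudyParams)

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if not 0.80 <= self.allele_identity <= 1.0:
            raise ValueError("allele_identity must be in [0.80, 1.0]")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _mutate(
    rng: np.random.Generator, arr: np.ndarray, n_subs: int
) -> np.ndarray:
    out = arr.copy()
    pos = rng.choice(arr.size, size=n_subs, replace=False)
    shift = rng.integers(1, 4, size=n_subs)
    idx = {b: i for i, b in enumerate(_BASES)}
    cur = np.array([idx[b] for b in out[pos]])
    out[pos] = _BASES[(cur + shift) % 4]
    return out


def make_allele_pair(
    length: int,
    identity: float,
    seed: int,
    *,
    gene: str = "HLA-A",
    group: int = 90,
) -> tuple[TranscriptRecord, TranscriptRecord]:
    """A random coding-like sequence and a mutated copy at the target identity.

    Substitutions are uniformly placed; the observed Hamming identity is
    within one percentage point of ``identity``.
    """
    if length < 200:
        raise ValueError("length must be >= 200")
    if not 0.80 <= identity <= 1.0:
        raise ValueError("identity must be in [0.80, 1.0]")
    rng = np.random.default_rng(seed)
    base = _random_seq(rng, length)
    n_subs = int(round((1.0 - identity) * length))
    other = _mutate(rng, base, n_subs) if n_subs else base.copy()
    a1 = parse_allele(f"{gene}*{group}:01:01")
    a2 = parse_allele(f"{gene}*{group + 1}:01:01")
    return (
        TranscriptRecord(
            id=a1.name, sequence=_decode(base), source="hla_allele", allele=a1
        ),
        TranscriptRecord(
            id=a2.name, sequence=_decode(other), source="hla_allele", allele=a2
        ),
    )


def make_transcriptome(
    n_background: int,
    allele_pairs: int,
    config: SimulationConfig,
    *,
    background_length: int = 1500,
    allele_length: int = 1100,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord], list[str]]:
    """Background transcripts, homologous allele pairs, and a removal list.

    For every allele pair a "decoy" HLA transcript — a third variant of
    the same family, the analogue of a generic reference HLA sequence
    the cell line does not carry — is placed in the reference and listed
    for removal.  Returns ``(reference, alleles, removal_ids)``; the
    reference includes the decoys.
    """
    if n_background < 1:
        raise ValueError("n_background must be >= 1")
    rng = np.random.default_rng(config.seed)
    reference = [
        TranscriptRecord(
            id=f"SIMT{i + 1:07d}",
            sequence=_decode(_random_seq(rng, background_length)),
            source="reference",
        )
        for i in range(n_background)
    ]
    genes = ["HLA-A", "HLA-B", "HLA-C", "HLA-DRB1", "HLA-DRB3", "HLA-DQB1"]
    alleles: list[TranscriptRecord] = []
    removal_ids: list[str] = []
    for p in range(allele_pairs):
        gene = genes[p % len(genes)]
        pair_seed = int(rng.integers(0, 2**31 - 1))
        a1, a2 = make_allele_pair(
            allele_length,
            config.allele_identity,
            pair_seed,
            gene=gene,
            group=90 + 2 * (p // len(genes)),
        )
        alleles.extend([a1, a2])
        # decoy: a reference HLA transcript from the same family, absent
        # from the simulated line, to be removed before indexing
        decoy_rng = np.random.default_rng(pair_seed + 1)
        decoy_arr = _mutate(
            decoy_rng,
            np.frombuffer(a1.sequence.encode(), dtype=np.uint8).copy(),
            int(round(0.10 * allele_length)),
        )
        decoy_id = f"SIMT_HLA_DECOY_{p + 1:03d}_{gene}"
        reference.append(
            TranscriptRecord(
                id=decoy_id, sequence=_decode(decoy_arr), source="reference"
            )
        )
        removal_ids.append(decoy_id)
    return reference, alleles, removal_ids


def simulate_reads(
    transcriptome: Sequence[TranscriptRecord],
    true_tpm: Mapping[str, float],
    config: SimulationConfig,
) -> tuple[list[str], pd.DataFrame]:
    """Draw single-end reads from known TPM abundances.

    A transcript is chosen with probability proportional to
    TPM x effective length (reads per transcript scale with both copy
    number and the number of valid start positions); start positions are
    uniform; substitution errors are applied per base.  Transcripts
    shorter than the read length contribute whole-transcript reads.
    Returns the reads and a truth table of true TPM and realized counts.
    """
    ids = [t.id for t in transcriptome]
    if set(true_tpm) != set(ids):
        raise ValueError("true_tpm must cover exactly the transcriptome ids")
    tpm = np.array([true_tpm[t] for t in ids], dtype=float)
    if abs(tpm.sum() - 1e6) > 1.0:
        raise ValueError(f"true TPM must sum to 1e6, got {tpm.sum():.3f}")
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    eff = np.array([max(1, len(t.sequence) - rl + 1) for t in transcriptome])
    probs = tpm * eff
    probs = probs / probs.sum()
    counts = rng.multinomial(config.n_reads, probs)
    reads: list[str] = []
    order = []
    for t, n in zip(transcriptome, counts):
        if n == 0:
            continue
        arr = np.frombuffer(t.sequence.encode(), dtype=np.uint8)
        L = arr.size
        take = min(rl, L)
        starts = rng.integers(0, L - take + 1, size=n)
        mat = arr[starts[:, None] + np.arange(take)[None, :]]
        if config.error_rate > 0:
            mask = rng.random(mat.shape) < config.error_rate
            n_err = int(mask.sum())
            if n_err:
                idx = {b: i for i, b in enumerate(_BASES)}
                lut = np.zeros(256, dtype=np.uint8)
                for b, i in idx.items():
                    lut[b] = i
                cur = lut[mat[mask]]
                shift = rng.integers(1, 4, size=n_err)
                mat[mask] = _BASES[(cur + shift) % 4]
        for row in mat:
            reads.append(row.tobytes().decode("ascii"))
        order.append(t.id)
    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]
    truth = pd.DataFrame(
        {
            "true_tpm": tpm,
            "eff_length": eff,
            "true_counts": counts,
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    return reads, truth


def simulate_grade_studies(
    config: SimulationConfig,
) -> tuple[list[StudyMatrix], pd.DataFrame]:
    """Independent grade-labelled studies sharing a planted signature.

    Per study, log2 expression = study-specific gene baseline +
    (planted signed log2 fold change, grade-3 samples of planted genes
    only) + Gaussian noise.  Planted genes alternate up/down.  Returns
    the studies and a truth table (gene, direction, log2 fold change).
    """
    p = config.study_params
    if p.planted_genes > p.n_genes:
        raise ValueError("planted gene count exceeds n_genes")
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:05d}" for i in range(p.n_genes)]
    planted = genes[: p.planted_genes]
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(p.planted_genes)])
    studies = []
    for s in range(p.n_studies):
        n = p.samples_per_group
        samples = [f"S{s + 1}_{j + 1:03d}" for j in range(2 * n)]
        grades = np.concatenate(
            [np.full(n, 3), rng.integers(1, 3, size=n)]
        )
        baseline = rng.normal(8.0, 1.0, size=p.n_genes)
        expr = (
            baseline[:, None]
            + rng.normal(0.0, p.noise_sd, size=(p.n_genes, 2 * n))
        )
        effect = np.zeros(p.n_genes)
        effect[: p.planted_genes] = signs * p.planted_log2_fc
        expr[:, :n] += effect[:, None]
        studies.append(
            StudyMatrix(
                study_id=f"STUDY{s + 1}",
                expression=pd.DataFrame(expr, index=genes, columns=samples),
                grade=pd.Series(grades, index=samples),
            )
        )
    truth = pd.DataFrame(
        {
            "direction": ["up" if s > 0 else "down" for s in signs],
            "log2_fc": signs * p.planted_log2_fc,
        },
        index=pd.Index(planted, name="gene"),
    )
    return studies, truth


def _filler_fields(rng: np.random.Generator, forbidden: set[str]) -> str:
    """A 2-digit field value outside ``forbidden``."""
    for _ in range(200):
        v = f"{rng.integers(60, 100):02d}"
        if v not in forbidden:
            return v
    raise RuntimeError("could not draw a distinct field value")  # pragma: no cover


def _non_matching_allele(
    rng: np.random.Generator, locus: str, line_alleles: Sequence[HlaAllele]
) -> HlaAllele:
    first_fields = {a.fields[0] for a in line_alleles}
    f1 = _filler_fields(rng, first_fields)
    return parse_allele(f"{locus}*{f1}:01:01")


def make_cohort_typings(
    line: HlaTyping,
    match_spec: Mapping[str, Mapping[str, str]],
    seed: int,
    *,
    line_expression: Optional[Mapping[str, bool]] = None,
) -> list[HlaTyping]:
    """Generate typings achieving requested match levels against a line.

    ``match_spec`` maps subject id -> locus -> desired level in
    {"allele", "group", "none"}.  Loci not mentioned are left untyped.
    When ``line_expression`` is given, allele- and group-level matches
    are built against expressed line alleles only (so the requested
    level survives the expression gate).  Unsatisfiable requests (e.g. a
    match at a locus the line lacks) raise
    :class:`UnsatisfiableMatchSpec`.
    """
    rng = np.random.default_rng(seed)

    def expressed(a: HlaAllele) -> bool:
        if line_expression is None:
            return True
        for n in range(a.resolution, 0, -1):
            name = truncate_allele(a, n).name
            if name in line_expression:
                return bool(line_expression[name])
        return False

    typings = []
    for subject_id, loci in match_spec.items():
        alleles: dict[str, list[HlaAllele]] = {}
        for locus, level in loci.items():
            if level not in ("allele", "group", "none"):
                raise UnsatisfiableMatchSpec(
                    f"{subject_id}/{locus}: unknown level {level!r}"
                )
            line_all = line.alleles.get(locus, [])
            if level in ("allele", "group") and not line_all:
                raise UnsatisfiableMatchSpec(
                    f"{subject_id}/{locus}: {level} match requested but the "
                    "line is untyped or negative at this locus"
                )
            if level == "allele":
                usable = [
                    a for a in line_all if a.resolution >= 3 and expressed(a)
                ]
                if not usable:
                    raise UnsatisfiableMatchSpec(
                        f"{subject_id}/{locus}: no expressed line allele with "
                        ">=3 fields to match"
                    )
                target = usable[int(rng.integers(0, len(usable)))]
                primary = truncate_allele(target, 3)
            elif level == "group":
                usable = [a for a in line_all if expressed(a)]
                if not usable:
                    raise UnsatisfiableMatchSpec(
                        f"{subject_id}/{locus}: no expressed line allele for a "
                        "group match"
                    )
                target = usable[int(rng.integers(0, len(usable)))]
                # same first field, second field clashing with no line
                # allele of that group: matches at 1 field, never at 2+
                same_group = {
                    a.fields[1]
                    for a in line_all
                    if a.fields[0] == target.fields[0] and a.resolution >= 2
                }
                f2 = _filler_fields(rng, same_group)
                primary = parse_allele(
                    f"{locus}*{target.fields[0]}:{f2}:01"
                )
            else:
                primary = _non_matching_allele(rng, locus, line_all)
            secondary = _non_matching_allele(
                rng, locus, list(line_all) + [primary]
            )
            alleles[locus] = [primary, secondary]
        typings.append(HlaTyping(subject_id=subject_id, alleles=alleles))
    return typings
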