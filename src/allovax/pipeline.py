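"""Configuration, shared I/O, and end-to-end pipeline orchestration.

A :class:`PipelineConfig` names the inputs for whichever stages are to
run; :func:`run_pipeline` executes the configured stages in order
(build-ref -> quantify -> call -> match -> signature -> rmg ->
clinical-summary), writes every output under the output directory, and
records a manifest with all parameters, the seed, and a SHA-256 digest
of every output so a rerun can be verified bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .clinical import (
    clinical_summary,
    load_adverse_event_table,
    load_subject_table,
    write_clinical_summary,
)
from .hla import (
    AugmentationPlan,
    build_augmented_transcriptome,
    load_removal_list,
    load_typing_table,
    read_fasta,
    write_fasta,
)
from .matching import (
    cohort_match_table,
    load_expression_table,
    match_subject,
    write_match_report,
)
from .quantify import (
    AbundanceTable,
    build_index,
    call_expressed,
    compute_tpm,
    em_abundances,
    pseudoalign,
)
from .signature import ConsensusSignature, consensus, load_study, rmg_scores, study_signature

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "read_reads"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


def read_reads(path: str | Path) -> list[str]:
    """Read sequences from FASTA or FASTQ (quality scores ignored)."""
    path = Path(path)
    text = path.read_text().splitlines()
    reads: list[str] = []
    if not text:
        return reads
    if text[0].startswith("@"):  # FASTQ: 4-line records
        for i in range(1, len(text), 4):
            reads.append(text[i].strip().upper())
    elif text[0].startswith(">"):
        current: list[str] = []
        for line in text:
            if line.startswith(">"):
                if current:
                    reads.append("".join(current))
                    current = []
            else:
                current.append(line.strip().upper())
        if current:
            reads.append("".join(current))
    else:
        raise ValueError(f"{path}: not FASTA or FASTQ")
    return reads


def write_reads_fastq(reads: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@read{i + 1}\n{r}\n+\n{'I' * len(r)}\n")


@dataclass
class PipelineConfig:
    """Paths and parameters for the configured pipeline stages.

    Stage inputs left ``None`` skip the stage.  ``reads`` maps a
    condition label (e.g. ``vehicle`` / ``ifng``) to a FASTA/FASTQ path.
    """

    out_dir: str = "allovax_out"
    seed: int = 0
    # build-ref
    reference_fasta: Optional[str] = None
    removal_list: Optional[str] = None
    alleles_fasta: Optional[str] = None
    # quantify
    reads: dict[str, str] = field(default_factory=dict)
    k: int = 21
    read_length: int = 150
    tpm_threshold: float = 1.0
    # match
    typings_csv: Optional[str] = None
    line_id: str = "SV-BR-1-GM"
    expression_tsv: Optional[str] = None
    # signature / rmg
    studies: list[dict] = field(default_factory=list)  # {id, expression, grades}
    fc_min: float = 2.0
    fdr: float = 0.01
    min_studies: int = 5
    cohort_matrix_tsv: Optional[str] = None
    # clinical
    subjects_csv: Optional[str] = None
    adverse_events_csv: Optional[str] = None
    repeat_observations: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def validate(self) -> None:
        """Check every referenced input path exists before any stage runs."""
        paths = [
            self.reference_fasta,
            self.removal_list,
            self.alleles_fasta,
            self.typings_csv,
            self.expression_tsv,
            self.cohort_matrix_tsv,
            self.subjects_csv,
            self.adverse_events_csv,
            *self.reads.values(),
        ]
        for s in self.studies:
            paths.extend([s.get("expression"), s.get("grades")])
        missing = [p for p in paths if p is not None and not Path(p).exists()]
        if missing:
            raise PipelineError(f"missing input files: {missing}")
        if self.k % 2 == 0 or not 11 <= self.k <= 31:
            raise PipelineError(f"k must be odd and in [11, 31], got {self.k}")
        if self.tpm_threshold < 0:
            raise PipelineError("tpm_threshold must be >= 0")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return the manifest (also written).

    Any stage error is re-raised as :class:`PipelineError` naming the
    stage.  With a fixed config and seed the outputs are bit-identical
    across runs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def record(stage: str, outputs: list[Path]) -> None:
        stages.append(
            {
                "stage": stage,
                "outputs": {str(p): _sha256(p) for p in outputs},
            }
        )

    def run_stage(stage: str, fn) -> None:
        try:
            outputs = fn()
        except Exception as exc:  # noqa: BLE001 - report stage context
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        record(stage, outputs)

    augmented_path = out / "augmented.fa"
    index = None
    calls_by_condition: dict[str, list] = {}

    if config.reference_fasta and config.alleles_fasta:

        def _build_ref() -> list[Path]:
            reference = read_fasta(config.reference_fasta)
            alleles = read_fasta(config.alleles_fasta, source="hla_allele")
            removal = (
                load_removal_list(config.removal_list)
                if config.removal_list
                else []
            )
            plan = AugmentationPlan(removal_ids=removal, insertions=alleles)
            augmented = build_augmented_transcriptome(reference, plan)
            write_fasta(augmented, augmented_path)
            nonlocal index
            index = build_index(
                augmented, k=config.k, read_length=config.read_length
            )
            return [augmented_path]

        run_stage("build-ref", _build_ref)

    if config.reads:
        if index is None:
            raise PipelineError(
                "stage 'quantify' failed: no index (configure build-ref)"
            )

        def _quantify() -> list[Path]:
            outputs = []
            for label, reads_path in config.reads.items():
                reads = read_reads(reads_path)
                ecs = pseudoalign(reads, index)
                table = em_abundances(ecs, index)
                table = compute_tpm(table)
                calls = call_expressed(table, threshold=config.tpm_threshold)
                calls_by_condition[label] = calls
                p = out / f"abundance_{label}.tsv"
                table.to_tsv(p, calls=calls)
                outputs.append(p)
            return outputs

        run_stage("quantify", _quantify)

        def _call() -> list[Path]:
            rows = []
            allele_ids = sorted(index.allele_ids) or sorted(index.ids)
            for t in allele_ids:
                row = {"allele": t}
                for label, calls in calls_by_condition.items():
                    expressed = {c.transcript_id: c.expressed for c in calls}
                    row[f"expressed_{label}"] = expressed.get(t, False)
                rows.append(row)
            p = out / "expression_calls.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            return [p]

        run_stage("call", _call)

    if config.typings_csv and config.expression_tsv:

        def _match() -> list[Path]:
            typings = load_typing_table(config.typings_csv)
            by_id = {t.subject_id: t for t in typings}
            if config.line_id not in by_id:
                raise ValueError(
                    f"line {config.line_id!r} not in {config.typings_csv}"
                )
            line = by_id.pop(config.line_id)
            gate = load_expression_table(config.expression_tsv)
            cohort = list(by_id.values())
            table = cohort_match_table(cohort, line, gate)
            p_csv = out / "match_report.csv"
            table.to_csv(p_csv, index=False)
            reports = [match_subject(t, line, gate) for t in cohort]
            p_json = out / "match_report.json"
            write_match_report(reports, p_json)
            return [p_csv, p_json]

        run_stage("match", _match)

    sig: Optional[ConsensusSignature] = None
    if config.studies:

        def _signature() -> list[Path]:
            nonlocal sig
            sigs = {}
            for s in config.studies:
                m = load_study(s["id"], s["expression"], s["grades"])
                sigs[s["id"]] = study_signature(
                    m, fc_min=config.fc_min, fdr=config.fdr
                )
            sig = consensus(sigs, min_studies=config.min_studies)
            p = out / "signature.tsv"
            sig.to_tsv(p)
            return [p]

        run_stage("signature", _signature)

    if config.cohort_matrix_tsv and (sig is not None):

        def _rmg() -> list[Path]:
            matrix = pd.read_csv(config.cohort_matrix_tsv, sep="\t", index_col=0)
            result = rmg_scores(matrix, sig)
            p = out / "rmg.tsv"
            result.to_tsv(p)
            return [p]

        run_stage("rmg", _rmg)

    if config.subjects_csv or config.adverse_events_csv:

        def _clinical() -> list[Path]:
            subjects = load_subject_table(config.subjects_csv)
            aes = load_adverse_event_table(config.adverse_events_csv)
            summary = clinical_summary(
                subjects, aes, repeat_observations=config.repeat_observations
            )
            p = out / "clinical_summary.json"
            write_clinical_summary(summary, p)
            return [p]

        run_stage("clinical-summary", _clinical)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "k": config.k,
            "read_length": config.read_length,
            "tpm_threshold": config.tpm_threshold,
            "fc_min": config.fc_min,
            "fdr": config.fdr,
            "min_studies": config.min_studies,
            "repeat_observations": config.repeat_observations,
            "line_id": config.line_id,
        },
        "stages": stages,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %d stage(s), manifest %s", len(stages), manifest_path)
    return manifest
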