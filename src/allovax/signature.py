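"""Tumor-grade gene-signature meta-analysis and Relative Molecular Grade.

Breast tumors are histologically graded 1 (well differentiated) to 3
(poorly differentiated).  Each expression study is queried for genes at
least two-fold higher or lower in grade-3 tumors than in grade-1/2
tumors at FDR 0.01 (Welch t-test on log2 intensities, Benjamini-
Hochberg correction within the study).  Genes passing in at least
``min_studies`` of the studies with a consistent direction form the
consensus signature, each weighted by its mean log2 fold change across
its qualifying studies.

The Relative Molecular Grade (RMG) scores a sample's resemblance to
grade-3 tumors: signature genes are z-scored across the cohort, summed
with the signed weights, and the raw sums are converted to within-cohort
rank percentiles on a 0-100 scale.  Higher RMG = more grade-3-like
(less differentiated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StudyMatrix",
    "ConsensusSignature",
    "RmgResult",
    "study_signature",
    "consensus",
    "rmg_scores",
    "load_study",
]

logger = logging.getLogger(__name__)

GRADE3 = 3
REFERENCE_GRADES = (1, 2)


@dataclass
class StudyMatrix:
    """One study: genes x samples log2 expression plus per-sample grade."""

    study_id: str
    expression: pd.DataFrame  # genes x samples, log2 intensities
    grade: pd.Series  # per sample, in {1, 2, 3}

    def __post_init__(self) -> None:
        if not set(self.grade.index) >= set(self.expression.columns):
            raise ValueError(f"{self.study_id}: grades missing for some samples")
        self.grade = self.grade.loc[self.expression.columns]
        if self.grade.isna().any():
            raise ValueError(f"{self.study_id}: missing grade labels")
        bad = set(self.grade.unique()) - {1, 2, 3}
        if bad:
            raise ValueError(f"{self.study_id}: invalid grades {sorted(bad)}")
        n3 = int((self.grade == GRADE3).sum())
        n12 = int(self.grade.isin(REFERENCE_GRADES).sum())
        if n3 < 2 or n12 < 2:
            raise ValueError(
                f"{self.study_id}: need >=2 samples per grade group "
                f"(grade 3: {n3}, grade 1/2: {n12})"
            )


def study_signature(
    m: StudyMatrix, fc_min: float = 2.0, fdr: float = 0.01
) -> pd.DataFrame:
    """Per-study differential genes: grade 3 vs grade 1-or-2.

    Welch two-sample t-test per gene on log2 values, BH correction over
    all genes in the study.  A gene passes iff |log2 fold change| >=
    log2(fc_min) and its BH q-value <= fdr (both thresholds inclusive).
    Returns a DataFrame of passing genes with columns ``log2_fc``,
    ``p_value``, ``fdr_q`` and ``direction``.
    """
    g3 = m.expression.loc[:, (m.grade == GRADE3).to_numpy()]
    g12 = m.expression.loc[:, m.grade.isin(REFERENCE_GRADES).to_numpy()]
    log2_fc = g3.mean(axis=1) - g12.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(
            g3.to_numpy(), g12.to_numpy(), axis=1, equal_var=False
        )
    p = np.where(np.isfinite(p), p, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    stats_df = pd.DataFrame(
        {"log2_fc": log2_fc, "p_value": p, "fdr_q": q}, index=m.expression.index
    )
    passing = stats_df[
        (stats_df["log2_fc"].abs() >= np.log2(fc_min)) & (stats_df["fdr_q"] <= fdr)
    ].copy()
    passing["direction"] = np.where(passing["log2_fc"] > 0, "up", "down")
    passing.index.name = "gene"
    return passing


@dataclass
class ConsensusSignature:
    """Signed, weighted gene list from the multi-study meta-analysis."""

    entries: pd.DataFrame  # index gene; columns direction, weight, n_studies
    min_studies: int = 5

    def __post_init__(self) -> None:
        sign = np.where(self.entries["direction"] == "up", 1.0, -1.0)
        if not (np.sign(self.entries["weight"]) == sign).all():
            raise ValueError("weight sign disagrees with direction")
        if (self.entries["n_studies"] < self.min_studies).any():
            raise ValueError("entry with fewer qualifying studies than required")

    @property
    def weights(self) -> pd.Series:
        return self.entries["weight"]

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, min_studies: int = 5) -> "ConsensusSignature":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(entries=df, min_studies=min_studies)


def consensus(
    signatures: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    min_studies: int = 5,
) -> ConsensusSignature:
    """Combine per-study signatures into the consensus gene list.

    A gene is included iff it passes in at least ``min_studies`` studies
    with the same direction; its weight is the mean log2 fold change
    over those qualifying studies.  Invariant to study input order.
    """
    if isinstance(signatures, Mapping):
        sig_list = list(signatures.values())
    else:
        sig_list = list(signatures)
    if len(sig_list) < min_studies:
        raise ValueError(
            f"need at least {min_studies} studies, got {len(sig_list)}"
        )
    per_gene: dict[tuple[str, str], list[float]] = {}
    for sig in sig_list:
        for gene, row in sig.iterrows():
            per_gene.setdefault((gene, row["direction"]), []).append(
                float(row["log2_fc"])
            )
    rows = []
    for (gene, direction), fcs in per_gene.items():
        if len(fcs) >= min_studies:
            rows.append(
                {
                    "gene": gene,
                    "direction": direction,
                    "weight": float(np.mean(fcs)),
                    "n_studies": len(fcs),
                }
            )
    entries = (
        pd.DataFrame(rows, columns=["gene", "direction", "weight", "n_studies"])
        .set_index("gene")
        .sort_index()
    )
    return ConsensusSignature(entries=entries, min_studies=min_studies)


@dataclass
class RmgResult:
    """Per-sample raw weighted z-score sums and 0-100 rank percentiles."""

    scores: pd.DataFrame  # index sample; columns raw, rmg
    n_genes_used: int = 0
    genes_dropped: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        out = self.scores.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")


def rmg_scores(
    cohort_expression: pd.DataFrame, sig: ConsensusSignature
) -> RmgResult:
    """Score each sample's resemblance to grade-3 tumors.

    Each signature gene is z-scored across samples (zero-variance genes
    contribute 0); the raw score is the weight-signed sum of z-scores;
    RMG is the within-cohort rank percentile, ``100 * (rank - 0.5) / n``
    with average ranks for ties, so values lie strictly inside (0, 100)
    and two identical samples both score 50 in a cohort of two.
    """
    if cohort_expression.shape[1] < 2:
        raise ValueError("need at least 2 samples to rank")
    present = [g for g in sig.entries.index if g in cohort_expression.index]
    dropped = [g for g in sig.entries.index if g not in cohort_expression.index]
    if dropped:
        logger.warning(
            "%d signature gene(s) absent from the cohort matrix: %s",
            len(dropped),
            ", ".join(dropped[:10]),
        )
    if not present:
        raise ValueError("no signature gene present in the cohort matrix")
    expr = cohort_expression.loc[present]
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=0)
    z = expr.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    raw = z.mul(sig.weights.loc[present], axis=0).sum(axis=0)
    ranks = stats.rankdata(raw.to_numpy(), method="average")
    rmg = 100.0 * (ranks - 0.5) / len(ranks)
    scores = pd.DataFrame(
        {"raw": raw.to_numpy(), "rmg": rmg},
        index=pd.Index(cohort_expression.columns, name="sample"),
    )
    return RmgResult(scores=scores, n_genes_used=len(present), genes_dropped=dropped)


def load_study(
    study_id: str, expression_path: str | Path, grades_path: str | Path
) -> StudyMatrix:
    """Read one study from an expression TSV (genes x samples) and a grade CSV.

    The grade CSV has columns ``sample`` and ``grade``.
    """
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    grades = pd.read_csv(grades_path, dtype={"sample": str}).set_index("sample")[
        "grade"
    ]
    return StudyMatrix(study_id=study_id, expression=expr, grade=grades)
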