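"""Trial summary statistics, DTH maxima, serology, and qPCR relative expression.

Operates on tabular transcriptions of the trial's subject, treatment,
and adverse-event tables (shipped with the package) or on any records
with the same shape.  Medians over an even number of subjects are the
mean of the central pair, additionally reported rounded half-up to
integer days — the convention the trial summaries use.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "AdverseEventRecord",
    "SkinTestMeasurement",
    "SerologySample",
    "QpcrWell",
    "MedianSummary",
    "summarize_exposure",
    "summarize_ttp",
    "survival_exceeding",
    "tally_adverse_events",
    "max_reaction_per_visit",
    "percent_change_mfi",
    "qpcr_relative_expression",
    "load_subject_table",
    "load_adverse_event_table",
    "load_demographics_table",
    "clinical_summary",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SubjectRecord:
    """One trial subject's treatment exposure and outcome (series 1).

    Off-protocol retreatment series values are carried separately and
    never enter the cohort summaries.
    """

    subject_id: str
    age: Optional[float] = None
    ecog: Optional[int] = None
    n_inoculations_series1: int = 0
    days_on_treatment_series1: float = 0.0
    ttp_series1: float = 0.0
    survival_months: float = 0.0
    tumor_regression: bool = False
    retreated: bool = False
    n_inoculations_series23: Optional[int] = None
    days_on_treatment_series23: Optional[float] = None
    ttp_series23: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "n_inoculations_series1",
            "days_on_treatment_series1",
            "ttp_series1",
            "survival_months",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.subject_id}: {name} must be >= 0")
        if not self.retreated and any(
            v is not None
            for v in (
                self.n_inoculations_series23,
                self.days_on_treatment_series23,
                self.ttp_series23,
            )
        ):
            raise ValueError(
                f"{self.subject_id}: series-2/3 values present but subject "
                "is not flagged retreated"
            )


@dataclass
class AdverseEventRecord:
    term: str
    n_patients: int
    grade_range: str = ""

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"{self.term}: n_patients must be >= 1")


@dataclass
class SkinTestMeasurement:
    subject_id: str
    visit: str
    site: str
    erythema_diameter: float = 0.0
    induration_diameter: float = 0.0

    def __post_init__(self) -> None:
        if self.erythema_diameter < 0 or self.induration_diameter < 0:
            raise ValueError("diameters must be >= 0")


@dataclass
class SerologySample:
    subject_id: str
    timepoint: str
    dilution: str  # "1:3" | "1:25"
    mfi: float

    def __post_init__(self) -> None:
        if self.mfi < 0:
            raise ValueError("MFI must be >= 0")


@dataclass
class QpcrWell:
    sample: str
    target: str
    ct_target: float
    ct_reference: float  # reference gene, e.g. ACTB

    def __post_init__(self) -> None:
        if self.ct_target is None or self.ct_reference is None:
            raise ValueError("missing Ct value")
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValueError("Ct values must be > 0")


@dataclass
class MedianSummary:
    median_raw: float
    median_rounded: int
    minimum: float
    maximum: float
    n: int


def _median_summary(values: Sequence[float]) -> MedianSummary:
    if len(values) == 0:
        raise ValueError("no records to summarize")
    arr = np.sort(np.asarray(values, dtype=float))
    med = float(np.median(arr))
    return MedianSummary(
        median_raw=med,
        median_rounded=_round_half_up(med),
        minimum=float(arr[0]),
        maximum=float(arr[-1]),
        n=len(arr),
    )


def summarize_exposure(
    records: Sequence[SubjectRecord],
) -> dict[str, MedianSummary]:
    """Median and range of series-1 inoculation counts and days on treatment."""
    return {
        "inoculations": _median_summary(
            [r.n_inoculations_series1 for r in records]
        ),
        "days_on_treatment": _median_summary(
            [r.days_on_treatment_series1 for r in records]
        ),
    }


def summarize_ttp(records: Sequence[SubjectRecord]) -> MedianSummary:
    """Median and range of series-1 time to tumor progression (days)."""
    return _median_summary([r.ttp_series1 for r in records])


def survival_exceeding(records: Sequence[SubjectRecord], threshold: float) -> int:
    """Count subjects with overall survival strictly above ``threshold`` months."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return sum(1 for r in records if r.survival_months > threshold)


def tally_adverse_events(
    records: Sequence[AdverseEventRecord], repeat_observations: int = 0
) -> dict[str, int]:
    """Total adverse events: distinct term-patient pairs plus repeats."""
    if repeat_observations < 0:
        raise ValueError("repeat_observations must be >= 0")
    patient_event_sum = sum(r.n_patients for r in records)
    return {
        "n_terms": len(records),
        "patient_event_sum": patient_event_sum,
        "repeat_observations": repeat_observations,
        "total_events": patient_event_sum + repeat_observations,
    }


def max_reaction_per_visit(
    measurements: Sequence[SkinTestMeasurement],
) -> pd.DataFrame:
    """Largest diameter over sites, per subject x visit, for each measure."""
    if not measurements:
        raise ValueError("no measurements")
    df = pd.DataFrame([asdict(m) for m in measurements])
    out = (
        df.groupby(["subject_id", "visit"], sort=False)
        .agg(
            max_erythema=("erythema_diameter", "max"),
            max_induration=("induration_diameter", "max"),
            n_sites=("site", "count"),
        )
        .reset_index()
    )
    return out


def percent_change_mfi(sample: SerologySample, baseline: SerologySample) -> float:
    """Percent change of MFI relative to baseline, same subject and dilution."""
    if sample.subject_id != baseline.subject_id:
        raise ValueError("subject mismatch between sample and baseline")
    if sample.dilution != baseline.dilution:
        raise ValueError("dilution mismatch between sample and baseline")
    if baseline.mfi <= 0:
        raise ValueError("baseline MFI must be > 0")
    return 100.0 * (sample.mfi - baseline.mfi) / baseline.mfi


def qpcr_relative_expression(
    sample: QpcrWell, calibrator: QpcrWell
) -> dict[str, float]:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_sample - (Ct_target -
    Ct_reference)_calibrator; fold = 2^-ddCt; percent = 100 * fold.
    """
    d_sample = sample.ct_target - sample.ct_reference
    d_cal = calibrator.ct_target - calibrator.ct_reference
    ddct = d_sample - d_cal
    fold = 2.0**-ddct
    return {"ddct": ddct, "fold": fold, "percent_of_calibrator": 100.0 * fold}


def _data_path(name: str):
    return resources.files("allovax.data").joinpath(name)


def load_subject_table(path: str | Path | None = None) -> list[SubjectRecord]:
    """Read subject treatment/outcome records (defaults to the packaged table)."""
    src = path if path is not None else _data_path("table3_treatment.csv")
    df = pd.read_csv(src)
    records = []
    for row in df.itertuples(index=False):
        retreated = bool(row.retreated)
        records.append(
            SubjectRecord(
                subject_id=row.subject_id,
                n_inoculations_series1=int(row.n_inoculations_series1),
                days_on_treatment_series1=float(row.days_on_treatment_series1),
                ttp_series1=float(row.ttp_series1),
                survival_months=float(row.survival_months),
                tumor_regression=bool(row.tumor_regression),
                retreated=retreated,
                n_inoculations_series23=(
                    int(row.n_inoculations_series23) if retreated else None
                ),
                days_on_treatment_series23=(
                    float(row.days_on_treatment_series23) if retreated else None
                ),
                ttp_series23=(float(row.ttp_series23) if retreated else None),
            )
        )
    return records


def load_adverse_event_table(
    path: str | Path | None = None,
) -> list[AdverseEventRecord]:
    """Read adverse-event records (defaults to the packaged table)."""
    src = path if path is not None else _data_path("table4_adverse_events.csv")
    df = pd.read_csv(src)
    return [
        AdverseEventRecord(
            term=row.term,
            n_patients=int(row.n_patients),
            grade_range=str(row.grade_range),
        )
        for row in df.itertuples(index=False)
    ]


def load_demographics_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read subject demographics (defaults to the packaged table)."""
    src = path if path is not None else _data_path("table2_subjects.csv")
    return pd.read_csv(src)


def clinical_summary(
    subjects: Sequence[SubjectRecord],
    adverse_events: Sequence[AdverseEventRecord],
    *,
    repeat_observations: int = 0,
    survival_threshold_months: float = 33.0,
) -> dict:
    """Full cohort summary as a JSON-serializable dict."""
    exposure = summarize_exposure(subjects)
    ttp = summarize_ttp(subjects)
    return {
        "n_subjects": len(subjects),
        "inoculations": asdict(exposure["inoculations"]),
        "days_on_treatment": asdict(exposure["days_on_treatment"]),
        "ttp_days": asdict(ttp),
        "survival_months": {
            "min": min(r.survival_months for r in subjects),
            "max": max(r.survival_months for r in subjects),
            f"n_over_{survival_threshold_months:g}": survival_exceeding(
                subjects, survival_threshold_months
            ),
        },
        "adverse_events": tally_adverse_events(
            adverse_events, repeat_observations
        ),
        "n_with_tumor_regression": sum(
            1 for r in subjects if r.tumor_regression
        ),
    }


def write_clinical_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
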