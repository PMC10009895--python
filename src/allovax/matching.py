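"""Patient-vs-cell-line HLA match classification with an expression gate.

A locus matches at *allele* level when a patient allele and a line
allele agree over the first three fields (the CDS level) and the line
allele is expressed — present in the line's transcriptome at least
following IFN-gamma stimulation.  Failing that, *group* matches are
tried at two fields, then one; the finest resolution with a match is
reported.  Line alleles that match by sequence but fail the expression
gate are recorded separately: sequence identity without expression
cannot contribute antigen presentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .hla import (
    CLASS_I_LOCI,
    CLASS_II_LOCI,
    HlaAllele,
    HlaTyping,
    alleles_match_at,
    truncate_allele,
)
from .quantify import ExpressionCall

__all__ = [
    "MatchResult",
    "MatchReport",
    "match_locus",
    "match_subject",
    "cohort_match_table",
    "load_expression_table",
    "gate_from_calls",
]

ALLELE_RESOLUTION = 3  # CDS level: first 3 fields


@dataclass
class MatchResult:
    locus: str
    level: str  # "allele" | "group" | "none"
    matched_alleles: list[tuple[HlaAllele, HlaAllele]] = field(default_factory=list)
    group_resolution: Optional[int] = None
    # pairs agreeing at <3 fields but not at the CDS level, kept even when
    # the locus already has an allele-level match via another pair
    group_matches: list[tuple[HlaAllele, HlaAllele, int]] = field(
        default_factory=list
    )
    expression_gated_out: list[HlaAllele] = field(default_factory=list)
    untyped: bool = False

    @property
    def match_names(self) -> list[str]:
        """Matched allele prefixes at the resolution of the match."""
        n = ALLELE_RESOLUTION if self.level == "allele" else self.group_resolution
        if n is None:
            return []
        names = []
        for _, line_allele in self.matched_alleles:
            name = truncate_allele(line_allele, min(n, line_allele.resolution)).name
            if name not in names:
                names.append(name)
        return names

    @property
    def group_match_names(self) -> list[str]:
        """Group-match prefixes at their resolutions (allele matches aside)."""
        names = []
        for _, line_allele, n in self.group_matches:
            name = truncate_allele(line_allele, min(n, line_allele.resolution)).name
            if name not in names:
                names.append(name)
        return names


@dataclass
class MatchReport:
    subject_id: str
    results: dict[str, MatchResult]
    class_I_loci_matched: list[str] = field(default_factory=list)
    class_II_loci_matched: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "class_I_loci_matched": self.class_I_loci_matched,
            "class_II_loci_matched": self.class_II_loci_matched,
            "loci": {
                locus: {
                    "level": r.level,
                    "resolution": (
                        ALLELE_RESOLUTION
                        if r.level == "allele"
                        else r.group_resolution
                    ),
                    "matches": r.match_names,
                    "matched_pairs": [
                        [p.name, l.name] for p, l in r.matched_alleles
                    ],
                    "group_matches": r.group_match_names,
                    "expression_gated_out": [
                        a.name for a in r.expression_gated_out
                    ],
                    "untyped": r.untyped,
                }
                for locus, r in self.results.items()
            },
        }


def _is_expressed(allele: HlaAllele, gate: Mapping[str, bool]) -> bool:
    """Look up an allele in the gate, falling back to coarser names.

    Expression calls from quantification are keyed by the CDS-level
    (3-field) allele id, while typings may carry a fourth, non-coding
    field.
    """
    for n in range(allele.resolution, 0, -1):
        name = truncate_allele(allele, n).name
        if name in gate:
            return bool(gate[name])
    raise KeyError(
        f"no expression call covers line allele {allele.name}"
    )


def _dedupe(alleles: Sequence[HlaAllele]) -> list[HlaAllele]:
    seen: set[str] = set()
    out = []
    for a in alleles:
        if a.name not in seen:
            seen.add(a.name)
            out.append(a)
    return out


def match_locus(
    locus: str,
    patient: Sequence[HlaAllele],
    line: Sequence[HlaAllele],
    line_expression: Mapping[str, bool],
    *,
    gate_group_matches: bool = True,
) -> MatchResult:
    """Classify one locus as allele / group / no match.

    Homozygous alleles count once.  With ``gate_group_matches`` (the
    default) the expression gate applies at group resolution as well.
    """
    for a in list(patient) + list(line):
        if a.gene != locus:
            raise ValueError(f"allele {a.name} does not belong to locus {locus}")
    patient_u = _dedupe(patient)
    line_u = _dedupe(line)
    if not patient_u or not line_u:
        return MatchResult(locus=locus, level="none", untyped=not patient_u)
    gated_out: list[HlaAllele] = []

    def pairs_at(
        n: int, apply_gate: bool = True
    ) -> tuple[list[tuple[HlaAllele, HlaAllele]], list[HlaAllele]]:
        matched, gated = [], []
        seen_pairs: set[tuple[str, str]] = set()
        for p in patient_u:
            for l in line_u:
                if not alleles_match_at(p, l, n, strict=True):
                    continue
                key = (
                    truncate_allele(p, n).name,
                    truncate_allele(l, n).name,
                )
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
                if not apply_gate or _is_expressed(l, line_expression):
                    matched.append((p, l))
                else:
                    gated.append(l)
        return matched, gated

    matched, gated = pairs_at(ALLELE_RESOLUTION)
    gated_out.extend(gated)
    # group candidates at the finest sub-CDS resolution per pair, collected
    # even when another pair already matches at allele level
    group_matches: list[tuple[HlaAllele, HlaAllele, int]] = []
    seen_group: set[tuple[str, str]] = set()
    for n in (2, 1):
        g_matched, g_gated = pairs_at(n, apply_gate=gate_group_matches)
        for p, l in g_matched:
            if alleles_match_at(p, l, ALLELE_RESOLUTION, strict=True):
                continue  # that pair is an allele-level match, not a group one
            key = (p.name, l.name)
            if key not in seen_group:
                seen_group.add(key)
                group_matches.append((p, l, n))
        for g in g_gated:
            if g.name not in {x.name for x in gated_out}:
                gated_out.append(g)
    if matched:
        return MatchResult(
            locus=locus,
            level="allele",
            matched_alleles=matched,
            group_matches=group_matches,
            expression_gated_out=_dedupe(gated_out),
        )
    if group_matches:
        best = max(n for *_, n in group_matches)
        return MatchResult(
            locus=locus,
            level="group",
            matched_alleles=[(p, l) for p, l, n in group_matches if n == best],
            group_resolution=best,
            group_matches=group_matches,
            expression_gated_out=_dedupe(gated_out),
        )
    return MatchResult(
        locus=locus, level="none", expression_gated_out=_dedupe(gated_out)
    )


def match_subject(
    patient: HlaTyping,
    line: HlaTyping,
    line_expression: Mapping[str, bool],
    *,
    gate_group_matches: bool = True,
) -> MatchReport:
    """Per-locus match results plus Class I / Class II rollups.

    Loci are taken from the line typing; loci the patient typing lacks
    (e.g. not determined) yield level ``none`` flagged untyped.  The
    rollups list loci with an allele-level (CDS, expressed) match.
    """
    results: dict[str, MatchResult] = {}
    for locus in line.loci():
        results[locus] = match_locus(
            locus,
            patient.alleles.get(locus, []),
            line.alleles[locus],
            line_expression,
            gate_group_matches=gate_group_matches,
        )
    class_i = [l for l in CLASS_I_LOCI if results.get(l) and results[l].level == "allele"]
    class_ii = [l for l in CLASS_II_LOCI if results.get(l) and results[l].level == "allele"]
    return MatchReport(
        subject_id=patient.subject_id,
        results=results,
        class_I_loci_matched=class_i,
        class_II_loci_matched=class_ii,
    )


def cohort_match_table(
    typings: Sequence[HlaTyping],
    line: HlaTyping,
    line_expression: Mapping[str, bool],
    *,
    gate_group_matches: bool = True,
) -> pd.DataFrame:
    """One row per subject x locus across a cohort."""
    if not typings:
        raise ValueError("cohort must contain at least one subject")
    ids = [t.subject_id for t in typings]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in cohort")
    rows = []
    for typing in typings:
        report = match_subject(
            typing, line, line_expression, gate_group_matches=gate_group_matches
        )
        for locus, r in report.results.items():
            rows.append(
                {
                    "subject_id": typing.subject_id,
                    "locus": locus,
                    "level": r.level,
                    "resolution": (
                        ALLELE_RESOLUTION
                        if r.level == "allele"
                        else (r.group_resolution if r.group_resolution else pd.NA)
                    ),
                    "matches": ";".join(r.match_names),
                    "group_matches": ";".join(r.group_match_names),
                    "expression_gated_out": ";".join(
                        a.name for a in r.expression_gated_out
                    ),
                    "untyped": r.untyped,
                }
            )
    return pd.DataFrame(rows)


def load_expression_table(path: str | Path) -> dict[str, bool]:
    """Read an allele expression TSV into the match gate.

    Columns: ``allele``, ``expressed_vehicle``, ``expressed_ifng``.  The
    gate passes when the allele is expressed in either condition —
    "expressed at least following IFN-gamma stimulation".
    """
    df = pd.read_csv(path, sep="\t", dtype={"allele": str})
    required = {"allele", "expressed_vehicle", "expressed_ifng"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression table must have columns {sorted(required)}")

    def _to_bool(v) -> bool:
        if isinstance(v, str):
            return v.strip().lower() in ("true", "1", "yes", "t")
        return bool(v)

    return {
        row.allele: _to_bool(row.expressed_vehicle) or _to_bool(row.expressed_ifng)
        for row in df.itertuples(index=False)
    }


def gate_from_calls(
    vehicle: Sequence[ExpressionCall], ifng: Sequence[ExpressionCall]
) -> dict[str, bool]:
    """Build the gate as the OR of vehicle and IFN-gamma expression calls."""
    gate: dict[str, bool] = {}
    for call in list(vehicle) + list(ifng):
        gate[call.transcript_id] = gate.get(call.transcript_id, False) or call.expressed
    return gate


def write_match_report(reports: Sequence[MatchReport], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in reports], indent=2) + "\n"
    )
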