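"""Per-patient diagnostic-alteration detection in CSF cfDNA and cohort tallies.

For each patient, the alterations that established the molecular diagnosis in
the primary tumor (SNVs and copy-number alterations) carry a flag saying
whether they were also found in the CSF cfDNA; notes record why detection was
impossible (non-contributive sample, gene not on the CSF panel, no copy-number
analysis for targeted data) and never count as detection.  Cohort tallies
count patients with at least one diagnostic alteration detected in CSF, with
entity-restricted views for the subgroup-defining drivers (WNT medulloblastoma
CTNNB1/APC, ATRT SMARCB1, ETMR C19MC).

Alterations flagged ``suggestive`` (subgroup-compatible but not diagnostic on
their own, e.g. a 1q gain in CNS neuroblastoma FOXR2) count toward CNA
detection but not toward the diagnostic tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .panel_io import ENTITIES

CSF_NOTES = frozenset({"", "non_contributive", "no_cn_analysis", "genes_not_in_panel"})


@dataclass(frozen=True)
class DiagnosticAlteration:
    """One molecularly diagnostic (or suggestive) alteration of a patient."""

    kind: str  # SNV | CNA
    descriptor: str
    flag: str = "diagnostic"  # diagnostic | suggestive
    in_tumor: bool = True
    detected_in_csf: bool = False
    csf_note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in {"SNV", "CNA"}:
            raise ValueError(f"kind must be SNV or CNA, got {self.kind!r}")
        if self.flag not in {"diagnostic", "suggestive"}:
            raise ValueError(f"flag must be diagnostic or suggestive, got {self.flag!r}")
        if self.csf_note not in CSF_NOTES:
            raise ValueError(f"unknown csf_note {self.csf_note!r}")
        if self.detected_in_csf and not self.in_tumor:
            raise ValueError(
                f"{self.descriptor}: CSF detection of a tumor-absent alteration is out of "
                "scope here (CSF-only findings belong to variant concordance)"
            )


@dataclass
class PatientDiagnosticRecord:
    """A patient's entity label and diagnostic alterations with CSF status."""

    patient_id: str
    entity: str
    alterations: list[DiagnosticAlteration] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.entity not in ENTITIES:
            raise ValueError(f"{self.patient_id}: unknown entity {self.entity!r}")


@dataclass(frozen=True)
class PatientVerdicts:
    any_diagnostic_in_csf: bool
    any_cna_in_csf: bool
    any_snv_in_csf: bool


@dataclass
class CohortTally:
    """Cohort-level detection counts."""

    n_patients: int
    n_diagnostic_detected: int
    n_cna_in_csf: int
    n_snv_in_csf: int
    per_entity: dict[str, tuple[int, int]]  # entity -> (detected, total)


def evaluate_patient(record: PatientDiagnosticRecord) -> PatientVerdicts:
    """Patient-level detection verdicts.

    ``any_diagnostic_in_csf`` requires a diagnostic-flagged alteration found
    in CSF; CNA/SNV verdicts count alterations of any flag.  One detected
    alteration suffices even when others of the same patient were missed.
    """
    return PatientVerdicts(
        any_diagnostic_in_csf=any(
            a.flag == "diagnostic" and a.detected_in_csf for a in record.alterations
        ),
        any_cna_in_csf=any(a.kind == "CNA" and a.detected_in_csf for a in record.alterations),
        any_snv_in_csf=any(a.kind == "SNV" and a.detected_in_csf for a in record.alterations),
    )


def tally_cohort(
    records: Sequence[PatientDiagnosticRecord],
    entity_filter: str | None = None,
) -> CohortTally:
    """Count patients with diagnostic / CNA / SNV detection in CSF cfDNA."""
    if entity_filter is not None:
        records = [r for r in records if r.entity == entity_filter]
    if not records:
        raise ValueError("tally_cohort requires at least one record")
    verdicts = [(r, evaluate_patient(r)) for r in records]
    per_entity: dict[str, tuple[int, int]] = {}
    for r, v in verdicts:
        det, tot = per_entity.get(r.entity, (0, 0))
        per_entity[r.entity] = (det + int(v.any_diagnostic_in_csf), tot + 1)
    return CohortTally(
        n_patients=len(records),
        n_diagnostic_detected=sum(v.any_diagnostic_in_csf for _, v in verdicts),
        n_cna_in_csf=sum(v.any_cna_in_csf for _, v in verdicts),
        n_snv_in_csf=sum(v.any_snv_in_csf for _, v in verdicts),
        per_entity=per_entity,
    )


def load_cohort_fixture() -> list[PatientDiagnosticRecord]:
    """Load the packaged 25-patient embryonal-brain-tumor cohort.

    The tables transcribe the published per-patient diagnostic alterations and
    their CSF cfDNA detection status; entity labels are assigned from the
    driver alterations (three WNT medulloblastomas, three ATRT, one ETMR, one
    CNS neuroblastoma FOXR2, one embryonal tumor NOS; remaining
    medulloblastomas carry no finer subgroup label).
    """
    data = resources.files("csfcfdna.data")
    with data.joinpath("ebt_cohort_patients.tsv").open() as fh:
        patients = pd.read_csv(fh, sep="\t", dtype={"patient_id": str})
    with data.joinpath("ebt_cohort_alterations.tsv").open() as fh:
        alts = pd.read_csv(fh, sep="\t", dtype={"patient_id": str}).fillna({"csf_note": ""})
    by_patient: dict[str, list[DiagnosticAlteration]] = {}
    for row in alts.itertuples(index=False):
        by_patient.setdefault(row.patient_id, []).append(
            DiagnosticAlteration(
                kind=row.kind,
                descriptor=row.descriptor,
                flag=row.flag,
                in_tumor=bool(row.in_tumor),
                detected_in_csf=bool(row.detected_in_csf),
                csf_note=str(row.csf_note),
            )
        )
    return [
        PatientDiagnosticRecord(
            patient_id=row.patient_id,
            entity=row.entity,
            alterations=by_patient.get(row.patient_id, []),
        )
        for row in patients.itertuples(index=False)
    ]
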