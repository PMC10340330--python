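"""Copy-number segment classification and tumor vs CSF concordance.

Segments (FACETS-style log2 ratios, 1-based inclusive coordinates) are binned
into conventional classes and matched between compartments by chromosome,
direction and reciprocal overlap; the cohort view is an alteration x patient
status matrix with per-alteration frequencies, mirroring the oncoprint-style
summary used for liquid-biopsy concordance studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

CNA_CLASSES = ("amplification", "gain", "neutral", "loss", "homozygous_deletion")

# log2-ratio thresholds: conventional values for FACETS-style total copy ratios
AMPLIFICATION_MIN = 2.0
GAIN_MIN = 0.3
LOSS_MAX = -0.3
HOMOZYGOUS_DELETION_MAX = -1.5

#: classes counting as the same direction when matching tumor vs CSF calls
_DIRECTION = {
    "amplification": "gain",
    "gain": "gain",
    "loss": "loss",
    "homozygous_deletion": "loss",
}


def classify_segment(log2_ratio: float) -> str:
    """Bin a segment's log2 copy ratio into a copy-number class."""
    if not math.isfinite(log2_ratio):
        raise ValueError(f"log2_ratio must be finite, got {log2_ratio}")
    if log2_ratio >= AMPLIFICATION_MIN:
        return "amplification"
    if log2_ratio >= GAIN_MIN:
        return "gain"
    if log2_ratio <= HOMOZYGOUS_DELETION_MAX:
        return "homozygous_deletion"
    if log2_ratio <= LOSS_MAX:
        return "loss"
    return "neutral"


@dataclass(frozen=True)
class CNASegment:
    """One copy-number segment call (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_markers: int
    log2_ratio: float
    cna_class: str = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.chrom}:{self.start}-{self.end}: end < start")
        if self.cna_class is None:
            object.__setattr__(self, "cna_class", classify_segment(self.log2_ratio))
        elif self.cna_class not in CNA_CLASSES:
            raise ValueError(f"unknown cna_class {self.cna_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def direction(self) -> str | None:
        return _DIRECTION.get(self.cna_class)


@dataclass
class CNAConcordance:
    """Per-patient tumor/CSF match status for every non-neutral segment."""

    patient_id: str
    #: (descriptor, status in {both, tumor_only, csf_only}, tumor seg or None, csf seg or None)
    alterations: list[tuple[str, str, CNASegment | None, CNASegment | None]]

    def status_counts(self) -> dict[str, int]:
        counts = {"both": 0, "tumor_only": 0, "csf_only": 0}
        for _, status, _, _ in self.alterations:
            counts[status] += 1
        return counts


def _check_non_overlapping(segments: Sequence[CNASegment], label: str) -> None:
    by_chrom: dict[str, list[CNASegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{label}: overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def reciprocal_overlap(a: CNASegment, b: CNASegment) -> float:
    """Min of the two mutual overlap fractions; 0 for disjoint or cross-chromosome."""
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def match_segments(
    tumor_segments: Sequence[CNASegment],
    csf_segments: Sequence[CNASegment],
    min_reciprocal_overlap: float = 0.5,
    patient_id: str = "patient",
) -> CNAConcordance:
    """Match non-neutral tumor and CSF segments into both/tumor_only/csf_only.

    Two segments match iff they share a chromosome, their classes point the
    same way (amplification pairs with gain, homozygous deletion with loss)
    and their reciprocal overlap reaches the threshold.  Greedy best-overlap
    matching; each segment joins at most one pair.
    """
    _check_non_overlapping(tumor_segments, "tumor")
    _check_non_overlapping(csf_segments, "csf")
    t_alt = [s for s in tumor_segments if s.cna_class != "neutral"]
    c_alt = [s for s in csf_segments if s.cna_class != "neutral"]

    candidates = []
    for i, t in enumerate(t_alt):
        for j, c in enumerate(c_alt):
            if t.direction != c.direction:
                continue
            ov = reciprocal_overlap(t, c)
            if ov >= min_reciprocal_overlap and ov > 0:
                candidates.append((ov, i, j))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))

    matched_t: dict[int, int] = {}
    matched_c: set[int] = set()
    for ov, i, j in candidates:
        if i in matched_t or j in matched_c:
            continue
        matched_t[i] = j
        matched_c.add(j)

    alterations: list[tuple[str, str, CNASegment | None, CNASegment | None]] = []
    for i, t in enumerate(t_alt):
        if i in matched_t:
            c = c_alt[matched_t[i]]
            alterations.append((describe_segment(t), "both", t, c))
        else:
            alterations.append((describe_segment(t), "tumor_only", t, None))
    for j, c in enumerate(c_alt):
        if j not in matched_c:
            alterations.append((describe_segment(c), "csf_only", None, c))
    return CNAConcordance(patient_id=patient_id, alterations=alterations)


def cohort_cna_matrix(concordances: Sequence[CNAConcordance]) -> pd.DataFrame:
    """Alteration x patient status matrix with per-alteration frequencies.

    Rows are canonical alteration descriptors, cells hold the status (empty
    string where absent) and the ``frequency`` column counts patients carrying
    the alteration in either compartment.
    """
    if not concordances:
        raise ValueError("cohort_cna_matrix requires at least one patient")
    patients = [c.patient_id for c in concordances]
    rows: dict[str, dict[str, str]] = {}
    for conc in concordances:
        for desc, status, _, _ in conc.alterations:
            rows.setdefault(desc, {})[conc.patient_id] = status
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=patients).fillna("")
    matrix["frequency"] = (matrix[patients] != "").sum(axis=1)
    return matrix.sort_values("frequency", ascending=False)


# ---------------------------------------------------------------------------
# Arm-level descriptors (packaged cytoband arm table, GRCh37 coordinates)
# ---------------------------------------------------------------------------

_ARM_TABLE: pd.DataFrame | None = None


def _arm_table() -> pd.DataFrame:
    global _ARM_TABLE
    if _ARM_TABLE is None:
        with resources.files("csfcfdna.data").joinpath("chrom_arms_grch37.tsv").open() as fh:
            _ARM_TABLE = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return _ARM_TABLE


_CLASS_LABEL = {
    "gain": "gain",
    "loss": "loss",
    "amplification": "amp",
    "homozygous_deletion": "homdel",
}


def describe_segment(seg: CNASegment, arm_fraction: float = 0.5) -> str:
    """Canonical descriptor: arm-level ("17p loss") when the segment covers at
    least ``arm_fraction`` of one arm, whole-chromosome when it covers both,
    else a locus descriptor ("chr20:30.5-30.8Mb amp")."""
    label = _CLASS_LABEL.get(seg.cna_class, seg.cna_class)
    arms = _arm_table()
    chrom = seg.chrom.removeprefix("chr")
    sub = arms[arms["chrom"] == chrom]
    if not sub.empty:
        covered = []
        for row in sub.itertuples(index=False):
            inter = min(seg.end, row.end) - max(seg.start, row.start) + 1
            if inter > 0 and inter / (row.end - row.start + 1) >= arm_fraction:
                covered.append(row.arm)
        if len(covered) == 2:
            return f"chr{chrom} {label}"
        if len(covered) == 1:
            return f"{chrom}{covered[0]} {label}"
    return f"chr{chrom}:{seg.start / 1e6:.1f}-{seg.end / 1e6:.1f}Mb {label}"
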