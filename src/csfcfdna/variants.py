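"""Tumor vs CSF somatic-SNV concordance and clonal-heterogeneity metrics.

A matched pair of somatic variant tables (primary tumor and CSF cfDNA) is
partitioned by exact key matching into shared, tumor-only and CSF-only sets;
shared-variant allele fractions are correlated, and the circulating-tumor-DNA
(ctDNA) fraction of the cfDNA is estimated from shared heterozygous variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantRecord:
    """One somatic SNV/indel allele with its read support.

    ``vaf`` is the variant allele fraction alt_depth / total_depth; it may be
    given explicitly (e.g. from an AF field) but must then agree with the
    depths to within 1e-9.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_depth: int
    total_depth: int
    gene: str | None = None
    vaf: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.alt_depth > self.total_depth:
            raise ValueError(
                f"{self.chrom}:{self.pos} alt_depth {self.alt_depth} > total_depth {self.total_depth}"
            )
        computed = self.alt_depth / self.total_depth if self.total_depth > 0 else 0.0
        if self.vaf is None:
            object.__setattr__(self, "vaf", computed)
        elif self.total_depth > 0 and abs(self.vaf - computed) > 1e-9:
            raise ValueError(
                f"{self.chrom}:{self.pos} vaf {self.vaf} inconsistent with depths ({computed})"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VariantPartition:
    """Shared / tumor-only / CSF-only split of a patient's variant keys."""

    patient_id: str
    shared: set[VariantKey]
    tumor_only: set[VariantKey]
    csf_only: set[VariantKey]
    #: key -> (tumor VAF, CSF VAF) for shared variants
    shared_vafs: dict[VariantKey, tuple[float, float]] = field(default_factory=dict)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.shared), len(self.tumor_only), len(self.csf_only))


@dataclass(frozen=True)
class CtDNAEstimate:
    """Estimated tumor-derived fraction of the CSF cfDNA."""

    patient_id: str
    fraction: float
    n_variants_used: int
    method: str = "2x_median_vaf"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"ctDNA fraction {self.fraction} outside [0, 1]")


def apply_detection_filter(
    variants: Iterable[VariantRecord],
    min_alt: int = 3,
    min_depth: int = 10,
    min_vaf: float = 0.01,
) -> list[VariantRecord]:
    """Keep variants with alt reads, depth and VAF all at or above threshold.

    Defaults (3 alt reads, 10x depth, 1% VAF) mimic the post-caller filters a
    somatic pipeline applies before visual review.
    """
    if min_alt < 0 or min_depth < 0 or min_vaf < 0:
        raise ValueError("detection thresholds must be >= 0")
    return [
        v
        for v in variants
        if v.alt_depth >= min_alt and v.total_depth >= min_depth and v.vaf >= min_vaf
    ]


def _index_by_key(variants: Iterable[VariantRecord], label: str) -> dict[VariantKey, VariantRecord]:
    index: dict[VariantKey, VariantRecord] = {}
    for v in variants:
        if v.key in index:
            raise ValueError(f"duplicate variant key in {label} table: {v.key}")
        index[v.key] = v
    return index


def partition_variants(
    tumor: Iterable[VariantRecord],
    csf: Iterable[VariantRecord],
    patient_id: str = "patient",
) -> VariantPartition:
    """Partition detection-filtered tumor and CSF variants by exact key.

    Keys are (chrom, pos, ref, alt); no positional fuzzing is attempted, so
    indels are assumed to be normalized upstream.
    """
    t_idx = _index_by_key(tumor, "tumor")
    c_idx = _index_by_key(csf, "csf")
    t_keys, c_keys = set(t_idx), set(c_idx)
    shared = t_keys & c_keys
    return VariantPartition(
        patient_id=patient_id,
        shared=shared,
        tumor_only=t_keys - c_keys,
        csf_only=c_keys - t_keys,
        shared_vafs={k: (t_idx[k].vaf, c_idx[k].vaf) for k in shared},
    )


def cohort_partition_summary(partitions: Sequence[VariantPartition]) -> dict:
    """Arithmetic means and (min, max) ranges of shared / tumor-only / CSF-only counts."""
    if not partitions:
        raise ValueError("cohort_partition_summary requires at least one partition")
    out: dict[str, dict[str, float | tuple[int, int]]] = {}
    for name in ("shared", "tumor_only", "csf_only"):
        counts = [len(getattr(p, name)) for p in partitions]
        out[name] = {
            "mean": float(np.mean(counts)),
            "range": (int(min(counts)), int(max(counts))),
        }
    out["n_patients"] = len(partitions)
    return out


def vaf_concordance(
    pairs: VariantPartition | Sequence[tuple[float, float]],
) -> tuple[float, float, int]:
    """Pearson correlation of (tumor VAF, CSF VAF) over shared variants.

    Accepts a partition (its shared pairs are pooled) or an explicit pair
    sequence; returns (r, two-sided p from the t distribution with n-2 df, n).
    """
    if isinstance(pairs, VariantPartition):
        pairs = list(pairs.shared_vafs.values())
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("vaf_concordance requires >= 3 shared VAF pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite VAF in input")
    x, y = arr[:, 0], arr[:, 1]
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance in VAF pairs")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), arr.shape[0]


def estimate_ctdna_fraction(
    csf_shared_variants: Sequence[VariantRecord],
    csf_segments=None,
    patient_id: str = "patient",
) -> CtDNAEstimate:
    """Estimate the ctDNA fraction as min(1, 2 x median CSF VAF).

    For a clonal heterozygous diploid variant the expected CSF VAF is half the
    ctDNA fraction, so twice the median VAF of shared somatic variants is a
    robust plug-in estimate.  When CSF copy-number segments are supplied,
    variants falling inside non-neutral segments are excluded as their VAF is
    distorted by copy state.
    """
    eligible = list(csf_shared_variants)
    if csf_segments is not None:
        from .cna import CNASegment  # noqa: F401  (type of csf_segments)

        def in_altered(v: VariantRecord) -> bool:
            return any(
                s.chrom == v.chrom and s.start <= v.pos <= s.end and s.cna_class != "neutral"
                for s in csf_segments
            )

        eligible = [v for v in eligible if not in_altered(v)]
    if not eligible:
        raise ValueError("no eligible variants for ctDNA fraction estimation")
    median_vaf = float(np.median([v.vaf for v in eligible]))
    return CtDNAEstimate(
        patient_id=patient_id,
        fraction=min(1.0, 2.0 * median_vaf),
        n_variants_used=len(eligible),
    )
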