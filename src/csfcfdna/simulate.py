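"""Synthetic cfDNA inputs with the statistical structure the analysis assumes.

Three generators emit the pipeline's input types together with the planted
ground truth, so every downstream stage can be validated end to end:

* :func:`simulate_tss_coverage` — two-state nucleosome-occupancy coverage over
  2 kb TSS windows: expressed genes carry a Gaussian coverage dip over the
  nucleosome-depleted region (with a phased-nucleosome cosine ripple in the
  flanks), silent genes are flat; per-base depths are Poisson.
* :func:`simulate_variant_cohort` — paired tumor/CSF somatic variant tables
  with planted shared/private fractions; CSF allele fractions are diluted by
  the circulating-tumor-DNA fraction and read counts are binomial.
* :func:`simulate_cna_cohort` — paired copy-number segment lists with planted
  shared and compartment-private alterations.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .panel_io import CoverageTrack, Panel
from .variants import VariantRecord
from .cna import CNASegment

#: expected reads per base contributed per (ng/mL cfDNA) per million library reads.
#: 10 ng/mL at a 1M-read library gives 2 reads/bp, so the 10 ng/mL
#: informativeness boundary sits in an exercisable depth regime.
DEPTH_PER_NG_PER_MREAD = 0.2

NUCLEOSOME_PERIOD = 190  # bp, phased-nucleosome repeat length


@dataclass(frozen=True)
class SimSampleParams:
    """Conditions for one simulated TSS-panel coverage sample.

    ``ndr_depletion`` is the fractional coverage loss at the TSS of expressed
    genes; ``ndr_width`` the Gaussian sigma of the dip in bp.  Base depth is
    proportional to cfdna_conc x library_size (see DEPTH_PER_NG_PER_MREAD).
    """

    library_size: int = 2_000_000
    cfdna_conc: float = 48.0  # cohort mean, ng/mL CSF
    ndr_depletion: float = 0.8
    ndr_width: float = 75.0
    flank_amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ndr_depletion <= 1.0:
            raise ValueError(f"ndr_depletion must be in [0, 1], got {self.ndr_depletion}")
        if not 0.0 < self.ndr_width < 2000.0:
            raise ValueError(f"ndr_width must be in (0, 2000), got {self.ndr_width}")
        if self.flank_amplitude < 0:
            raise ValueError("flank_amplitude must be >= 0")

    @property
    def base_depth(self) -> float:
        return DEPTH_PER_NG_PER_MREAD * self.cfdna_conc * self.library_size / 1e6


@dataclass(frozen=True)
class SimVariantParams:
    """Conditions for one simulated paired tumor/CSF variant cohort.

    Counts may be fixed integers or (lo, hi) inclusive ranges resolved per
    patient.  ``tumor_vaf`` is either a fixed allele fraction or Beta(a, b)
    parameters; the default Beta(10, 10) models clonal heterozygous variants
    with purity/sampling spread.  ``ctdna_fraction`` is a fixed value or a
    (lo, hi) uniform range per patient; the default spans the 0.15-0.86 range
    reported for CSF cfDNA in embryonal brain tumors.
    """

    n_shared: int | tuple[int, int] = 83
    n_tumor_only: int | tuple[int, int] = 18
    n_csf_only: int | tuple[int, int] = 5
    tumor_vaf: float | tuple[float, float] = (10.0, 10.0)
    ctdna_fraction: float | tuple[float, float] = (0.15, 0.86)
    depth_tumor: float = 100.0
    depth_csf: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_shared", "n_tumor_only", "n_csf_only"):
            v = getattr(self, name)
            lo = v[0] if isinstance(v, tuple) else v
            if lo < 0:
                raise ValueError(f"{name} must be >= 0")
        f = self.ctdna_fraction
        hi = f[1] if isinstance(f, tuple) else f
        lo = f[0] if isinstance(f, tuple) else f
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError(f"ctdna_fraction must lie in [0, 1], got {f}")


@dataclass(frozen=True)
class SimCNAParams:
    """Conditions for one simulated paired tumor/CSF copy-number cohort."""

    n_shared: int = 4
    n_tumor_only: int = 2
    n_csf_only: int = 1
    n_markers: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_shared, self.n_tumor_only, self.n_csf_only) < 0:
            raise ValueError("planted segment counts must be >= 0")
        if self.n_shared + self.n_tumor_only + self.n_csf_only > 22:
            raise ValueError("at most 22 planted alterations per patient (one per autosome)")


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside simulated data."""

    expression_state: dict[str, str] = field(default_factory=dict)  # gene -> expressed|silent
    variant_keys: dict[str, dict[str, set]] = field(default_factory=dict)
    ctdna_fraction: dict[str, float] = field(default_factory=dict)
    cna_status: dict[str, list[tuple[CNASegment, str]]] = field(default_factory=dict)


def expected_tss_profile(
    params: SimSampleParams, state: str, window_size: int = 2000
) -> np.ndarray:
    """Noise-free per-base expected depth over one TSS window.

    Expressed genes: base x (1 - d exp(-(x-tss)^2 / 2 sigma^2))
                          x (1 + d A cos(2 pi (x - tss) / 190)).
    Silent genes: flat base depth.  The flank ripple scales with the depletion
    d, since nucleosome phasing exists only around an established NDR; with
    d = 0 both states coincide exactly.
    """
    base = params.base_depth
    if state == "silent":
        return np.full(window_size, base)
    if state != "expressed":
        raise ValueError(f"unknown truth state {state!r}")
    x = np.arange(window_size) - window_size / 2 + 0.5
    dip = 1.0 - params.ndr_depletion * np.exp(-(x**2) / (2.0 * params.ndr_width**2))
    ripple = 1.0 + params.ndr_depletion * params.flank_amplitude * np.cos(
        2.0 * np.pi * x / NUCLEOSOME_PERIOD
    )
    return base * dip * ripple


def simulate_tss_coverage(
    panel: Panel,
    truth_states: Mapping[str, str],
    params: SimSampleParams,
    sample_id: str = "sim",
) -> tuple[CoverageTrack, TruthSet]:
    """Simulate one sample's Poisson coverage track over the panel's TSS windows."""
    windows = panel.tss_windows()
    missing = [w.gene_id for w in windows if w.gene_id not in truth_states]
    if missing:
        raise ValueError(f"no truth state for panel genes: {missing[:5]}")
    rng = np.random.default_rng(params.seed)
    pieces: dict[str, list[tuple[int, np.ndarray]]] = {}
    for w in windows:
        mu = expected_tss_profile(params, truth_states[w.gene_id], w.window_end - w.window_start)
        if w.strand == "-":
            mu = mu[::-1]  # profile is symmetric, but keep the convention explicit
        counts = rng.poisson(mu).astype(float)
        pieces.setdefault(w.chrom, []).append((w.window_start, counts))
    track = CoverageTrack(library_size=params.library_size, sample_id=sample_id)
    for chrom, blocks in pieces.items():
        starts_l, ends_l, vals_l = [], [], []
        for start, counts in sorted(blocks):
            change = np.flatnonzero(np.diff(counts)) + 1
            run_starts = np.concatenate([[0], change])
            run_ends = np.concatenate([change, [counts.size]])
            vals = counts[run_starts]
            keep = vals != 0
            starts_l.append(run_starts[keep] + start)
            ends_l.append(run_ends[keep] + start)
            vals_l.append(vals[keep])
        starts = np.concatenate(starts_l) if starts_l else np.empty(0, dtype=np.int64)
        if starts.size:
            track.add_intervals(chrom, starts, np.concatenate(ends_l), np.concatenate(vals_l))
    truth = TruthSet(expression_state={w.gene_id: truth_states[w.gene_id] for w in windows})
    return track, truth


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _resolve_count(v: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(v, tuple):
        return int(rng.integers(v[0], v[1] + 1))
    return int(v)


def _draw_tumor_vaf(spec: float | tuple[float, float], rng: np.random.Generator, n: int) -> np.ndarray:
    if isinstance(spec, tuple):
        return rng.beta(spec[0], spec[1], size=n)
    return np.full(n, float(spec))


def _unique_keys(n: int, rng: np.random.Generator) -> list[tuple[str, int, str, str]]:
    keys: set[tuple[str, int, str, str]] = set()
    while len(keys) < n:
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(1, 100_000_000))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        keys.add((chrom, pos, str(ref), str(alt)))
    return sorted(keys)


def _make_record(key, vaf_true: float, mean_depth: float, rng: np.random.Generator) -> VariantRecord:
    depth = max(1, int(rng.poisson(mean_depth)))
    alt = int(rng.binomial(depth, min(1.0, max(0.0, vaf_true))))
    return VariantRecord(chrom=key[0], pos=key[1], ref=key[2], alt=key[3], alt_depth=alt, total_depth=depth)


def simulate_variant_cohort(
    n_patients: int,
    params: SimVariantParams,
) -> tuple[dict[str, tuple[list[VariantRecord], list[VariantRecord]]], TruthSet]:
    """Simulate paired tumor/CSF variant tables for a cohort.

    Shared variants appear in both tables; for a heterozygous diploid variant
    with tumor allele fraction v the expected CSF allele fraction is
    v x ctdna_fraction (clonal fraction 2v diluted to ctdna_fraction, halved
    for heterozygosity).  Read counts are Binomial(Poisson depth, VAF).
    """
    rng = np.random.default_rng(params.seed)
    cohort: dict[str, tuple[list[VariantRecord], list[VariantRecord]]] = {}
    truth = TruthSet()
    for i in range(n_patients):
        pid = f"SIM{i + 1:03d}"
        n_sh = _resolve_count(params.n_shared, rng)
        n_t = _resolve_count(params.n_tumor_only, rng)
        n_c = _resolve_count(params.n_csf_only, rng)
        keys = _unique_keys(n_sh + n_t + n_c, rng)
        rng.shuffle(keys)
        shared, tumor_only, csf_only = (
            keys[:n_sh],
            keys[n_sh : n_sh + n_t],
            keys[n_sh + n_t :],
        )
        f = params.ctdna_fraction
        fraction = float(rng.uniform(f[0], f[1])) if isinstance(f, tuple) else float(f)
        tumor_records, csf_records = [], []
        vafs = _draw_tumor_vaf(params.tumor_vaf, rng, len(keys))
        for key, v in zip(shared, vafs[: n_sh]):
            tumor_records.append(_make_record(key, v, params.depth_tumor, rng))
            csf_records.append(_make_record(key, v * fraction, params.depth_csf, rng))
        for key, v in zip(tumor_only, vafs[n_sh : n_sh + n_t]):
            tumor_records.append(_make_record(key, v, params.depth_tumor, rng))
        for key, v in zip(csf_only, vafs[n_sh + n_t :]):
            csf_records.append(_make_record(key, v * fraction, params.depth_csf, rng))
        cohort[pid] = (tumor_records, csf_records)
        truth.variant_keys[pid] = {
            "shared": set(shared),
            "tumor_only": set(tumor_only),
            "csf_only": set(csf_only),
        }
        truth.ctdna_fraction[pid] = fraction
    return cohort, truth


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

_LOG2_BY_CLASS = {
    "gain": (0.3, 0.8),
    "loss": (-0.8, -0.3),
    "amplification": (2.0, 3.0),
    "homozygous_deletion": (-2.5, -1.5),
}

_CHROM_LENGTHS = {f"chr{i}": 50_000_000 + 8_000_000 * i for i in range(1, 23)}


def simulate_cna_cohort(
    n_patients: int,
    params: SimCNAParams,
) -> tuple[dict[str, tuple[list[CNASegment], list[CNASegment]]], TruthSet]:
    """Simulate paired tumor/CSF copy-number segment lists.

    Each planted alteration occupies its own autosome (guaranteeing
    non-overlap); shared alterations are emitted in both compartments with
    independent log2 ratios of the same class, private ones in one only.
    """
    rng = np.random.default_rng(params.seed)
    cohort: dict[str, tuple[list[CNASegment], list[CNASegment]]] = {}
    truth = TruthSet()
    classes = list(_LOG2_BY_CLASS)
    for i in range(n_patients):
        pid = f"SIM{i + 1:03d}"
        total = params.n_shared + params.n_tumor_only + params.n_csf_only
        chroms = rng.choice(np.arange(1, 23), size=total, replace=False)
        statuses = (
            ["both"] * params.n_shared
            + ["tumor_only"] * params.n_tumor_only
            + ["csf_only"] * params.n_csf_only
        )
        tumor_segs, csf_segs, planted = [], [], []
        for chrom_i, status in zip(chroms, statuses):
            chrom = f"chr{chrom_i}"
            length = _CHROM_LENGTHS[chrom]
            start = int(rng.integers(1, length // 2))
            end = int(start + rng.integers(5_000_000, length - start))
            cls = classes[int(rng.integers(len(classes)))]
            lo, hi = _LOG2_BY_CLASS[cls]

            def seg(sample_suffix: str) -> CNASegment:
                return CNASegment(
                    sample_id=f"{pid}_{sample_suffix}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_markers=params.n_markers,
                    log2_ratio=round(float(rng.uniform(lo, hi)), 4),
                )

            if status in ("both", "tumor_only"):
                tumor_segs.append(seg("T"))
            if status in ("both", "csf_only"):
                csf_segs.append(seg("CSF"))
            planted.append((tumor_segs[-1] if status != "csf_only" else csf_segs[-1], status))
        cohort[pid] = (tumor_segs, csf_segs)
        truth.cna_status[pid] = planted
    return cohort, truth


def load_cohort_fixture():
    """Packaged per-patient diagnostic-alteration records for the 25-patient
    embryonal brain tumor cohort (see :mod:`csfcfdna.diagnostics`)."""
    from .diagnostics import load_cohort_fixture as _load

    return _load()
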