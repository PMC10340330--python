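"""Data model for the TSS capture panel and readers/writers for the flat-file
formats the pipeline consumes.

The panel is a set of 2 kb windows centred on transcription start sites
(TSS ±1 kb) of tumor-classification genes, plus control TSSs, coding regions
and mutation hotspots.  Coverage arrives as bedGraph, somatic variants as
VCF 4.x, copy-number segments as SEG, and cohort metadata as TSV.

Coordinate conventions: BED/bedGraph are 0-based half-open on disk; SEG and
VCF are 1-based.  Internally, single positions are 1-based and intervals are
kept in the convention of their source format (documented per field).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TSS_WINDOW_SIZE = 2000

WINDOW_CATEGORIES = frozenset(
    {
        "panel_gene",
        "control_ubiquitous",
        "control_cns_silent",
        "control_cns_expressed",
        "coding_region",
        "hotspot",
    }
)

#: Categories whose windows are TSS-centred and take part in footprinting.
TSS_CATEGORIES = frozenset(
    {"panel_gene", "control_ubiquitous", "control_cns_silent", "control_cns_expressed"}
)

ENTITIES = frozenset(
    {
        "MB_WNT",
        "MB_SHH",
        "MB_G3",
        "MB_G4",
        "MB_NOS",
        "ATRT",
        "ETMR",
        "CNS_NB_FOXR2",
        "EBT_NOS",
    }
)


class PanelFormatError(ValueError):
    """Malformed or invariant-violating panel / track / table input."""


@dataclass(frozen=True)
class TSSWindow:
    """One capture window, usually TSS ±1 kb in genomic orientation.

    ``window_start``/``window_end`` are 0-based half-open; ``tss_pos`` is the
    1-based genomic coordinate of the transcription start site.  Minus-strand
    windows are stored in genomic orientation; transcript-orientation flipping
    happens only when coverage matrices are built.
    """

    gene_id: str
    chrom: str
    tss_pos: int
    strand: str
    window_start: int
    window_end: int
    category: str = "panel_gene"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise PanelFormatError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.category not in WINDOW_CATEGORIES:
            raise PanelFormatError(f"{self.gene_id}: unknown category {self.category!r}")
        if not self.window_start <= self.tss_pos - 1 < self.window_end:
            raise PanelFormatError(
                f"{self.gene_id}: TSS {self.tss_pos} outside window "
                f"[{self.window_start}, {self.window_end})"
            )
        if self.category in TSS_CATEGORIES and self.window_end - self.window_start != TSS_WINDOW_SIZE:
            raise PanelFormatError(
                f"{self.gene_id}: TSS window must span {TSS_WINDOW_SIZE} bp, "
                f"got {self.window_end - self.window_start}"
            )

    @property
    def is_tss(self) -> bool:
        return self.category in TSS_CATEGORIES


@dataclass
class Panel:
    """Ordered collection of capture windows with unique gene identifiers."""

    windows: list[TSSWindow]
    name: str = "tss_panel"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for w in self.windows:
            if w.gene_id in seen:
                raise PanelFormatError(f"duplicate gene_id in panel: {w.gene_id}")
            seen.add(w.gene_id)
        self.windows = sorted(self.windows, key=lambda w: (w.chrom, w.window_start))

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[TSSWindow]:
        return iter(self.windows)

    def tss_windows(self) -> list[TSSWindow]:
        """Windows participating in TSS footprinting (panel genes + controls)."""
        return [w for w in self.windows if w.is_tss]

    def get(self, gene_id: str) -> TSSWindow:
        for w in self.windows:
            if w.gene_id == gene_id:
                return w
        raise KeyError(gene_id)


class CoverageTrack:
    """Sparse per-base sequencing depth for one sample.

    Backed by per-chromosome sorted, non-overlapping 0-based half-open
    intervals; any position not covered by an interval reads as depth 0.
    """

    def __init__(
        self,
        intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
        library_size: int = 0,
        sample_id: str = "sample",
    ):
        if library_size < 0:
            raise PanelFormatError("library_size must be >= 0")
        self.library_size = int(library_size)
        self.sample_id = sample_id
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if intervals:
            for chrom, (starts, ends, values) in intervals.items():
                self.add_intervals(chrom, starts, ends, values)

    def add_intervals(
        self,
        chrom: str,
        starts: Sequence[int],
        ends: Sequence[int],
        values: Sequence[float],
    ) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(ends <= starts):
            raise PanelFormatError(f"{chrom}: empty or inverted interval")
        if np.any(starts[1:] < ends[:-1]):
            raise PanelFormatError(f"{chrom}: overlapping intervals")
        if np.any(values < 0):
            raise PanelFormatError(f"{chrom}: negative coverage value")
        if chrom in self._chroms:
            raise PanelFormatError(f"{chrom}: intervals already registered")
        self._chroms[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def depth_at(self, chrom: str, pos: int) -> float:
        """Depth at a 1-based position; 0.0 outside any interval."""
        return float(self.window_depths(chrom, pos - 1, pos)[0])

    def window_depths(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depths over a 0-based half-open window, zeros where absent."""
        if end < start:
            raise PanelFormatError("window end < start")
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._chroms:
            return out
        starts, ends, values = self._chroms[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            if b > a:
                out[a:b] = values[i]
        return out

    def iter_intervals(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, values = self._chroms[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    @classmethod
    def from_dense(
        cls,
        chrom_arrays: Mapping[str, tuple[int, np.ndarray]],
        library_size: int,
        sample_id: str = "sample",
    ) -> "CoverageTrack":
        """Build a track from dense per-base arrays.

        ``chrom_arrays`` maps chromosome -> (offset, depths) where ``offset``
        is the 0-based start of the dense block.  Runs of equal depth are
        collapsed into single intervals; zero runs are omitted.
        """
        track = cls(library_size=library_size, sample_id=sample_id)
        for chrom, (offset, depths) in chrom_arrays.items():
            depths = np.asarray(depths, dtype=float)
            if depths.size == 0:
                continue
            change = np.flatnonzero(np.diff(depths)) + 1
            run_starts = np.concatenate([[0], change])
            run_ends = np.concatenate([change, [depths.size]])
            vals = depths[run_starts]
            keep = vals != 0
            track.add_intervals(
                chrom,
                run_starts[keep] + offset,
                run_ends[keep] + offset,
                vals[keep],
            )
        return track


@dataclass(frozen=True)
class CohortRow:
    """Per-patient cohort metadata: entity, cfDNA yield and sequencing scale."""

    patient_id: str
    entity: str
    cfdna_conc: float  # ng cfDNA per mL CSF
    library_size: int  # deduplicated reads
    assays: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.entity not in ENTITIES:
            raise PanelFormatError(f"{self.patient_id}: unknown entity {self.entity!r}")
        if self.cfdna_conc < 0:
            raise PanelFormatError(f"{self.patient_id}: cfdna_conc must be >= 0")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_panel_bed(path: str | Path) -> Panel:
    """Read a capture panel from BED6 (optional 7th column = category).

    For 2 kb records the TSS is reconstructed as the window midpoint; other
    records (coding regions, hotspots) also use the midpoint as their anchor.
    """
    windows: list[TSSWindow] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise PanelFormatError(f"{path}:{lineno}: expected >=6 BED columns, got {len(parts)}")
            try:
                chrom, start, end, gene_id, _score, strand = parts[:6]
                start, end = int(start), int(end)
            except ValueError as exc:
                raise PanelFormatError(f"{path}:{lineno}: unparseable coordinates") from exc
            if end <= start:
                raise PanelFormatError(f"{path}:{lineno}: end <= start")
            category = parts[6] if len(parts) > 6 else (
                "panel_gene" if end - start == TSS_WINDOW_SIZE else "coding_region"
            )
            tss_pos = start + (end - start) // 2 + 1  # 1-based midpoint
            try:
                windows.append(
                    TSSWindow(gene_id, chrom, tss_pos, strand, start, end, category)
                )
            except PanelFormatError as exc:
                raise PanelFormatError(f"{path}:{lineno}: {exc}") from exc
    if not windows:
        logger.warning("panel file %s contains no records", path)
        warnings.warn(f"panel file {path} contains no records", stacklevel=2)
    return Panel(windows, name=path.stem)


def write_panel_bed(panel: Panel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in panel.windows:
            fh.write(
                f"{w.chrom}\t{w.window_start}\t{w.window_end}\t{w.gene_id}\t.\t{w.strand}\t{w.category}\n"
            )


def read_bedgraph(path: str | Path, library_size: int, sample_id: str | None = None) -> CoverageTrack:
    """Read a bedGraph coverage file into a :class:`CoverageTrack`.

    Intervals must be 0-based half-open and non-overlapping per chromosome;
    positions absent from the file read as depth 0.
    """
    path = Path(path)
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise PanelFormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise PanelFormatError(f"{path}:{lineno}: unparseable record") from exc
            if value < 0:
                raise PanelFormatError(f"{path}:{lineno}: negative coverage value {value}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    track = CoverageTrack(library_size=library_size, sample_id=sample_id or path.stem)
    for chrom, rows in per_chrom.items():
        starts, ends, values = zip(*rows)
        track.add_intervals(chrom, starts, ends, values)
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def _variant_record_cls():
    # local import: VariantRecord lives with the concordance logic
    from .variants import VariantRecord

    return VariantRecord


def read_vcf_minimal(path: str | Path):
    """Read somatic variants from a VCF 4.x file (first sample column).

    Returns one record per ALT allele; multi-allelic rows are split.  The
    variant allele fraction is taken from the AF field when present and
    otherwise computed as alt depth / total depth from AD/DP.
    """
    from cyvcf2 import VCF

    VariantRecord = _variant_record_cls()
    records = []
    vcf = VCF(str(path))
    try:
        for var in vcf:
            gene = None
            try:
                gene = var.INFO.get("GENE")
            except Exception:
                gene = None
            try:
                ad = var.format("AD")
            except KeyError:
                ad = None
            if ad is None:
                raise PanelFormatError(
                    f"{path}: record {var.CHROM}:{var.POS} {var.REF}>{','.join(var.ALT)} lacks AD depths"
                )
            ad = np.asarray(ad[0]).ravel()  # first sample: [ref, alt1, alt2, ...]
            try:
                dp = var.format("DP")
            except KeyError:
                dp = None
            total_depth = int(ad.sum()) if dp is None else int(np.asarray(dp[0]).ravel()[0])
            for i, alt in enumerate(var.ALT):
                alt_depth = int(ad[i + 1])
                records.append(
                    VariantRecord(
                        chrom=var.CHROM,
                        pos=var.POS,
                        ref=var.REF,
                        alt=alt,
                        alt_depth=alt_depth,
                        total_depth=total_depth,
                        gene=gene,
                    )
                )
    finally:
        vcf.close()
    return records


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf_minimal(records, path: str | Path, sample_id: str = "SAMPLE") -> None:
    """Write variant records as a minimal single-sample VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(sample=sample_id))
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            info = f"GENE={r.gene}" if r.gene else "."
            ref_depth = r.total_depth - r.alt_depth
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\t"
                f"AD:DP\t{ref_depth},{r.alt_depth}:{r.total_depth}\n"
            )


SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_markers", "log2_ratio"]


def read_seg(path: str | Path):
    """Read copy-number segments from a SEG-like TSV (1-based inclusive).

    Segments are sorted per sample and classified by log2 ratio.
    """
    from .cna import CNASegment, classify_segment

    df = pd.read_csv(path, sep="\t", header=0, names=SEG_COLUMNS, dtype={"sample": str, "chrom": str})
    segments = []
    for row in df.itertuples(index=False):
        if row.end < row.start:
            raise PanelFormatError(
                f"{path}: segment {row.sample} {row.chrom}:{row.start}-{row.end} has end < start"
            )
        segments.append(
            CNASegment(
                sample_id=row.sample,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                n_markers=int(row.n_markers),
                log2_ratio=float(row.log2_ratio),
                cna_class=classify_segment(float(row.log2_ratio)),
            )
        )
    segments.sort(key=lambda s: (s.sample_id, s.chrom, s.start))
    return segments


def write_seg(segments, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for s in segments:
            fh.write(
                f"{s.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.n_markers}\t{s.log2_ratio:g}\n"
            )


def load_packaged_panel() -> Panel:
    """Load the packaged TSS capture panel fixture.

    The fixture is synthetic: it carries the panel's structure (112 TSS
    windows of 2 kb, eight control TSSs, six coding regions, five hotspot
    loci) with the named marker and control genes, but placeholder gene names
    (EBT001...) and placeholder coordinates elsewhere, since the full capture
    design is not public.
    """
    from importlib import resources

    ref = resources.files("csfcfdna.data").joinpath("tss_panel_synthetic.bed")
    with resources.as_file(ref) as path:
        panel = read_panel_bed(path)
    panel.name = "tss_panel_synthetic"
    return panel


def read_cohort_table(path: str | Path) -> list[CohortRow]:
    """Read cohort metadata TSV: patient_id, entity, cfdna_conc, library_size[, assays]."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    rows = []
    for rec in df.itertuples(index=False):
        assays = frozenset(
            str(getattr(rec, "assays", "")).split(",") if getattr(rec, "assays", "") else []
        )
        rows.append(
            CohortRow(
                patient_id=rec.patient_id,
                entity=rec.entity,
                cfdna_conc=float(rec.cfdna_conc),
                library_size=int(rec.library_size),
                assays=assays,
            )
        )
    return rows
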