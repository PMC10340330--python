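"""Nucleosome-footprint expression inference from TSS coverage.

Active promoters shed nucleosomes over the nucleosome-depleted region (NDR),
so cfDNA — protected from nuclease digestion only where nucleosome-bound —
shows a local coverage dip over the TSS of expressed genes and a flat profile
over silent ones.  This module turns per-base coverage over 2 kb TSS windows
into binned matrices, classifies genes into two occupancy states by k-means,
gates samples on informativeness, z-scores NDR coverage across samples, calls
expressed/silent states, selects disease-discriminating genes and builds the
hierarchically clustered heatmap view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .panel_io import CohortRow, CoverageTrack, Panel, TSS_WINDOW_SIZE

DEFAULT_BIN_SIZE = 20  # bp; 100 bins per 2 kb window
DEFAULT_NDR_HALFWIDTH = 150  # bp around the TSS
MIN_INFORMATIVE_CONC = 10.0  # ng cfDNA / mL CSF
MIN_INFORMATIVE_LIBRARY = 1_000_000  # deduplicated reads
DEFAULT_MIN_SEPARABILITY = 0.25  # mean silhouette


@dataclass
class CoverageMatrix:
    """Genes x bins mean coverage for one sample, in transcript orientation.

    Bin 0 is 1 kb upstream of the TSS; the TSS sits at the window midpoint.
    ``values`` is a DataFrame indexed by gene_id with integer bin columns.
    """

    sample_id: str
    values: pd.DataFrame
    bin_size: int
    library_size: int
    normalized: str = "raw"  # raw | cpm

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def ndr_bins(self, ndr_halfwidth: int = DEFAULT_NDR_HALFWIDTH) -> list[int]:
        """Bins whose centres lie within ±ndr_halfwidth of the TSS."""
        centre = TSS_WINDOW_SIZE / 2
        out = []
        for i in range(self.n_bins):
            c = i * self.bin_size + self.bin_size / 2
            if abs(c - centre) <= ndr_halfwidth:
                out.append(i)
        return out


@dataclass
class GeneClusterResult:
    """Two-state (open vs closed chromatin) k-means classification of genes."""

    sample_id: str
    labels: dict[str, str]  # gene -> {open, closed}
    cluster_profiles: dict[str, np.ndarray]  # label -> mean profile
    separability: float  # mean silhouette in [-1, 1]
    degenerate: bool = False
    dropped_genes: list[str] = field(default_factory=list)


@dataclass
class SampleInformativeness:
    """Verdict on whether a sample supports two-state TSS clustering."""

    sample_id: str
    cfdna_conc: float
    library_size: int
    separability: float
    informative: bool
    reasons: list[str] = field(default_factory=list)


def build_tss_matrix(
    track: CoverageTrack, panel: Panel, bin_size: int = DEFAULT_BIN_SIZE
) -> CoverageMatrix:
    """Bin per-base coverage over every TSS window of the panel.

    Rows follow panel order restricted to TSS windows; minus-strand windows
    are reversed so every row runs upstream -> downstream of transcription.
    Bin values are arithmetic means of per-base depth.
    """
    if bin_size <= 0 or TSS_WINDOW_SIZE % bin_size != 0:
        raise ValueError(f"bin_size must divide {TSS_WINDOW_SIZE}, got {bin_size}")
    n_bins = TSS_WINDOW_SIZE // bin_size
    rows, genes = [], []
    for w in panel.tss_windows():
        depths = track.window_depths(w.chrom, w.window_start, w.window_end)
        if w.strand == "-":
            depths = depths[::-1]
        rows.append(depths.reshape(n_bins, bin_size).mean(axis=1))
        genes.append(w.gene_id)
    values = pd.DataFrame(np.asarray(rows), index=genes, columns=range(n_bins))
    return CoverageMatrix(
        sample_id=track.sample_id,
        values=values,
        bin_size=bin_size,
        library_size=track.library_size,
    )


def normalize_cpm(matrix: CoverageMatrix, library_size: int | None = None) -> CoverageMatrix:
    """Counts-per-million scaling: value * 1e6 / library_size."""
    lib = matrix.library_size if library_size is None else library_size
    if lib is None or lib <= 0:
        raise ValueError("library_size must be > 0 for CPM normalization")
    return CoverageMatrix(
        sample_id=matrix.sample_id,
        values=matrix.values * (1e6 / lib),
        bin_size=matrix.bin_size,
        library_size=lib,
        normalized="cpm",
    )


def cluster_tss_profiles(
    matrix: CoverageMatrix,
    seed: int = 0,
    n_init: int = 10,
    ndr_halfwidth: int = DEFAULT_NDR_HALFWIDTH,
) -> GeneClusterResult:
    """Two-cluster Euclidean k-means over gene TSS coverage profiles.

    The cluster with the lower mean NDR (central-bin) coverage is labelled
    "open" (nucleosome-depleted, putatively expressed), the other "closed".
    All-zero rows are dropped with a warning; identical profiles yield a
    degenerate single-cluster result.  Fitting happens on canonically sorted
    rows so the outcome does not depend on input row order.
    """
    vals = matrix.values
    finite = vals.notna().all(axis=1)
    nonzero = (vals.abs().sum(axis=1) > 0) & finite
    dropped = list(vals.index[~nonzero])
    if dropped:
        warnings.warn(
            f"{matrix.sample_id}: dropping {len(dropped)} zero-coverage windows from clustering",
            stacklevel=2,
        )
    data = vals.loc[nonzero]
    if data.shape[0] < 2:
        raise ValueError("cluster_tss_profiles requires >= 2 genes with coverage")

    X = data.to_numpy(dtype=float)
    # canonical row order -> permutation-invariant restarts
    order = np.lexsort(X.T[::-1])
    Xs = X[order]
    if np.allclose(Xs, Xs[0]):
        labels = {g: "closed" for g in data.index}
        return GeneClusterResult(
            sample_id=matrix.sample_id,
            labels=labels,
            cluster_profiles={"closed": X.mean(axis=0)},
            separability=0.0,
            degenerate=True,
            dropped_genes=dropped,
        )
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed, algorithm="lloyd")
    raw_sorted = km.fit_predict(Xs)
    raw = np.empty_like(raw_sorted)
    raw[order] = raw_sorted

    ndr = matrix.ndr_bins(ndr_halfwidth) or list(range(matrix.n_bins))
    central = {k: X[raw == k][:, ndr].mean() for k in (0, 1)}
    if central[0] == central[1]:  # tie: cluster of the first gene is "open"
        open_k = raw[0]
    else:
        open_k = min(central, key=lambda k: central[k])
    name = {open_k: "open", 1 - open_k: "closed"}
    labels = {g: name[k] for g, k in zip(data.index, raw)}
    sep = float(silhouette_score(X, raw)) if len(set(raw)) == 2 else 0.0
    profiles = {name[k]: X[raw == k].mean(axis=0) for k in (0, 1) if np.any(raw == k)}
    return GeneClusterResult(
        sample_id=matrix.sample_id,
        labels=labels,
        cluster_profiles=profiles,
        separability=sep,
        degenerate=len(set(raw)) < 2,
        dropped_genes=dropped,
    )


def assess_sample_informativeness(
    cohort_row: CohortRow,
    cluster_result: GeneClusterResult,
    min_conc: float = MIN_INFORMATIVE_CONC,
    min_library: int = MIN_INFORMATIVE_LIBRARY,
    s_min: float = DEFAULT_MIN_SEPARABILITY,
) -> SampleInformativeness:
    """Gate a sample for footprint analysis.

    Informative samples need cfDNA concentration above 10 ng/mL, at least one
    million deduplicated reads and distinguishable two-state clustering
    (mean silhouette >= s_min).
    """
    reasons = []
    if not cohort_row.cfdna_conc > min_conc:
        reasons.append("low_concentration")
    if not cohort_row.library_size >= min_library:
        reasons.append("low_library")
    if cluster_result.degenerate or not cluster_result.separability >= s_min:
        reasons.append("poor_separability")
    return SampleInformativeness(
        sample_id=cohort_row.patient_id,
        cfdna_conc=cohort_row.cfdna_conc,
        library_size=cohort_row.library_size,
        separability=cluster_result.separability,
        informative=not reasons,
        reasons=reasons,
    )


def compute_ndr_zscores(
    cpm_matrices: Mapping[str, CoverageMatrix],
    ndr_halfwidth: int = DEFAULT_NDR_HALFWIDTH,
) -> pd.DataFrame:
    """Row z-scores of log2(CPM + 1) mean NDR coverage, genes x samples.

    Uses the population standard deviation; rows with zero dispersion are set
    to all zeros.
    """
    if len(cpm_matrices) < 2:
        raise ValueError("compute_ndr_zscores requires >= 2 informative samples")
    cols = {}
    for sample_id, m in cpm_matrices.items():
        if m.normalized != "cpm":
            raise ValueError(f"{sample_id}: matrix must be CPM-normalized")
        ndr = m.ndr_bins(ndr_halfwidth)
        cols[sample_id] = np.log2(m.values.iloc[:, ndr].mean(axis=1) + 1.0)
    v = pd.DataFrame(cols)
    mu = v.mean(axis=1)
    sd = v.std(axis=1, ddof=0)
    z = v.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def call_expression_state(zmatrix: pd.DataFrame) -> pd.DataFrame:
    """Call each (gene, sample) expressed (z < 0) or silent (z >= 0).

    Low NDR coverage relative to other samples means open chromatin, hence
    the negative side maps to "expressed"; the z = 0 boundary is silent.
    """
    if not np.isfinite(zmatrix.to_numpy()).all():
        raise ValueError("z-score matrix contains non-finite values")
    return zmatrix.map(lambda z: "expressed" if z < 0 else "silent")


def select_discriminating_genes(
    zmatrix: pd.DataFrame,
    entity_labels: Mapping[str, str],
    entity_a: str,
    entity_b: str,
) -> dict[str, str]:
    """Genes whose z-scores perfectly separate two entities around zero.

    A gene is selected iff every entity-a sample and every entity-b sample lie
    strictly on opposite sides of z = 0; the value is the entity whose samples
    sit below zero (the entity the gene appears expressed in).
    """
    a_cols = [s for s in zmatrix.columns if entity_labels.get(s) == entity_a]
    b_cols = [s for s in zmatrix.columns if entity_labels.get(s) == entity_b]
    if not a_cols or not b_cols:
        raise ValueError(f"no samples for entity {entity_a if not a_cols else entity_b!r}")
    out: dict[str, str] = {}
    for gene, row in zmatrix.iterrows():
        a, b = row[a_cols].to_numpy(), row[b_cols].to_numpy()
        if (a < 0).all() and (b > 0).all():
            out[gene] = entity_a
        elif (a > 0).all() and (b < 0).all():
            out[gene] = entity_b
    return out


@dataclass
class HeatmapClustering:
    """Hierarchically clustered z-score matrix ready for plotting."""

    matrix: pd.DataFrame  # reordered genes x samples
    gene_linkage: np.ndarray
    gene_order: list[str]
    sample_linkage: np.ndarray | None = None
    sample_order: list[str] | None = None


def cluster_heatmap(
    zmatrix: pd.DataFrame,
    entity_labels: Mapping[str, str] | None = None,
    cluster_samples: bool = False,
) -> HeatmapClustering:
    """Agglomerative clustering of gene rows (Euclidean, average linkage).

    Samples are ordered by entity label (then name) unless sample clustering
    is requested, in which case columns get their own dendrogram too.
    """
    if zmatrix.shape[0] < 2:
        raise ValueError("cluster_heatmap requires >= 2 genes")
    gene_link = hierarchy.linkage(zmatrix.to_numpy(), method="average", metric="euclidean")
    gene_order = [zmatrix.index[i] for i in hierarchy.leaves_list(gene_link)]
    sample_link = None
    if cluster_samples and zmatrix.shape[1] >= 2:
        sample_link = hierarchy.linkage(zmatrix.to_numpy().T, method="average", metric="euclidean")
        sample_order = [zmatrix.columns[i] for i in hierarchy.leaves_list(sample_link)]
    elif entity_labels:
        sample_order = sorted(zmatrix.columns, key=lambda s: (entity_labels.get(s, ""), s))
    else:
        sample_order = list(zmatrix.columns)
    return HeatmapClustering(
        matrix=zmatrix.loc[gene_order, sample_order],
        gene_linkage=gene_link,
        gene_order=gene_order,
        sample_linkage=sample_link,
        sample_order=sample_order,
    )


def plot_heatmap(clustering: HeatmapClustering, ax=None, cmap: str = "RdBu_r"):
    """Render the clustered z-score heatmap with matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, clustering.matrix.shape[1]), 8))
    m = clustering.matrix
    vmax = float(np.nanmax(np.abs(m.to_numpy()))) or 1.0
    im = ax.imshow(m.to_numpy(), aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(m.shape[1]), m.columns, rotation=90)
    ax.set_yticks(range(m.shape[0]), m.index, fontsize=5)
    ax.set_xlabel("sample")
    ax.figure.colorbar(im, ax=ax, label="row z-score of log2(CPM+1) NDR coverage")
    return ax
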