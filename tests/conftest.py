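import numpy as np
import pytest

from csfcfdna import CoverageTrack, Panel, TSSWindow


def make_panel(n_genes: int, alternate_strands: bool = True, spacing: int = 10_000) -> Panel:
    """Small synthetic panel: 2 kb TSS windows on one chromosome."""
    windows = []
    start = 1000
    for i in range(n_genes):
        strand = "-" if (alternate_strands and i % 2) else "+"
        windows.append(
            TSSWindow(
                gene_id=f"G{i:03d}",
                chrom="chr1",
                tss_pos=start + 1001,
                strand=strand,
                window_start=start,
                window_end=start + 2000,
            )
        )
        start += 2000 + spacing
    return Panel(windows, name="test_panel")


def random_track(rng: np.random.Generator, n_intervals: int = 30, chrom: str = "chr1") -> CoverageTrack:
    """Random non-overlapping bedGraph-style track with integer depths."""
    bounds = np.sort(rng.choice(np.arange(0, 5000), size=2 * n_intervals, replace=False))
    starts, ends = bounds[::2], bounds[1::2]
    values = rng.integers(0, 50, size=n_intervals).astype(float)
    track = CoverageTrack(library_size=1_000_000, sample_id="rand")
    track.add_intervals(chrom, starts, ends, values)
    return track


def dense_expansion(track: CoverageTrack, chrom: str, size: int = 6000) -> np.ndarray:
    """Brute-force per-base expansion of a track for oracle comparisons."""
    out = np.zeros(size)
    for c, s, e, v in track.iter_intervals():
        if c == chrom:
            out[s:e] = v
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20230707)
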