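"""TSS coverage matrices, two-state clustering, z-scoring and gene selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from csfcfdna import (
    CohortRow,
    CoverageMatrix,
    CoverageTrack,
    assess_sample_informativeness,
    build_tss_matrix,
    call_expression_state,
    cluster_heatmap,
    cluster_tss_profiles,
    compute_ndr_zscores,
    normalize_cpm,
    select_discriminating_genes,
)

from conftest import make_panel


def matrix_from_values(values: np.ndarray, sample_id="s", bin_size=20, library_size=10**6, normalized="raw"):
    df = pd.DataFrame(np.asarray(values, dtype=float))
    df.index = [f"G{i:03d}" for i in range(df.shape[0])]
    return CoverageMatrix(sample_id=sample_id, values=df, bin_size=bin_size,
                          library_size=library_size, normalized=normalized)


class TestBuildMatrix:
    def test_constant_depth_fills_all_bins(self):
        panel = make_panel(1, alternate_strands=False)
        w = panel.windows[0]
        track = CoverageTrack(library_size=1)
        track.add_intervals("chr1", [w.window_start], [w.window_end], [5.0])
        m = build_tss_matrix(track, panel, bin_size=20)
        assert m.values.shape == (1, 100)
        assert (m.values.to_numpy() == 5.0).all()

    def test_minus_strand_row_is_reversed(self):
        panel = make_panel(2)  # G001 is on the minus strand
        w = panel.get("G001")
        depths = np.arange(2000, dtype=float) + 1.0  # increasing along the genome
        track = CoverageTrack.from_dense({"chr1": (w.window_start, depths)}, 1)
        m = build_tss_matrix(track, panel, bin_size=20)
        row = m.values.loc["G001"].to_numpy()
        assert (np.diff(row) < 0).all()  # strictly decreasing in transcript orientation

    def test_bins_match_brute_force_average(self, rng):
        panel = make_panel(3)
        track = CoverageTrack(library_size=1)
        dense = {}
        for w in panel.windows:
            d = rng.integers(0, 30, size=2000).astype(float)
            dense[w.gene_id] = d
        starts = [w.window_start for w in panel.windows]
        track = CoverageTrack.from_dense(
            {"chr1": (starts[0], np.concatenate([
                np.concatenate([dense[w.gene_id], np.zeros(panel.windows[i + 1].window_start - w.window_end)])
                if i + 1 < len(panel.windows) else dense[w.gene_id]
                for i, w in enumerate(panel.windows)
            ]))},
            1,
        )
        m = build_tss_matrix(track, panel, bin_size=50)
        for w in panel.windows:
            d = dense[w.gene_id]
            if w.strand == "-":
                d = d[::-1]
            expected = d.reshape(40, 50).mean(axis=1)
            np.testing.assert_allclose(m.values.loc[w.gene_id].to_numpy(), expected)

    def test_bin_size_must_divide_window(self):
        panel = make_panel(1)
        with pytest.raises(ValueError, match="bin_size"):
            build_tss_matrix(CoverageTrack(library_size=1), panel, bin_size=300)


class TestCpm:
    def test_matches_scalar_formula(self, rng):
        vals = rng.uniform(0, 100, size=(5, 10))
        m = matrix_from_values(vals, library_size=3_456_789)
        cpm = normalize_cpm(m)
        np.testing.assert_allclose(cpm.values.to_numpy(), vals * 1e6 / 3_456_789)
        assert cpm.normalized == "cpm"

    def test_doubling_library_halves_values(self):
        m = matrix_from_values([[2.0, 4.0]])
        a = normalize_cpm(m, 10**6).values.to_numpy()
        b = normalize_cpm(m, 2 * 10**6).values.to_numpy()
        np.testing.assert_allclose(a, 2 * b)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            normalize_cpm(matrix_from_values([[1.0]]), 0)


def dipped_profile(n_bins=100, depth=100.0, d=0.8):
    x = np.arange(n_bins) - n_bins / 2 + 0.5
    return depth * (1 - d * np.exp(-(x**2) / (2 * 4.0**2)))


class TestKmeans:
    def test_noiseless_two_state_recovery(self):
        flat = np.full((10, 100), 100.0)
        dipped = np.tile(dipped_profile(), (10, 1))
        m = matrix_from_values(np.vstack([flat, dipped]))
        res = cluster_tss_profiles(m, seed=0)
        labels = [res.labels[f"G{i:03d}"] for i in range(20)]
        assert labels[:10] == ["closed"] * 10 and labels[10:] == ["open"] * 10
        assert res.separability > 0.9

    @pytest.mark.parametrize("n_genes,n_bins", [(8, 5), (10, 4), (12, 3)])
    def test_inertia_equals_exhaustive_two_partition_optimum(self, rng, n_genes, n_bins):
        X = rng.normal(size=(n_genes, n_bins))
        m = matrix_from_values(X, bin_size=2000 // n_bins)
        res = cluster_tss_profiles(m, seed=1)
        genes = list(m.values.index)
        got = sum(
            float(((X[[genes.index(g) for g, l in res.labels.items() if l == lab]]
                    - X[[genes.index(g) for g, l in res.labels.items() if l == lab]].mean(axis=0)) ** 2).sum())
            for lab in ("open", "closed")
        )
        # independent oracle: enumerate every 2-partition
        best = np.inf
        for r in range(1, n_genes):
            for subset in itertools.combinations(range(n_genes), r):
                a = X[list(subset)]
                b = X[[i for i in range(n_genes) if i not in subset]]
                wss = ((a - a.mean(0)) ** 2).sum() + ((b - b.mean(0)) ** 2).sum()
                best = min(best, wss)
        assert got == pytest.approx(best, rel=1e-9)

    def test_row_permutation_leaves_labels_unchanged(self, rng):
        X = np.vstack([np.full((6, 50), 50.0) + rng.normal(size=(6, 50)),
                       np.tile(dipped_profile(50, 50.0), (6, 1)) + rng.normal(size=(6, 50))])
        m = matrix_from_values(X)
        res = cluster_tss_profiles(m, seed=3)
        perm = rng.permutation(12)
        m2 = CoverageMatrix("s", m.values.iloc[perm], m.bin_size, m.library_size)
        res2 = cluster_tss_profiles(m2, seed=3)
        assert res.labels == res2.labels

    def test_scale_invariance_of_labels(self, rng):
        X = np.vstack([np.full((5, 100), 80.0), np.tile(dipped_profile(depth=80.0), (5, 1))])
        X += rng.normal(scale=0.5, size=X.shape)
        a = cluster_tss_profiles(matrix_from_values(X), seed=0).labels
        b = cluster_tss_profiles(matrix_from_values(3.7 * X), seed=0).labels
        assert a == b

    def test_degenerate_identical_profiles_flagged(self):
        m = matrix_from_values(np.full((4, 10), 7.0), bin_size=200)
        res = cluster_tss_profiles(m, seed=0)
        assert res.degenerate

    def test_fewer_than_two_genes_rejected(self):
        with pytest.raises(ValueError):
            cluster_tss_profiles(matrix_from_values([[1.0] * 100]), seed=0)

    def test_zero_coverage_rows_dropped_with_warning(self):
        X = np.vstack([np.zeros((1, 100)), np.full((5, 100), 10.0), np.tile(dipped_profile(depth=10.0), (5, 1))])
        with pytest.warns(UserWarning, match="zero-coverage"):
            res = cluster_tss_profiles(matrix_from_values(X), seed=0)
        assert "G000" not in res.labels and res.dropped_genes == ["G000"]


class FakeCluster:
    def __init__(self, separability, degenerate=False):
        self.separability = separability
        self.degenerate = degenerate


class TestInformativeness:
    @pytest.mark.parametrize(
        "conc,lib,sil,ok,reason",
        [
            (8.0, 5_000_000, 0.6, False, "low_concentration"),
            (50.0, 800_000, 0.6, False, "low_library"),
            (50.0, 5_000_000, 0.6, True, None),
            (50.0, 5_000_000, 0.1, False, "poor_separability"),
            (10.0, 1_000_000, 0.6, False, "low_concentration"),  # boundary: strictly > 10 required
        ],
    )
    def test_criteria(self, conc, lib, sil, ok, reason):
        row = CohortRow("P", "MB_NOS", conc, lib)
        v = assess_sample_informativeness(row, FakeCluster(sil))
        assert v.informative is ok
        if reason:
            assert reason in v.reasons

    def test_all_failed_criteria_listed(self):
        row = CohortRow("P", "ATRT", 2.0, 100)
        v = assess_sample_informativeness(row, FakeCluster(0.0, degenerate=True))
        assert set(v.reasons) == {"low_concentration", "low_library", "poor_separability"}


def cpm_matrix_with_ndr(cpm_value, sample_id):
    # constant profile -> NDR mean equals the constant
    return matrix_from_values(np.full((3, 100), float(cpm_value)), sample_id=sample_id, normalized="cpm")


class TestZScores:
    def test_hand_computed_row(self):
        # log2(CPM+1) values of (1, 2, 3) -> population z = (-1.2247, 0, 1.2247)
        mats = {f"s{i}": cpm_matrix_with_ndr(2**v - 1, f"s{i}") for i, v in enumerate([1.0, 2.0, 3.0])}
        z = compute_ndr_zscores(mats)
        np.testing.assert_allclose(z.iloc[0].to_numpy(), [-1.22474487, 0.0, 1.22474487], atol=1e-8)

    def test_zero_dispersion_rows_are_zero(self):
        mats = {s: cpm_matrix_with_ndr(5.0, s) for s in ("a", "b", "c")}
        z = compute_ndr_zscores(mats)
        assert (z.to_numpy() == 0.0).all()

    def test_normalization_law_on_random_rows(self, rng):
        mats = {f"s{i}": matrix_from_values(rng.uniform(0, 50, size=(20, 100)), normalized="cpm")
                for i in range(6)}
        z = compute_ndr_zscores(mats)
        arr = z.to_numpy()
        nonzero = arr.any(axis=1)
        np.testing.assert_allclose(arr[nonzero].mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(arr[nonzero].std(axis=1), 1.0, atol=1e-9)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            compute_ndr_zscores({"a": cpm_matrix_with_ndr(1.0, "a")})


class TestExpressionCalls:
    def test_boundaries(self):
        z = pd.DataFrame({"s1": [-1.83, 2.24, 0.0]}, index=["a", "b", "c"])
        calls = call_expression_state(z)
        assert list(calls["s1"]) == ["expressed", "silent", "silent"]


class TestDiscriminatingGenes:
    def labels(self):
        return {"a1": "ATRT", "a2": "ATRT", "m1": "MB", "m2": "MB"}

    def test_consistent_split_selected(self):
        z = pd.DataFrame([[-1, -1, 1, 1]], columns=["a1", "a2", "m1", "m2"], index=["g"], dtype=float)
        assert select_discriminating_genes(z, self.labels(), "ATRT", "MB") == {"g": "ATRT"}

    def test_inconsistent_within_entity_not_selected(self):
        z = pd.DataFrame([[-1, 1, -1, 1]], columns=["a1", "a2", "m1", "m2"], index=["g"], dtype=float)
        assert select_discriminating_genes(z, self.labels(), "ATRT", "MB") == {}

    def test_matches_brute_force_row_scan(self, rng):
        cols = ["a1", "a2", "m1", "m2"]
        z = pd.DataFrame(rng.normal(size=(112, 4)), columns=cols,
                         index=[f"g{i}" for i in range(112)])
        got = select_discriminating_genes(z, self.labels(), "ATRT", "MB")
        expected = {}
        for g in z.index:
            a = z.loc[g, ["a1", "a2"]].to_numpy()
            b = z.loc[g, ["m1", "m2"]].to_numpy()
            if (a < 0).all() and (b > 0).all():
                expected[g] = "ATRT"
            if (a > 0).all() and (b < 0).all():
                expected[g] = "MB"
        assert got == expected

    def test_invariance_to_column_order_and_entity_swap(self, rng):
        cols = ["a1", "a2", "m1", "m2"]
        z = pd.DataFrame(rng.normal(size=(50, 4)), columns=cols, index=[f"g{i}" for i in range(50)])
        base = select_discriminating_genes(z, self.labels(), "ATRT", "MB")
        shuffled = select_discriminating_genes(z[["m2", "a1", "m1", "a2"]], self.labels(), "ATRT", "MB")
        assert base == shuffled
        swapped = select_discriminating_genes(z, self.labels(), "MB", "ATRT")
        assert swapped == base  # direction names the expressed-in entity either way

    def test_empty_entity_rejected(self):
        z = pd.DataFrame([[1.0]], columns=["a1"], index=["g"])
        with pytest.raises(ValueError):
            select_discriminating_genes(z, {"a1": "ATRT"}, "ATRT", "MB")


def brute_force_average_linkage(X):
    """Hand-rolled agglomerative average linkage; returns sorted merge heights."""
    clusters = {i: [i] for i in range(len(X))}
    dist = {(i, j): float(np.linalg.norm(X[i] - X[j])) for i in range(len(X)) for j in range(i + 1, len(X))}

    def d(a, b):
        return float(np.mean([dist[tuple(sorted((i, j)))] for i in clusters[a] for j in clusters[b]]))

    heights = []
    keys = sorted(clusters)
    next_id = len(X)
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(((d(a, b), a, b) for i, a in enumerate(keys) for b in keys[i + 1:]), key=lambda t: t[0])
        h, a, b = best
        heights.append(h)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return sorted(heights)


class TestHeatmapClustering:
    def test_identical_rows_merge_at_zero(self):
        z = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], index=list("abc"), columns=["s1", "s2"])
        res = cluster_heatmap(z)
        assert res.gene_linkage[0, 2] == 0.0

    def test_top_split_separates_well_separated_pairs(self):
        z = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]],
            index=list("abcd"), columns=["s1", "s2"],
        )
        res = cluster_heatmap(z)
        order = res.gene_order
        assert {tuple(sorted(order[:2])), tuple(sorted(order[2:]))} == {("a", "b"), ("c", "d")}

    def test_merge_heights_match_hand_rolled_average_linkage(self, rng):
        X = rng.normal(size=(6, 4))
        z = pd.DataFrame(X, index=[f"g{i}" for i in range(6)], columns=[f"s{i}" for i in range(4)])
        res = cluster_heatmap(z)
        np.testing.assert_allclose(sorted(res.gene_linkage[:, 2]), brute_force_average_linkage(X), rtol=1e-9)

    def test_samples_ordered_by_entity(self, rng):
        z = pd.DataFrame(rng.normal(size=(3, 4)), index=list("abc"), columns=["s1", "s2", "s3", "s4"])
        res = cluster_heatmap(z, entity_labels={"s1": "MB", "s2": "ATRT", "s3": "ATRT", "s4": "ETMR"})
        assert res.sample_order == ["s2", "s3", "s4", "s1"]

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            cluster_heatmap(pd.DataFrame([[1.0]], index=["g"], columns=["s"]))
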