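"""MI estimator vs a brute-force histogram oracle; DPI; top-k truncation."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from ssgcn import (
    MIMatrix,
    build_mi_matrix,
    candidate_pair_count,
    dpi_prune,
    mutual_information,
    top_k_edges,
)
from ssgcn.mi import _bin_codes, default_bins


def oracle_mi(x, y, bins):
    """Independent plug-in MI oracle: explicit rank binning + double loop."""
    def codes(v):
        order = np.argsort(v, kind="stable")
        c = np.empty(len(v), dtype=int)
        for rank, idx in enumerate(order):
            c[idx] = rank * bins // len(v)
        return c

    cx, cy = codes(np.asarray(x, float)), codes(np.asarray(y, float))
    n = len(cx)
    mi = 0.0
    for a in range(bins):
        for b in range(bins):
            pab = np.sum((cx == a) & (cy == b)) / n
            pa = np.sum(cx == a) / n
            pb = np.sum(cy == b) / n
            if pab > 0:
                mi += pab * math.log(pab / (pa * pb))
    return max(mi, 0.0)


class TestMutualInformation:
    @pytest.mark.parametrize("n,bins,seed", [(64, 4, 0), (100, 5, 1), (257, 7, 2)])
    def test_matches_brute_force_oracle(self, n, bins, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        assert mutual_information(x, y, bins=bins) == pytest.approx(
            oracle_mi(x, y, bins), abs=1e-12
        )

    def test_identity_gives_log_bins(self):
        x = np.random.default_rng(3).permutation(1000).astype(float)
        assert mutual_information(x, x, bins=10) == pytest.approx(math.log(10), abs=1e-12)

    def test_coupled_binary_gives_ln2(self):
        x = np.tile([0.0, 1.0], 500)
        assert mutual_information(x, x, bins=2) == pytest.approx(math.log(2), abs=1e-12)

    def test_independent_profiles_near_zero(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(size=1000)
        y = rng.permutation(rng.uniform(size=1000))
        assert mutual_information(x, y, bins=10) < 0.05

    def test_constant_vector_warns_and_returns_zero(self):
        x = np.arange(100, dtype=float)
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(x, np.zeros(100)) == 0.0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="8"):
            mutual_information(np.arange(4), np.arange(4))

    def test_default_bins_cube_root(self):
        assert default_bins(1000) == 10
        assert default_bins(100) == 4
        assert default_bins(8) == 2


class TestBuildMIMatrix:
    def _frame(self, values):
        return pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        )

    def test_matches_scalar_estimator_per_pair(self, rng):
        df = self._frame(rng.normal(size=(6, 120)))
        mim = build_mi_matrix(df, bins=5)
        for i in range(6):
            for j in range(i + 1, 6):
                expected = mutual_information(
                    df.iloc[i].to_numpy(), df.iloc[j].to_numpy(), bins=5
                )
                assert mim.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_three_genes_three_pairs(self, rng):
        mim = build_mi_matrix(self._frame(rng.normal(size=(3, 50))))
        assert candidate_pair_count(3) == 3
        assert np.count_nonzero(np.triu(np.ones_like(mim.matrix), 1)) == 3

    def test_sample_order_invariance(self, rng):
        df = self._frame(rng.normal(size=(5, 90)))
        shuffled = df[list(rng.permutation(df.columns))]
        a = build_mi_matrix(df, bins=4).matrix
        b = build_mi_matrix(shuffled, bins=4).matrix
        assert np.array_equal(a, b)

    def test_pair_count_printed_scale(self):
        assert candidate_pair_count(5000) == 12_497_500

    def test_nonfinite_rejected(self):
        df = self._frame(np.array([[1.0, np.nan, 2.0] * 4, [1.0, 2.0, 3.0] * 4]))
        with pytest.raises(ValueError, match="non-finite"):
            build_mi_matrix(df)

    def test_symmetric_nonnegative(self, rng):
        m = build_mi_matrix(self._frame(rng.normal(size=(8, 64)))).matrix
        assert np.allclose(m, m.T)
        assert (m >= 0).all()


class TestDPI:
    def _mim(self, mat):
        genes = [f"g{i}" for i in range(mat.shape[0])]
        return MIMatrix(gene_ids=genes, matrix=np.asarray(mat, float))

    def test_weakest_triangle_edge_removed(self):
        m = np.array([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]])
        pruned = dpi_prune(self._mim(m), 0.0).matrix
        assert pruned[0, 1] == 0.0
        assert pruned[0, 2] == 0.5 and pruned[1, 2] == 0.5

    def test_equilateral_triangle_kept(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 0.0)
        pruned = dpi_prune(self._mim(m), 0.0).matrix
        assert np.array_equal(pruned, m)

    def test_tolerance_bounds_checked(self):
        m = np.zeros((3, 3))
        with pytest.raises(ValueError):
            dpi_prune(self._mim(m), 1.5)

    def test_markov_chain_indirect_edge_removed(self):
        """X -> Y -> Z: the (X, Z) edge should be pruned in >= 90% of runs."""
        removed = 0
        reps = 100
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            x = rng.normal(size=2000)
            y = 0.9 * x + rng.normal(size=2000) * 0.45
            z = 0.9 * y + rng.normal(size=2000) * 0.45
            df = pd.DataFrame([x, y, z], index=["x", "y", "z"])
            pruned = dpi_prune(build_mi_matrix(df), tolerance=0.15).matrix
            if pruned[0, 2] == 0.0 and pruned[0, 1] > 0 and pruned[1, 2] > 0:
                removed += 1
        assert removed >= 90

    def test_median_mi_respects_data_processing_inequality(self):
        mi_xy, mi_xz = [], []
        for rep in range(30):
            rng = np.random.default_rng(1000 + rep)
            x = rng.normal(size=500)
            y = 0.8 * x + 0.6 * rng.normal(size=500)
            z = 0.8 * y + 0.6 * rng.normal(size=500)
            df = pd.DataFrame([x, y, z], index=["x", "y", "z"])
            m = build_mi_matrix(df).matrix
            mi_xy.append(m[0, 1])
            mi_xz.append(m[0, 2])
        assert np.median(mi_xz) < np.median(mi_xy)


class TestTopK:
    def _mim(self, mat, genes):
        return MIMatrix(gene_ids=genes, matrix=np.asarray(mat, float))

    def test_exactly_k_nonzero_pairs_all_returned(self):
        m = np.array([[0, 0.2, 0], [0.2, 0, 0.3], [0, 0.3, 0]])
        edges = top_k_edges(self._mim(m, ["a", "b", "c"]), k=2)
        assert edges.pairs() == {("a", "b"), ("b", "c")}
        assert edges.df["weight"].tolist() == [0.3, 0.2]

    def test_ties_break_lexicographically(self):
        m = np.full((4, 4), 0.5)
        np.fill_diagonal(m, 0.0)
        edges = top_k_edges(self._mim(m, ["d", "c", "b", "a"]), k=3)
        assert list(zip(edges.df["gene_a"], edges.df["gene_b"])) == [
            ("a", "b"), ("a", "c"), ("a", "d"),
        ]

    def test_fewer_pairs_than_k_warns(self):
        m = np.array([[0, 0.2], [0.2, 0]])
        with pytest.warns(UserWarning, match="only 1 pairs"):
            edges = top_k_edges(self._mim(m, ["a", "b"]), k=5)
        assert len(edges) == 1

    def test_k_10000_on_200_gene_universe(self, rng):
        g = 200
        m = rng.uniform(size=(g, g))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        edges = top_k_edges(self._mim(m, [f"g{i:03d}" for i in range(g)]), k=10_000)
        assert len(edges) == 10_000
        w = edges.df["weight"].to_numpy()
        assert (np.diff(w) <= 1e-15).all()  # sorted descending

    def test_edge_list_input_roundtrip(self):
        df = pd.DataFrame(
            {"gene_a": ["a", "a", "b"], "gene_b": ["b", "c", "c"],
             "weight": [0.1, 0.5, 0.3]}
        )
        edges = top_k_edges(df, k=2)
        assert edges.pairs() == {("a", "c"), ("b", "c")}

    def test_deterministic(self, rng):
        m = rng.uniform(size=(20, 20))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        genes = [f"g{i}" for i in range(20)]
        e1 = top_k_edges(self._mim(m, genes), k=50)
        e2 = top_k_edges(self._mim(m, genes), k=50)
        pd.testing.assert_frame_equal(e1.df, e2.df)
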