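"""Gene filtering and TMM normalization, cross-checked against edgeR."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from ssgcn import ExpressionMatrix, filter_genes, gc_length_correct, normalize, tmm_factors
from ssgcn.preprocess import MEAN_NORMALIZED_COUNT_MIN


def _matrix(values, genes=None, samples=None, stage="raw"):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), stage=stage)


class TestTMM:
    def test_identical_libraries_give_unit_factors(self, rng):
        col = rng.integers(1, 500, size=200)
        m = _matrix(np.column_stack([col, col, col]))
        nf = tmm_factors(m)
        assert np.allclose(nf.factors, 1.0)

    def test_pure_depth_difference_gives_unit_factors(self, rng):
        a = rng.integers(1, 500, size=300)
        m = _matrix(np.column_stack([a, 2 * a]))
        nf = tmm_factors(m)
        # all M-values against the library-size-scaled reference are zero
        assert np.allclose(nf.factors, 1.0, atol=1e-12)

    def test_single_outlier_gene_is_trimmed(self, rng):
        a = rng.integers(50, 500, size=1001).astype(float)
        b = a.copy()
        b[0] *= 10  # one gene 10x up in sample B, 1000 genes unchanged
        nf = tmm_factors(_matrix(np.column_stack([a, b])))
        assert abs(nf.factors.iloc[1] / nf.factors.iloc[0] - 1.0) < 0.01

    def test_geometric_mean_is_one(self, rng):
        m = _matrix(rng.integers(0, 1000, size=(400, 6)))
        nf = tmm_factors(m)
        assert abs(np.exp(np.log(nf.factors).mean()) - 1.0) < 1e-12

    def test_all_zero_sample_rejected(self):
        m = pd.DataFrame([[1, 0], [2, 0]], index=["g1", "g2"], columns=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(m)

    def test_matches_edger_calc_norm_factors(self, rng, tmp_path):
        """Independent oracle: edgeR's TMM on the same matrix via Rscript."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        counts = rng.negative_binomial(5, 0.02, size=(500, 5)).astype(int)
        counts[:50, 2] *= 3  # force a real composition difference
        df = pd.DataFrame(
            counts, index=[f"g{i}" for i in range(500)],
            columns=[f"s{j}" for j in range(5)],
        )
        csv = tmp_path / "counts.csv"
        df.to_csv(csv)
        script = tmp_path / "tmm.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.csv("{csv}", row.names = 1))
            f <- calcNormFactors(x, method = "TMM")
            cat(f, sep = "\\n")
        """))
        res = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert res.returncode == 0, res.stderr
        expected = np.array([float(v) for v in res.stdout.split()])
        ours = tmm_factors(df).factors.to_numpy()
        assert np.allclose(ours, expected, rtol=1e-4)


class TestNormalize:
    def test_unit_factors_equal_libraries_identity(self):
        m = pd.DataFrame(
            [[10, 10], [20, 20], [5, 5]], index=list("abc"), columns=["s1", "s2"]
        )
        out = normalize(m, tmm_factors(m))
        assert np.allclose(out.values.to_numpy(), m.to_numpy())

    def test_doubling_a_sample_leaves_profile_unchanged(self, rng):
        a = rng.integers(1, 500, size=300)
        b = rng.integers(1, 500, size=300)
        m1 = pd.DataFrame({"s1": a, "s2": b}, index=[f"g{i}" for i in range(300)])
        m2 = m1.copy()
        m2["s2"] = 2 * m2["s2"]
        n1 = normalize(m1, tmm_factors(m1)).values
        n2 = normalize(m2, tmm_factors(m2)).values
        # same relative profile: compare after removing the global mean-library scale
        r1 = n1["s2"] / n1["s2"].sum()
        r2 = n2["s2"] / n2["s2"].sum()
        assert np.allclose(r1, r2, rtol=1e-9)

    def test_stage_tag_is_normalized(self, rng):
        m = _matrix(rng.integers(0, 100, size=(50, 4)))
        assert normalize(m, tmm_factors(m)).stage == "normalized"


class TestFilterGenes:
    def test_all_zero_genes_removed_by_zero_rule(self, rng):
        # with >= 25% all-zero genes the quantile threshold is 0, so the
        # zero rule (not the quantile rule) is what removes them
        values = rng.integers(100, 200, size=(20, 4))
        values[:8] = 0
        m = _matrix(values)
        filtered, report = filter_genes(m)
        zero_rules = report.loc[report["gene_id"].isin([f"g{i}" for i in range(8)]), "rule"]
        assert (zero_rules == "all_zero").all() and len(zero_rules) == 8
        assert not set(filtered.gene_ids) & {f"g{i}" for i in range(8)}

    def test_quantile_rule_on_toy_means(self):
        # gene means 1, 10, 100, 1000 -> 0.25 linear-interpolation quantile = 7.75
        m = _matrix(np.array([[1, 1], [10, 10], [100, 100], [1000, 1000]]))
        filtered, report = filter_genes(m)
        q = np.quantile([1, 10, 100, 1000], 0.25)
        dropped = set(report.loc[report["rule"] == "low_quantile", "gene_id"])
        expected = {f"g{i}" for i, mean in enumerate([1, 10, 100, 1000]) if mean < q}
        assert dropped == expected

    def test_mean_normalized_count_threshold_at_50(self):
        # equal library sizes and unit factors: normalized == raw, so means
        # of 49.9 and 50.1 sit on either side of the cutoff
        base = np.full((30, 10), 1000.0)
        low = np.full(10, 49.9)
        high = np.full(10, 50.1)
        values = np.vstack([base, low, high])
        # integer raw counts are required; bypass via filtered-stage frame
        df = pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(32)],
            columns=[f"s{j}" for j in range(10)],
        )
        norm = normalize(df, tmm_factors(df)).values
        means = norm.mean(axis=1)
        assert means.loc["g30"] < MEAN_NORMALIZED_COUNT_MIN <= means.loc["g31"]

    def test_threshold_behaviour_end_to_end_with_counts(self):
        # raw integer counts engineered so one gene's mean normalized count
        # falls just below 50 and a sibling's just above
        rng = np.random.default_rng(0)
        small = rng.integers(10, 30, size=(20, 10))  # below the 0.25 quantile
        big = rng.integers(60, 90, size=(30, 10))
        low = np.full(10, 49)
        high = np.full(10, 51)
        m = _matrix(np.vstack([small, big, low, high]))
        filtered, report = filter_genes(m)
        rules = report.set_index("gene_id")["rule"]
        assert rules.get("g50") == "mean_tmm_below_50"
        assert "g51" in filtered.gene_ids

    def test_idempotent_on_filtered_matrix(self, rng):
        m = _matrix(rng.integers(40, 2000, size=(100, 6)))
        once, _ = filter_genes(m)
        twice, report = filter_genes(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert len(report) == 0

    def test_gene_order_is_subsequence_of_input(self, rng):
        m = _matrix(rng.integers(0, 2000, size=(100, 6)))
        filtered, _ = filter_genes(m)
        positions = [m.gene_ids.index(g) for g in filtered.gene_ids]
        assert positions == sorted(positions)

    def test_everything_filtered_raises(self):
        m = _matrix(np.zeros((5, 3), dtype=int))
        with pytest.raises(ValueError, match="relax"):
            filter_genes(m)


class TestGCLengthCorrect:
    def _annotation(self, genes, gc, length):
        return pd.DataFrame(
            {
                "chromosome": "1",
                "cytoband": "1p11",
                "start": 1,
                "end": 2,
                "gc_fraction": gc,
                "length": length,
            },
            index=pd.Index(genes, name="gene_id"),
        )

    def test_constant_covariates_identity(self, rng):
        values = rng.integers(1, 500, size=(50, 3))
        m = _matrix(values)
        ann = self._annotation(m.gene_ids, 0.5, 1000)
        out = gc_length_correct(m.values, ann)
        assert np.allclose(out.values.to_numpy(), values, atol=1e-9)

    def test_gc_driven_counts_decorrelated(self, rng):
        from scipy import stats
        n_genes = 1000
        gc = rng.uniform(0.3, 0.7, n_genes)
        counts = np.round(np.exp(2 + 6 * gc)[:, None] * np.ones((1, 3))).astype(int)
        m = _matrix(counts)
        ann = self._annotation(m.gene_ids, gc, 1000)
        out = gc_length_correct(m.values, ann).values.to_numpy()
        rho = stats.spearmanr(out[:, 0], gc).statistic
        assert abs(rho) < 0.05

    def test_disabled_flag_passes_through(self, rng):
        values = rng.integers(1, 500, size=(20, 2))
        m = _matrix(values)
        ann = self._annotation(m.gene_ids, 0.5, 1000)
        out = gc_length_correct(m.values, ann, enabled=False)
        assert np.array_equal(out.values.to_numpy(), values)

    def test_missing_annotation_rows_listed(self, rng):
        values = rng.integers(1, 500, size=(5, 2))
        m = _matrix(values)
        ann = self._annotation(m.gene_ids[:-1], 0.5, 1000)
        with pytest.raises(ValueError, match="g4"):
            gc_length_correct(m.values, ann)
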