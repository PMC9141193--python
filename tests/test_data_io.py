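"""Parsing, probe collapsing, missingness filtering and cohort alignment."""

import numpy as np
import pandas as pd
import pytest

from cwgcna import data_io


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadExpressionMatrix:
    def test_plain_tsv(self, tmp_path):
        p = _write(tmp_path, "m.tsv", "id\ts1\ts2\ng1\t1.5\t2.0\ng2\t0.1\t0.2\ng3\t3\t4\n")
        m = data_io.load_expression_matrix(p)
        assert m.shape == (3, 2)
        assert m.gene_ids == ["g1", "g2", "g3"]
        assert m.values.loc["g3", "s2"] == 4.0

    def test_series_matrix_null_cell_becomes_missing(self, tmp_path):
        text = (
            "!Series_title\t\"x\"\n"
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"GSM1"\t"GSM2"\n'
            '"p1"\t1.0\tnull\n'
            '"p2"\t2.0\t3.0\n'
            "!series_matrix_table_end\n"
        )
        m = data_io.load_expression_matrix(
            _write(tmp_path, "s.txt", text), format="series_matrix"
        )
        assert m.shape == (2, 2)
        assert np.isnan(m.values.loc["p1", "GSM2"])
        assert m.values.loc["p2", "GSM2"] == 3.0

    def test_duplicate_sample_headers_error(self, tmp_path):
        p = _write(tmp_path, "d.tsv", "id\ts1\ts1\ng1\t1\t2\n")
        with pytest.raises(ValueError, match="duplicate sample"):
            data_io.load_expression_matrix(p)

    def test_empty_series_block_error(self, tmp_path):
        text = "!series_matrix_table_begin\n!series_matrix_table_end\n"
        with pytest.raises(ValueError, match="empty data block"):
            data_io.load_expression_matrix(
                _write(tmp_path, "e.txt", text), format="series_matrix"
            )


class TestCollapseProbes:
    def test_highest_mean_probe_retained(self):
        m = data_io.ExpressionMatrix(
            pd.DataFrame(
                [[4.0, 6.0], [6.0, 8.0]], index=["A", "B"], columns=["s1", "s2"]
            )
        )
        out = data_io.collapse_probes(m, {"A": "gene1", "B": "gene1"})
        assert out.gene_ids == ["GENE1"]
        assert list(out.values.loc["GENE1"]) == [6.0, 8.0]

    def test_one_probe_per_gene_is_identity_up_to_renaming(self):
        m = data_io.ExpressionMatrix(
            pd.DataFrame([[1.0], [2.0]], index=["p1", "p2"], columns=["s"])
        )
        out = data_io.collapse_probes(m, {"p1": "ga", "p2": "gb"})
        assert out.gene_ids == ["GA", "GB"]
        assert out.values.loc["GA", "s"] == 1.0

    def test_unmapped_and_empty_symbol_probes_dropped(self):
        m = data_io.ExpressionMatrix(
            pd.DataFrame([[1.0], [2.0], [3.0]], index=["p1", "p2", "p3"], columns=["s"])
        )
        out = data_io.collapse_probes(m, {"p1": "g1", "p2": ""})
        assert out.gene_ids == ["G1"]

    def test_idempotent_on_gene_keyed_matrix(self):
        m = data_io.ExpressionMatrix(
            pd.DataFrame([[1.0], [2.0]], index=["G1", "G2"], columns=["s"])
        )
        ident = {"G1": "G1", "G2": "G2"}
        once = data_io.collapse_probes(m, ident)
        twice = data_io.collapse_probes(once, ident)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_no_mapping_error(self):
        m = data_io.ExpressionMatrix(
            pd.DataFrame([[1.0]], index=["p"], columns=["s"])
        )
        with pytest.raises(ValueError, match="no probe maps"):
            data_io.collapse_probes(m, {"other": "g"})


class TestFilterMissing:
    def _matrix(self):
        vals = pd.DataFrame(
            {
                "s1": [1.0, np.nan, 5.0, 2.0],
                "s2": [2.0, np.nan, 5.0, 2.5],
                "s3": [3.0, np.nan, 5.0, np.nan],
                "s4": [4.0, 1.0, 5.0, 3.0],
                "s5": [5.0, 2.0, 5.0, 3.5],
            },
            index=["ok", "gappy", "flat", "mild"],
        )
        return data_io.ExpressionMatrix(vals)

    def test_gene_above_missing_threshold_removed(self):
        out = data_io.filter_missing(self._matrix(), max_gene_missing=0.5)
        assert "gappy" not in out.gene_ids  # 60% missing

    def test_constant_gene_removed(self):
        out = data_io.filter_missing(self._matrix(), min_variance=1e-10)
        assert "flat" not in out.gene_ids

    def test_clean_matrix_unchanged(self):
        m = data_io.ExpressionMatrix(
            pd.DataFrame(np.arange(12, dtype=float).reshape(3, 4) ** 1.5)
        )
        out = data_io.filter_missing(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_filtering_reduces_overall_missingness(self, rng):
        X = rng.standard_normal((30, 12))
        X[rng.random(X.shape) < 0.2] = np.nan
        X[:, 0] = np.nan  # force one bad sample too
        X[0, :] = rng.standard_normal(12)  # keep at least one full gene
        m = data_io.ExpressionMatrix(pd.DataFrame(X))
        before = m.values.isna().to_numpy().mean()
        out = data_io.filter_missing(m, 0.3, 0.3)
        # global missing fraction can only shrink, and every retained
        # sample meets its threshold after the final pass
        assert out.values.isna().to_numpy().mean() <= before
        assert (out.values.isna().mean(axis=0) <= 0.3).all()

    def test_all_genes_removed_error(self):
        m = data_io.ExpressionMatrix(
            pd.DataFrame([[1.0, 1.0], [2.0, 2.0]], columns=["a", "b"])
        )
        with pytest.raises(ValueError, match="genes removed"):
            data_io.filter_missing(m, min_variance=1e-10)


class TestAlignCohorts:
    def _m(self, genes, name):
        return data_io.ExpressionMatrix(
            pd.DataFrame(
                np.arange(len(genes) * 2, dtype=float).reshape(len(genes), 2),
                index=genes,
                columns=["s1", "s2"],
            ),
            cohort_name=name,
        )

    def test_identical_gene_sets_order_normalized(self):
        a = self._m(["A", "B", "C"], "x")
        b = self._m(["C", "A", "B"], "y")
        out = data_io.align_cohorts([a, b])
        assert out[0].gene_ids == out[1].gene_ids == ["A", "B", "C"]

    def test_intersection(self):
        a = self._m(["A", "B", "C"], "x")
        b = self._m(["B", "C", "D"], "y")
        out = data_io.align_cohorts([a, b])
        assert out[0].gene_ids == ["B", "C"]
        assert out[0].gene_ids == out[1].gene_ids

    def test_empty_intersection_error(self):
        with pytest.raises(ValueError, match="no genes shared"):
            data_io.align_cohorts([self._m(["A"], "x"), self._m(["B"], "y")])

    def test_case_normalization(self):
        out = data_io.align_cohorts([self._m(["Abc", "D"], "x"), self._m(["ABC", "E"], "y")])
        assert out[0].gene_ids == ["ABC"]


class TestTraitTable:
    def test_roundtrip_and_validation(self, tmp_path):
        p = _write(
            tmp_path,
            "t.tsv",
            "sample_id\tphenotype\tfvc\tdlco\ns1\t1\t80.5\t\ns2\t0\t\t60.0\ns3\t1\t75\t55\n",
        )
        tt = data_io.read_trait_table(p)
        assert tt.sample_ids == ["s1", "s2", "s3"]
        assert np.isnan(tt.trait("dlco").iloc[0])
        m = data_io.ExpressionMatrix(
            pd.DataFrame(np.ones((2, 3)) * [[1], [2]], columns=["s1", "s2", "s3"])
        )
        tt.validate_against(m)

    def test_single_class_phenotype_rejected(self):
        tt = data_io.TraitTable(
            pd.DataFrame({"phenotype": [1, 1]}, index=["s1", "s2"])
        )
        m = data_io.ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], columns=["s1", "s2"])
        )
        with pytest.raises(ValueError, match="case and one control"):
            tt.validate_against(m)
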