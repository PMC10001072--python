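import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emtspectrum import (
    ExpressionMatrix, log1p_transform, normalize_total, read_expression,
    read_gmt, scale_genes, select_hvg, write_expression, write_gmt, GeneSet,
)


class TestReadExpression:
    def test_dense_csv_integer_counts_is_raw(self, tmp_path, tiny_counts):
        path = tmp_path / "m.csv"
        write_expression(tiny_counts, path)
        em = read_expression(path)
        assert em.layer == "raw"
        assert em.values.shape == (3, 4)
        np.testing.assert_allclose(em.values, tiny_counts.values)
        assert em.cell_ids == tiny_counts.cell_ids

    def test_non_integer_csv_is_normalized_layer(self, tmp_path):
        df = pd.DataFrame([[0.5, 1.5]], index=["c1"], columns=["G1", "G2"])
        df.to_csv(tmp_path / "m.csv")
        assert read_expression(tmp_path / "m.csv").layer == "normalized"

    def test_mtx_round_trip_full_precision(self, tmp_path, tiny_counts):
        write_expression(tiny_counts, tmp_path / "m.mtx", format="mtx")
        em = read_expression(tmp_path / "m.mtx")
        np.testing.assert_array_equal(em.values, tiny_counts.values)
        assert em.gene_ids == tiny_counts.gene_ids

    def test_mtx_with_zero_stored_entries(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n2 3 0\n")
        (tmp_path / "cells.tsv").write_text("c1\nc2\n")
        (tmp_path / "genes.tsv").write_text("G1\nG2\nG3\n")
        em = read_expression(tmp_path / "m.mtx")
        assert em.values.shape == (2, 3)
        assert np.all(em.values == 0)

    def test_missing_companion_file_errors(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n1 1 0\n")
        with pytest.raises(FileNotFoundError):
            read_expression(tmp_path / "m.mtx")

    def test_duplicate_gene_header_errors_naming_offender(self, tmp_path):
        (tmp_path / "m.csv").write_text(",G1,G1\nc1,1,2\n")
        with pytest.raises(ValueError, match="G1"):
            read_expression(tmp_path / "m.csv")


class TestGMT:
    def test_parse_line_and_case_policy(self, tmp_path):
        (tmp_path / "s.gmt").write_text("EPI\tdesc\tCdh1\tEPCAM\nMES\td\tVIM\n")
        sets = read_gmt(tmp_path / "s.gmt")
        assert [s.name for s in sets] == ["EPI", "MES"]
        assert sets[0].genes == frozenset({"CDH1", "EPCAM"})

    def test_short_line_errors_with_line_number(self, tmp_path):
        (tmp_path / "s.gmt").write_text("OK\td\tG1\nBAD\tdesc\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(tmp_path / "s.gmt")

    def test_write_read_round_trip(self, tmp_path):
        sets = [GeneSet("A", frozenset({"G1", "G2"})), GeneSet("B", frozenset({"G3"}))]
        write_gmt(sets, tmp_path / "s.gmt")
        back = read_gmt(tmp_path / "s.gmt")
        assert {s.name: s.genes for s in back} == {s.name: s.genes for s in sets}


class TestNormalizeTotal:
    def test_fixed_target_arithmetic(self, lognorm_from):
        em = ExpressionMatrix([[1, 0, 1], [2, 3, 5]], ["c1", "c2"],
                              ["G1", "G2", "G3"], layer="raw")
        out = normalize_total(em, target_sum=10)
        np.testing.assert_allclose(out.values[0], [5, 0, 5])
        np.testing.assert_allclose(out.values[1], [2, 3, 5])
        assert out.layer == "normalized"

    def test_auto_target_is_median_of_totals(self):
        em = ExpressionMatrix([[4, 0], [8, 8]], ["c1", "c2"], ["G1", "G2"],
                              layer="raw")
        out = normalize_total(em)  # totals {4, 16}, median 10
        np.testing.assert_allclose(out.values.sum(axis=1), [10, 10])

    def test_all_zero_cell_errors_naming_cell(self):
        em = ExpressionMatrix([[1, 1], [0, 0]], ["c1", "czero"], ["G1", "G2"],
                              layer="raw")
        with pytest.raises(ValueError, match="czero"):
            normalize_total(em)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(0, 50), min_size=3, max_size=8).filter(lambda v: sum(v) > 0))
    def test_within_cell_proportions_conserved(self, counts):
        em = ExpressionMatrix([counts], ["c"], [f"G{i}" for i in range(len(counts))],
                              layer="raw")
        out = normalize_total(em, target_sum=7.5)
        np.testing.assert_allclose(out.values[0] / 7.5, np.array(counts) / sum(counts))


class TestChainOrder:
    def test_each_stage_refuses_wrong_layer(self, tiny_counts):
        with pytest.raises(ValueError, match="layer"):
            log1p_transform(tiny_counts)  # raw, not normalized
        with pytest.raises(ValueError, match="layer"):
            scale_genes(tiny_counts)
        lognorm = log1p_transform(normalize_total(tiny_counts, 10))
        with pytest.raises(ValueError, match="layer"):
            normalize_total(lognorm)

    def test_log1p_values_and_monotonicity(self, tiny_counts):
        norm = normalize_total(tiny_counts, 12)
        out = log1p_transform(norm)
        np.testing.assert_allclose(out.values, np.log1p(norm.values))
        # order of values within a cell is preserved
        for before, after in zip(norm.values, out.values):
            assert np.array_equal(np.argsort(before), np.argsort(after))


class TestScaleGenes:
    def test_population_sd_convention(self, lognorm_from):
        em = lognorm_from([[0.0], [2.0]])
        out = scale_genes(em, clip=None)
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 1.0])

    def test_constant_gene_becomes_zero(self, lognorm_from):
        out = scale_genes(lognorm_from([[3.0, 1.0], [3.0, 2.0]]), clip=None)
        np.testing.assert_allclose(out.values[:, 0], 0.0)

    def test_clipping_bounds_output(self, lognorm_from):
        out = scale_genes(lognorm_from([[0.0], [0.0], [10.0]]), clip=1.0)
        assert out.values.max() == pytest.approx(1.0)


class TestSelectHVG:
    def test_mean_bounds_are_hard(self, lognorm_from):
        rng = np.random.default_rng(0)
        base = np.log1p(rng.poisson(3.0, size=(100, 30)).astype(float))
        base[:, 0] = np.log1p(rng.poisson(0.001, size=100).astype(float))  # below min_mean
        em = lognorm_from(base)
        selected = select_hvg(em, min_mean=0.0125, max_mean=5, min_disp=-10)
        assert "G0" not in selected

    def test_inflated_dispersion_gene_selected(self, lognorm_from):
        rng = np.random.default_rng(1)
        lam = np.full(40, 3.0)
        x = rng.poisson(lam, size=(300, 40)).astype(float)
        # inflate gene 5's dispersion ~10x at the same mean
        burst = rng.random(300) < 0.1
        x[burst, 5] = x[burst, 5] * 10
        em = lognorm_from(np.log1p(x))
        selected = select_hvg(em, min_mean=0.0125, max_mean=10, min_disp=0.8)
        assert "G5" in selected

    def test_identical_genes_yield_empty_selection(self, lognorm_from):
        em = lognorm_from(np.tile(np.log1p([[1.0], [2.0], [3.0]]), (1, 25)))
        assert select_hvg(em) == []


class TestInvariants:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(np.zeros((2, 1)), ["c1", "c1"], ["G1"], layer="raw")

    def test_raw_layer_requires_integers(self):
        with pytest.raises(ValueError, match="integer"):
            ExpressionMatrix(np.array([[0.5]]), ["c1"], ["G1"], layer="raw")

    def test_gene_ids_uppercased(self):
        em = ExpressionMatrix(np.zeros((1, 1)), ["c1"], ["Vim"], layer="raw")
        assert em.gene_ids == ["VIM"]
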