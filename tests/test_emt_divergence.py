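import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emtspectrum import (
    ExpressionMatrix, GeneSet, ScoreTable, bh_adjust, classify_m_genes,
    cross_dataset_correlation, marker_positive, mw_test, score_correlation,
)


def lognorm(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ExpressionMatrix(values, [f"c{i}" for i in range(n)],
                            gene_ids or [f"G{j}" for j in range(g)], layer="lognorm")


class TestMannWhitney:
    def test_exact_one_sided_worked_value(self):
        # all 20 rank arrangements of 3+3; full separation has probability 1/20
        _, p = mw_test([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(0.05)
        _, p = mw_test([4, 5, 6], [1, 2, 3], alternative="greater")
        assert p == pytest.approx(0.05)

    def test_identical_groups_two_sided_p_one(self):
        u, p = mw_test([1, 2, 3], [1, 2, 3], alternative="two-sided")
        assert p == pytest.approx(1.0)
        u, p = mw_test([2, 2, 2], [2, 2, 2], alternative="two-sided")
        assert u == pytest.approx(4.5)
        assert p == 1.0

    def test_swap_symmetry_of_u(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=12), rng.normal(size=9)
        u_xy, _ = mw_test(x, y)
        u_yx, _ = mw_test(y, x)
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mw_test([], [1.0])


class TestBH:
    def test_hand_worked_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.04, 0.03]),
                                   [0.03, 0.04, 0.04])

    def test_single_and_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([0.07, 0.07, 0.07]), [0.07] * 3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_bh_below_holm_and_bounded(self, ps):
        from emtspectrum import holm_adjust
        bh, holm = bh_adjust(ps), holm_adjust(ps)
        assert np.all(bh <= holm + 1e-12)
        assert np.all((bh >= np.asarray(ps) - 1e-12) & (bh <= 1.0))


class TestClassifyMGenes:
    def _planted(self, seed=0, shift=1.0, n_per_class=200, n_m1=40, n_m2=40, n_null=20):
        rng = np.random.default_rng(seed)
        genes = ([f"M1G{i}" for i in range(n_m1)] + [f"M2G{i}" for i in range(n_m2)]
                 + [f"NULLG{i}" for i in range(n_null)])
        labels = np.array(["N"] * n_per_class + ["Y"] * n_per_class)
        x = rng.normal(2.0, 1.0, size=(2 * n_per_class, len(genes))).clip(min=0)
        x[labels == "N", :n_m1] += shift
        x[labels == "Y", n_m1:n_m1 + n_m2] += shift
        em = lognorm(x, gene_ids=genes)
        m_set = GeneSet("M", frozenset(genes))
        return em, labels, m_set

    def test_planted_shift_classified_m1(self):
        em, labels, m_set = self._planted()
        table = classify_m_genes(em, labels, m_set)
        assert (table.set_index("gene").loc["M1G0", "m_class"]) == "M1"

    def test_recovery_rate_and_sign_errors(self):
        em, labels, m_set = self._planted(seed=7)
        table = classify_m_genes(em, labels, m_set).set_index("gene")
        m1_called = table[table["m_class"] == "M1"].index
        m2_called = table[table["m_class"] == "M2"].index
        # no sign errors: an M1 call on a planted M2 gene or vice versa
        assert not any(g.startswith("M2G") for g in m1_called)
        assert not any(g.startswith("M1G") for g in m2_called)
        recovered = sum(g.startswith("M1G") for g in m1_called) + \
            sum(g.startswith("M2G") for g in m2_called)
        assert recovered >= 0.9 * 80

    def test_m1_m2_disjoint_subsets_of_m_set(self):
        em, labels, m_set = self._planted(seed=3)
        table = classify_m_genes(em, labels, m_set)
        m1 = set(table.loc[table["m_class"] == "M1", "gene"])
        m2 = set(table.loc[table["m_class"] == "M2", "gene"])
        assert m1.isdisjoint(m2)
        assert (m1 | m2) <= m_set.genes

    def test_null_gene_unclassified_and_fdr_respected(self):
        em, labels, m_set = self._planted(seed=5, shift=0.0, n_m1=0, n_m2=0,
                                          n_null=60)
        table = classify_m_genes(em, labels, m_set)
        frac_called = (table["m_class"] != "unclassified").mean()
        assert frac_called <= 0.05 + 0.05  # fdr_cut + Monte-Carlo margin

    def test_missing_class_errors(self):
        em, labels, m_set = self._planted()
        with pytest.raises(ValueError, match="absent"):
            classify_m_genes(em, np.array(["N"] * len(labels)), m_set)


class TestCrossDataset:
    def _table(self, diffs):
        return pd.DataFrame({"gene": [f"G{i}" for i in range(len(diffs))],
                             "mean_diff": diffs})

    def test_identical_and_negated(self):
        t = self._table([0.5, -0.2, 1.0, -0.7])
        assert cross_dataset_correlation(t, t).coefficient == pytest.approx(1.0)
        neg = t.assign(mean_diff=-t["mean_diff"])
        assert cross_dataset_correlation(t, neg).coefficient == pytest.approx(-1.0)

    def test_shared_planted_structure_correlates(self):
        rng = np.random.default_rng(0)
        true_diff = np.concatenate([np.full(40, 1.0), np.full(40, -1.0)])
        a = self._table(true_diff + rng.normal(0, 0.5, 80))
        b = self._table(true_diff + rng.normal(0, 0.5, 80))
        res = cross_dataset_correlation(a, b)
        assert res.coefficient >= 0.5
        assert res.method == "pearson"

    def test_too_few_shared_genes_errors(self):
        a = self._table([1.0, 2.0])
        with pytest.raises(ValueError, match=">= 3"):
            cross_dataset_correlation(a, a)


class TestScoreCorrelation:
    def _scores(self, cols):
        names = list(cols)
        vals = np.column_stack([cols[k] for k in names])
        return ScoreTable([f"c{i}" for i in range(vals.shape[0])], names, vals)

    def test_monotone_transform_gives_unit_spearman(self):
        x = np.linspace(0, 1, 30)
        scores = self._scores({"x": x, "y": np.exp(3 * x)})
        res = score_correlation(scores, "x", "y")
        assert res[0].coefficient == pytest.approx(1.0)
        res = score_correlation(self._scores({"x": x, "y": -x}), "x", "y")
        assert res[0].coefficient == pytest.approx(-1.0)

    def test_gene_symbol_resolution_and_marker_stratum(self):
        rng = np.random.default_rng(1)
        expr = rng.uniform(0, 2, size=(40, 2))
        expr[:20, 1] = 0.0  # ASCL1-negative half
        em = lognorm(expr, gene_ids=["CDH1", "ASCL1"])
        scores = self._scores({"x": expr[:, 0]})
        strata = {"all": np.ones(40, dtype=bool),
                  "ASCL1+": marker_positive(em, "ASCL1")}
        res = score_correlation(scores, "x", "CDH1", em=em, strata=strata)
        by_stratum = {r.stratum: r for r in res}
        assert by_stratum["all"].coefficient == pytest.approx(1.0)
        assert by_stratum["ASCL1+"].n == 20

    def test_small_stratum_skipped(self):
        scores = self._scores({"x": np.arange(5.0), "y": np.arange(5.0)})
        strata = {"tiny": np.array([True, True, False, False, False])}
        assert score_correlation(scores, "x", "y", strata=strata) == []

    def test_planted_a2_e_coupling_ordering(self, small_lognorm):
        """The shared latent factor couples the A2 signature to the E program:
        sr(A2 score, E score) is positive and exceeds sr(A score, E score)."""
        from emtspectrum import ssgsea_score, nnpca_fit
        lognorm_em, labels, gt = small_lognorm
        e_model = nnpca_fit(lognorm_em, GeneSet("E", gt.gene_sets["E"]),
                            n_components=1)
        cols = {"E_nnpc1": e_model.scores[:, 0]}
        for s in ("A", "A2"):
            cols[f"{s}_score"] = ssgsea_score(
                lognorm_em, GeneSet(s, gt.gene_sets[f"SIG_{s}"])).values[:, 0]
        scores = ScoreTable(lognorm_em.cell_ids, list(cols),
                            np.column_stack(list(cols.values())))
        sr_a2 = score_correlation(scores, "A2_score", "E_nnpc1")[0].coefficient
        sr_a = score_correlation(scores, "A_score", "E_nnpc1")[0].coefficient
        assert sr_a2 > 0
        assert sr_a2 > sr_a
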