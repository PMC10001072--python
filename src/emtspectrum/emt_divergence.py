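"""Subtype-contrast statistics: divergent mesenchymal programs and score
correlations.

The mesenchymal signature is not one program: comparing log-normalized
expression of each M gene between the neuroendocrine N class and the
non-neuroendocrine Y class splits the signature into M1 genes (higher in N,
ZEB1-like) and M2 genes (higher in Y, VIM-like), gated at Benjamini-Hochberg
FDR < 0.05 on two-sided Mann-Whitney tests.  Cross-dataset agreement is
summarized by the Pearson correlation of per-gene N-Y mean differences over
the shared genes.  Spearman correlations between subtype scores and E/M
scores support stratification by metadata (e.g. treatment) and by marker
positivity (e.g. ASCL1+, any detected transcript on the lognorm layer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionMatrix, GeneSet
from .ssgsea import ScoreTable

logger = logging.getLogger("emtspectrum")


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    coefficient: float  # Spearman sr or Pearson r depending on method
    p: float
    n: int
    method: str = "spearman"
    stratum: str = "all"


def mw_test(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U test of x against y (scipy's convention for
    ``alternative``: 'greater' means x tends to exceed y).

    Uses exact enumeration when both groups have <= 8 values and no ties
    occur, the tie-corrected normal approximation otherwise.  Returns
    (U statistic for x, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mw_test requires non-empty groups")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        # all observations identical: U at its null mean, no evidence
        return float(x.size * y.size / 2), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=(method == "asymptotic"))
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify_m_genes(
    em: ExpressionMatrix,
    labels: np.ndarray | list[str],
    m_set: GeneSet,
    n_class: str = "N",
    y_class: str = "Y",
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-gene N-vs-Y divergence table with M1/M2 classification.

    For each mesenchymal gene present in the matrix: the N-minus-Y mean
    lognorm difference, the two-sided Mann-Whitney p, and the BH-adjusted q
    over the whole M set.  M1 = mean_diff > 0 and q < fdr_cut; M2 =
    mean_diff < 0 and q < fdr_cut; otherwise unclassified.
    """
    if em.layer != "lognorm":
        raise ValueError("classify_m_genes operates on the lognorm layer")
    labels = np.asarray([str(s) for s in labels])
    for cls in (n_class, y_class):
        if cls not in labels:
            raise ValueError(f"class {cls!r} absent from labels")
    n_mask = labels == n_class
    y_mask = labels == y_class
    if n_mask.sum() < 3 or y_mask.sum() < 3:
        raise ValueError("each class needs >= 3 cells")
    present = [g for g in sorted(m_set.genes) if g in em.gene_ids]
    missing = sorted(m_set.genes - set(present))
    if missing:
        logger.info("classify_m_genes: %d M genes absent from matrix: %s",
                    len(missing), missing[:10])
    if not present:
        raise ValueError("no M-set genes present in the matrix")
    rows = []
    for g in present:
        col = em.values[:, em.gene_ids.index(g)]
        xn, xy = col[n_mask], col[y_mask]
        u, p = mw_test(xn, xy, alternative="two-sided")
        rows.append((g, float(xn.mean() - xy.mean()), u, p))
    df = pd.DataFrame(rows, columns=["gene", "mean_diff", "u_stat", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["m_class"] = "unclassified"
    df.loc[(df["mean_diff"] > 0) & (df["q"] < fdr_cut), "m_class"] = "M1"
    df.loc[(df["mean_diff"] < 0) & (df["q"] < fdr_cut), "m_class"] = "M2"
    return df


def cross_dataset_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation of per-gene N-Y mean differences across datasets,
    over the gene intersection (>= 3 shared genes required)."""
    merged = table_a.merge(table_b, on="gene", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} shared genes; need >= 3")
    r, p = stats.pearsonr(merged["mean_diff_a"], merged["mean_diff_b"])
    return CorrelationResult(x_name="mean_diff_a", y_name="mean_diff_b",
                             coefficient=float(r), p=float(p), n=len(merged),
                             method="pearson")


def _resolve(name: str, scores: ScoreTable | None, em: ExpressionMatrix | None) -> np.ndarray:
    if scores is not None and name in scores.score_names:
        return scores.column(name)
    if em is not None and name.upper() in em.gene_ids:
        if em.layer != "lognorm":
            raise ValueError("gene-expression variables require the lognorm layer")
        return em.values[:, em.gene_ids.index(name.upper())]
    raise KeyError(f"{name!r} is neither a score column nor a matrix gene")


def score_correlation(
    scores: ScoreTable,
    x: str,
    y: str,
    em: ExpressionMatrix | None = None,
    strata: dict[str, np.ndarray] | None = None,
    marker_threshold: float = 0.0,
) -> list[CorrelationResult]:
    """Spearman correlation between two per-cell variables, per stratum.

    ``x``/``y`` resolve to a score column or, failing that, a gene's lognorm
    expression.  ``strata`` maps stratum names to boolean cell masks; a
    marker stratum like ``"ASCL1+"`` can be built with
    :func:`marker_positive`.  Strata with fewer than 3 cells are skipped.
    """
    if em is not None and scores.cell_ids != em.cell_ids:
        raise ValueError("scores and expression matrix must share cell order")
    xv = _resolve(x, scores, em)
    yv = _resolve(y, scores, em)
    if strata is None:
        strata = {"all": np.ones(len(xv), dtype=bool)}
    out = []
    for name, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        if n < 3:
            logger.info("score_correlation: stratum %s has n=%d < 3; skipped", name, n)
            continue
        sr, p = stats.spearmanr(xv[mask], yv[mask])
        out.append(CorrelationResult(x_name=x, y_name=y, coefficient=float(sr),
                                     p=float(p), n=n, stratum=name))
    return out


def marker_positive(em: ExpressionMatrix, gene: str, threshold: float = 0.0) -> np.ndarray:
    """Boolean mask of cells with lognorm expression of ``gene`` above
    ``threshold`` (default 0: any detected transcript)."""
    if em.layer != "lognorm":
        raise ValueError("marker positivity is defined on the lognorm layer")
    g = gene.upper()
    if g not in em.gene_ids:
        raise KeyError(f"marker gene {gene!r} not in matrix")
    return em.values[:, em.gene_ids.index(g)] > threshold


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": [r.x_name for r in results],
            "y": [r.y_name for r in results],
            "method": [r.method for r in results],
            "coefficient": [r.coefficient for r in results],
            "p": [r.p for r in results],
            "n": [r.n for r in results],
            "stratum": [r.stratum for r in results],
        }
    )
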