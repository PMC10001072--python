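"""Non-negative-loading PCA fitted by expectation-maximization.

Standard PCA seeks a unit loading vector w maximizing var(Xw).  Framed as an
EM problem, each iteration projects the data onto the current loading
(E-step, y = X w_t) and then re-fits the loading by least squares
(M-step, w_{t+1} = argmin sum_n ||x_n - y_n w||^2).  The unconstrained M-step
solution is X'y / ||y||^2; imposing w >= 0 elementwise turns the minimizer
into the clipped form w ∝ max(X'y, 0), which is then renormalized to unit
length.  Non-negativity applies only to the loadings: component scores can be
negative because the input is centered gene-wise before fitting.

Subsequent components are made orthogonal by deflation: after accepting
component k the fitted rank-one part y_k w_k' is subtracted from the working
matrix, so successive score vectors are orthogonal by construction.

Component selection for E/M scoring uses a two-stage ranking: take the
candidates with the highest variance explained, then reorder them by the
variance of the per-subtype mean scores, so the top component is the one that
best separates the subtype populations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import ExpressionMatrix, GeneSet
from .ssgsea import ScoreTable

logger = logging.getLogger("emtspectrum")


@dataclass
class NNPCAModel:
    """Fitted non-negative PCA: loadings, scores and variance accounting.

    ``variance_explained`` is var(score_k) relative to the total variance of
    the centered, gene-set-restricted matrix before any deflation.
    """

    gene_ids: list[str]
    components: np.ndarray        # n_components x n_genes, entries >= 0, rows unit norm
    scores: np.ndarray            # n_cells x n_components
    variance_explained: np.ndarray
    n_iter: list[int]
    converged: list[bool]
    objective_paths: list[list[float]] = field(default_factory=list)

    def score_table(self, cell_ids: list[str], prefix: str) -> ScoreTable:
        names = [f"{prefix}_nnpc{k + 1}" for k in range(self.scores.shape[1])]
        return ScoreTable(cell_ids, names, self.scores)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "components": self.components.tolist(),
            "variance_explained": self.variance_explained.tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "variance_denominator": "total variance of centered input before deflation",
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _best_single_gene_axis(x: np.ndarray) -> np.ndarray:
    """Fallback loading when no non-negative direction improves: the basis
    vector of the highest-variance gene (ties -> lowest index)."""
    variances = x.var(axis=0)
    w = np.zeros(x.shape[1])
    w[int(np.argmax(variances))] = 1.0
    return w


def nnpca_fit(
    em: ExpressionMatrix,
    gene_set: GeneSet,
    n_components: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> NNPCAModel:
    """Fit non-negative PCA on the gene-set restriction of the matrix.

    Columns are restricted to the gene set and centered to zero mean.  Each
    component runs the EM loop to convergence (inf-norm change in the loading
    below ``tol``) or ``max_iter``; the working matrix is then deflated.
    Initialization is the normalized absolute value of the leading right
    singular vector of the current matrix — deterministic, so ``seed`` is
    accepted for interface stability but the fit has no stochastic step.
    """
    idx = em.gene_index(gene_set.genes)
    if len(idx) < 2:
        raise ValueError(
            f"gene set {gene_set.name!r}: need >=2 genes present, found {len(idx)}"
        )
    x = em.values[:, idx].astype(float)
    x = x - x.mean(axis=0)
    n_cells, n_genes = x.shape
    if n_components > min(n_cells - 1, n_genes):
        raise ValueError(
            f"n_components={n_components} exceeds min(cells-1, genes)="
            f"{min(n_cells - 1, n_genes)}"
        )
    total_var = x.var(axis=0).sum()
    if total_var == 0:
        raise ValueError("gene-set restriction has zero total variance")

    components = np.zeros((n_components, n_genes))
    scores = np.zeros((n_cells, n_components))
    var_explained = np.zeros(n_components)
    n_iters: list[int] = []
    converged: list[bool] = []
    objective_paths: list[list[float]] = []

    work = x.copy()
    for k in range(n_components):
        # deterministic init: |leading right singular vector| of current matrix
        _, _, vt = np.linalg.svd(work, full_matrices=False)
        w = np.abs(vt[0])
        norm = np.linalg.norm(w)
        w = w / norm if norm > 0 else _best_single_gene_axis(work)
        path: list[float] = []
        it = 0
        conv = False
        for it in range(1, max_iter + 1):
            y = work @ w                       # E-step
            path.append(float(y.var()))
            w_new = np.maximum(work.T @ y, 0)  # constrained M-step, then renormalize
            norm = np.linalg.norm(w_new)
            if norm == 0:
                logger.warning(
                    "nnpca component %d: no feasible non-negative direction; "
                    "falling back to best single-gene axis", k + 1,
                )
                w = _best_single_gene_axis(work)
                conv = True
                break
            w_new = w_new / norm
            if np.max(np.abs(w_new - w)) < tol:
                w = w_new
                conv = True
                break
            w = w_new
        if not conv:
            logger.warning("nnpca component %d: not converged in %d iterations",
                           k + 1, max_iter)
        y = work @ w
        path.append(float(y.var()))
        components[k] = w
        scores[:, k] = y
        var_explained[k] = y.var() / total_var
        n_iters.append(it)
        converged.append(conv)
        objective_paths.append(path)
        # projection deflation: remove the score direction from every gene
        # column, so the next component's scores are orthogonal to y by
        # construction even when the non-negativity constraint was active
        yy = float(y @ y)
        if yy > 0:
            work = work - np.outer(y, y @ work) / yy

    return NNPCAModel(
        gene_ids=[em.gene_ids[i] for i in idx],
        components=components,
        scores=scores,
        variance_explained=var_explained,
        n_iter=n_iters,
        converged=converged,
        objective_paths=objective_paths,
    )


def select_em_pcs(
    model: NNPCAModel,
    labels: np.ndarray | list[str],
    n_candidates: int = 5,
) -> list[int]:
    """Two-criterion component ranking for subtype-resolving E/M scores.

    Take the ``n_candidates`` components with the highest variance explained,
    then reorder them (descending) by the variance of the per-subtype mean
    scores.  Ties break by higher variance explained, then lower index.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("select_em_pcs needs >=2 subtypes in labels")
    n_comp = model.scores.shape[1]
    order = np.argsort(-model.variance_explained, kind="stable")
    candidates = list(order[: min(n_candidates, n_comp)])
    between_var = {}
    for k in candidates:
        subtype_means = [model.scores[labels == s, k].mean() for s in uniq]
        between_var[k] = float(np.var(subtype_means))
    ranked = sorted(
        candidates,
        key=lambda k: (-between_var[k], -model.variance_explained[k], k),
    )
    return ranked
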