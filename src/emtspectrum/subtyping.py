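"""Archetype specialists and the stratified resampling enrichment test.

Cells carry archetype weight vectors on the simplex (one weight per archetype,
summing to 1).  A cell is a *specialist* of an archetype when that weight
exceeds a threshold (default 0.95, strict inequality); everything else is a
generalist.  To decide which transcriptional subtype each archetype
represents, the mean bulk-signature score of its specialists, m, is compared
to a null distribution built by resampling: B times, draw (with replacement)
as many non-specialist cells as there are specialists — sampled evenly across
strata such as time points so sparse time points are not swamped — and record
the mean score.  p is the fraction of null means >= m.  Across all
(archetype, signature) pairs the p-values are Holm-adjusted and q < 0.1 is
called significant; an archetype significant for several signatures gets the
merged class label (e.g. "A/N").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("emtspectrum")

SUBTYPE_ORDER = ("A", "A2", "N", "P", "Y")


@dataclass
class ArchetypeWeights:
    """Per-cell simplex weights over archetypes (rows sum to 1, entries >= 0)."""

    cell_ids: list[str]
    archetype_names: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.cell_ids), len(self.archetype_names)):
            raise ValueError("ArchetypeWeights shape mismatch")
        if np.any(self.weights < 0):
            raise ValueError("archetype weights must be non-negative")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-6):
            bad = np.where(~np.isclose(self.weights.sum(axis=1), 1.0, atol=1e-6))[0]
            raise ValueError(
                f"archetype weight rows must sum to 1; offenders: "
                f"{[self.cell_ids[i] for i in bad[:5]]}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=pd.Index(self.cell_ids, name="cell_id"),
                            columns=self.archetype_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ArchetypeWeights":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))


@dataclass
class EnrichmentResult:
    """Outcome of the resampling test for one (archetype, signature) pair."""

    archetype: str
    signature: str
    m: float                 # mean bulk score of the specialists
    n_a: int                 # number of specialists
    null_means: np.ndarray   # B resampled means, kept for audit
    p: float
    q: float = np.nan        # Holm-adjusted, filled by holm_adjust_results
    significant: bool = False


def label_specialists(aw: ArchetypeWeights, threshold: float = 0.95) -> dict[str, str]:
    """Map each cell to the archetype whose weight strictly exceeds
    ``threshold``, or ``"unassigned"`` (generalists).

    ``threshold`` must exceed 0.5 so at most one archetype can qualify.
    """
    if threshold <= 0.5:
        raise ValueError("threshold must be > 0.5 for a unique assignment")
    out = {}
    winners = np.argmax(aw.weights, axis=1)
    top = aw.weights[np.arange(len(aw.cell_ids)), winners]
    for cell, arch_idx, w in zip(aw.cell_ids, winners, top):
        out[cell] = aw.archetype_names[arch_idx] if w > threshold else "unassigned"
    return out


def _stratum_allocation(n_a: int, strata_names: list[str], sizes: dict[str, int]) -> dict[str, int]:
    """Split a sample of size n_a evenly over strata; remainder cells go to
    the largest strata first (name order on size ties).  Deterministic."""
    k = len(strata_names)
    base, rem = divmod(n_a, k)
    alloc = {s: base for s in strata_names}
    for s in sorted(strata_names, key=lambda s: (-sizes[s], s))[:rem]:
        alloc[s] += 1
    return alloc


def enrichment_test(
    scores: np.ndarray,
    specialist_mask: np.ndarray,
    strata: np.ndarray | None = None,
    B: int = 1000,
    seed: int = 0,
    strict_greater: bool = False,
    smooth: bool = False,
    archetype: str = "",
    signature: str = "",
) -> EnrichmentResult:
    """Stratified resampling test for specialist enrichment in one signature.

    Parameters
    ----------
    scores : per-cell bulk signature score, aligned with ``specialist_mask``.
    specialist_mask : boolean, True for the archetype's specialist cells.
    strata : optional per-cell stratum labels (e.g. time point); resamples are
        allocated evenly across strata.
    strict_greater : count only null means strictly above m (the literal
        "percentage of means above m"); by default ties count against
        enrichment so constant data yield p = 1 rather than 0.
    smooth : use (count + 1) / (B + 1) instead of count / B.
    """
    scores = np.asarray(scores, dtype=float)
    specialist_mask = np.asarray(specialist_mask, dtype=bool)
    if scores.shape != specialist_mask.shape:
        raise ValueError("scores and specialist_mask must align")
    n_a = int(specialist_mask.sum())
    if n_a == 0:
        raise ValueError("no specialist cells")
    if B < 100:
        logger.warning("enrichment_test: B=%d is small; null estimate is coarse", B)
    m = float(scores[specialist_mask].mean())
    rest = ~specialist_mask
    rng = np.random.default_rng(seed)

    if strata is None:
        pool = scores[rest]
        if pool.size == 0:
            raise ValueError("no non-specialist cells to resample from")
        draws = rng.integers(0, pool.size, size=(B, n_a))
        null_means = pool[draws].mean(axis=1)
    else:
        strata = np.asarray(strata)
        names = sorted({str(s) for s in strata})
        pools = {s: scores[rest & (strata.astype(str) == s)] for s in names}
        empty = [s for s in names if pools[s].size == 0]
        if empty:
            raise ValueError(f"strata with no non-specialist cells: {empty}")
        sizes = {s: int(pools[s].size) for s in names}
        alloc = _stratum_allocation(n_a, names, sizes)
        null_sums = np.zeros(B)
        for s in names:
            k = alloc[s]
            if k == 0:
                continue
            draws = rng.integers(0, pools[s].size, size=(B, k))
            null_sums += pools[s][draws].sum(axis=1)
        null_means = null_sums / n_a

    count = int((null_means > m).sum()) if strict_greater else int((null_means >= m).sum())
    p = (count + 1) / (B + 1) if smooth else count / B
    return EnrichmentResult(archetype=archetype, signature=signature, m=m, n_a=n_a,
                            null_means=null_means, p=float(p))


def holm_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Holm (step-down Bonferroni) adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def holm_adjust_results(results: list[EnrichmentResult], q_cut: float = 0.1) -> list[EnrichmentResult]:
    """Fill q and significance across a family of enrichment tests."""
    qs = holm_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
        r.significant = bool(q < q_cut)
    return results


def assign_subtypes(results: list[EnrichmentResult], q_cut: float = 0.1) -> dict[str, str]:
    """Label each archetype with every signature significant at q < q_cut.

    Multiple significant signatures give a merged class like "A/N" (canonical
    subtype order); no significant signature gives "unassigned".
    """
    by_archetype: dict[str, list[str]] = {}
    for r in results:
        if np.isnan(r.q):
            raise ValueError("run holm_adjust_results before assign_subtypes")
        by_archetype.setdefault(r.archetype, [])
        if r.q < q_cut:
            by_archetype[r.archetype].append(r.signature)
    out = {}
    for arch, sigs in by_archetype.items():
        if not sigs:
            out[arch] = "unassigned"
        else:
            ordered = sorted(set(sigs), key=lambda s: (
                SUBTYPE_ORDER.index(s) if s in SUBTYPE_ORDER else len(SUBTYPE_ORDER), s))
            out[arch] = "/".join(ordered)
    return out


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "archetype": [r.archetype for r in results],
            "signature": [r.signature for r in results],
            "m": [r.m for r in results],
            "n_a": [r.n_a for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "significant": [r.significant for r in results],
        }
    )
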