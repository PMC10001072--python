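"""Expression-matrix I/O and the standard single-cell preprocessing chain.

The pipeline's matrices move through a fixed sequence of layers::

    raw  --normalize_total-->  normalized  --log1p_transform-->  lognorm
         --scale_genes-->  scaled

Each stage checks the incoming layer tag and refuses out-of-order input, so a
matrix can never be, say, scaled twice or log-transformed before library-size
normalization.  Gene symbols are uppercased throughout so mouse (``Vim``) and
human (``VIM``) data hit the same gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger("emtspectrum")

LAYERS = ("raw", "normalized", "lognorm", "scaled")

# Default cell/gene filters; dataset-specific in practice, so exposed as
# arguments everywhere they are used.
DEFAULT_MIN_GENES_PER_CELL = 200
DEFAULT_MIN_CELLS_PER_GENE = 3


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = 1
    if dups:
        raise ValueError(f"duplicate {what} IDs: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Dense cells x genes expression values with a layer tag.

    Parameters
    ----------
    values : ndarray, shape (n_cells, n_genes)
        Non-negative for ``raw``/``normalized``/``lognorm`` layers; any real
        for ``scaled``.
    cell_ids, gene_ids : list of str
        Ordered, unique identifiers.  Gene IDs are stored uppercased.
    layer : {"raw", "normalized", "lognorm", "scaled"}
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g).upper() for g in self.gene_ids]
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes matrix")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if self.layer in ("raw", "normalized", "lognorm") and np.any(self.values < 0):
            raise ValueError(f"layer {self.layer!r} must be non-negative")
        if self.layer == "raw" and not np.allclose(self.values, np.round(self.values)):
            raise ValueError("raw layer must hold integer counts")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, symbols: Iterable[str]) -> np.ndarray:
        """Column indices of the given symbols in matrix column order
        (deterministic even for set-like inputs); missing symbols skipped."""
        want = {str(s).upper() for s in symbols}
        return np.array(
            [i for i, g in enumerate(self.gene_ids) if g in want], dtype=int
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class GeneSet:
    """A named set of gene symbols, stored uppercased."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        genes = [str(g).upper() for g in self.genes]
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        self.genes = frozenset(genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return str(symbol).upper() in self.genes


SUBTYPE_LABELS = ("A", "A2", "N", "P", "Y", "A/N", "P/Y", "unassigned")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited cell metadata table; ``cell_id`` column required."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in df.columns:
        raise ValueError(f"{path}: metadata must have a 'cell_id' column")
    if df["cell_id"].duplicated().any():
        dups = sorted(df.loc[df["cell_id"].duplicated(), "cell_id"].unique())
        raise ValueError(f"{path}: duplicate cell_id entries: {dups}")
    return df


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from dense CSV or Matrix Market triplet.

    CSV: cells as rows, first column = cell IDs, header = gene IDs.
    MTX: ``<stem>.mtx`` (cells x genes) with companion ``genes.tsv`` and
    ``cells.tsv`` (one ID per line) in the same directory.

    The layer is ``raw`` when every entry is an integer, else ``normalized``.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "csv"
    if format == "csv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")[1:]
        _check_unique(header, "gene")  # pandas would silently mangle duplicates
        df = pd.read_csv(path, index_col=0)
        _check_unique([str(i) for i in df.index], "cell")
        values = df.to_numpy(dtype=float)
        cell_ids, gene_ids = list(df.index.astype(str)), list(df.columns.astype(str))
    elif format == "mtx":
        genes_path = path.parent / "genes.tsv"
        cells_path = path.parent / "cells.tsv"
        for companion in (genes_path, cells_path):
            if not companion.exists():
                raise FileNotFoundError(
                    f"MTX companion file missing: {companion}"
                )
        mat = spio.mmread(path)
        values = np.asarray(sparse.coo_matrix(mat).todense(), dtype=float)
        gene_ids = genes_path.read_text().split()
        cell_ids = cells_path.read_text().split()
        if values.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"{path}: matrix shape {values.shape} does not match "
                f"{len(cell_ids)} cells / {len(gene_ids)} genes"
            )
    else:
        raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'csv'")
    is_int = np.allclose(values, np.round(values))
    layer = "raw" if is_int else "normalized"
    return ExpressionMatrix(values, cell_ids, gene_ids, layer=layer)


def write_expression(em: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    """Write to dense CSV or MTX triplet (with genes.tsv / cells.tsv)."""
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "csv"
    if format == "csv":
        em.to_frame().to_csv(path, float_format="%.17g")
    elif format == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(em.values), precision=17)
        (path.parent / "genes.tsv").write_text("\n".join(em.gene_ids) + "\n")
        (path.parent / "cells.tsv").write_text("\n".join(em.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``name TAB description TAB gene TAB gene ...``."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3"
                )
            sets.append(GeneSet(name=fields[0], genes=frozenset(fields[2:])))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description] + sorted(gs.genes)) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing chain
# ---------------------------------------------------------------------------

def _require_layer(em: ExpressionMatrix, layer: str, op: str) -> None:
    if em.layer != layer:
        raise ValueError(f"{op} requires layer={layer!r}, got {em.layer!r}")


def filter_cells_genes(
    em: ExpressionMatrix,
    min_genes_per_cell: int = DEFAULT_MIN_GENES_PER_CELL,
    min_cells_per_gene: int = DEFAULT_MIN_CELLS_PER_GENE,
) -> ExpressionMatrix:
    """Drop cells expressing too few genes, then genes seen in too few cells."""
    _require_layer(em, "raw", "filter_cells_genes")
    genes_per_cell = (em.values > 0).sum(axis=1)
    keep_cells = genes_per_cell >= min_genes_per_cell
    values = em.values[keep_cells]
    cells_per_gene = (values > 0).sum(axis=0)
    keep_genes = cells_per_gene >= min_cells_per_gene
    logger.info(
        "filter: %d/%d cells kept (min %d genes), %d/%d genes kept (min %d cells)",
        keep_cells.sum(), em.n_cells, min_genes_per_cell,
        keep_genes.sum(), em.n_genes, min_cells_per_gene,
    )
    return ExpressionMatrix(
        values[:, keep_genes],
        [c for c, k in zip(em.cell_ids, keep_cells) if k],
        [g for g, k in zip(em.gene_ids, keep_genes) if k],
        layer="raw",
    )


def normalize_total(em: ExpressionMatrix, target_sum: float | str = "auto") -> ExpressionMatrix:
    """Scale each cell so its total counts equal ``target_sum``.

    ``target_sum="auto"`` uses the median of the per-cell totals.
    """
    _require_layer(em, "raw", "normalize_total")
    totals = em.values.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        offenders = [c for c, z in zip(em.cell_ids, zero) if z]
        raise ValueError(f"all-zero cells cannot be normalized: {offenders}")
    if target_sum == "auto":
        target = float(np.median(totals))
    else:
        target = float(target_sum)
        if target <= 0:
            raise ValueError("target_sum must be positive")
    values = em.values * (target / totals)[:, None]
    return ExpressionMatrix(values, em.cell_ids, em.gene_ids, layer="normalized")


def log1p_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log(1 + x) of library-size-normalized values."""
    _require_layer(em, "normalized", "log1p_transform")
    if np.any(em.values < 0):
        raise ValueError("log1p requires non-negative input")
    return ExpressionMatrix(np.log1p(em.values), em.cell_ids, em.gene_ids, layer="lognorm")


def scale_genes(em: ExpressionMatrix, clip: float | None = 10.0) -> ExpressionMatrix:
    """Center each gene to mean 0 and unit population SD, then clip.

    Zero-variance genes become all-zero columns.  ``clip=None`` disables
    clipping; the default +/-10 follows the common single-cell convention.
    """
    _require_layer(em, "lognorm", "scale_genes")
    mean = em.values.mean(axis=0)
    sd = em.values.std(axis=0)  # population (n) convention
    centered = em.values - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    if clip is not None:
        if clip <= 0:
            raise ValueError("clip must be positive")
        scaled = np.clip(scaled, -clip, clip)
    return ExpressionMatrix(scaled, em.cell_ids, em.gene_ids, layer="scaled")


def select_hvg(
    em: ExpressionMatrix,
    min_mean: float = 0.0125,
    max_mean: float = 5.0,
    min_disp: float = 0.8,
    n_bins: int = 20,
) -> list[str]:
    """Dispersion-based highly-variable-gene selection.

    Per-gene mean and dispersion (variance/mean) are computed on ``expm1`` of
    the lognorm layer; genes are binned into ``n_bins`` equal-frequency bins
    by mean; dispersion is z-scored within each bin; a gene is kept when
    ``min_mean < mean < max_mean`` and its normalized dispersion exceeds
    ``min_disp``.
    """
    _require_layer(em, "lognorm", "select_hvg")
    x = np.expm1(em.values)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if em.n_cells > 1 else np.zeros(em.n_genes)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), np.nan)
    if em.n_genes < n_bins:
        logger.warning(
            "select_hvg: only %d genes (< %d bins); using a single bin",
            em.n_genes, n_bins,
        )
        bins = pd.Series(np.zeros(em.n_genes, dtype=int))
    else:
        bins = pd.qcut(pd.Series(mean).rank(method="first"), q=n_bins, labels=False)
    df = pd.DataFrame({"mean": mean, "disp": disp, "bin": np.asarray(bins)})
    grouped = df.groupby("bin")["disp"]
    bin_mean = grouped.transform("mean")
    bin_sd = grouped.transform(lambda s: s.std(ddof=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        norm_disp = (df["disp"] - bin_mean) / bin_sd.replace(0.0, np.nan)
    norm_disp = norm_disp.fillna(0.0).to_numpy()
    keep = (mean > min_mean) & (mean < max_mean) & (norm_disp > min_disp)
    selected = [g for g, k in zip(em.gene_ids, keep) if k]
    logger.info("select_hvg: %d/%d genes selected", len(selected), em.n_genes)
    return selected
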