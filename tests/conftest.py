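import numpy as np
import pytest

from emtspectrum import (
    ExpressionMatrix, GeneSet, SyntheticConfig, filter_cells_genes,
    log1p_transform, normalize_total, simulate_dataset,
)

SUBTYPES = ("A", "A2", "N", "P", "Y")


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic dataset shared across tests: 80 cells/subtype."""
    cfg = SyntheticConfig(
        n_cells_per_subtype={s: 80 for s in SUBTYPES},
        n_genes_background=400,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_lognorm(small_sim):
    em, meta, aw, gt = small_sim
    lognorm = log1p_transform(normalize_total(filter_cells_genes(em)))
    labels = (
        meta.set_index("cell_id").reindex(lognorm.cell_ids)["subtype_label"].to_numpy()
    )
    return lognorm, labels, gt


@pytest.fixture
def tiny_counts():
    """3 cells x 4 genes of hand-enterable integer counts."""
    values = np.array([[1.0, 0.0, 1.0, 2.0], [2.0, 3.0, 5.0, 0.0], [4.0, 4.0, 4.0, 4.0]])
    return ExpressionMatrix(values, ["c1", "c2", "c3"], ["G1", "G2", "G3", "G4"],
                            layer="raw")


@pytest.fixture
def lognorm_from(tiny_counts):
    def make(values, cell_ids=None, gene_ids=None):
        values = np.asarray(values, dtype=float)
        n_cells, n_genes = values.shape
        return ExpressionMatrix(
            values,
            cell_ids or [f"c{i}" for i in range(n_cells)],
            gene_ids or [f"G{j}" for j in range(n_genes)],
            layer="lognorm",
        )
    return make


@pytest.fixture
def gs():
    def make(name, *genes):
        return GeneSet(name=name, genes=frozenset(genes))
    return make
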