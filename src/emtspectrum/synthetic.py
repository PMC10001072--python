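"""Synthetic single-cell datasets with planted EMT / subtype structure.

The generator emulates the statistical shape of UMI-count scRNA-seq from a
tumor carrying five transcriptional subtypes (A, A2, N, P, Y) arranged on an
epithelial-mesenchymal spectrum:

* an epithelial program (default 232 genes, including ``CDH1``) shifted up in
  A2, mildly up in A, and down in P/Y;
* a mesenchymal program split into two divergent halves — M1 (default 96
  genes, including ``ZEB1``) up in the neuroendocrine A/N subtypes, and M2
  (default 97 genes, including ``VIM``) up in the non-neuroendocrine P/Y
  subtypes — with A2 low on both, so the combined M signature is lowest in A2;
* a 105-gene subtype signature (21 genes per subtype, up only in its own
  subtype) sharing a configurable number of genes (default 20) with the EMT
  sets, giving the planted Jaccard overlap 20/510;
* a per-cell latent epithelial factor shared by the E genes and the A2
  signature genes within neuroendocrine cells, so the A2-epithelial coupling
  exists even inside a single subtype;
* an ``ASCL1`` marker expressed in A/A2 cells and largely undetected
  elsewhere;
* treatment modeled as an increment of the M2 program in treated cells
  (a cisplatin-induced EMT-like shift), plus uniform time-point assignment
  for stratified resampling.

Counts are negative binomial around cell-specific lognormal library sizes;
dispersion is shared across genes.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, GeneSet
from .subtyping import ArchetypeWeights

SUBTYPES = ("A", "A2", "N", "P", "Y")

# log-scale shift multipliers applied as effect_size * entry
_E_SHIFT = {"A": 0.5, "A2": 1.0, "N": 0.0, "P": -0.5, "Y": -0.5}
_M1_SHIFT = {"A": 1.0, "A2": -1.0, "N": 1.0, "P": 0.0, "Y": 0.0}
_M2_SHIFT = {"A": 0.0, "A2": -1.0, "N": 0.0, "P": 1.0, "Y": 1.0}


@dataclass
class SyntheticConfig:
    """Generative parameters; the defaults are the study conditions."""

    n_cells_per_subtype: dict[str, int] = field(
        default_factory=lambda: {s: 500 for s in SUBTYPES})
    n_genes_background: int = 1500
    e_set_size: int = 232
    m1_set_size: int = 96
    m2_set_size: int = 97
    sclc_sig_size: int = 105          # split evenly over the five subtypes
    overlap_genes: int = 20           # shared between SCLC signature and EMT sets
    effect_size: float = 1.0          # log-scale mean shift
    nb_dispersion: float = 10.0       # NB size parameter (var = m + m^2/size)
    library_size_lognormal: tuple[float, float] = (9.2, 0.35)  # (mu, sigma) of log lib
    baseline_log_sd: float = 0.5      # spread of per-gene baseline log rates
    latent_loading: float = 0.7       # E / A2-signature coupling strength
    latent_sd: float = 0.5
    specialist_fraction: float = 0.6  # cells drawn with archetype weight > 0.95
    n_time_points: int = 3
    treatment_fraction: float = 0.3
    treatment_m2_shift: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.n_cells_per_subtype or any(
                n <= 0 for n in self.n_cells_per_subtype.values()):
            raise ValueError("n_cells_per_subtype must be positive")
        for name in ("n_genes_background", "e_set_size", "m1_set_size",
                     "m2_set_size", "sclc_sig_size", "n_time_points"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("specialist_fraction", "treatment_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.overlap_genes < 0:
            raise ValueError("overlap_genes must be >= 0")
        per_sig = self.sclc_sig_size // len(SUBTYPES)
        e_ov, m1_ov, m2_ov = _overlap_split(self.overlap_genes)
        if e_ov > min(per_sig, self.e_set_size) or m1_ov > min(per_sig, self.m1_set_size) \
                or m2_ov > min(per_sig, self.m2_set_size):
            raise ValueError("overlap_genes too large for the configured set sizes")


def _overlap_split(overlap: int) -> tuple[int, int, int]:
    """Split the EMT/signature overlap between the E, M1 and M2 sets."""
    e = overlap // 2
    m1 = (overlap - e) // 2
    return e, m1, overlap - e - m1


@dataclass
class GroundTruth:
    """Planted structure emitted alongside each synthetic dataset."""

    cell_subtype: dict[str, str]
    gene_program: dict[str, str]          # E / M1 / M2 / signature / marker / background
    gene_sets: dict[str, frozenset[str]]  # E, M1, M2, M, SIG_<subtype>, SCLC_SIG
    archetype_weights: ArchetypeWeights
    latent_factor: np.ndarray             # per-cell epithelial latent factor


def _gene_names(cfg: SyntheticConfig) -> tuple[dict[str, list[str]], list[str]]:
    """Build gene name lists per program, with named marker genes planted."""
    e = ["CDH1"] + [f"EGENE{i:04d}" for i in range(1, cfg.e_set_size)]
    m1 = ["ZEB1"] + [f"M1GENE{i:04d}" for i in range(1, cfg.m1_set_size)]
    m2 = ["VIM"] + [f"M2GENE{i:04d}" for i in range(1, cfg.m2_set_size)]
    bg = [f"BG{i:05d}" for i in range(cfg.n_genes_background)]

    per_sig = cfg.sclc_sig_size // len(SUBTYPES)
    e_ov, m1_ov, m2_ov = _overlap_split(cfg.overlap_genes)
    sig: dict[str, list[str]] = {}
    counter = 0
    for s in SUBTYPES:
        n_unique = per_sig
        borrowed: list[str] = []
        if s == "A2":
            borrowed, n_unique = e[:e_ov], per_sig - e_ov
        elif s == "N":
            borrowed, n_unique = m1[:m1_ov], per_sig - m1_ov
        elif s == "Y":
            borrowed, n_unique = m2[:m2_ov], per_sig - m2_ov
        unique = [f"SIG{s.replace('/', '')}{i:03d}" for i in range(counter, counter + n_unique)]
        counter += n_unique
        sig[s] = borrowed + unique
    programs = {"E": e, "M1": m1, "M2": m2, "background": bg}
    for s in SUBTYPES:
        programs[f"SIG_{s}"] = sig[s]
    order = e + m1 + m2
    for s in SUBTYPES:
        order += [g for g in sig[s] if g not in set(order)]
    order += ["ASCL1"] + bg
    return programs, order


def simulate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, ArchetypeWeights, GroundTruth]:
    """Generate one dataset: raw counts, cell metadata, archetype weights and
    the planted ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    programs, gene_order = _gene_names(config)
    gene_pos = {g: i for i, g in enumerate(gene_order)}
    n_genes = len(gene_order)

    subtype_of_cell: list[str] = []
    for s, n in config.n_cells_per_subtype.items():
        subtype_of_cell += [s] * n
    n_cells = len(subtype_of_cell)
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]

    # log-scale rate matrix: baseline + planted shifts
    base = rng.normal(0.0, config.baseline_log_sd, size=n_genes)
    log_rate = np.tile(base, (n_cells, 1))
    d = config.effect_size
    e_idx = np.array([gene_pos[g] for g in programs["E"]])
    m1_idx = np.array([gene_pos[g] for g in programs["M1"]])
    m2_idx = np.array([gene_pos[g] for g in programs["M2"]])
    sig_idx = {s: np.array([gene_pos[g] for g in programs[f"SIG_{s}"]]) for s in SUBTYPES}
    ascl1_idx = gene_pos["ASCL1"]

    subtype_arr = np.asarray(subtype_of_cell)
    for s in SUBTYPES:
        rows = np.where(subtype_arr == s)[0]
        if rows.size == 0:
            continue
        log_rate[np.ix_(rows, e_idx)] += d * _E_SHIFT[s]
        log_rate[np.ix_(rows, m1_idx)] += d * _M1_SHIFT[s]
        log_rate[np.ix_(rows, m2_idx)] += d * _M2_SHIFT[s]
        log_rate[np.ix_(rows, sig_idx[s])] += d
        log_rate[rows, ascl1_idx] += 2.0 * d if s in ("A", "A2") else -2.0

    # shared epithelial latent factor within neuroendocrine cells
    latent = rng.normal(0.0, config.latent_sd, size=n_cells)
    ne_mask = np.isin(subtype_arr, ("A", "A2", "N"))
    coupled_idx = np.unique(np.concatenate([e_idx, sig_idx["A2"]]))
    log_rate[np.ix_(np.where(ne_mask)[0], coupled_idx)] += (
        config.latent_loading * latent[ne_mask][:, None])

    # covariates
    time_point = rng.integers(0, config.n_time_points, size=n_cells)
    treated = rng.random(n_cells) < config.treatment_fraction
    log_rate[np.ix_(np.where(treated)[0], m2_idx)] += config.treatment_m2_shift

    # counts: NB around lognormal library sizes
    rates = np.exp(log_rate)
    props = rates / rates.sum(axis=1, keepdims=True)
    mu_lib, sd_lib = config.library_size_lognormal
    lib = rng.lognormal(mu_lib, sd_lib, size=n_cells)
    mean = props * lib[:, None]
    theta = config.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mean)).astype(float)

    em = ExpressionMatrix(counts, cell_ids, gene_order, layer="raw")

    # archetype weights: specialists concentrated at their own vertex
    archetypes = list(config.n_cells_per_subtype.keys())
    k = len(archetypes)
    weights = np.zeros((n_cells, k))
    specialist = rng.random(n_cells) < config.specialist_fraction
    own = np.array([archetypes.index(s) for s in subtype_arr])
    for i in range(n_cells):
        if specialist[i]:
            if k == 1:
                row = np.array([1.0])
            else:
                w_own = rng.uniform(0.955, 0.995)
                rest = rng.dirichlet(np.ones(k - 1)) * (1 - w_own)
                row = np.insert(rest, own[i], w_own)
        else:
            alpha = np.ones(k)
            alpha[own[i]] = 3.0
            row = rng.dirichlet(alpha)
        weights[i] = row
    aw = ArchetypeWeights(cell_ids, archetypes, weights)

    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "subtype_label": subtype_arr,
            "time_point": [f"tp{t}" for t in time_point],
            "treatment": np.where(treated, "treated", "untreated"),
            "tumor_id": "simtumor",
        }
    )

    gene_program = {}
    for prog in ("E", "M1", "M2", "background"):
        for g in programs[prog]:
            gene_program[g] = prog
    for s in SUBTYPES:
        for g in programs[f"SIG_{s}"]:
            gene_program.setdefault(g, "signature")
    gene_program["ASCL1"] = "marker"

    gene_sets = {
        "E": frozenset(programs["E"]),
        "M1": frozenset(programs["M1"]),
        "M2": frozenset(programs["M2"]),
        "M": frozenset(programs["M1"]) | frozenset(programs["M2"]),
        "SCLC_SIG": frozenset(g for s in SUBTYPES for g in programs[f"SIG_{s}"]),
    }
    for s in SUBTYPES:
        gene_sets[f"SIG_{s}"] = frozenset(programs[f"SIG_{s}"])

    gt = GroundTruth(
        cell_subtype=dict(zip(cell_ids, subtype_arr)),
        gene_program=gene_program,
        gene_sets=gene_sets,
        archetype_weights=aw,
        latent_factor=latent,
    )
    return em, meta, aw, gt


def emit_gene_sets(gt: GroundTruth) -> list[GeneSet]:
    """Planted gene sets as GeneSet objects, ready for GMT export: the
    epithelial set, the combined and split mesenchymal sets, the full subtype
    signature and its per-subtype slices."""
    names = ["E", "M", "M1", "M2", "SCLC_SIG"] + [
        n for n in sorted(gt.gene_sets) if n.startswith("SIG_")]
    return [GeneSet(name=n, genes=gt.gene_sets[n]) for n in names]
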