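"""End-to-end orchestration: preprocess, score, subtype, contrast, report.

A run takes an expression matrix (or simulates one), pushes it through the
preprocessing chain, computes ssGSEA and nnPCA E/M scores plus per-subtype
signature scores, runs the archetype-enrichment resampling test, classifies
divergent mesenchymal genes, and writes the correlation panel — all into one
report directory of tab-delimited tables whose headers record the seed and a
hash of the configuration.  All randomness flows from a single root seed,
split per stage by stable stage names.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (
    ExpressionMatrix, GeneSet, filter_cells_genes, log1p_transform,
    normalize_total, read_expression, read_gmt, read_metadata, write_expression,
    write_gmt,
)
from .emt_divergence import (
    classify_m_genes, correlation_frame, marker_positive, score_correlation,
)
from .nnpca import nnpca_fit, select_em_pcs
from .ssgsea import ScoreTable, exclude_overlap, ssgsea_score
from .subtyping import (
    ArchetypeWeights, assign_subtypes, enrichment_test, holm_adjust_results,
    label_specialists, results_frame,
)
from .synthetic import SyntheticConfig, emit_gene_sets, simulate_dataset

logger = logging.getLogger("emtspectrum")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Flat run configuration; every field has a module default."""

    # inputs (all optional when simulate=True)
    expr_path: str | None = None
    meta_path: str | None = None
    weights_path: str | None = None
    sets_path: str | None = None
    simulate: bool = True
    out_dir: str = "emtspectrum_report"
    seed: int = 0
    # preprocessing
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    target_sum: float | str = "auto"
    # scoring
    alpha: float = 0.25
    n_components: int = 5
    # subtyping
    specialist_threshold: float = 0.95
    B: int = 1000
    q_cut: float = 0.1
    # divergence
    n_class: str = "N"
    y_class: str = "Y"
    fdr_cut: float = 0.05
    # robustness rerun
    exclude_overlap_rerun: bool = True
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", {})
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if syn:
            if "n_cells_per_subtype" in syn:
                syn["n_cells_per_subtype"] = dict(syn["n_cells_per_subtype"])
            if "library_size_lognormal" in syn:
                syn["library_size_lognormal"] = tuple(syn["library_size_lognormal"])
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg


def _write_table(df: pd.DataFrame, path: Path, seed: int, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config={cfg_hash} emtspectrum={__version__}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate:
        syn = cfg.synthetic
        syn.seed = stage_seed(cfg.seed, "simulate")
        em, meta, aw, gt = simulate_dataset(syn)
        sets = {gs.name: gs for gs in emit_gene_sets(gt)}
        return em, meta, aw, sets
    if not (cfg.expr_path and cfg.meta_path and cfg.weights_path and cfg.sets_path):
        raise ValueError("non-simulated runs need expr/meta/weights/sets paths")
    em = read_expression(cfg.expr_path)
    meta = read_metadata(cfg.meta_path)
    aw = ArchetypeWeights.from_frame(
        pd.read_csv(cfg.weights_path, sep="\t", index_col=0))
    sets = {gs.name: gs for gs in read_gmt(cfg.sets_path)}
    return em, meta, aw, sets


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("emtspectrum %s  seed=%d  config=%s", __version__,
                    config.seed, cfg_hash)
        logger.info("parameters: %s", json.dumps(asdict(config), default=str))

        em_raw, meta, aw, sets = _load_inputs(config)
        for required in ("E", "M", "SCLC_SIG"):
            if required not in sets:
                raise ValueError(f"gene set {required!r} missing from inputs")
        logger.info("input: %d cells x %d genes", em_raw.n_cells, em_raw.n_genes)

        # --- preprocessing -------------------------------------------------
        em_f = filter_cells_genes(em_raw, config.min_genes_per_cell,
                                  config.min_cells_per_gene)
        lognorm = log1p_transform(normalize_total(em_f, config.target_sum))
        meta = meta.set_index("cell_id").reindex(lognorm.cell_ids).reset_index()

        # --- ssGSEA E/M scores --------------------------------------------
        e_col = ssgsea_score(lognorm, sets["E"], alpha=config.alpha,
                             score_name="E_ssgsea")
        m_col = ssgsea_score(lognorm, sets["M"], alpha=config.alpha,
                             score_name="M_ssgsea")

        # --- nnPCA E/M scores ---------------------------------------------
        labels = meta["subtype_label"].to_numpy() if "subtype_label" in meta else None
        nn_tables = []
        for axis in ("E", "M"):
            n_comp = min(config.n_components,
                         len(lognorm.gene_index(sets[axis].genes)),
                         lognorm.n_cells - 1)
            model = nnpca_fit(lognorm, sets[axis], n_components=n_comp,
                              seed=stage_seed(config.seed, f"nnpca_{axis}"))
            model.to_json(out / f"nnpca_{axis}.json")
            order = (select_em_pcs(model, labels)
                     if labels is not None and len(np.unique(labels)) > 1
                     else list(np.argsort(-model.variance_explained)))
            ranked = ScoreTable(
                lognorm.cell_ids,
                [f"{axis}_nnpc{j + 1}" for j in range(len(order))],
                model.scores[:, order],
            )
            nn_tables.append(ranked)
            logger.info("nnpca %s: variance explained %s, ranked order %s",
                        axis, np.round(model.variance_explained, 4).tolist(), order)

        # --- subtype signature scores ---------------------------------------
        sig_names = [n for n in sets if n.startswith("SIG_")]
        sig_tables = [
            ssgsea_score(lognorm, sets[n], alpha=config.alpha,
                         score_name=n.replace("SIG_", "") + "_score")
            for n in sorted(sig_names)
        ]
        scores = ScoreTable.concat([e_col, m_col] + nn_tables + sig_tables)
        _write_table(scores.to_frame().reset_index(), out / "scores.tsv",
                     config.seed, cfg_hash)

        # --- archetype enrichment test --------------------------------------
        aw_aligned = ArchetypeWeights.from_frame(
            aw.to_frame().reindex(lognorm.cell_ids))
        spec_map = label_specialists(aw_aligned, config.specialist_threshold)
        strata = (meta["time_point"].to_numpy()
                  if "time_point" in meta else None)
        results = []
        for arch in aw_aligned.archetype_names:
            mask = np.array([spec_map[c] == arch for c in lognorm.cell_ids])
            if mask.sum() == 0:
                logger.warning("archetype %s has no specialists; skipped", arch)
                continue
            for tbl in sig_tables:
                sig = tbl.score_names[0].replace("_score", "")
                results.append(enrichment_test(
                    tbl.values[:, 0], mask, strata=strata, B=config.B,
                    seed=stage_seed(config.seed, f"enrich_{arch}_{sig}"),
                    archetype=arch, signature=sig,
                ))
        holm_adjust_results(results, q_cut=config.q_cut)
        _write_table(results_frame(results), out / "enrichment.tsv",
                     config.seed, cfg_hash)
        subtype_map = assign_subtypes(results, q_cut=config.q_cut)
        _write_table(
            pd.DataFrame(sorted(subtype_map.items()),
                         columns=["archetype", "assigned_subtype"]),
            out / "subtypes.tsv", config.seed, cfg_hash)

        # --- M1/M2 divergence -----------------------------------------------
        if labels is not None and {config.n_class, config.y_class} <= set(labels):
            mgenes = classify_m_genes(lognorm, labels, sets["M"],
                                      n_class=config.n_class,
                                      y_class=config.y_class,
                                      fdr_cut=config.fdr_cut)
        else:
            logger.warning("N/Y classes unavailable; mgenes table empty")
            mgenes = pd.DataFrame(
                columns=["gene", "mean_diff", "u_stat", "p", "q", "m_class"])
        _write_table(mgenes, out / "mgenes.tsv", config.seed, cfg_hash)

        # --- correlation panel ------------------------------------------------
        strata_masks = {"all": np.ones(lognorm.n_cells, dtype=bool)}
        if "ASCL1" in lognorm.gene_ids:
            strata_masks["ASCL1+"] = marker_positive(lognorm, "ASCL1")
        if "treatment" in meta:
            tr = meta["treatment"].to_numpy()
            strata_masks["treated"] = tr == "treated"
            strata_masks["untreated"] = tr == "untreated"
        corr_results = []
        for x, y in (("A2_score", "E_nnpc1"), ("A_score", "E_nnpc1"),
                     ("A2_score", "M_nnpc1"), ("A2_score", "CDH1")):
            try:
                corr_results += score_correlation(scores, x, y, em=lognorm,
                                                  strata=strata_masks)
            except KeyError as exc:
                logger.warning("correlation %s vs %s skipped: %s", x, y, exc)
        _write_table(correlation_frame(corr_results), out / "correlations.tsv",
                     config.seed, cfg_hash)

        # --- overlap-exclusion robustness -------------------------------------
        if config.exclude_overlap_rerun:
            from scipy.stats import spearmanr
            rows = []
            for axis, before in (("E", e_col), ("M", m_col)):
                reduced = exclude_overlap(sets[axis], sets["SCLC_SIG"])
                after = ssgsea_score(lognorm, reduced, alpha=config.alpha,
                                     score_name=f"{axis}_ssgsea_excl")
                sr, _ = spearmanr(before.values[:, 0], after.values[:, 0])
                rows.append((axis, len(sets[axis]), len(reduced), float(sr)))
                logger.info("robustness %s: before/after Spearman %.4f", axis, sr)
            _write_table(
                pd.DataFrame(rows, columns=["axis", "n_genes_before",
                                            "n_genes_after", "spearman"]),
                out / "robustness.tsv", config.seed, cfg_hash)

        logger.info("report written to %s", out)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()


def write_simulation(syn: SyntheticConfig, out_dir: str | Path) -> Path:
    """Materialize one synthetic dataset as the pipeline's input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    em, meta, aw, gt = simulate_dataset(syn)
    write_expression(em, out / "expr.mtx", format="mtx")
    meta.to_csv(out / "meta.tsv", sep="\t", index=False)
    aw.to_frame().to_csv(out / "archetypes.tsv", sep="\t")
    write_gmt(emit_gene_sets(gt), out / "sets.gmt")
    truth = {
        "cell_subtype": gt.cell_subtype,
        "gene_program": gt.gene_program,
        "latent_factor": gt.latent_factor.tolist(),
    }
    (out / "truth.json").write_text(json.dumps(truth))
    return out
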