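"""Umbrella pipeline: simulate/load -> preprocess -> test -> enrich -> concord.

Configuration is a flat key-value mapping (YAML on disk); unknown keys are
rejected and cross-field constraints (e.g. ``min_pass <= n_imputations``)
are checked before any stage runs.  Every run writes a manifest recording
input digests, the full parameter snapshot, per-stage record counts and
output digests, which together suffice to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import concordance_report
from .diffabund import ModeratedStabilitySelector
from .enrichment import MeanStatEnrichment, OverlapClusterer
from .errors import ValidationError
from .io import (file_digest, read_design_tsv, read_gene_table_tsv, read_gmt,
                 read_id_map_tsv, read_intensity_tsv, write_design_tsv,
                 write_gene_table_tsv, write_gmt, write_intensity_tsv)
from .preprocess import MedianNormalizer, MissingnessRouter
from .simulate import (SimulationParams, make_category_collection,
                       simulate_gene_table, simulate_proteome)

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "schema_version": "1",
    "seed": 0,
    # inputs (ignored when simulate=True)
    "simulate": False,
    "matrix_path": None,
    "design_path": None,
    "gmt_path": None,
    "gene_table_path": None,
    "id_map_path": None,
    "zero_is_missing": False,
    # preprocessing
    "min_per_group": 4,
    "nmin_present": None,
    "nmax_absent": None,
    # differential abundance
    "n_imputations": 50,
    "q_threshold": 0.1,
    "min_pass": None,
    "q_method": "bh",
    # enrichment
    "n_perm": 10_000,
    "fdr": 0.10,
    "min_nodes": 3,
    "cut_height": 0.7,
    # concordance
    "deg_p_threshold": 0.05,
    "deg_logfc_threshold": 0.5,
    # simulation (sim_* keys map onto SimulationParams fields)
    "sim_n_proteins": 2000,
    "sim_n_per_group": 10,
    "sim_n_batches": 2,
    "sim_frac_da": 0.1,
    "sim_effect_size": 1.0,
    "sim_frac_unique": 0.05,
    "sim_n_categories": 50,
    "sim_n_planted": 4,
    "sim_n_genes": 2000,
    "sim_frac_deg": 0.1,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge defaults, an optional YAML file, and explicit overrides."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with Path(path).open() as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"{path}: config must be a flat mapping")
        config.update(loaded)
    if overrides:
        config.update({k: v for k, v in overrides.items() if v is not None})
    return validate_config(config)


def validate_config(config: dict) -> dict:
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    config = {**DEFAULT_CONFIG, **config}
    for key in ("q_threshold", "fdr", "sim_frac_da", "sim_frac_unique",
                "sim_frac_deg", "deg_p_threshold"):
        if not 0.0 <= float(config[key]) <= 1.0:
            raise ValidationError(f"{key} must lie in [0, 1]")
    if config["n_imputations"] < 1:
        raise ValidationError("n_imputations must be >= 1")
    if (config["min_pass"] is not None
            and config["min_pass"] > config["n_imputations"]):
        raise ValidationError("min_pass cannot exceed n_imputations")
    if config["q_method"] not in ("bh", "storey"):
        raise ValidationError("q_method must be 'bh' or 'storey'")
    if not config["simulate"] and not config["matrix_path"]:
        raise ValidationError("either simulate=true or matrix_path is required")
    return config


def _logger(out_dir: Path) -> logging.Logger:
    log = logging.getLogger(f"lfqstab.{out_dir}")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s [%(stage)s] %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(out_dir / "pipeline.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)
    return log


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute all stages, write outputs + manifest, return the manifest."""
    config = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _logger(out_dir)

    def info(stage, msg):
        log.info(msg, extra={"stage": stage})

    manifest: dict = {
        "software": f"lfqstab {__version__}",
        "schema_version": config["schema_version"],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": {k: v for k, v in config.items()},
        "inputs": {},
        "counts": {},
        "outputs": {},
    }
    seed = int(config["seed"])

    # ---- inputs -----------------------------------------------------------
    id_map = None
    gene_table = None
    gene_sets = None
    if config["simulate"]:
        info("simulate", "generating synthetic study")
        params = SimulationParams(
            n_proteins=config["sim_n_proteins"],
            n_per_group=config["sim_n_per_group"],
            n_batches=config["sim_n_batches"],
            frac_da=config["sim_frac_da"],
            effect_size=config["sim_effect_size"],
            frac_unique=config["sim_frac_unique"],
            seed=seed,
        )
        matrix, design, truth = simulate_proteome(params)
        gene_table, gene_truth = simulate_gene_table(
            config["sim_n_genes"], config["sim_frac_deg"],
            config["sim_effect_size"], seed=seed + 1)
        gene_sets = make_category_collection(
            list(matrix.index), n_categories=config["sim_n_categories"],
            size_range=(10, min(40, len(matrix.index))),
            n_planted=config["sim_n_planted"], seed=seed + 2, truth=truth)
        # synthetic accession -> symbol map pairs protein i with gene i
        id_map = {p: g for p, g in zip(matrix.index, gene_table["gene"])}
        write_intensity_tsv(matrix, out_dir / "matrix.tsv")
        write_design_tsv(design, out_dir / "design.tsv")
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
        write_gene_table_tsv(gene_table, out_dir / "gene_table.tsv")
        gene_truth.to_csv(out_dir / "gene_truth.tsv", sep="\t", index=False)
        write_gmt(gene_sets, out_dir / "categories.gmt")
    else:
        for key in ("matrix_path", "design_path", "gmt_path",
                    "gene_table_path", "id_map_path"):
            if config[key]:
                manifest["inputs"][key] = file_digest(config[key])
        matrix = read_intensity_tsv(config["matrix_path"],
                                    zero_is_missing=config["zero_is_missing"])
        design = read_design_tsv(config["design_path"])
        if config["gmt_path"]:
            gene_sets = read_gmt(config["gmt_path"])
        if config["gene_table_path"]:
            gene_table = read_gene_table_tsv(config["gene_table_path"])
        if config["id_map_path"]:
            id_map = read_id_map_tsv(config["id_map_path"])
    manifest["counts"]["proteins_in"] = len(matrix)
    info("preprocess", f"{len(matrix)} proteins x {matrix.shape[1]} samples")

    # ---- preprocess -------------------------------------------------------
    normalized = MedianNormalizer().fit_transform(matrix)
    write_intensity_tsv(normalized, out_dir / "normalized_matrix.tsv")
    router = MissingnessRouter(
        min_per_group=config["min_per_group"],
        nmin_present=config["nmin_present"],
        nmax_absent=config["nmax_absent"]).fit(normalized, design)
    routing = router.routing_
    pd.DataFrame({
        "protein_id": routing.quantitative_ids + routing.heuristic_ids,
        "path": (["quantitative"] * len(routing.quantitative_ids)
                 + ["heuristic"] * len(routing.heuristic_ids)),
    }).to_csv(out_dir / "routing.tsv", sep="\t", index=False)
    router.unique_calls_.to_csv(out_dir / "unique_calls.tsv", sep="\t", index=False)
    manifest["counts"]["quantitative"] = len(routing.quantitative_ids)
    manifest["counts"]["heuristic"] = len(routing.heuristic_ids)
    n_unique = int((router.unique_calls_["call"] != "insufficient").sum())
    manifest["counts"]["unique_expression_calls"] = n_unique
    info("preprocess", f"{len(routing.quantitative_ids)} quantitative, "
                       f"{len(routing.heuristic_ids)} heuristic, "
                       f"{n_unique} unique-expression calls")

    # ---- differential abundance ------------------------------------------
    selector = ModeratedStabilitySelector(
        n_imputations=config["n_imputations"],
        q_threshold=config["q_threshold"],
        min_pass=config["min_pass"],
        q_method=config["q_method"],
        random_state=seed,
    ).fit(normalized.loc[routing.quantitative_ids], design)
    results = selector.results_
    results.to_csv(out_dir / "differential_results.tsv", sep="\t")
    selector.per_round_.to_csv(out_dir / "per_round.tsv", sep="\t", index=False)
    called = results[results["called"]]
    manifest["counts"]["called"] = len(called)
    info("diffabund", f"{len(called)} proteins called differentially abundant "
                      f"({config['n_imputations']} imputation rounds)")

    # ---- enrichment -------------------------------------------------------
    protein_sig: list = []
    if gene_sets is not None:
        enr = MeanStatEnrichment(n_perm=config["n_perm"], fdr=config["fdr"],
                                 random_state=seed).fit(results["median_t"],
                                                        gene_sets)
        enr.results_.to_csv(out_dir / "enrichment.tsv", sep="\t")
        sig = enr.results_[enr.results_["significant"]]
        protein_sig = list(sig.index)
        manifest["counts"]["significant_categories"] = len(sig)
        info("enrich", f"{len(sig)} significant categories of {len(enr.results_)}")
        if len(sig):
            clusters = OverlapClusterer(
                min_nodes=config["min_nodes"],
                cut_height=config["cut_height"]).fit(sig, gene_sets).clusters_
            clusters.to_csv(out_dir / "clusters.tsv", sep="\t")
            manifest["counts"]["clusters"] = len(clusters)
            manifest["counts"]["clusters_included"] = int(clusters["included"].sum())
            info("enrich", f"{len(clusters)} clusters "
                           f"({int(clusters['included'].sum())} with >= "
                           f"{config['min_nodes']} nodes)")

    # ---- concordance ------------------------------------------------------
    if gene_table is not None and id_map is not None:
        report = concordance_report(
            list(called.index), gene_table, id_map,
            protein_sig_categories=protein_sig, gene_sig_categories=[],
            p_threshold=config["deg_p_threshold"],
            logfc_threshold=config["deg_logfc_threshold"])
        pd.DataFrame({"shared_molecule": report.shared_molecules}).to_csv(
            out_dir / "concordance.tsv", sep="\t", index=False)
        summary = (f"DA proteins: {report.n_da_proteins}\n"
                   f"DEGs: {report.n_degs}\n"
                   f"shared molecules: {report.n_shared_molecules}\n"
                   f"shared categories: {report.n_shared_categories}\n"
                   f"unmapped proteins: {len(report.unmapped_proteins)}\n")
        (out_dir / "concordance_summary.txt").write_text(summary)
        manifest["counts"]["degs"] = report.n_degs
        manifest["counts"]["shared_molecules"] = report.n_shared_molecules
        info("concord", f"{report.n_shared_molecules} shared molecules, "
                        f"{report.n_degs} DEGs")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    for f in sorted(out_dir.iterdir()):
        if f.suffix in (".tsv", ".gmt", ".txt") and f.name != "pipeline.log":
            manifest["outputs"][f.name] = file_digest(f)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str) + "\n")
    return manifest
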