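"""Config-driven pipeline runner with a checksummed run manifest.

A single flat YAML config names the stages to run and their parameters.
The AP-MS branch runs simulate -> enrich -> score -> call -> classify ->
export; the RNA-seq branch runs simulate-rnaseq -> de-filter ->
endogenous -> concordance.  Every stochastic stage takes an explicit seed
(from the config or the ``seed`` argument); the manifest records the
resolved parameters and a SHA-256 checksum of every file written, so a
re-run can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import calls as calls_mod
from . import enrichment as enr
from . import rnaseq as rna
from . import saint as saint_mod
from . import synthetic as syn
from .phenotype import load_phenotype_table, validate_rows

logger = logging.getLogger(__name__)

APMS_STAGES = ["simulate-apms", "enrich", "score", "call", "classify", "export"]
RNASEQ_STAGES = ["simulate-rnaseq", "de-filter", "endogenous", "concordance"]

__all__ = ["run_pipeline", "load_config", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised with a stage-qualified message when a stage fails."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: dict | str | Path,
    out_dir,
    seed: int | None = None,
    dry_run: bool = False,
) -> dict:
    """Execute the configured stages in order; return the run manifest.

    With ``dry_run`` the resolved stage plan and parameters are returned
    (and logged) without writing any file.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir)
    stages = config.get("stages")
    if not stages:
        stages = APMS_STAGES if "rnaseq" not in config else RNASEQ_STAGES
    seed = int(config.get("seed", 0) if seed is None else seed)

    manifest: dict = {"seed": seed, "stages": list(stages), "outputs": {}, "config": config}
    if dry_run:
        logger.info("dry run: stages=%s seed=%d out_dir=%s", stages, seed, out_dir)
        manifest["dry_run"] = True
        return manifest

    out_dir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    for stage in stages:
        try:
            _run_stage(stage, config, seed, out_dir, state, manifest)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-qualify by stage
            raise PipelineError(stage, str(exc)) from exc

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _record(manifest: dict, name: str, path: Path) -> None:
    manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}


def _run_stage(
    stage: str, config: dict, seed: int, out_dir: Path, state: dict, manifest: dict
) -> None:
    if stage == "simulate-apms":
        acfg = config.get("apms", {})
        design = syn.default_design(
            n_proteins=int(acfg.get("n_proteins", 200)),
            bait_protein_id=int(acfg.get("bait_protein_id", 0)),
        )
        truth = syn.default_apms_truth(
            design,
            n_interactors=int(acfg.get("n_interactors", 20)),
            enrichment_factor=float(acfg.get("enrichment_factor", 8.0)),
            dispersion=float(acfg.get("dispersion", 0.2)),
            batch_multiplier=float(acfg.get("batch_multiplier", 1.2)),
            seed=seed,
        )
        matrix, truth_table = syn.simulate_apms(design, truth)
        state.update(
            matrix=matrix,
            truth_table=truth_table,
            design=design,
            bait_index=design.bait_protein_id,
        )
        for name, path in syn.write_apms(matrix, truth_table, out_dir).items():
            _record(manifest, f"apms_{name}", path)

    elif stage == "enrich":
        matrix = _ensure_matrix(state, config, stage)
        construct = config.get("construct", "WT")
        table = enr.enrichment_table(
            matrix,
            construct,
            pseudocount=float(config.get("pseudocount", 0.5)),
            g_alpha=float(config.get("criteria", {}).get("g_alpha", 0.05)),
        )
        bait_id = matrix.protein_ids[state["bait_index"]]
        state.update(enrichment=table, bait_id=bait_id, construct=construct)
        path = out_dir / "enrichment.tsv"
        table.to_csv(path, sep="\t", index_label="protein_id")
        _record(manifest, "enrichment", path)

    elif stage == "score":
        matrix = _require(state, "matrix", stage, "no spectral-count matrix loaded")
        bg = saint_mod.fit_background(matrix)
        scores = saint_mod.score_construct(
            matrix, state.get("construct", "WT"), bg, exclude=[state.get("bait_id")]
        )
        state.update(scores=scores, background=bg)
        path = out_dir / "saint_scores.tsv"
        scores.to_csv(path, sep="\t", index_label="protein_id")
        _record(manifest, "saint_scores", path)

    elif stage == "call":
        records = _require(state, "enrichment", stage, "run enrich first")
        scores = _require(state, "scores", stage, "run score first")
        criteria = calls_mod.CallCriteria(**config.get("criteria", {}))
        bait_id = state.get("bait_id")
        rec = records.drop(index=[bait_id]) if bait_id in records.index else records
        called = calls_mod.call_interactors(
            rec, scores, criteria, construct=state.get("construct", "WT")
        )
        state["calls"] = called
        path = out_dir / "interaction_calls.tsv"
        called.to_csv(path, sep="\t", index_label="protein_id")
        _record(manifest, "interaction_calls", path)

    elif stage == "classify":
        matrix = _require(state, "matrix", stage, "no spectral-count matrix loaded")
        called = _require(state, "calls", stage, "run call first")
        bait_id = state["bait_id"]
        deletions = [
            c for c in matrix.constructs if c.startswith("d")
        ] or config.get("deletions", [])
        factors = enr.bait_correction(matrix, bait_id, state.get("construct", "WT"))
        corrected = enr.apply_correction(matrix, factors, bait_id)
        wt_called = list(called.index[called["called"]])
        records = calls_mod.classify_domain_dependence(
            wt_called, corrected, deletions, wt_construct=state.get("construct", "WT")
        )
        table = calls_mod.dependence_table(records)
        state["dependence"] = table
        path = out_dir / "domain_dependence.tsv"
        table.to_csv(path, sep="\t", index_label="protein_id")
        _record(manifest, "domain_dependence", path)

    elif stage == "export":
        called = _require(state, "calls", stage, "run call first")
        for name, path in calls_mod.export_network(
            called, out_dir, bait_label=config.get("bait_label", "BAIT")
        ).items():
            _record(manifest, f"network_{name}", path)

    elif stage == "simulate-rnaseq":
        rcfg = config.get("rnaseq", {})
        truth = syn.default_rnaseq_truth(
            n_genes=int(rcfg.get("n_genes", 2000)),
            n_tag_genes=int(rcfg.get("n_tag_genes", 40)),
            n_bait_genes=int(rcfg.get("n_bait_genes", 23)),
            transgene_multiplier=float(rcfg.get("transgene_multiplier", 30.0)),
            seed=seed,
        )
        groups = syn.default_groups(int(rcfg.get("replicates", 3)))
        gene_table, exon_table, truth_table = syn.simulate_rnaseq(truth, groups)
        state.update(
            gene_table=gene_table, exon_table=exon_table,
            rnaseq_truth=truth, rnaseq_truth_table=truth_table,
        )
        gp = out_dir / "gene_counts.tsv"
        gene_table.counts.to_csv(gp, sep="\t", index_label="gene_id")
        _record(manifest, "gene_counts", gp)
        tp = out_dir / "rnaseq_truth.tsv"
        truth_table.to_csv(tp, sep="\t", index_label="gene_id")
        _record(manifest, "rnaseq_truth", tp)

    elif stage == "de-filter":
        gene_table = _require(state, "gene_table", stage, "run simulate-rnaseq first")
        de_bait = rna.nb_de_test(gene_table, "WT", "YFP")
        de_tag = rna.nb_de_test(gene_table, "YFP", "untransfected")
        cfg = rna.FilterConfig(**config.get("filter", {}))
        specific = rna.matr3_specific_filter(
            de_bait, de_tag, gene_table.condition_mean_rpkm(), cfg
        )
        state.update(de_bait=de_bait, de_tag=de_tag, specific=specific)
        for name, df in (("de_bait_vs_tag", de_bait), ("de_tag_vs_untransfected", de_tag)):
            path = out_dir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index_label="gene_id")
            _record(manifest, name, path)
        path = out_dir / "bait_specific_genes.tsv"
        pd.Series(specific, name="gene_id").to_csv(path, sep="\t", index=False)
        _record(manifest, "bait_specific_genes", path)

    elif stage == "endogenous":
        exon_table = _require(state, "exon_table", stage, "run simulate-rnaseq first")
        truth = state["rnaseq_truth"]
        if truth.transgene is None:
            raise ValueError("no transgene defined in the simulation")
        gi, shared, _ = truth.transgene
        gene_id = f"G{gi:05d}"
        shared_ids = [f"{gene_id}_E{e}" for e in shared]
        est = rna.endogenous_expression(exon_table, gene_id, shared_ids)
        state["endogenous"] = est
        path = out_dir / "endogenous_rpkm.tsv"
        est.rename("endogenous_rpkm").to_csv(path, sep="\t", index_label="sample")
        _record(manifest, "endogenous_rpkm", path)

    elif stage == "concordance":
        gene_table = _require(state, "gene_table", stage, "run simulate-rnaseq first")
        corr, order, _ = rna.pairwise_pearson(rna.rpkm(gene_table))
        state.update(concordance=corr, leaf_order=order)
        path = out_dir / "pearson_concordance.tsv"
        corr.to_csv(path, sep="\t", index_label="sample")
        _record(manifest, "pearson_concordance", path)
        manifest["leaf_order"] = order

    elif stage == "phenotype":
        path_in = config.get("phenotype_table")
        if not path_in:
            raise ValueError("config key 'phenotype_table' (TSV path) is required")
        report = validate_rows(load_phenotype_table(path_in))
        path = out_dir / "phenotype_report.tsv"
        report.to_csv(path, sep="\t")
        _record(manifest, "phenotype_report", path)

    else:
        raise PipelineError(stage, f"unknown stage '{stage}'")


def _require(state: dict, key: str, stage: str, hint: str):
    if key not in state:
        raise PipelineError(stage, f"missing upstream result '{key}': {hint}")
    return state[key]


def _ensure_matrix(state: dict, config: dict, stage: str):
    """Use the in-memory matrix or load the one named under config['inputs']."""
    if "matrix" in state:
        return state["matrix"]
    inputs = config.get("inputs", {})
    if "counts" in inputs and "run_meta" in inputs:
        matrix = enr.read_matrix(inputs["counts"], inputs["run_meta"])
        state["matrix"] = matrix
        state["bait_index"] = int(config.get("apms", {}).get("bait_protein_id", 0))
        return matrix
    raise PipelineError(
        stage,
        "no spectral-count matrix available: run simulate-apms first or set "
        "inputs.counts and inputs.run_meta in the config",
    )
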