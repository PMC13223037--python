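"""End-to-end synthetic pipeline runner.

Executes simulate -> differential expression / modules -> enrichment ->
signature scoring / stratification -> delta-AUC -> multimodal modelling ->
network, writing each stage's tables into the output directory plus a
manifest recording the configuration, seeds and SHA-256 hashes of every
artifact.  Deterministic stages therefore produce byte-identical manifests
on rerun.

Each stage is also runnable standalone through the library (or the CLI)
with identical results given identical inputs; ``run_pipeline`` simply
chains them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, drugresponse, enrichment, multimodal, network, synthetic
from .config import PipelineConfig
from .preprocess import write_groups_tsv, zscore_genes
from .signature import median_split, score_signature, tertile_stratify

logger = logging.getLogger("rair_axis")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _package_version() -> str:
    try:
        return _pkg_version("rair-axis")
    except PackageNotFoundError:
        return "unknown"


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full synthetic pipeline; returns in-memory stage artifacts.

    Writes stage tables under ``out_dir`` and a ``manifest.json`` with
    versions, seeds and input hashes.  A failing stage raises with the stage
    named in the log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    art: dict = {"config": config}
    cfg = config

    try:
        _stage_simulate(cfg, out, art)
        _stage_de(cfg, out, art)
        _stage_enrich(cfg, out, art)
        _stage_score(cfg, out, art)
        _stage_deltaauc(cfg, out, art)
        _stage_model(cfg, out, art)
        _stage_network(cfg, out, art)
    except Exception:
        logger.exception("pipeline failed in stage %r", art.get("_stage"))
        raise

    manifest = {
        "package_version": _package_version(),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "files": {p.name: _sha256(p) for p in sorted(out.iterdir())
                  if p.is_file() and p.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    art["manifest"] = manifest
    return art


# ----------------------------------------------------------------- stages

def _stage_simulate(cfg: PipelineConfig, out: Path, art: dict) -> None:
    art["_stage"] = "simulate"
    c = cfg.cohort
    planted_up = frozenset(range(c.n_planted_up))
    planted_down = frozenset(range(c.n_planted_up, c.n_planted_up + c.n_planted_down))
    spec = synthetic.CohortSpec(
        n_genes=c.n_genes, n_per_group=tuple(c.n_per_group),
        planted_up=planted_up, planted_down=planted_down,
        effect_size=c.effect_size, noise_sd=c.noise_sd,
        seed=synthetic.child_seed(cfg.seed, "cohort"),
        group_labels=("avid", "refractory"))
    cohort, truth = synthetic.generate_cohort(spec)
    art["cohort_spec"], art["cohort"], art["cohort_truth"] = spec, cohort, truth

    rep = cfg.replicates
    base = synthetic.CohortSpec(
        n_genes=c.n_genes, n_per_group=tuple(c.n_per_group),
        effect_size=c.effect_size, noise_sd=c.noise_sd,
        seed=synthetic.child_seed(cfg.seed, "atc_cohorts"),
        group_labels=("control", "atc"))
    art["replicates"] = synthetic.replicate_cohorts(
        base, rep.n_cohorts, core_up=planted_up, n_private=rep.n_private)

    p = cfg.panel
    if p.engagement != "linspace":
        raise ValueError(f"unknown engagement scheme {p.engagement!r}")
    engagement = np.linspace(0.0, 1.0, p.n_cells)
    panel_spec = synthetic.CohortSpec(
        n_genes=c.n_genes, n_per_group=(1, max(1, p.n_cells - 1)),
        planted_up=planted_up, effect_size=c.effect_size, noise_sd=p.noise_sd,
        seed=synthetic.child_seed(cfg.seed, "panel"))
    panel = synthetic.generate_cell_panel(panel_spec, engagement)
    art["engagement"], art["panel"] = engagement, panel

    s = cfg.screen
    screen_spec = synthetic.default_screen_spec(
        seed=cfg.seed, n_cells=p.n_cells, n_drugs=s.n_drugs,
        interaction_effect=s.interaction_effect, noise_sd=s.noise_sd,
        cell_effect_sd=s.cell_effect_sd, class_sizes=s.class_sizes)
    response, screen_truth = synthetic.generate_screen(screen_spec, engagement)
    art["screen_spec"], art["response"], art["screen_truth"] = \
        screen_spec, response, screen_truth

    cohort.to_tsv(out / "cohort_expression.tsv")
    write_groups_tsv(cohort.sample_groups, out / "cohort_groups.tsv")
    panel.to_tsv(out / "panel_expression.tsv")
    drugresponse.write_response_csv(response, out / "responses.csv")
    truth.to_csv(out / "cohort_truth.csv")
    screen_truth.to_csv(out / "screen_truth.csv")
    synthetic.annotation_table(screen_spec).to_csv(out / "annotations.csv", index=False)


def _stage_de(cfg: PipelineConfig, out: Path, art: dict) -> None:
    art["_stage"] = "de"
    th = cfg.thresholds
    de = diffexpr.moderated_t(art["cohort"])
    up, down = diffexpr.call_de(de, th.p, th.lfc)
    art["de"] = de
    art["module_up"] = diffexpr.GeneModule(
        name="RAIR_up", direction="up", genes=up,
        provenance={g: ["discovery"] for g in up})
    per_cohort_up = {}
    for i, (m, _) in enumerate(art["replicates"]):
        rep_de = diffexpr.moderated_t(m)
        rep_up, _ = diffexpr.call_de(rep_de, th.p, th.lfc)
        per_cohort_up[f"atc_{i + 1}"] = rep_up
    art["atc_module_up"] = diffexpr.union_modules(
        per_cohort_up, name="ATC_up", direction="up",
        min_support=cfg.replicates.min_support)
    diffexpr.write_de_tsv(de, out / "de_results.tsv")
    modules = enrichment.GeneSetCollection(
        sets={"RAIR_up": art["module_up"].genes,
              "ATC_up": art["atc_module_up"].genes}, source="pipeline")
    enrichment.write_gmt(modules, out / "modules.gmt")


def _stage_enrich(cfg: PipelineConfig, out: Path, art: dict) -> None:
    art["_stage"] = "enrich"
    th = cfg.thresholds
    planted_genes = sorted(art["module_up"].genes)
    collection = enrichment.GeneSetCollection(
        sets=synthetic.make_collection(
            art["cohort"].gene_ids, planted_genes,
            seed=synthetic.child_seed(cfg.seed, "collection")),
        source="synthetic hallmark-like")
    art["collection"] = collection
    ranked = art["de"].table["t_mod"]
    art["enrichment"] = enrichment.enrich_collection(
        ranked, collection, n_perm=th.n_perm,
        seed=synthetic.child_seed(cfg.seed, "collection"))
    art["enrichment"].to_csv(out / "enrichment.tsv", sep="\t")
    enrichment.write_gmt(collection, out / "collection.gmt")


def _stage_score(cfg: PipelineConfig, out: Path, art: dict) -> None:
    art["_stage"] = "score"
    cohort_z = zscore_genes(art["cohort"])
    panel_z = zscore_genes(art["panel"])
    art["cohort_scores"] = score_signature(cohort_z, art["module_up"])
    art["panel_scores"] = score_signature(panel_z, art["module_up"])
    art["cohort_strata"] = (tertile_stratify(art["cohort_scores"])
                            if cfg.stratify == "tertile"
                            else median_split(art["cohort_scores"]))
    art["panel_strata"] = median_split(art["panel_scores"])

    paths_cohort = enrichment.meanz_pathway_scores(cohort_z, art["collection"])
    paths_panel = enrichment.meanz_pathway_scores(panel_z, art["collection"])
    art["correlations"] = enrichment.correlate_signature(
        art["cohort_scores"].scores, paths_cohort,
        art["panel_scores"].scores, paths_panel)

    art["cohort_scores"].scores.rename("score").to_csv(
        out / "cohort_scores.tsv", sep="\t", index_label="sample_id")
    art["panel_scores"].scores.rename("score").to_csv(
        out / "panel_scores.tsv", sep="\t", index_label="cell_id")
    art["cohort_strata"].assignments.to_csv(
        out / "cohort_strata.tsv", sep="\t", index_label="sample_id")
    art["panel_strata"].assignments.to_csv(
        out / "panel_strata.tsv", sep="\t", index_label="cell_id")
    art["correlations"].to_csv(out / "correlations.tsv", sep="\t")


def _stage_deltaauc(cfg: PipelineConfig, out: Path, art: dict) -> None:
    art["_stage"] = "deltaauc"
    annotated = drugresponse.annotate_targeted(
        synthetic.annotation_table(art["screen_spec"]))
    classes = annotated.set_index("drug_id")["drug_class"]
    art["drug_classes"] = classes
    art["delta_auc"] = drugresponse.delta_auc(art["response"], art["panel_strata"])
    art["class_summary"] = drugresponse.class_summary(art["delta_auc"], classes)
    art["delta_auc"].to_csv(out / "delta_auc.tsv", sep="\t")
    art["class_summary"].to_csv(out / "class_summary.tsv", sep="\t")


def _stage_model(cfg: PipelineConfig, out: Path, art: dict) -> None:
    art["_stage"] = "model"
    th = cfg.thresholds
    results: dict[str, multimodal.CVResult] = {}
    for config_name in multimodal.MODEL_CONFIGS:
        feats = multimodal.build_features(
            art["panel"], art["response"], config_name,
            module=art["module_up"], n_components=th.n_components)
        results[config_name] = multimodal.cross_validate(
            feats, k=th.cv_folds, lam=th.ridge_lambda, seed=th.fold_seed)
    drug_sig = multimodal.build_features(
        art["panel"], art["response"], "drug_only", module=art["module_up"],
        n_components=th.n_components, include_signature=True)
    results["drug_only+signature"] = multimodal.cross_validate(
        drug_sig, k=th.cv_folds, lam=th.ridge_lambda, seed=th.fold_seed)
    art["cv_results"] = results
    art["model_metrics"] = multimodal.compare_models(results)
    art["delta_r2_signature"] = multimodal.delta_r2(
        results["drug_only"], results["drug_only+signature"])
    art["model_metrics"].to_csv(out / "model_metrics.tsv", sep="\t")
    mm = results["multimodal"]
    pd.DataFrame({"cell_id": art["response"]["cell_id"],
                  "drug_id": art["response"]["drug_id"],
                  "auc": mm.y_hat_cv}).to_csv(out / "predicted_auc.csv", index=False)


def _stage_network(cfg: PipelineConfig, out: Path, art: dict) -> None:
    art["_stage"] = "network"
    th = cfg.thresholds
    targeted = art["class_summary"].index != drugresponse.UNSPECIFIED_CLASS
    predicted = pd.read_csv(out / "predicted_auc.csv")
    art["network"] = network.build_network(
        art["enrichment"], art["class_summary"][targeted],
        art["panel_strata"], art["response"], art["drug_classes"],
        module_name=art["module_up"].name,
        q_thresh=th.network_q, delta_thresh=th.network_delta,
        predicted=predicted)
    network.export_network(art["network"], out)
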