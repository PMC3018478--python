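"""End-to-end orchestration: simulate/load -> preprocess -> DM -> DE ->
integration -> survival screen, with a machine-readable run manifest.

The run configuration is a mapping (usually loaded from YAML) with keys:

``inputs``  paths to beta/expr/annotation/clinical TSVs, or
``simulate``  generator parameters for a synthetic cohort;
``params``  PipelineConfig overrides; ``seed``; ``stages`` (subset of
{preprocess, dm, de, integrate, survival}); ``mgmt_probe`` (optional probe
id used to derive MGMT status from the beta matrix).

Stage-local random streams are derived from the global seed at fixed
offsets so skipping a stage never shifts another stage's draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .data_io import (BetaMatrix, ClinicalTable, CorrPair, DERecord, DMRecord,
                      ExpressionMatrix, ProbeAnnotation, SurvivalMarker,
                      read_annotation, read_beta_matrix,
                      read_clinical_table, read_expression_matrix,
                      write_matrix, write_results_table)
from .diffexpr import call_de_genes, collapse_probes, rank_product
from .diffmeth import annotation_enrichment, call_dm_sites, \
    hierarchical_cluster
from .integrate import call_inverse_pairs, classify_concordance, pair_probes
from .preprocess import (bin_expression_profile, impute_knn,
                         normalize_expression, select_extreme_probes)
from .simulate import GeneratorConfig, generate_dataset
from .survival import select_survival_markers

logger = logging.getLogger(__name__)

ALL_STAGES = ("preprocess", "dm", "de", "integrate", "survival")
SEED_OFFSET_SIMULATE = 0
SEED_OFFSET_DE = 1000


def run_full_pipeline(config: Mapping[str, Any],
                      out_dir: str | Path) -> dict[str, Any]:
    """Execute the configured stages and write tables plus manifest.

    Returns the manifest dictionary. A stage failure aborts the run after
    writing a manifest recording the stages completed so far.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 17))
    params = dict(config.get("params", {}))
    params.setdefault("seed", seed)
    cfg = PipelineConfig.from_mapping(params)
    stages = tuple(config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "config": {"params": cfg.to_dict(), "stages": list(stages)},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def finalize() -> dict[str, Any]:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest

    try:
        beta, expr, ann, clinical = _load_inputs(config, seed, out, manifest)

        imputed = beta
        selected: set[str] | None = None
        if "preprocess" in stages:
            imputed, selected = _stage_preprocess(beta, expr, ann, cfg, out,
                                                  manifest)
        dm_records: list[DMRecord] = []
        if "dm" in stages:
            dm_records = _stage_dm(imputed, clinical, ann, cfg, out, manifest)
        de_records: list[DERecord] = []
        if "de" in stages:
            de_records = _stage_de(expr, clinical, ann, cfg, seed, out,
                                   manifest)
        inverse: list[CorrPair] = []
        if "integrate" in stages:
            inverse = _stage_integrate(imputed, expr, ann, clinical, cfg,
                                       dm_records, de_records, selected,
                                       out, manifest)
        if "survival" in stages:
            _stage_survival(imputed, clinical, ann, cfg,
                            config.get("mgmt_probe"), out, manifest)
    except Exception:
        manifest["failed"] = True
        finalize()
        raise
    return finalize()


def _load_inputs(config: Mapping[str, Any], seed: int, out: Path,
                 manifest: dict) -> tuple[BetaMatrix, ExpressionMatrix,
                                          ProbeAnnotation, ClinicalTable]:
    if "simulate" in config:
        gen_cfg = GeneratorConfig.from_mapping(config["simulate"] or {})
        ds = generate_dataset(gen_cfg, seed=seed + SEED_OFFSET_SIMULATE)
        manifest["stages"]["simulate"] = {
            "n_probes": gen_cfg.n_probes, "n_genes": gen_cfg.n_genes,
            "n_samples_beta": len(ds.beta.sample_ids),
            "n_samples_expr": len(ds.expr.sample_ids),
        }
        return ds.beta, ds.expr, ds.ann, ds.clinical
    inputs = config.get("inputs")
    if not inputs:
        raise ValueError("config needs either 'inputs' or 'simulate'")
    beta = read_beta_matrix(inputs["beta"], inputs.get("dialect", "tsv"))
    expr = read_expression_matrix(inputs["expr"])
    ann = read_annotation(inputs["annotation"])
    clinical = read_clinical_table(inputs["clinical"])
    manifest["stages"]["load"] = {
        "n_probes": len(beta.probe_ids),
        "n_samples_beta": len(beta.sample_ids),
        "n_samples_expr": len(expr.sample_ids),
    }
    return beta, expr, ann, clinical


def _stage_preprocess(beta, expr, ann, cfg, out, manifest):
    n_missing = beta.n_missing
    imputed = impute_knn(beta, k=cfg.knn_k)
    write_matrix(imputed, out / "beta_imputed.tsv")
    selected = select_extreme_probes(imputed, cfg.beta_low, cfg.beta_high,
                                     cfg.min_extreme_samples)
    pd.Series(sorted(selected), name="probe_id").to_csv(
        out / "selected_probes.tsv", sep="\t", index=False)
    expr_samples = [s for s in imputed.sample_ids
                    if s in set(expr.sample_ids)]
    profile = bin_expression_profile(
        BetaMatrix(imputed.values[expr_samples]), expr, ann, cfg.bin_width)
    pd.DataFrame({
        "bin_low": profile.bin_edges[:-1],
        "bin_high": profile.bin_edges[1:],
        "mean_max_expr": profile.mean_max_expr,
        "sem": profile.sem,
        "n": profile.n_observations,
    }).to_csv(out / "bin_profile.tsv", sep="\t", index=False,
              float_format="%.6g", na_rep="NA")
    manifest["stages"]["preprocess"] = {
        "imputed_missing_cells": n_missing,
        "selected_probes": len(selected),
        "bin_observations": int(profile.n_observations.sum()),
    }
    return imputed, selected


def _stage_dm(imputed, clinical, ann, cfg, out, manifest):
    records = call_dm_sites(imputed, clinical, cfg, ann=ann)
    write_results_table(records, out / "dm_sites.tsv", DMRecord)
    background = set(ann.meth_genes())
    hyper_genes = {r.entrez_id for r in records
                   if r.direction == "hyper" and r.entrez_id}
    hypo_genes = {r.entrez_id for r in records
                  if r.direction == "hypo" and r.entrez_id}
    enrich_rows = []
    for name, gene_set in (("hyper", hyper_genes), ("hypo", hypo_genes)):
        for flag in ("cgi", "prc2"):
            if not gene_set:
                continue
            res = annotation_enrichment(gene_set, background, flag, ann)
            enrich_rows.append({
                "gene_set": name, "flag": flag,
                "set_size": res.set_size, "set_flagged": res.set_flagged,
                "proportion_set": res.proportion_set,
                "proportion_background": res.proportion_background,
                "odds_ratio": res.odds_ratio, "p_value": res.p_value,
            })
    pd.DataFrame(enrich_rows).to_csv(out / "dm_enrichment.tsv", sep="\t",
                                     index=False, float_format="%.6g")
    # cluster samples on the called sites
    cluster_path = out / "dm_clusters.tsv"
    if len(records) >= 2:
        cols = [s for s in imputed.sample_ids]
        X = imputed.values.loc[[r.probe_id for r in records], cols]
        _, labels = hierarchical_cluster(X.T.to_numpy(), n_clusters=2)
        pd.DataFrame({"sample_id": cols, "cluster": labels}).to_csv(
            cluster_path, sep="\t", index=False)
    manifest["stages"]["dm"] = {
        "dm_calls": len(records),
        "hyper": sum(r.direction == "hyper" for r in records),
        "hypo": sum(r.direction == "hypo" for r in records),
        "enrichment_rows": len(enrich_rows),
    }
    return records


def _stage_de(expr, clinical, ann, cfg, seed, out, manifest):
    norm = normalize_expression(expr)
    collapsed, probe_map = collapse_probes(norm, ann)
    sample_groups = np.array([
        clinical.data.loc[s, "group"] == "tumor"
        if s in clinical.data.index else False
        for s in collapsed.sample_ids])
    rp = rank_product(collapsed, sample_groups,
                      n_permutations=cfg.n_permutations,
                      seed=seed + SEED_OFFSET_DE)
    records = call_de_genes(rp, collapsed, sample_groups, cfg,
                            probe_map=probe_map)
    write_results_table(records, out / "de_genes.tsv", DERecord)
    manifest["stages"]["de"] = {
        "genes_tested": len(rp.ids),
        "comparisons": rp.n_comparisons,
        "permutations": rp.n_permutations,
        "de_calls": len(records),
        "up": sum(r.direction == "up" for r in records),
        "down": sum(r.direction == "down" for r in records),
    }
    return records


def _stage_integrate(imputed, expr, ann, clinical, cfg, dm_records,
                     de_records, selected, out, manifest):
    norm = normalize_expression(expr)
    pairs = pair_probes(ann, selected_meth_probes=selected)
    tumor_samples = [s for s in imputed.sample_ids
                     if s in set(norm.sample_ids)
                     and s in clinical.data.index
                     and clinical.data.loc[s, "group"] == "tumor"]
    corr = call_inverse_pairs(imputed, norm, pairs, cfg,
                              samples=tumor_samples)
    write_results_table(corr, out / "corr_pairs.tsv", CorrPair)
    universe = set(ann.meth_genes()) & set(ann.expr_genes())
    table, labels = classify_concordance(dm_records, de_records, corr,
                                         universe)
    pd.Series(labels, name="class").rename_axis("entrez_id").to_csv(
        out / "concordance_classes.tsv", sep="\t")
    with open(out / "concordance_summary.json", "w") as fh:
        json.dump(dataclasses.asdict(table), fh, indent=2)
    manifest["stages"]["integrate"] = {
        "pairs": len(pairs),
        "corr_pairs": len(corr),
        "inverse_pairs": sum(c.inverse_flag for c in corr),
        "inverse_cpgs": len({c.meth_probe for c in corr if c.inverse_flag}),
        "inverse_genes": len({c.entrez_id for c in corr if c.inverse_flag}),
        "concordant_anticorrelated": table.concordant_anticorrelated,
    }
    return corr


def _stage_survival(imputed, clinical, ann, cfg, mgmt_probe, out, manifest):
    screen = select_survival_markers(imputed, clinical, cfg, ann=ann,
                                     mgmt_probe=mgmt_probe)
    write_results_table(screen.markers, out / "survival_markers.tsv",
                        SurvivalMarker)
    km_dir = out / "km_curves"
    km_dir.mkdir(exist_ok=True)
    for probe, curves in screen.km_curves.items():
        frames = []
        for grp, c in curves.items():
            frames.append(pd.DataFrame({
                "group": grp, "time": c.event_times,
                "survival": c.survival, "at_risk": c.at_risk}))
        pd.concat(frames).to_csv(km_dir / f"{probe}.tsv", sep="\t",
                                 index=False, float_format="%.6g")
    manifest["stages"]["survival"] = {
        "markers": len(screen.markers), **screen.stage_counts}
    return screen


def load_yaml_config(path: str | Path) -> dict[str, Any]:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}
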