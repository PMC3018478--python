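#!/usr/bin/env python
"""Pair methylation and expression probes by gene, flag inversely
correlated pairs in tumors, and cross-classify differential methylation
against differential expression.

Writes results/integrate/{corr_pairs.tsv, concordance_classes.tsv,
concordance_summary.json}.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from methgex.config import PipelineConfig
from methgex.data_io import (CorrPair, DERecord, DMRecord, read_annotation,
                             read_beta_matrix, read_clinical_table,
                             read_expression_matrix, read_results_table,
                             write_results_table)
from methgex.integrate import (call_inverse_pairs, classify_concordance,
                               pair_probes)
from methgex.preprocess import normalize_expression
from methgex.simulate import evaluate_recovery

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = BASE / "integrate"
    out.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig()
    beta = read_beta_matrix(BASE / "preprocess" / "beta_imputed.tsv")
    expr = normalize_expression(
        read_expression_matrix(BASE / "data" / "expr.tsv"))
    ann = read_annotation(BASE / "data" / "annotation.tsv")
    clinical = read_clinical_table(BASE / "data" / "clinical.tsv")
    dm = read_results_table(BASE / "diffmeth" / "dm_sites.tsv", DMRecord)
    de = read_results_table(BASE / "diffexpr" / "de_genes.tsv", DERecord)
    truth = json.loads((BASE / "data" / "truth.json").read_text())
    selected = set(pd.read_csv(BASE / "preprocess" / "selected_probes.tsv",
                               sep="\t")["probe_id"])

    pairs = pair_probes(ann, selected_meth_probes=selected)
    tumors = [s for s in beta.sample_ids
              if s in set(expr.sample_ids)
              and clinical.data.loc[s, "group"] == "tumor"]
    corr = call_inverse_pairs(beta, expr, pairs, cfg, samples=tumors)
    write_results_table(corr, out / "corr_pairs.tsv", CorrPair)

    inv_genes = {c.entrez_id for c in corr if c.inverse_flag}
    inv_cpgs = {c.meth_probe for c in corr if c.inverse_flag}
    print(f"{len(pairs)} probe pairs correlated over {len(tumors)} tumors: "
          f"{len(inv_cpgs)} CpG sites / {len(inv_genes)} genes inversely "
          f"correlated (r < {cfg.corr_r}, p < {cfg.corr_p})")
    score = evaluate_recovery(inv_genes, set(truth["regulated_genes"]))
    print(f"planted regulated-gene recovery: {score.sensitivity:.2f} "
          f"sensitivity, {score.precision:.2f} precision")

    universe = set(ann.meth_genes()) & set(ann.expr_genes())
    table, labels = classify_concordance(dm, de, corr, universe)
    pd.Series(labels, name="class").rename_axis("entrez_id").to_csv(
        out / "concordance_classes.tsv", sep="\t")
    (out / "concordance_summary.json").write_text(
        json.dumps(dataclasses.asdict(table), indent=2))
    print(f"concordance over {len(universe)} genes: "
          f"{table.concordant} concordant ({table.concordant_anticorrelated}"
          " of them also anti-correlated -- promoter methylation likely "
          "drives their expression), "
          f"{table.discordant} discordant; chi-square "
          f"{table.chi2:.1f} (p = {table.p_value:.2g})")


if __name__ == "__main__":
    main()
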