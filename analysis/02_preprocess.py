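#!/usr/bin/env python
"""Impute missing betas, profile expression against promoter methylation,
and select the CpG probes with a putative direct effect on expression.

Reads results/data/, writes the imputed matrix, the beta-binned maximal
expression profile and the selected-probe list under results/preprocess/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from methgex.config import PipelineConfig
from methgex.data_io import (BetaMatrix, read_annotation, read_beta_matrix,
                             read_expression_matrix, write_matrix)
from methgex.preprocess import (bin_expression_profile, impute_knn,
                                select_extreme_probes)

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = BASE / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig()
    beta = read_beta_matrix(BASE / "data" / "beta.tsv")
    expr = read_expression_matrix(BASE / "data" / "expr.tsv")
    ann = read_annotation(BASE / "data" / "annotation.tsv")

    n_missing = beta.n_missing
    imputed = impute_knn(beta, k=cfg.knn_k)
    write_matrix(imputed, out / "beta_imputed.tsv")
    print(f"imputed {n_missing} missing cells by {cfg.knn_k}-nearest-"
          "neighbour averaging")

    expr_samples = [s for s in imputed.sample_ids
                    if s in set(expr.sample_ids)]
    profile = bin_expression_profile(
        BetaMatrix(imputed.values[expr_samples]), expr, ann, cfg.bin_width)
    pd.DataFrame({"bin_low": profile.bin_edges[:-1],
                  "bin_high": profile.bin_edges[1:],
                  "mean_max_expr": profile.mean_max_expr,
                  "sem": profile.sem,
                  "n": profile.n_observations}).to_csv(
        out / "bin_profile.tsv", sep="\t", index=False,
        float_format="%.6g", na_rep="NA")
    low = np.nanmean(profile.mean_max_expr[:3])
    mid = np.nanmean(profile.mean_max_expr[8:12])
    high = np.nanmean(profile.mean_max_expr[-3:])
    print("expression by beta bin: "
          f"low-beta {low:.2f}, mid {mid:.2f}, high-beta {high:.2f} "
          "(silencing visible at the methylated extreme)")

    selected = select_extreme_probes(imputed, cfg.beta_low, cfg.beta_high,
                                     cfg.min_extreme_samples)
    pd.Series(sorted(selected), name="probe_id").to_csv(
        out / "selected_probes.tsv", sep="\t", index=False)
    print(f"{len(selected)} of {len(imputed.probe_ids)} CpG probes have "
          f"beta < {cfg.beta_low} or > {cfg.beta_high} in at least "
          f"{cfg.min_extreme_samples} samples")


if __name__ == "__main__":
    main()
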