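"""Rank-product differential expression with permutation FDR.

The rank product compares every tumor sample against every control sample,
ranks genes by log fold-change within each pairwise comparison, and scores
each gene by the geometric mean of its ranks. Because only ranks enter the
statistic it is robust to per-hybridisation intensity distortions. The
attached pfp (proportion of false positives) is a permutation estimate of
the FDR at each gene's rank-product value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .data_io import DERecord, ExpressionMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)


@dataclass
class RankProductResult:
    """Per-gene rank products and permutation FDR estimates."""

    ids: list[str]
    rp_up: np.ndarray
    rp_down: np.ndarray
    pfp_up: np.ndarray
    pfp_down: np.ndarray
    n_comparisons: int
    n_permutations: int


def collapse_probes(expr: ExpressionMatrix,
                    ann: ProbeAnnotation) -> tuple[ExpressionMatrix, dict]:
    """One expression probe per gene: the probe with highest mean expression.

    Returns the collapsed matrix (rows indexed by entrez id) and the
    gene -> chosen probe map.
    """
    genes = ann.expr_genes()
    sub = expr.values.loc[expr.values.index.intersection(genes.index)]
    if sub.empty:
        raise ValueError("no annotated expression probes present")
    means = sub.mean(axis=1)
    chosen: dict[str, str] = {}
    for probe in means.sort_values(ascending=False).index:
        gene = genes[probe]
        chosen.setdefault(gene, probe)
    picked = list(chosen.values())
    collapsed = sub.loc[picked]
    collapsed.index = [genes[p] for p in picked]
    return ExpressionMatrix(collapsed.sort_index()), chosen


def _geometric_mean_ranks(ranks: np.ndarray) -> np.ndarray:
    return np.exp(np.mean(np.log(ranks), axis=1))


def rank_product(expr: ExpressionMatrix, groups,
                 n_permutations: int = 1000, seed: int = 17,
                 max_comparisons: int | None = None) -> RankProductResult:
    """Rank products and permutation pfp for tumor-vs-control regulation.

    Parameters
    ----------
    expr
        log2 expression, one row per gene.
    groups
        Boolean array over ``expr`` samples, True = tumor.
    n_permutations
        Null replicates: per permutation each comparison's rank list is an
        independent uniformly random permutation of 1..G.
    max_comparisons
        Optional cap on the number of tumor-control pairs (taken in a fixed
        deterministic order); all pairs are used by default.

    For gene g at ascending-RP position i, pfp = (mean count of null RP
    values <= RP_g per permutation) / i.
    """
    groups = np.asarray(groups, dtype=bool)
    values = expr.values.to_numpy(dtype=float)
    tumors = np.flatnonzero(groups)
    controls = np.flatnonzero(~groups)
    if tumors.size == 0 or controls.size == 0:
        raise ValueError("need at least one tumor and one control")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pairs = [(t, c) for t in tumors for c in controls]
    if max_comparisons is not None:
        pairs = pairs[:max_comparisons]
    K = len(pairs)
    G = values.shape[0]
    # log fold-change per gene per comparison, then within-comparison ranks
    L = np.stack([values[:, t] - values[:, c] for t, c in pairs], axis=1)
    ranks_up = stats.rankdata(-L, axis=0)   # 1 = most up-regulated
    ranks_down = stats.rankdata(L, axis=0)  # 1 = most down-regulated
    rp_up = _geometric_mean_ranks(ranks_up)
    rp_down = _geometric_mean_ranks(ranks_down)

    rng = np.random.default_rng(seed)
    base = np.tile(np.arange(1, G + 1, dtype=float), (K, 1))
    null_rps = np.empty(n_permutations * G)
    for b in range(n_permutations):
        perm_ranks = rng.permuted(base, axis=1).T  # G x K
        null_rps[b * G:(b + 1) * G] = _geometric_mean_ranks(perm_ranks)
    null_sorted = np.sort(null_rps)

    def pfp_for(rp: np.ndarray) -> np.ndarray:
        exceed = np.searchsorted(null_sorted, rp, side="right")
        position = stats.rankdata(rp, method="max")
        return (exceed / n_permutations) / position

    return RankProductResult(
        ids=list(expr.values.index), rp_up=rp_up, rp_down=rp_down,
        pfp_up=pfp_for(rp_up), pfp_down=pfp_for(rp_down),
        n_comparisons=K, n_permutations=n_permutations)


def call_de_genes(rp: RankProductResult, expr: ExpressionMatrix, groups,
                  cfg: PipelineConfig,
                  probe_map: dict[str, str] | None = None) -> list[DERecord]:
    """Emit up/down differential-expression records from rank-product output.

    The fold change is 2^(mean log2 tumor - mean log2 control); up calls
    require pfp_up < cfg.de_fdr and FC > cfg.de_fc, down calls pfp_down <
    cfg.de_fdr and FC < 1/cfg.de_fc.
    """
    groups = np.asarray(groups, dtype=bool)
    values = expr.values.to_numpy(dtype=float)
    log_fc = values[:, groups].mean(axis=1) - values[:, ~groups].mean(axis=1)
    fc = 2.0 ** log_fc
    records: list[DERecord] = []
    for i, gene in enumerate(rp.ids):
        up = rp.pfp_up[i] < cfg.de_fdr and fc[i] > cfg.de_fc
        down = rp.pfp_down[i] < cfg.de_fdr and fc[i] < 1.0 / cfg.de_fc
        if not (up or down):
            continue
        records.append(DERecord(
            entrez_id=gene,
            probe_id=(probe_map or {}).get(gene, ""),
            fold_change=float(fc[i]),
            rp_up=float(rp.rp_up[i]),
            rp_down=float(rp.rp_down[i]),
            pfp_up=float(rp.pfp_up[i]),
            pfp_down=float(rp.pfp_down[i]),
            direction="up" if up else "down",
        ))
    logger.info("call_de_genes: %d calls (%d up / %d down) from %d genes",
                len(records), sum(r.direction == "up" for r in records),
                sum(r.direction == "down" for r in records), len(rp.ids))
    return records
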