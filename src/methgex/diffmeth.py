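"""Differential methylation calling, enrichment tests and clustering.

Tumor-versus-control comparison of beta values per CpG site with Welch
t-tests, Benjamini-Hochberg adjustment over the variability-filtered probe
universe, an effect-size gate on the group mean difference, Fisher-exact
enrichment of CpG-island / PRC2-target annotation in the called gene sets,
and agglomerative clustering of samples on the called sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .data_io import BetaMatrix, ClinicalTable, DMRecord, ProbeAnnotation
from .preprocess import sd_filter

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # reporting floor for underflowed p-values


def welch_t_test(a, b):
    """Two-sided Welch (unequal-variance) t-test.

    Returns (t, df, p) with t = (mean(a) - mean(b)) / sqrt(sa^2/na + sb^2/nb)
    and Welch-Satterthwaite degrees of freedom. Two groups that are constant
    and equal give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=False)
    t, df, p = float(res.statistic), float(res.df), float(res.pvalue)
    if np.isnan(t):  # zero variance in both groups
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise FloatingPointError("degenerate zero-variance comparison")
    return t, df, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dm_sites(beta: BetaMatrix, clinical: ClinicalTable,
                  cfg: PipelineConfig,
                  ann: ProbeAnnotation | None = None,
                  probes: set[str] | None = None) -> list[DMRecord]:
    """Call differentially methylated CpG sites between tumor and control.

    Probes are pre-filtered on SD >= cfg.sd_dm (unless an explicit probe set
    is supplied); Welch tests run per surviving probe; BH adjustment is
    applied over exactly the tested set; emitted records satisfy adjusted
    p < cfg.dm_alpha and |delta beta| > cfg.dm_delta.
    """
    tumors = [s for s in clinical.tumor_samples() if s in beta.sample_ids]
    controls = [s for s in clinical.control_samples() if s in beta.sample_ids]
    if len(tumors) < 2 or len(controls) < 2:
        raise ValueError("need at least two tumors and two controls")
    if probes is None:
        sub = BetaMatrix(beta.values[tumors + controls])
        probes = sd_filter(sub, cfg.sd_dm, inclusive=True)
    tested = [p for p in beta.probe_ids if p in probes]
    if not tested:
        return []
    A = beta.values.loc[tested, tumors].to_numpy(dtype=float)
    B = beta.values.loc[tested, controls].to_numpy(dtype=float)
    if np.isnan(A).any() or np.isnan(B).any():
        raise ValueError("beta matrix must be imputed before DM calling")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(A, B, axis=1, equal_var=False)
    t = np.array(res.statistic, dtype=float)
    df = np.array(res.df, dtype=float)
    p = np.array(res.pvalue, dtype=float)
    degenerate = np.isnan(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    df[degenerate] = A.shape[1] + B.shape[1] - 2
    p_adj = bh_adjust(p)
    delta = A.mean(axis=1) - B.mean(axis=1)
    keep = (p_adj < cfg.dm_alpha) & (np.abs(delta) > cfg.dm_delta)
    gene_map = ann.meth["entrez_id"] if ann is not None else None
    records = []
    for i in np.flatnonzero(keep):
        pid = tested[i]
        records.append(DMRecord(
            probe_id=pid,
            entrez_id=(gene_map.get(pid, "") if gene_map is not None else ""),
            mean_beta_tumor=float(A[i].mean()),
            mean_beta_control=float(B[i].mean()),
            delta_beta=float(delta[i]),
            t_stat=float(t[i]),
            df=float(df[i]),
            p_value=float(max(p[i], P_FLOOR)),
            p_adjusted=float(max(p_adj[i], P_FLOOR)),
            direction="hyper" if delta[i] > 0 else "hypo",
        ))
    logger.info("call_dm_sites: %d tested, %d called (%d hyper / %d hypo)",
                len(tested), len(records),
                sum(r.direction == "hyper" for r in records),
                sum(r.direction == "hypo" for r in records))
    return records


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns the sample odds ratio ad/bc (inf when bc = 0 and ad > 0) and the
    exact two-sided p-value. Zero margins are rejected.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("fisher_exact requires positive margins")
    res = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class EnrichmentResult:
    """Fisher-exact enrichment of an annotation flag in a gene set."""

    flag: str
    set_size: int
    set_flagged: int
    background_size: int
    background_flagged: int
    proportion_set: float
    proportion_background: float
    odds_ratio: float
    p_value: float


def annotation_enrichment(gene_set: set[str], background_genes: set[str],
                          flag: str, ann: ProbeAnnotation) -> EnrichmentResult:
    """Test whether a gene set is enriched in CGI- or PRC2-flagged genes.

    A gene is flagged when any of its methylation probes carries the flag.
    The 2x2 table contrasts set membership against flag status over the
    background (typically all genes on the array).
    """
    if flag not in ("cgi", "prc2"):
        raise ValueError("flag must be 'cgi' or 'prc2'")
    if not gene_set:
        raise ValueError("empty gene set")
    if not gene_set <= background_genes:
        raise ValueError("gene_set must be a subset of background_genes")
    col = f"{flag}_flag"
    genes = ann.meth_genes()
    flagged = set(genes[ann.meth.loc[genes.index, col]])
    set_flagged = len(gene_set & flagged)
    rest = background_genes - gene_set
    rest_flagged = len(rest & flagged)
    table = np.array([[set_flagged, len(gene_set) - set_flagged],
                      [rest_flagged, len(rest) - rest_flagged]])
    if not rest:
        logger.warning("annotation_enrichment: gene set equals background; "
                       "no contrast")
        odds, p = float("nan"), 1.0
    else:
        odds, p = fisher_exact(table)
    return EnrichmentResult(
        flag=flag, set_size=len(gene_set), set_flagged=set_flagged,
        background_size=len(background_genes),
        background_flagged=set_flagged + rest_flagged,
        proportion_set=set_flagged / len(gene_set),
        proportion_background=(set_flagged + rest_flagged)
        / len(background_genes),
        odds_ratio=odds, p_value=p)


def hierarchical_cluster(matrix, distance: str = "one_minus_pearson",
                         linkage: str = "average",
                         n_clusters: int | None = None):
    """Agglomerative clustering of rows of ``matrix``.

    ``distance`` is ``one_minus_pearson`` (1 - Pearson correlation between
    rows) or ``euclidean``; linkage is average, complete or ward. Returns
    (merge tree in scipy linkage form, labels) -- labels are 1..k for a
    requested cut, or all ones otherwise.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n_clusters is not None and n_clusters > n:
        raise ValueError("fewer items than requested clusters")
    if n == 1:
        return np.empty((0, 4)), np.ones(1, dtype=int)
    if distance == "one_minus_pearson":
        d = pdist(X, metric="correlation")
    elif distance == "euclidean":
        d = pdist(X, metric="euclidean")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in ("average", "complete", "ward"):
        raise ValueError(f"unknown linkage {linkage!r}")
    Z = hierarchy.linkage(d, method=linkage)
    if n_clusters is None:
        labels = np.ones(n, dtype=int)
    else:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, labels
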