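"""Beta computation, imputation, normalization and probe-selection filters.

These operations prepare an Infinium-style beta matrix and a log2 expression
matrix for the downstream differential and survival analyses: computing beta
from intensity pairs, k-nearest-neighbour imputation of missing betas,
quantile normalization with median-baseline transformation, the beta-binned
maximal-expression profile, and the variability/extremeness probe filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import BetaMatrix, ExpressionMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)

BETA_OFFSET = 100.0  # stabilising constant in the beta denominator


def compute_beta(M, U):
    """Methylation fraction from methylated/unmethylated signal intensities.

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + 100). Background-corrected
    signals may be negative on input; they are floored at zero inside the
    formula, so the result always lies in [0, 1).
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(U))):
        raise ValueError("intensities must be finite")
    m = np.maximum(M, 0.0)
    u = np.maximum(U, 0.0)
    beta = m / (m + u + BETA_OFFSET)
    return beta if beta.ndim else float(beta)


def impute_knn(matrix: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Fill missing betas by nearest-neighbour averaging over probes.

    For each missing cell (probe i, sample j) the k probes nearest to i --
    Euclidean distance over jointly observed samples -- that have sample j
    observed contribute the mean of their values at j. Observed cells are
    never altered; a probe with no observed value at all falls back to
    column means (with a warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = matrix.values.to_numpy(dtype=float).copy()
    mask = np.isnan(X)
    if not mask.any():
        return matrix
    obs = ~mask
    col_means = np.nanmean(X, axis=0)
    filled = X.copy()
    for i in np.flatnonzero(mask.any(axis=1)):
        if not obs[i].any():
            filled[i, :] = col_means
            logger.warning("probe %s has no observed values; filled with "
                           "column means", matrix.values.index[i])
            continue
        # squared Euclidean distance to every other probe on shared samples
        diff = X - X[i]
        diff[~(obs & obs[i])] = 0.0
        shared = (obs & obs[i]).sum(axis=1)
        d2 = np.einsum("ij,ij->i", diff, diff)
        d2[shared == 0] = np.inf
        d2[i] = np.inf
        for j in np.flatnonzero(mask[i]):
            donors = np.flatnonzero(obs[:, j] & np.isfinite(d2))
            if donors.size == 0:
                filled[i, j] = col_means[j]
                logger.warning("no donor probe for cell (%s, %s); used "
                               "column mean", matrix.values.index[i],
                               matrix.values.columns[j])
                continue
            if donors.size < k:
                logger.warning("only %d donor probes available (k=%d) for "
                               "probe %s", donors.size, k,
                               matrix.values.index[i])
            order = donors[np.argsort(d2[donors], kind="stable")[:k]]
            filled[i, j] = X[order, j].mean()
    out = pd.DataFrame(np.clip(filled, 0.0, 1.0),
                       index=matrix.values.index,
                       columns=matrix.values.columns)
    return BetaMatrix(out)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean of the sorted columns.

    Ties within a column receive the mean of the reference values at their
    would-be positions (average ranks, linearly interpolated).
    """
    arr = values.to_numpy(dtype=float)
    n = arr.shape[0]
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_expression(raw: ExpressionMatrix,
                         log2_transform: bool = False) -> ExpressionMatrix:
    """log2 transform (optional), quantile normalize, median-centre probes.

    The baseline transformation subtracts each probe's median across samples,
    so every probe has zero median afterwards.
    """
    values = raw.values
    if log2_transform:
        arr = values.to_numpy(dtype=float)
        bad = arr <= 0
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-positive intensity {arr[i, j]} at probe "
                f"{values.index[i]!r}, sample {values.columns[j]!r} "
                "cannot be log2-transformed")
        values = pd.DataFrame(np.log2(arr), index=values.index,
                              columns=values.columns)
    qn = quantile_normalize(values)
    centred = qn.sub(qn.median(axis=1), axis=0)
    return ExpressionMatrix(centred)


@dataclass
class BinProfile:
    """Mean maximal gene expression per beta-value bin.

    Twenty half-open bins of width 0.05 cover [0, 1] (the last bin is closed
    above so beta = 1 is counted). Each (gene-linked CpG probe, sample)
    observation contributes the maximum expression over the linked gene's
    expression probes in that sample.
    """

    bin_edges: np.ndarray          # length n_bins + 1
    mean_max_expr: np.ndarray      # log2 units, NaN where empty
    sem: np.ndarray                # SD/sqrt(n), NaN where n < 2
    n_observations: np.ndarray


def gene_max_expression(expr: ExpressionMatrix,
                        ann: ProbeAnnotation) -> pd.DataFrame:
    """Per-sample maximum expression over each gene's probes (genes x samples)."""
    genes = ann.expr_genes()
    sub = expr.values.loc[expr.values.index.intersection(genes.index)]
    if sub.empty:
        raise ValueError("no annotated expression probes present")
    grouped = sub.groupby(genes.reindex(sub.index))
    return grouped.max()


def bin_expression_profile(beta: BetaMatrix, expr: ExpressionMatrix,
                           ann: ProbeAnnotation,
                           bin_width: float = 0.05) -> BinProfile:
    """Profile expression as a function of promoter methylation level.

    CpG-by-sample observations are binned on beta (bins ``bin_width`` wide);
    each observation's value is the maximal expression of the CpG's gene in
    that sample; per-bin mean, SEM and count are returned.
    """
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    gene_max = gene_max_expression(expr, ann)
    shared = [s for s in beta.sample_ids if s in set(gene_max.columns)]
    if not shared:
        raise ValueError("no shared samples between beta and expression")
    meth_genes = ann.meth_genes()
    linked = [p for p in beta.probe_ids
              if meth_genes.get(p, "") in gene_max.index]
    if not linked:
        raise ValueError("no gene-linked CpG probes with expression data")
    b = beta.values.loc[linked, shared].to_numpy(dtype=float)
    e = gene_max.loc[meth_genes.loc[linked], shared].to_numpy(dtype=float)
    ok = ~np.isnan(b)
    idx = np.minimum((b[ok] / bin_width).astype(int), n_bins - 1)
    vals = e[ok]
    n = np.bincount(idx, minlength=n_bins)
    s = np.bincount(idx, weights=vals, minlength=n_bins)
    s2 = np.bincount(idx, weights=vals ** 2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        var = np.where(n > 1, (s2 - n * mean ** 2) / np.maximum(n - 1, 1),
                       np.nan)
        sem = np.sqrt(np.maximum(var, 0.0) / np.maximum(n, 1))
    sem[n < 2] = np.nan
    mean[n == 0] = np.nan
    return BinProfile(bin_edges=edges, mean_max_expr=mean, sem=sem,
                      n_observations=n)


def select_extreme_probes(matrix: BetaMatrix, low: float = 0.15,
                          high: float = 0.9,
                          min_samples: int = 3) -> set[str]:
    """CpG probes with a putative direct effect on expression.

    A probe is kept when its beta falls below ``low`` in at least
    ``min_samples`` samples or above ``high`` in at least ``min_samples``
    samples -- counted per tail, so consistently extreme states are required.
    """
    arr = matrix.values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        n_low = np.nansum(arr < low, axis=1)
        n_high = np.nansum(arr > high, axis=1)
    keep = (n_low >= min_samples) | (n_high >= min_samples)
    return set(matrix.values.index[keep])


def sd_filter(matrix: BetaMatrix, threshold: float,
              inclusive: bool) -> set[str]:
    """Probes whose per-probe sample SD (n-1 denominator) passes a threshold.

    The differential-methylation stage uses the inclusive form (SD >= t),
    the survival screen the strict form (SD > t).
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("sd_filter needs at least two samples")
    sd = matrix.values.std(axis=1, ddof=1, skipna=True)
    keep = sd >= threshold if inclusive else sd > threshold
    return set(matrix.values.index[keep.to_numpy()])
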