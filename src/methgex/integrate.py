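"""Methylation-expression pairing, inverse correlation, and concordance.

Methylation and expression probes are paired through shared Entrez gene
ids; Pearson correlation between promoter beta and expression over tumor
samples flags inversely regulated pairs (r < -0.5, p < 0.001 by default);
gene-level differential-methylation and differential-expression calls are
cross-classified into concordant/discordant classes with a chi-square test
of association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .data_io import (BetaMatrix, CorrPair, DERecord, DMRecord,
                      ExpressionMatrix, ProbeAnnotation)

logger = logging.getLogger(__name__)


def pair_probes(ann: ProbeAnnotation,
                selected_meth_probes: set[str] | None = None
                ) -> list[tuple[str, str, str]]:
    """All (meth probe, expr probe, entrez) combinations sharing a gene.

    Probes without a gene mapping, and genes present on only one platform,
    are excluded (counts logged).
    """
    meth_genes = ann.meth_genes()
    if selected_meth_probes is not None:
        meth_genes = meth_genes[meth_genes.index.isin(selected_meth_probes)]
    expr_genes = ann.expr_genes()
    expr_by_gene: dict[str, list[str]] = {}
    for probe, gene in expr_genes.items():
        expr_by_gene.setdefault(gene, []).append(probe)
    pairs = [(mp, ep, gene)
             for mp, gene in meth_genes.items()
             for ep in expr_by_gene.get(gene, [])]
    n_unpaired = int((~meth_genes.isin(expr_by_gene)).sum())
    if not pairs:
        logger.warning("pair_probes: no shared Entrez ids between platforms")
    else:
        logger.info("pair_probes: %d pairs; %d mapped meth probes without "
                    "expression counterpart", len(pairs), n_unpaired)
    return pairs


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided p from the t transform on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0 - 1e-12:  # exact collinearity up to rounding
        return float(np.sign(r)), 0.0
    return float(r), float(p)


def call_inverse_pairs(beta: BetaMatrix, expr: ExpressionMatrix,
                       pairs: list[tuple[str, str, str]],
                       cfg: PipelineConfig,
                       samples: list[str] | None = None) -> list[CorrPair]:
    """Correlate each pair over tumor samples and flag inverse regulation.

    ``samples`` restricts the computation (the study correlates on tumors
    only). Pairs with zero variance in either member are skipped with a log
    message.
    """
    if samples is None:
        samples = [s for s in beta.sample_ids if s in set(expr.sample_ids)]
    b = beta.values[samples]
    e = expr.values[samples]
    out: list[CorrPair] = []
    n_skipped = 0
    for mp, ep, gene in pairs:
        if mp not in b.index or ep not in e.index:
            continue
        x = b.loc[mp].to_numpy(dtype=float)
        y = e.loc[ep].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            n_skipped += 1
            continue
        r, p = pearson_corr(x[ok], y[ok])
        out.append(CorrPair(
            meth_probe=mp, expr_probe=ep, entrez_id=gene, r=r, p_value=p,
            n=int(ok.sum()),
            inverse_flag=bool(r < cfg.corr_r and p < cfg.corr_p)))
    if n_skipped:
        logger.info("call_inverse_pairs: skipped %d degenerate pairs",
                    n_skipped)
    flagged_cpgs = {c.meth_probe for c in out if c.inverse_flag}
    flagged_genes = {c.entrez_id for c in out if c.inverse_flag}
    logger.info("call_inverse_pairs: %d/%d pairs flagged "
                "(%d CpG sites, %d genes)",
                sum(c.inverse_flag for c in out), len(out),
                len(flagged_cpgs), len(flagged_genes))
    return out


@dataclass
class ConcordanceTable:
    """Gene-level cross-classification of DM and DE calls.

    concordant = (hyper and down) or (hypo and up); the headline class
    additionally requires an inverse-correlated promoter CpG. The chi-square
    (2x2, no continuity correction) tests association between DM and DE
    membership over the gene universe.
    """

    concordant: int
    discordant: int
    dm_only: int
    de_only: int
    neither: int
    mixed: int
    concordant_anticorrelated: int
    chi2: float
    p_value: float


def classify_concordance(dm: list[DMRecord], de: list[DERecord],
                         inverse: list[CorrPair],
                         gene_universe: set[str]
                         ) -> tuple[ConcordanceTable, dict[str, str]]:
    """Partition the gene universe by joint DM/DE status.

    Genes with conflicting DM directions across their CpGs are labelled
    "mixed" and excluded from the concordance counts. Returns the count
    table plus a per-gene class label map.
    """
    dm_dir: dict[str, set[str]] = {}
    for rec in dm:
        if rec.entrez_id and rec.entrez_id in gene_universe:
            dm_dir.setdefault(rec.entrez_id, set()).add(rec.direction)
    de_dir = {rec.entrez_id: rec.direction for rec in de
              if rec.entrez_id in gene_universe}
    inverse_genes = {c.entrez_id for c in inverse if c.inverse_flag}

    labels: dict[str, str] = {}
    counts = dict(concordant=0, discordant=0, dm_only=0, de_only=0,
                  neither=0, mixed=0, concordant_anticorrelated=0)
    n_mixed_logged = 0
    for gene in sorted(gene_universe):
        dirs = dm_dir.get(gene)
        ded = de_dir.get(gene)
        if dirs is not None and len(dirs) > 1:
            labels[gene] = "mixed"
            counts["mixed"] += 1
            n_mixed_logged += 1
            continue
        dmd = next(iter(dirs)) if dirs else None
        if dmd and ded:
            concordant = (dmd == "hyper" and ded == "down") or \
                         (dmd == "hypo" and ded == "up")
            if concordant and gene in inverse_genes:
                labels[gene] = "concordant, anti-correlated"
                counts["concordant"] += 1
                counts["concordant_anticorrelated"] += 1
            elif concordant:
                labels[gene] = "concordant"
                counts["concordant"] += 1
            else:
                labels[gene] = "discordant"
                counts["discordant"] += 1
        elif dmd:
            labels[gene] = "dm_only"
            counts["dm_only"] += 1
        elif ded:
            labels[gene] = "de_only"
            counts["de_only"] += 1
        else:
            labels[gene] = "neither"
            counts["neither"] += 1
    if n_mixed_logged:
        logger.info("classify_concordance: %d genes with conflicting DM "
                    "directions excluded as 'mixed'", n_mixed_logged)

    dm_member = counts["concordant"] + counts["discordant"] + counts["dm_only"]
    de_member = counts["concordant"] + counts["discordant"] + counts["de_only"]
    both = counts["concordant"] + counts["discordant"]
    table = np.array([
        [both, dm_member - both],
        [de_member - both,
         len(gene_universe) - counts["mixed"] - dm_member - (de_member - both)],
    ])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        chi2, p = float("nan"), float("nan")
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ConcordanceTable(chi2=float(chi2), p_value=float(p), **counts), labels


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)
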