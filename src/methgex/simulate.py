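"""Synthetic beadchip-like cohorts with known planted truth.

The generator emulates the statistical shape of a promoter-methylation
study of glioblastoma versus control brain: a non-symmetric bimodal beta
distribution that is globally hypomethylated (median beta around 0.1), a
large tumor group against a very small control group, planted hyper- and
hypomethylated CpG sites preferentially located inside/outside CpG islands,
PRC2-target enrichment among hypermethylated genes, genes whose log2
expression decreases linearly with promoter beta, and censored Weibull
survival times whose hazard shifts when a prognostic probe's beta exceeds a
cutoff (plus a protective MGMT-like marker).

Every draw comes from one seeded generator, so a fixed seed reproduces the
cohort bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Any, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .data_io import (BetaMatrix, ClinicalTable, ExpressionMatrix,
                      ProbeAnnotation)

logger = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    """Study-design parameters of the simulated cohort.

    Sample sizes mirror the emulated study: ``n_tumors`` tumors with
    expression data, ``n_controls`` control brains, and ``n_survival``
    uniformly treated patients with follow-up; the methylation cohort spans
    max(n_tumors, n_survival) tumors plus the controls.

    Beta-mixture parameters are calibration constants frozen against the
    global median (~0.1) and the bimodal shape; they are not tuned per run.
    """

    n_probes: int = 5000
    n_genes: int = 3000
    n_tumors: int = 40
    n_controls: int = 3
    n_survival: int = 50

    # bimodal baseline: w * Beta(1.5, 12) + (1 - w) * Beta(10, 2.5)
    low_mode: tuple[float, float] = (1.5, 12.0)
    high_mode: tuple[float, float] = (10.0, 2.5)
    low_mode_weight: float = 0.90
    tech_sd: float = 0.03          # per-cell replicate noise on beta
    bio_sd: float = 0.10           # tumor heterogeneity on planted DM shifts
    frac_variable: float = 0.08    # null probes with inter-individual spread
    bio_sd_null: float = 0.06      # half-normal scale of that spread
    missing_rate: float = 0.005

    # planted differential methylation
    n_dm_hyper: int = 150
    n_dm_hypo: int = 50
    dm_delta: float = 0.4
    cgi_prob_hyper: float = 0.97
    cgi_prob_hypo: float = 0.09
    cgi_prob_background: float = 0.73
    prc2_prob_hyper: float = 0.35
    prc2_prob_background: float = 0.095

    # expression
    expr_mean: float = 7.0
    expr_gene_sd: float = 1.0
    expr_noise_sd: float = 0.4
    n_regulated: int = 50
    regulation_slope: float = 4.0  # log2 units lost per unit beta
    n_linked: int = 15             # genes both hypermethylated and silenced
    n_de_up: int = 60
    n_de_down: int = 60
    de_log2fc: float = 1.322       # 2.5-fold

    # survival
    n_prognostic: int = 1
    prognostic_cutoff: float = 0.45
    prognostic_hr: float = 4.0  # the emulated study's markers are stronger
    mgmt_hr: float = 0.35
    mgmt_cutoff: float = 0.10
    age_hr: float = 1.4
    weibull_shape: float = 1.2
    weibull_scale: float = 24.4    # null median OS ~ 18 months
    censor_low: float = 12.0   # uniform censoring; ~85-90% of patients die
    censor_high: float = 96.0  # within follow-up, as in real GBM cohorts

    def __post_init__(self) -> None:
        planted = self.n_dm_hyper + self.n_dm_hypo + self.n_regulated \
            + self.n_linked + self.n_prognostic + 1  # + MGMT probe
        if planted > self.n_probes:
            raise ValueError("planted probe sets exceed n_probes")
        if self.n_regulated + self.n_linked + self.n_de_up \
                + self.n_de_down > self.n_genes:
            raise ValueError("planted gene sets exceed n_genes")
        if not 0.0 <= self.frac_variable <= 1.0:
            raise ValueError("frac_variable must lie in [0, 1]")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "GeneratorConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown generator keys: {sorted(unknown)}")
        return cls(**dict(mapping))


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated cohort."""

    dm_hyper: set[str] = field(default_factory=set)
    dm_hypo: set[str] = field(default_factory=set)
    dm_delta: float = 0.0
    regulated_genes: set[str] = field(default_factory=set)
    regulated_probes: dict[str, str] = field(default_factory=dict)  # probe -> gene
    regulation_slope: float = 0.0
    linked_genes: set[str] = field(default_factory=set)  # DM + silenced
    de_up: set[str] = field(default_factory=set)
    de_down: set[str] = field(default_factory=set)
    prognostic: dict[str, tuple[float, float]] = field(default_factory=dict)
    mgmt_probe: str = ""
    variable_null_probes: set[str] = field(default_factory=set)

    @property
    def dm_probes(self) -> set[str]:
        return self.dm_hyper | self.dm_hypo


class SyntheticDataset(NamedTuple):
    beta: BetaMatrix
    expr: ExpressionMatrix
    ann: ProbeAnnotation
    clinical: ClinicalTable
    truth: SyntheticTruth


def _bimodal_baseline(rng: np.random.Generator, n: int,
                      cfg: GeneratorConfig) -> np.ndarray:
    low = rng.random(n) < cfg.low_mode_weight
    out = np.empty(n)
    out[low] = rng.beta(*cfg.low_mode, size=int(low.sum()))
    out[~low] = rng.beta(*cfg.high_mode, size=int((~low).sum()))
    return out  # caller passes the beta-block generator


def generate_dataset(cfg: GeneratorConfig | None = None,
                     seed: int = 17) -> SyntheticDataset:
    """Simulate one cohort: beta matrix, expression, annotation, clinical.

    See the module docstring for the generative model. The truth object
    records every planted probe/gene set so recovery can be scored.
    """
    cfg = cfg or GeneratorConfig()
    # one independent child stream per generation block, so a change inside
    # one block never shifts the draws of the others
    children = np.random.SeedSequence(seed).spawn(5)
    rng_assign, rng_beta, rng_expr, rng_ann, rng_clin = \
        (np.random.default_rng(c) for c in children)

    n_tum_total = max(cfg.n_tumors, cfg.n_survival)
    tumors = [f"T{i + 1:03d}" for i in range(n_tum_total)]
    controls = [f"N{i + 1:02d}" for i in range(cfg.n_controls)]
    samples = tumors + controls
    expr_tumors = tumors[:cfg.n_tumors]
    surv_tumors = tumors[:cfg.n_survival]
    probes = [f"cg{i + 1:06d}" for i in range(cfg.n_probes)]
    genes = [str(1000 + i) for i in range(cfg.n_genes)]
    symbols = {g: f"GENE{i + 1:04d}" for i, g in enumerate(genes)}

    # --- truth set assignment (disjoint probe sets)
    order = rng_assign.permutation(cfg.n_probes)
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        sel = [probes[i] for i in order[cursor:cursor + n]]
        cursor += n
        return sel

    hyper = take(cfg.n_dm_hyper)
    hypo = take(cfg.n_dm_hypo)
    regulated_probes = take(cfg.n_regulated)
    linked_probes = take(cfg.n_linked)
    prognostic_probes = take(cfg.n_prognostic)
    mgmt_probe = take(1)[0]
    remaining = [probes[i] for i in order[cursor:]]
    n_var = int(round(cfg.frac_variable * len(remaining)))
    variable_null = set(remaining[:n_var])

    # --- probe -> gene map; planted probes get dedicated genes so each
    # planted effect lands on its own gene
    gene_order = rng_assign.permutation(cfg.n_genes)
    gcursor = 0

    def take_genes(n: int) -> list[str]:
        nonlocal gcursor
        sel = [genes[i] for i in gene_order[gcursor:gcursor + n]]
        gcursor += n
        return sel

    regulated_genes = take_genes(cfg.n_regulated)
    linked_genes = take_genes(cfg.n_linked)
    de_up_genes = set(take_genes(cfg.n_de_up))
    de_down_genes = set(take_genes(cfg.n_de_down))
    hyper_genes = take_genes(cfg.n_dm_hyper)
    mgmt_gene = take_genes(1)[0]
    symbols[mgmt_gene] = "MGMT"

    probe_gene: dict[str, str] = {}
    for p, g in zip(regulated_probes + linked_probes,
                    regulated_genes + linked_genes):
        probe_gene[p] = g
    for p, g in zip(hyper, hyper_genes):
        probe_gene[p] = g
    probe_gene[mgmt_probe] = mgmt_gene
    unassigned = [p for p in probes if p not in probe_gene]
    # ~2% of probes stay unmapped, the rest draw a random gene
    unmapped = set(unassigned[:max(1, int(0.02 * cfg.n_probes))])
    for p in unassigned:
        probe_gene[p] = "" if p in unmapped else \
            genes[int(rng_assign.integers(cfg.n_genes))]

    # --- beta matrix
    n_s = len(samples)
    is_tumor = np.array([s in set(tumors) for s in samples])
    baseline = _bimodal_baseline(rng_beta, cfg.n_probes, cfg)
    probe_idx = {p: i for i, p in enumerate(probes)}
    for p in hyper:  # hyper sites start from the unmethylated mode
        baseline[probe_idx[p]] = rng_beta.beta(*cfg.low_mode)
    for p in hypo:   # hypo sites start methylated
        baseline[probe_idx[p]] = rng_beta.beta(*cfg.high_mode)

    beta = baseline[:, None] + rng_beta.normal(0.0, cfg.tech_sd,
                                          size=(cfg.n_probes, n_s))
    # regulated probes span the beta range so the methylation-expression
    # slope is identifiable within tumors
    for p in regulated_probes:
        beta[probe_idx[p]] = 0.05 + 0.9 * rng_beta.beta(1.3, 1.3, size=n_s)
    # variable null probes: unimodal inter-individual variability around the
    # probe's baseline, with a per-probe half-normal biological SD (identical
    # in tumors and controls -- no group effect)
    for p in variable_null:
        sd_i = abs(rng_beta.normal(0.0, cfg.bio_sd_null))
        beta[probe_idx[p]] = baseline[probe_idx[p]] \
            + rng_beta.normal(0.0, sd_i, size=n_s)
    # prognostic probes are bimodal across patients around their cutoff,
    # mirroring how promoter markers (e.g. MGMT) behave in tumors
    for p in prognostic_probes:
        c = cfg.prognostic_cutoff
        low_side = rng_beta.random(n_s) < 0.5
        row = np.where(low_side,
                       rng_beta.uniform(0.05, max(c - 0.05, 0.07), size=n_s),
                       rng_beta.uniform(min(c + 0.05, 0.93), 0.95, size=n_s))
        beta[probe_idx[p]] = row
    # linked probes: unmethylated control brain, heterogeneous tumor
    # hypermethylation that silences the gene through the regulation slope
    for p in linked_probes:
        row = np.empty(n_s)
        row[~is_tumor] = 0.08 + rng_beta.normal(0.0, cfg.tech_sd,
                                           size=int((~is_tumor).sum()))
        row[is_tumor] = 0.05 + 0.9 * rng_beta.beta(1.3, 1.3,
                                              size=int(is_tumor.sum()))
        beta[probe_idx[p]] = row
    # MGMT-like marker: bimodal across patients around the clinical cutoff
    low_grp = rng_beta.random(n_s) < 0.45
    mgmt_vals = np.where(low_grp,
                         rng_beta.uniform(0.01, 0.09, size=n_s),
                         rng_beta.uniform(0.15, 0.85, size=n_s))
    beta[probe_idx[mgmt_probe]] = mgmt_vals
    for p in hyper:
        shift = cfg.dm_delta + rng_beta.normal(0.0, cfg.bio_sd,
                                          size=int(is_tumor.sum()))
        beta[probe_idx[p], is_tumor] += shift
    for p in hypo:
        shift = cfg.dm_delta + rng_beta.normal(0.0, cfg.bio_sd,
                                          size=int(is_tumor.sum()))
        beta[probe_idx[p], is_tumor] -= shift
    beta = np.clip(beta, 0.0, 1.0)

    if cfg.missing_rate > 0:
        miss = rng_beta.random(beta.shape) < cfg.missing_rate
        beta[miss] = np.nan

    beta_df = pd.DataFrame(beta, index=probes, columns=samples)

    # --- expression matrix (log2 scale)
    expr_samples = expr_tumors + controls
    expr_tumor_mask = np.array([s in set(expr_tumors) for s in expr_samples])
    mu = rng_expr.normal(cfg.expr_mean, cfg.expr_gene_sd, size=cfg.n_genes)
    expr_probes: list[str] = []
    expr_probe_gene: list[str] = []
    for i, g in enumerate(genes):
        n_pr = 2 if rng_expr.random() < 0.2 else 1
        for j in range(n_pr):
            expr_probes.append(f"ep{i + 1:05d}_{j + 1}")
            expr_probe_gene.append(g)
    E = np.empty((len(expr_probes), len(expr_samples)))
    gene_mu = {g: mu[i] for i, g in enumerate(genes)}
    gene_beta = {g: beta_df.loc[p, expr_samples].to_numpy(dtype=float)
                 for p, g in zip(regulated_probes + linked_probes,
                                 regulated_genes + linked_genes)}
    for k, (ep, g) in enumerate(zip(expr_probes, expr_probe_gene)):
        base = gene_mu[g]
        row = np.full(len(expr_samples), base)
        if g in gene_beta:
            b = np.nan_to_num(gene_beta[g], nan=0.5)
            row = base + cfg.regulation_slope / 2.0 \
                - cfg.regulation_slope * b
        if g in de_up_genes:
            row = row + cfg.de_log2fc * expr_tumor_mask
        if g in de_down_genes:
            row = row - cfg.de_log2fc * expr_tumor_mask
        E[k] = row + rng_expr.normal(0.0, cfg.expr_noise_sd,
                                size=len(expr_samples))
    expr_df = pd.DataFrame(E, index=expr_probes, columns=expr_samples)

    # --- annotation
    cgi = np.zeros(cfg.n_probes, dtype=bool)
    hyper_set = set(hyper) | set(linked_probes)
    hypo_set = set(hypo)
    hyper_gene_set = set(hyper_genes) | set(linked_genes)
    for i, p in enumerate(probes):
        if p in hyper_set:
            cgi[i] = rng_ann.random() < cfg.cgi_prob_hyper
        elif p in hypo_set:
            cgi[i] = rng_ann.random() < cfg.cgi_prob_hypo
        else:
            cgi[i] = rng_ann.random() < cfg.cgi_prob_background
    # PRC2-target status is a property of the gene; probes inherit it
    gene_is_prc2 = {
        g: rng_ann.random() < (cfg.prc2_prob_hyper if g in hyper_gene_set
                               else cfg.prc2_prob_background)
        for g in genes}
    prc2 = np.array([gene_is_prc2.get(probe_gene[p], False)
                     for p in probes])
    meth_ann = pd.DataFrame({
        "entrez_id": [probe_gene[p] for p in probes],
        "symbol": [symbols.get(probe_gene[p], "") for p in probes],
        "cgi_flag": cgi,
        "prc2_flag": prc2,
    }, index=pd.Index(probes, name="probe_id"))
    expr_ann = pd.DataFrame({
        "entrez_id": expr_probe_gene,
        "symbol": [symbols[g] for g in expr_probe_gene],
    }, index=pd.Index(expr_probes, name="probe_id"))
    ann = ProbeAnnotation(meth=meth_ann, expr=expr_ann)

    # --- clinical table with censored Weibull survival
    age = np.clip(rng_clin.normal(58.0, 11.0, size=n_s), 26.0, 80.0).round(1)
    sex = rng_clin.choice(["M", "F"], size=n_s)
    kps = rng_clin.choice([40, 50, 60, 70, 80, 90, 100], size=n_s,
                     p=[0.03, 0.05, 0.10, 0.22, 0.30, 0.20, 0.10])
    clin = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    clin["group"] = np.where(is_tumor, "tumor", "control")
    clin["age"] = age
    clin["sex"] = sex
    clin["kps"] = kps
    clin["os_months"] = np.nan
    clin["event"] = np.nan
    clin["treatment"] = np.where(is_tumor, "RT", "none")
    clin["mgmt_methylated"] = np.nan

    surv_idx = [samples.index(s) for s in surv_tumors]
    lp = np.zeros(len(surv_idx))
    mgmt_beta_surv = mgmt_vals[surv_idx]
    mgmt_flag = mgmt_beta_surv > cfg.mgmt_cutoff
    lp += np.log(cfg.mgmt_hr) * mgmt_flag
    for p in prognostic_probes:
        pv = np.nan_to_num(beta[probe_idx[p], :][surv_idx], nan=0.5)
        lp += np.log(cfg.prognostic_hr) * (pv > cfg.prognostic_cutoff)
    lp += np.log(cfg.age_hr) * (age[surv_idx] >= 50.0)
    u = rng_clin.random(len(surv_idx))
    t_event = cfg.weibull_scale * (-np.log(u) / np.exp(lp)) \
        ** (1.0 / cfg.weibull_shape)
    censor = rng_clin.uniform(cfg.censor_low, cfg.censor_high,
                         size=len(surv_idx))
    observed = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(float)
    clin.loc[surv_tumors, "os_months"] = np.maximum(observed, 0.1).round(1)
    clin.loc[surv_tumors, "event"] = event
    clin.loc[surv_tumors, "treatment"] = "STUPP"
    clin.loc[surv_tumors, "mgmt_methylated"] = mgmt_flag.astype(float)

    truth = SyntheticTruth(
        dm_hyper=hyper_set, dm_hypo=hypo_set, dm_delta=cfg.dm_delta,
        regulated_genes=set(regulated_genes) | set(linked_genes),
        regulated_probes=dict(zip(regulated_probes + linked_probes,
                                  regulated_genes + linked_genes)),
        regulation_slope=cfg.regulation_slope,
        linked_genes=set(linked_genes),
        de_up=de_up_genes, de_down=de_down_genes,
        prognostic={p: (cfg.prognostic_cutoff, cfg.prognostic_hr)
                    for p in prognostic_probes},
        mgmt_probe=mgmt_probe, variable_null_probes=variable_null)

    logger.info("generate_dataset: %d probes x %d samples, %d expression "
                "probes x %d samples, %d survival patients",
                cfg.n_probes, n_s, len(expr_probes), len(expr_samples),
                len(surv_tumors))
    return SyntheticDataset(beta=BetaMatrix(beta_df),
                            expr=ExpressionMatrix(expr_df),
                            ann=ann, clinical=ClinicalTable(clin),
                            truth=truth)


@dataclass
class RecoveryScore:
    """Sensitivity/precision of a call set against a planted truth set."""

    sensitivity: float
    precision: float  # NaN when no calls were made against non-empty truth
    n_calls: int
    n_truth: int
    n_true_calls: int


def evaluate_recovery(calls: set[str], truth_set: set[str],
                      universe: set[str] | None = None) -> RecoveryScore:
    """Score a call set: sensitivity = TP/|truth|, precision = TP/|calls|.

    Empty calls against empty truth count as perfect; empty calls against a
    non-empty truth leave precision undefined (NaN).
    """
    calls = set(calls)
    truth_set = set(truth_set)
    if universe is not None:
        stray = (calls | truth_set) - set(universe)
        if stray:
            raise ValueError(f"ids outside the universe: {sorted(stray)[:5]}")
    tp = len(calls & truth_set)
    if not truth_set:
        sens = 1.0
    else:
        sens = tp / len(truth_set)
    if calls:
        prec = tp / len(calls)
    else:
        prec = 1.0 if not truth_set else float("nan")
    return RecoveryScore(sensitivity=sens, precision=prec,
                         n_calls=len(calls), n_truth=len(truth_set),
                         n_true_calls=tp)
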