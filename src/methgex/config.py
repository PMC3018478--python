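"""Pipeline-wide thresholds and tuning constants.

All defaults are the published cutoffs of the analysis this package
re-implements: an Infinium 27K promoter-methylation screen of glioblastoma
versus control brain, integrated with expression arrays and overall survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any, Mapping


@dataclass
class PipelineConfig:
    """Thresholds used by every analysis stage.

    Parameters
    ----------
    beta_low, beta_high, min_extreme_samples
        A CpG probe is retained for the expression-linked analyses when its
        beta value is below ``beta_low`` or above ``beta_high`` in at least
        ``min_extreme_samples`` samples (counted per tail).
    bin_width
        Width of the beta-value bins of the expression profile (fraction).
    sd_dm, sd_surv
        Per-probe standard-deviation filters feeding the differential
        methylation stage (inclusive, SD >= sd_dm) and the survival screen
        (strict, SD > sd_surv).
    dm_alpha, dm_delta
        Differential methylation calls require BH-adjusted p < ``dm_alpha``
        and |mean beta difference| > ``dm_delta``.
    de_fdr, de_fc
        Rank-product calls require estimated FDR (pfp) < ``de_fdr`` and a
        linear fold-change beyond ``de_fc`` (up) or 1/``de_fc`` (down).
    corr_r, corr_p
        A methylation/expression pair is inversely correlated when Pearson
        r < ``corr_r`` and p < ``corr_p``.
    cox_p, logrank_p, min_group
        Survival screen gates: univariate Cox p < ``cox_p``; best-cutoff
        log-rank p < ``logrank_p`` with at least ``min_group`` patients on
        each side of the cutoff.
    age_cut
        Age (years) splitting the strata of every survival test.
    horizon_months
        Horizon for predicted survival probabilities and time-dependent ROC.
    multivariate_p
        Markers below this p in the MGMT-adjusted Cox model are flagged as
        MGMT-independent.
    knn_k
        Neighbour count for nearest-neighbour imputation of missing betas.
    mgmt_beta_cutoff
        Beta above which the MGMT promoter probe is called methylated.
    n_permutations
        Rank-product permutation count.
    seed
        Global seed; stage-local generators are derived at fixed offsets.
    """

    beta_low: float = 0.15
    beta_high: float = 0.9
    min_extreme_samples: int = 3
    bin_width: float = 0.05
    sd_dm: float = 0.10
    sd_surv: float = 0.15
    dm_alpha: float = 0.01
    dm_delta: float = 0.2
    de_fdr: float = 0.05
    de_fc: float = 2.0
    corr_r: float = -0.5
    corr_p: float = 0.001
    cox_p: float = 0.05
    logrank_p: float = 0.001
    min_group: int = 5
    age_cut: float = 50.0
    horizon_months: float = 18.0
    multivariate_p: float = 0.01
    knn_k: int = 10
    mgmt_beta_cutoff: float = 0.10
    n_permutations: int = 1000
    seed: int = 17

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta_low < self.beta_high <= 1.0):
            raise ValueError("beta_low/beta_high must satisfy 0 <= low < high <= 1")
        for name in ("dm_alpha", "de_fdr", "corr_p", "cox_p", "logrank_p",
                     "multivariate_p"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not -1.0 <= self.corr_r <= 0.0:
            raise ValueError("corr_r must lie in [-1, 0]")
        if self.de_fc <= 1.0:
            raise ValueError("de_fc must exceed 1")
        if self.min_extreme_samples < 1 or self.min_group < 1:
            raise ValueError("sample-count thresholds must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
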