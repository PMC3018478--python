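"""CpG survival-marker discovery.

Per-CpG screen on an overall-survival cohort: variability filter, univariate
age-stratified Cox regression with beta as the predictor, maximally selected
log-rank cutpoint (best stratification p over admissible beta thresholds),
Kaplan-Meier summaries, model-based survival probability at a fixed horizon,
cumulative/dynamic time-dependent ROC AUC with Kaplan-Meier censoring
handling, AUC comparison across markers, a Schoenfeld-residual proportional-
hazards check, and a multivariate Cox model adjusting for MGMT promoter
methylation status.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test
from lifelines.utils import ConvergenceWarning
from scipy import stats

from .config import PipelineConfig
from .data_io import BetaMatrix, ClinicalTable, ProbeAnnotation, SurvivalMarker
from .preprocess import sd_filter

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit survival curve with at-risk counts."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # NaN when S never reaches 0.5


def km_estimate(os_months, event) -> KMCurve:
    """Kaplan-Meier estimate; median = first time S(t) <= 0.5."""
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size < 1:
        raise ValueError("need at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    event_times = np.unique(t[e == 1]) if (e == 1).any() else t
    keep = np.isin(times, event_times) & (times > 0)
    times, surv = times[keep], surv[keep]
    at_risk = np.array([(t >= ti).sum() for ti in times])
    med = kmf.median_survival_time_
    return KMCurve(event_times=times, survival=surv, at_risk=at_risk,
                   median=float(med) if np.isfinite(med) else float("nan"))


def _km_survival_at(times: np.ndarray, events: np.ndarray,
                    horizon: float) -> float:
    """S(horizon) by the product-limit formula (fast, allocation-light)."""
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    n = t.size
    s = 1.0
    i = 0
    while i < n and t[i] <= horizon:
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            d += int(e[j])
            j += 1
        if d:
            s *= 1.0 - d / (n - i)
        i = j
    return s


# ---------------------------------------------------------------------------
# log-rank test


def logrank_test(group_labels, os_months, event,
                 strata=None) -> tuple[float, float]:
    """Log-rank test across >= 2 groups, optionally summed over strata.

    Observed-minus-expected event counts over shared risk sets with the
    hypergeometric variance; chi-square with (groups - 1) df.
    """
    g = np.asarray(group_labels)
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(event, dtype=int)
    levels, codes = np.unique(g, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValueError("need at least two groups")
    strata_codes = (np.zeros(t.size, dtype=int) if strata is None
                    else np.unique(np.asarray(strata), return_inverse=True)[1])
    ome = np.zeros(k)
    V = np.zeros((k, k))
    for s in np.unique(strata_codes):
        m = strata_codes == s
        ts, es, cs = t[m], e[m], codes[m]
        for ti in np.unique(ts[es == 1]):
            at_risk = ts >= ti
            n = at_risk.sum()
            if n == 0:
                continue
            d = int(((ts == ti) & (es == 1)).sum())
            n_g = np.bincount(cs[at_risk], minlength=k).astype(float)
            d_g = np.bincount(cs[(ts == ti) & (es == 1)],
                              minlength=k).astype(float)
            ome += d_g - d * n_g / n
            if n > 1:
                frac = n_g / n
                V += d * (n - d) / (n - 1) * (np.diag(frac)
                                              - np.outer(frac, frac))
    sub = V[:-1, :-1]
    vec = ome[:-1]
    try:
        chi2 = float(vec @ np.linalg.solve(sub, vec))
    except np.linalg.LinAlgError:
        chi2 = float(vec @ np.linalg.pinv(sub) @ vec)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    return chi2, p


# ---------------------------------------------------------------------------
# cutpoint scan


@dataclass
class CutoffResult:
    """Best log-rank stratification threshold for one marker."""

    found: bool
    cutoff: float = float("nan")
    p_logrank: float = float("nan")
    chi2: float = float("nan")
    n_low: int = 0
    n_high: int = 0


def scan_best_cutoff(marker_beta, os_months, event, strata=None,
                     min_group: int = 5) -> CutoffResult:
    """Maximally selected log-rank cutpoint over admissible beta thresholds.

    Candidates are midpoints between consecutive distinct observed values;
    only splits leaving at least ``min_group`` patients on each side are
    evaluated (hypomethylated: beta <= cutoff; hypermethylated: beta >
    cutoff). Ties on p go to the smaller cutoff. A constant marker or an
    empty admissible set yields ``found=False``, not an error.
    """
    x = np.asarray(marker_beta, dtype=float)
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(event, dtype=int)
    distinct = np.unique(x)
    if distinct.size < 2 or x.size < 2 * min_group:
        return CutoffResult(found=False)
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    best = CutoffResult(found=False)
    for c in midpoints:
        hi = x > c
        n_high = int(hi.sum())
        n_low = x.size - n_high
        if n_low < min_group or n_high < min_group:
            continue
        chi2, p = logrank_test(hi.astype(int), t, e, strata=strata)
        if not best.found or p < best.p_logrank:
            best = CutoffResult(found=True, cutoff=float(c), p_logrank=p,
                                chi2=chi2, n_low=n_low, n_high=n_high)
    return best


# ---------------------------------------------------------------------------
# Cox regression


@dataclass
class CoxResult:
    """Fitted proportional-hazards model plus per-covariate summaries."""

    summary: pd.DataFrame     # hr, ci_low, ci_high, z, p per covariate
    fitter: CoxPHFitter = field(repr=False)
    training: pd.DataFrame = field(repr=False)
    strata_col: str | None
    separation_flag: bool
    n_events: int


def cox_fit(covariates: pd.DataFrame, os_months, event,
            strata=None) -> CoxResult:
    """Cox partial-likelihood fit (Breslow ties), optionally stratified.

    ``strata`` defines separate baseline hazards (shared coefficients).
    Monotone likelihood (perfect separation) is reported through
    ``separation_flag`` with the coefficient left at lifelines' capped
    value; non-convergence raises.
    """
    df = covariates.copy()
    df["_T"] = np.asarray(os_months, dtype=float)
    df["_E"] = np.asarray(event, dtype=int)
    n_events = int(df["_E"].sum())
    if n_events == 0:
        raise ValueError("no events in the data")
    strata_col = None
    if strata is not None:
        df["_strata"] = np.asarray(strata)
        strata_col = "_strata"
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            cph.fit(df, duration_col="_T", event_col="_E", strata=strata_col)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"Cox fit failed to converge: {err}") from err
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                separation = True
    summ = cph.summary
    with np.errstate(over="ignore"):  # a degenerate CI bound may hit inf
        out = pd.DataFrame({
            "hr": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
            "ci_high": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
            "z": summ["z"],
            "p": summ["p"],
        })
    out.index = summ.index
    return CoxResult(summary=out, fitter=cph, training=df,
                     strata_col=strata_col, separation_flag=separation,
                     n_events=n_events)


def survival_prob_at(cox: CoxResult, covariate_values: dict,
                     t: float) -> float:
    """Model-based S(t | x) from the Breslow baseline cumulative hazard.

    For t beyond the last observed time the step function's final value is
    returned (with a log flag).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0:
        return 1.0
    row = dict(covariate_values)
    if cox.strata_col is not None and cox.strata_col not in row:
        raise ValueError("stratified model needs a strata value")
    X = pd.DataFrame([row])
    t_max = float(cox.training["_T"].max())
    t_eval = t
    if t > t_max:
        logger.warning("survival_prob_at: t=%.3g beyond last observed time "
                       "%.3g; returning the final step value", t, t_max)
        t_eval = t_max
    sf = cox.fitter.predict_survival_function(X, times=[t_eval])
    return float(sf.iloc[0, 0])


def ph_check(cox: CoxResult) -> pd.DataFrame:
    """Grambsch-Therneau proportional-hazards score test per covariate.

    Scaled Schoenfeld residuals are correlated against (rank-transformed)
    event time; returns a frame with test_statistic and p per covariate.
    Requires at least three events.
    """
    if cox.n_events < 3:
        raise ValueError("ph_check requires at least three events")
    res = proportional_hazard_test(cox.fitter, cox.training,
                                   time_transform="rank")
    summ = res.summary
    return pd.DataFrame({"test_statistic": summ["test_statistic"],
                         "p": summ["p"]})


# ---------------------------------------------------------------------------
# time-dependent ROC


def td_roc_auc(marker, os_months, event, t: float) -> float:
    """Cumulative-case / dynamic-control AUC at horizon ``t``.

    Cases are subjects with an observed event by ``t``, controls subjects
    event-free past ``t``. Censoring is handled through the Kaplan-Meier
    estimator of survival conditional on the marker exceeding each
    threshold: sens(c) = P(X > c | T <= t) and spec(c) = P(X <= c | T > t)
    are recovered from subgroup KM curves by Bayes' rule, and the AUC is the
    trapezoid integral of the resulting ROC curve.
    """
    x = np.asarray(marker, dtype=float)
    times = np.asarray(os_months, dtype=float)
    events = np.asarray(event, dtype=int)
    if not np.any((events == 1) & (times <= t)):
        raise ValueError(f"no events observed by t={t}")
    if not np.any(times > t):
        raise ValueError(f"no subjects event-free past t={t}")
    s_all = _km_survival_at(times, events, t)
    if not 0.0 < s_all < 1.0:
        raise ValueError(f"degenerate overall survival at t={t}")
    # trace the ROC path from the strictest threshold (no positives) to the
    # loosest (all positive); sensitivity/fpr both grow along this path
    thresholds = np.unique(x)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for c in thresholds:
        hi = x > c
        p_hi = hi.mean()
        s_hi = _km_survival_at(times[hi], events[hi], t) if p_hi > 0 else 1.0
        s_lo = (_km_survival_at(times[~hi], events[~hi], t)
                if p_hi < 1 else 1.0)
        sens = (1.0 - s_hi) * p_hi / (1.0 - s_all)
        spec = s_lo * (1.0 - p_hi) / s_all
        tpr.append(min(max(sens, 0.0), 1.0))
        fpr.append(min(max(1.0 - spec, 0.0), 1.0))
    tpr.append(1.0)
    fpr.append(1.0)
    return float(np.trapezoid(np.array(tpr), np.array(fpr)))


@dataclass
class AUCComparison:
    """Kruskal-Wallis comparison of per-marker AUC(t) series."""

    statistic: float
    p_value: float
    mean_auc: dict[str, float]
    exceeds_reference: dict[str, bool]


def compare_auc(series: dict[str, np.ndarray],
                reference: str) -> AUCComparison:
    """Rank-test whether AUC(t) series differ; report means vs a reference.

    All series must share the same time grid (same length here; the caller
    owns grid construction).
    """
    if reference not in series:
        raise ValueError(f"reference series {reference!r} missing")
    arrays = {k: np.asarray(v, dtype=float) for k, v in series.items()}
    lengths = {v.size for v in arrays.values()}
    if len(lengths) != 1:
        raise ValueError("AUC series are on mismatched grids")
    if len(arrays) < 2 or lengths.pop() < 3:
        raise ValueError("need >= 2 series with >= 3 grid points")
    values = list(arrays.values())
    if all(np.array_equal(values[0], v) for v in values[1:]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*values)
    means = {k: float(v.mean()) for k, v in arrays.items()}
    ref_mean = means[reference]
    exceeds = {k: means[k] > ref_mean for k in arrays if k != reference}
    return AUCComparison(statistic=float(stat), p_value=float(p),
                         mean_auc=means, exceeds_reference=exceeds)


# ---------------------------------------------------------------------------
# the full marker screen


@dataclass
class MarkerScreenResult:
    """Survival-marker screen output plus per-stage counts."""

    markers: list[SurvivalMarker]
    stage_counts: dict[str, int]
    km_curves: dict[str, dict[str, KMCurve]] = field(default_factory=dict)


def select_survival_markers(beta: BetaMatrix, clinical: ClinicalTable,
                            cfg: PipelineConfig,
                            ann: ProbeAnnotation | None = None,
                            mgmt_probe: str | None = None
                            ) -> MarkerScreenResult:
    """Run the full per-CpG prognostic screen.

    Stages: SD > cfg.sd_surv filter -> univariate age-stratified Cox (beta
    continuous, keep p < cfg.cox_p) -> best log-rank cutpoint (keep
    p < cfg.logrank_p with both groups >= cfg.min_group) -> per survivor:
    time-dependent AUC at the horizon, horizon survival probabilities per
    methylation group, and a multivariate Cox including MGMT status.
    MGMT status comes from the clinical table, or is derived as beta >
    cfg.mgmt_beta_cutoff at ``mgmt_probe`` when designated.
    """
    cohort = [s for s in clinical.survival_samples()
              if s in set(beta.sample_ids)
              and clinical.data.loc[s, "group"] == "tumor"]
    if len(cohort) < 2 * cfg.min_group:
        raise ValueError("survival cohort too small")
    sub = clinical.data.loc[cohort]
    t = sub["os_months"].to_numpy(dtype=float)
    e = sub["event"].to_numpy(dtype=int)
    age_strata = (sub["age"].to_numpy(dtype=float) >= cfg.age_cut).astype(int)
    B = beta.values[cohort]
    if B.isna().to_numpy().any():
        raise ValueError("beta matrix must be imputed before the screen")

    candidates = sorted(sd_filter(BetaMatrix(B), cfg.sd_surv,
                                  inclusive=False))
    counts = {"cohort": len(cohort), "sd_filtered": len(candidates)}

    mgmt_status: np.ndarray | None = None
    if clinical.has_mgmt and sub["mgmt_methylated"].notna().all():
        mgmt_status = sub["mgmt_methylated"].to_numpy(dtype=float)
    elif mgmt_probe is not None and mgmt_probe in B.index:
        mgmt_status = (B.loc[mgmt_probe].to_numpy(dtype=float)
                       > cfg.mgmt_beta_cutoff).astype(float)
    if mgmt_status is None:
        logger.warning("no MGMT status available; multivariate stage skipped")

    cox_pass: list[tuple[str, pd.Series]] = []
    for probe in candidates:
        x = B.loc[probe].to_numpy(dtype=float)
        try:
            res = cox_fit(pd.DataFrame({"beta": x}), t, e, strata=age_strata)
        except (ConvergenceError, ValueError) as err:
            logger.warning("univariate Cox failed for %s: %s", probe, err)
            continue
        row = res.summary.loc["beta"]
        if row["p"] < cfg.cox_p:
            cox_pass.append((probe, row))
    counts["cox_selected"] = len(cox_pass)

    markers: list[SurvivalMarker] = []
    km_curves: dict[str, dict[str, KMCurve]] = {}
    for probe, uni in cox_pass:
        x = B.loc[probe].to_numpy(dtype=float)
        cut = scan_best_cutoff(x, t, e, strata=age_strata,
                               min_group=cfg.min_group)
        if not cut.found or cut.p_logrank >= cfg.logrank_p:
            continue
        hi = x > cut.cutoff
        try:
            auc = td_roc_auc(x, t, e, cfg.horizon_months)
        except ValueError as err:
            logger.warning("AUC unavailable for %s: %s", probe, err)
            auc = float("nan")
        # classical (unstratified) Cox on the methylation group for the
        # horizon survival probabilities
        try:
            grp_cox = cox_fit(pd.DataFrame({"hyper": hi.astype(float)}), t, e)
            s_low = survival_prob_at(grp_cox, {"hyper": 0.0},
                                     cfg.horizon_months)
            s_high = survival_prob_at(grp_cox, {"hyper": 1.0},
                                      cfg.horizon_months)
        except (ConvergenceError, ValueError) as err:
            logger.warning("group Cox failed for %s: %s", probe, err)
            s_low = s_high = float("nan")
        hr_multi = p_multi = float("nan")
        independent = False
        if mgmt_status is not None:
            try:
                multi = cox_fit(
                    pd.DataFrame({"marker": hi.astype(float),
                                  "mgmt": mgmt_status}),
                    t, e, strata=age_strata)
                hr_multi = float(multi.summary.loc["marker", "hr"])
                p_multi = float(multi.summary.loc["marker", "p"])
                independent = p_multi < cfg.multivariate_p
            except (ConvergenceError, ValueError) as err:
                logger.warning("multivariate Cox failed for %s: %s",
                               probe, err)
        symbol = ""
        if ann is not None and probe in ann.meth.index:
            symbol = str(ann.meth.loc[probe, "symbol"])
        markers.append(SurvivalMarker(
            probe_id=probe, symbol=symbol,
            hr=float(uni["hr"]), ci_low=float(uni["ci_low"]),
            ci_high=float(uni["ci_high"]), z=float(uni["z"]),
            p_cox=float(uni["p"]), cutoff=cut.cutoff,
            p_logrank=cut.p_logrank, n_low=cut.n_low, n_high=cut.n_high,
            auc=auc, surv18_low=s_low, surv18_high=s_high,
            hr_multivariate=hr_multi, p_multivariate=p_multi,
            mgmt_independent=independent))
        km_curves[probe] = {
            "hypomethylated": km_estimate(t[~hi], e[~hi]),
            "hypermethylated": km_estimate(t[hi], e[hi]),
        }
    counts["logrank_selected"] = len(markers)
    logger.info("survival screen: %s", counts)
    return MarkerScreenResult(markers=markers, stage_counts=counts,
                              km_curves=km_curves)
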