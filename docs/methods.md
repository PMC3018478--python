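# Methods

`methgex` re-implements, as a tested pipeline over synthetic cohorts with
known planted truth, an integrative analysis of promoter DNA methylation
and gene expression in glioblastoma (GBM): differential-methylation calling
against control brain, rank-product differential expression,
methylation–expression anti-correlation, CpG-island / PRC2-target
enrichment, and a per-CpG overall-survival marker screen with maximally
selected β-cutoffs and time-dependent ROC.

## The measurement model

Methylation at a CpG site is summarised by the beadchip β-value

    β = max(M, 0) / (max(M, 0) + max(U, 0) + 100),

the fraction of methylated signal M over total signal, with
background-corrected intensities floored at zero and a +100 offset that
stabilises low-intensity probes; β ∈ [0, 1). Missing β-values are imputed
by k-nearest-neighbour averaging over probes (Euclidean distance on
jointly observed samples, k = 10 by default — the convention of the
standard microarray imputation method). Expression arrays are
log2-transformed, quantile-normalized (each sample's sorted values mapped
onto the across-sample mean of sorted values, ties receiving interpolated
positions) and baseline-transformed (per-probe median subtraction), after
which every probe has zero median across samples.

## Stage-by-stage procedure and parameters

All thresholds live in `PipelineConfig`; defaults are the published
cutoffs of the emulated study.

**Expression-linked probe selection.** CpG-by-sample observations are
binned on β (bins 0.05 wide; the last bin is closed so β = 1 is counted);
each observation carries the per-sample maximum expression over the linked
gene's probes. Expression responds to methylation only at the extremes of
the β range, so probes with β < 0.15 or β > 0.9 in at least three samples
(counted per tail) are selected for the correlation analysis.

**Differential methylation (DM).** Probes are pre-filtered on per-probe
SD ≥ 0.10 (n−1 denominator); Welch two-sample t-tests compare tumors with
control brain; Benjamini–Hochberg adjustment runs over exactly the
filtered set; calls require adjusted p < 0.01 and |Δβ| > 0.2, with the
sign of Δβ (tumor − control) giving the hyper/hypo direction.
CGI and PRC2-target enrichment of the called gene sets uses two-sided
Fisher exact tests of (set vs rest of array) × (flagged vs not), where a
gene is flagged when any of its promoter probes is; samples are clustered
on the called sites with average linkage on 1 − Pearson distance (the
linkage and metric are not dictated by the analysis; they are recorded in
the outputs).

**Differential expression (DE).** One probe per gene (highest mean
expression across arrays) enters a rank-product analysis over all
n_tumor × n_control pairwise comparisons: genes are ranked by log
fold-change within each comparison and scored by the geometric mean of
their ranks, separately for up- and down-regulation. The attached pfp
(proportion of false positives) is estimated from permutations that draw
an independent random rank list per comparison (1,000 by default; 100 in
the bundled analyses, which the planted effect sizes resolve easily).
Calls require pfp < 0.05 and linear fold-change beyond 2 (or below 1/2).

**Integration.** Methylation and expression probes are paired through
shared Entrez gene ids (all combinations). Pearson correlation between
promoter β and expression is computed over tumor samples only; a pair is
inversely correlated when r < −0.5 and p < 0.001 (p from the t transform
on n − 2 df). Gene-level DM and DE calls are cross-classified: concordant
means hypermethylated∧down or hypomethylated∧up; the headline gene set is
concordant genes whose promoter CpG is also inverse-flagged; association
between DM and DE membership uses a 2×2 chi-square without continuity
correction (the analysis does not specify a correction; none is the
natural choice at these counts). Genes with conflicting DM directions are
labelled mixed and excluded from the concordance table.

**Survival screen.** On the uniformly treated cohort (overall survival in
months, death indicator), probes with SD > 0.15 (strict) are screened:

1. univariate Cox regression with β as a continuous predictor, stratified
   by age (≥ 50 vs < 50 years; separate baseline hazards, shared
   coefficient; Breslow ties); keep p < 0.05;
2. maximally selected log-rank cutpoint: candidate cutoffs are midpoints
   between consecutive distinct observed β values; only splits leaving at
   least 5 patients per side are admissible; the cutoff minimising the
   age-stratified log-rank p is selected (ties → smaller cutoff;
   hypomethylated = β ≤ cutoff); keep p < 0.001;
3. for each surviving marker: 18-month survival probabilities per
   methylation group from a classical (unstratified) Cox model on the
   group indicator, S(t|x) = exp(−H₀(t)·exp(xβ)) with the Breslow
   baseline; a cumulative-case/dynamic-control ROC AUC at 18 months; and
   a multivariate age-stratified Cox model with the marker's binary
   status plus MGMT promoter methylation status (β > 0.10 at the MGMT
   probe, or the clinical table's call). Markers with multivariate
   p < 0.01 are flagged MGMT-independent.

No multiplicity correction is applied across CpGs in the survival screen
(raw p thresholds at each stage, as in the emulated analysis); the
selection-bias inflation this causes is intentional and the null behaviour
is characterised in the test suite. The time-dependent AUC handles
censoring through Kaplan–Meier estimates of survival conditional on the
marker exceeding each threshold (Bayes' rule recovers sensitivity
P(X > c | T ≤ t) and specificity P(X ≤ c | T > t)); the ROC path is
traced from the strictest to the loosest threshold and integrated by
trapezoid. Without censoring before the horizon this reduces exactly to
the empirical Mann–Whitney AUC of the event-by-t indicator. AUC(t) series
of different markers are compared on a 3–60 month grid (3-month steps)
with a Kruskal–Wallis rank test; the grid is a package choice, as the
comparison's construction is not otherwise determined.
The proportional-hazards check correlates scaled Schoenfeld residuals
against rank-transformed event time (Grambsch–Therneau score test,
χ² with 1 df per covariate).

Whether the multivariate model should also include age as a covariate
(rather than a stratum) is not determined by the source analysis; this
implementation stratifies, keeping every survival test on the same
footing.

## The synthetic cohort

`generate_dataset` draws one cohort from a seeded generator (independent
sub-streams per block — truth assignment, β, expression, annotation,
clinical — so the blocks are reproducible in isolation):

- **Samples.** 50 tumors (the first 40 with expression arrays; all 50
  with survival follow-up) and 3 control brains.
- **β landscape.** Per-probe baselines from a two-component Beta mixture,
  0.90·Beta(1.5, 12) + 0.10·Beta(10, 2.5); per-cell replicate noise
  N(0, 0.03). These mixture constants were calibrated once against two
  realism targets — global median β ≈ 0.1 (promoter arrays are globally
  hypomethylated) and a clearly bimodal histogram — and then frozen. 8%
  of null probes additionally carry inter-individual variability with a
  per-probe half-normal(0.06) SD, identical in tumors and controls; most
  null CpGs vary little across individuals, which is also the regime the
  SD pre-filter presumes (see Limitations). 0.5% of cells are masked as
  missing.
- **Planted differential methylation.** 150 hyper probes start in the
  unmethylated mode and gain Δβ = 0.4 in tumors (plus N(0, 0.1) tumor
  heterogeneity — GBMs are epigenetically heterogeneous, control brains
  are not); 50 hypo probes mirror this downward. Hyper probes sit in a
  CpG island with probability 0.97 (hypo: 0.09; background: 0.73), and
  their genes are PRC2 targets with probability 0.35 against a 9.5%
  gene-level background — the enrichment structure reported for de novo
  methylation in tumors.
- **Expression.** Gene means N(7, 1) log2 units, per-cell noise
  N(0, 0.4); 60 up- and 60 down-regulated genes shifted by ±1.322 log2
  units (2.5-fold) in tumors; 50 "regulated" genes follow
  μ + s/2 − s·β with slope s = 4 log2 units per β unit, read off their
  promoter probe (spread across the β range in all samples); 15 "linked"
  genes combine both layers — unmethylated in control brain,
  heterogeneously hypermethylated in tumors, expression driven by β —
  producing the concordant, anti-correlated headline class.
- **Survival.** Weibull times (shape 1.2, scale 24.4 ⇒ null-group median
  ≈ 18 months, the cohort's published median being a realism target, not
  an assertion); log-hazard shifts: +log 4 above the prognostic probe's
  cutoff (β > 0.45; the marker is bimodal across patients around its
  cutoff, as MGMT is around 0.10), +log 1.4 for age ≥ 50, and log 0.35
  for MGMT-methylated patients (protective). Censoring is
  Uniform(12, 96) months, so 85–90% of patients die within follow-up —
  GBM is near-universally fatal, and the earlier, heavier censoring draft
  starved the cutpoint scan of events. The default prognostic effect
  (HR 4) matches the strength of the markers the emulated study reports
  (univariate hazard ratios of 18–113 per β unit); the recovery tests
  additionally exercise a weaker HR 3 marker on an otherwise effect-free
  cohort.

What the generator does **not** emulate: probe-type chemistry and batch
effects, copy-number confounding of expression, correlated probe blocks
within promoters, non-uniform censoring, or cohort substructure such as
the methylator phenotype. Passing tests therefore demonstrate that the
statistics and gates behave as specified on data with the study's
first-order structure — not that the pipeline is robust to artefacts the
generator omits.

## Numerical choices

- Reported p-values are floored at 1e-300; output floats carry 6
  significant digits.
- Degenerate Welch comparisons (both groups constant and equal) return
  t = 0, p = 1; exact collinearity in Pearson correlation snaps to
  r = ±1, p = 0.
- BH adjustment is the standard step-up with monotonicity enforcement,
  applied over exactly the tested probe set.
- The rank-product null draws a fresh uniform permutation of ranks per
  comparison; pfp at ascending-RP position i is
  (mean null count ≤ RP) / i. For a fixed seed results are
  bit-reproducible.
- Cox fits use lifelines (Breslow baseline); monotone likelihood is
  surfaced as a separation flag rather than an error; predicted survival
  beyond the last observed time returns the final step value with a
  warning.
- The cutpoint scan evaluates the stratified log-rank statistic with
  hypergeometric variance summed over strata; a singular variance matrix
  falls back to a pseudo-inverse.
- Stage-local random streams derive from the global seed at fixed
  offsets, so skipping a stage never shifts another stage's draws.

## Known limitations

- **Small-control Welch tail.** With 3 controls the Welch approximation
  is anti-conservative deep in the tail (measured ≈ ×80 at p = 1e-4,
  ≈ ×440 at 1e-5 under an exact Gaussian null at 40-vs-3). On probes
  with substantial inter-individual variability this produces occasional
  BH-significant false DM calls that the |Δβ| > 0.2 gate does not always
  stop. The SD pre-filter makes the procedure safe only in the regime
  where null variability stays below the filter scale; conclusions from
  3-control designs on highly variable probes should be treated with
  caution.
- **Rank-product pfp with shared controls.** All tumor–control pairs
  share the 3 controls, so observed rank lists are strongly correlated
  while the permutation null assumes independent lists; raw pfp is
  therefore anti-conservative (a quarter of null genes can fall below
  pfp 0.05 at 40-vs-3). The joint pfp + fold-change gate is what holds
  the null call count at zero, and only the joint calls are reported.
- **Maximally selected cutpoints.** The best-stratifying cutoff is a
  noisy estimator at n = 50 (errors of ±0.1 in β are routine) and its
  log-rank p is selection-inflated; the screen reproduces the emulated
  analysis's choices deliberately and reports group sizes alongside.
- **Survival-probability model.** The 18-month probabilities come from an
  unstratified Cox model on the dichotomised marker, matching the
  "classical Cox model" summary display; they are descriptive, not
  adjusted estimates.
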