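# methgex

Integrative analysis of promoter DNA methylation and gene expression for
glioblastoma-style cohorts: differential-methylation calling on Infinium
β-values, rank-product differential expression, methylation–expression
inverse correlation, CpG-island / PRC2-target enrichment, and per-CpG
survival-marker discovery with optimal β-cutoff stratification and
time-dependent ROC.

It is written for analysts who work with beadchip promoter methylation
(β = max(M,0)/[max(M,0)+max(U,0)+100] ∈ [0,1]) paired with expression
arrays and clinical follow-up, and who want the full published analysis
chain as a reusable, tested library rather than a one-off script stack.
Because the original cohort data live behind repository accessions, the
package ships a first-class synthetic-cohort generator that emulates the
study design — a bimodal, globally hypomethylated β landscape (median
β ≈ 0.1), 40–55 tumors against 3 control brains, CpG-island-biased
hypermethylation, genes whose log2 expression falls linearly with
promoter β, and censored survival whose hazard shifts when a marker
crosses a β cutoff — with every planted truth set recorded, so each
pipeline stage is scored against known ground truth.

## The statistics at the core

- **DM sites:** per-CpG Welch t-tests (tumor vs control) on SD-filtered
  probes (SD ≥ 0.1), Benjamini–Hochberg over the tested set; call when
  adjusted p < 0.01 and |Δβ| > 0.2.
- **DE genes:** rank product RP_g = (∏ₖ r_{g,k})^{1/K} over all
  tumor×control comparisons with permutation pfp; call when pfp < 0.05
  and |FC| > 2.
- **Inverse pairs:** Pearson r between promoter β and expression over
  tumors; flag when r < −0.5 and p < 0.001.
- **Survival markers:** age-stratified univariate Cox (β continuous,
  p < 0.05) → maximally selected log-rank β-cutoff (p < 0.001, ≥ 5
  patients per side) → 18-month survival probabilities, time-dependent
  ROC AUC (Kaplan–Meier-weighted cumulative/dynamic construction), and
  an MGMT-adjusted multivariate Cox model.

`docs/methods.md` documents the model, the generator's design and its
limits, and every numerical choice.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_differential_methylation.py
```

which prints (seed 17, the repository default):

```
cohort: 5000 CpG probes x 53 methylation arrays; 3600 expression probes x 43 arrays
global median beta = 0.114 (globally hypomethylated, bimodal)
survival cohort: n=50, 44 deaths, median OS 8.4 months
...
216 DM CpG sites (adjusted p < 0.01, |delta beta| > 0.2): 165 hyper-, 51 hypomethylated in tumors
planted-truth recovery: sensitivity 1.00, precision 0.99
98% of hypermethylated sites lie in a CpG island; 84% of hypomethylated sites lie outside one
PRC2 targets: 33.3% of the hypermethylated gene set vs 11.1% of the array (Fisher p = 1.1e-15)
```

i.e. the pipeline recovers essentially all 215 planted differentially
methylated sites with one false call, and the called hypermethylated
genes show the CpG-island and PRC2-target enrichment that the generator
planted. Continuing with `04_differential_expression.py`,
`05_integration.py` and `06_survival_markers.py` recovers the planted
up/down-regulated genes, the genes whose expression tracks promoter
methylation (the concordant, anti-correlated class), and the planted
prognostic CpG:

```
  cg004792 (GENE1761): HR 7.3 [1.8, 30], cutoff 0.45, log-rank p 0.00058,
  AUC 0.76, S(18mo) 0.55 vs 0.12 (MGMT-independent)
```

— the β cutoff 0.45 is exactly the planted threshold, and the marker's
time-dependent AUC exceeds the MGMT-like probe's across the 3–60-month
grid (Kruskal–Wallis p = 2.3e-07).

The same stages are available as a CLI
(`methgex simulate|preprocess|dm|de|integrate|survival|all`), e.g.

```bash
methgex all --config run.yaml --out results/run/
```

with a YAML config naming either input TSVs (`inputs:`) or generator
parameters (`simulate:`); every run writes a `manifest.json` with the
config snapshot, seed and per-stage counts, and fixed seeds give
byte-identical outputs.

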