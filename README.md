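# methyldef

Global gene-body methylation "definition" analysis for censored survival
outcomes.

Solid tumors tend to lose *defined* gene-body (GB) methylation: instead
of most genes sitting near fully methylated (beta ≈ 1) or fully
unmethylated (beta ≈ 0), methylation drifts into intermediate states.
`methyldef` quantifies this global phenotype and tests whether it
predicts overall survival. It is aimed at researchers with
region-resolved methylation data (RRBS/WGBS CpG calls or array betas)
plus censored survival and, optionally, expression counts for the same
cohort.

## Method

1. **Region aggregation** — per-CpG beta values (methylated / total
   calls) are averaged per gene body or CpG island with coverage weights
   `w = log10(depth + 0.1)`; a region needs ≥ 11 called CpGs to count.
   Per sample, region averages are binned into ten methylation deciles
   (0–10% … 90–100%).
2. **Survival screen** — each decile count is scored against overall
   survival with a modified Cox score `d = U/(√V + s0)` and a permutation
   null (times and events permuted against the counts); deciles outside a
   data-chosen band are called at a 5% false discovery rate, signed by
   hazard direction.
3. **MDF / MUMF** — the *methylation definition factor* of a sample is
   the ratio of its region counts in the screen's unfavorable deciles to
   the counts in the favorable ones (classically: extreme deciles over
   intermediate ones); the glioblastoma-style MUMF fixes the sets to
   deciles 6–10 over 1–5.
4. **Cutpoint + Cox models** — the factor is dichotomised at the cutpoint
   minimising the Wald p of the dichotomised term inside a
   covariate-adjusted Cox model, then fit in univariate and multiple Cox
   models, the latter with backward AIC selection (factor forced in).
5. **Correlations** — GB↔CGI methylation correlation per paired region,
   CV-vs-mean variability profiles, and factor↔expression screening with
   Benjamini–Hochberg control producing signed gene lists.

A synthetic-data generator produces CpG calls, regions, survival and
expression with known ground truth (latent per-sample "definition"
phenotype linked to hazard), so the whole pipeline is testable offline;
see `docs/methods.md` for the model and its limits.

## Worked example

Simulate a 45-sample cohort and run every stage:

```bash
methyldef simulate --seed 5 --out-dir demo/data --n-samples 45 --n-genes 400
cat > demo/config.yaml <<'YAML'
calls_paths: [demo/data/calls/S001.tsv, ...]   # all 45 call files
calls_mode: counts
regions_bed: demo/data/regions.bed
survival_path: demo/data/survival.tsv
expression_path: demo/data/expression.tsv
n_permutations: 500
covariates: [age]
mdf_spec: auto
expression_fdr_cutoff: 0.10
seed: 7
YAML
methyldef run --config demo/config.yaml --out-dir demo/run
cat demo/run/report.txt
```

prints

```
Gene-body methylation definition analysis
==========================================

samples: 45   events: 32
significant deciles (FDR 5%): decile_1(-), decile_3(+), decile_4(+), decile_5(+), decile_6(+), decile_7(+), decile_9(-), decile_10(-)
factor: MDF  defined=[3, 4, 5, 6, 7]  undefined=[1, 9, 10]
cutpoint: 65.59 (p=4.48e-06, 12 high vs 33 low, 34 candidates)
univariate Cox: HR 6.18 (2.72-14.04) p=1.328e-05 [n=45, events=32]
multiple Cox: HR 8.02 (3.30-19.53) p=4.481e-06 [n=45, events=32]
covariates retained: ['age'] excluded: []
expression screen: 0 positively / 0 negatively correlated genes of 400 tested (FDR < 10%)
```

Reading the report: intermediate deciles (3–7) carry positive scores —
samples with many half-methylated gene bodies die sooner — so the derived
factor puts them in the numerator and the extreme deciles in the
denominator. Dichotomised at its optimal cutpoint, a high factor (poorly
defined methylome) carries a hazard ratio of ~6 alone and ~8 after
adjusting for age; in this simulated cohort that direction is the planted
truth. Stage outputs (region betas with CpG counts and a JSON sidecar of
parameters, decile counts, screen table, factor values, cutpoint and Cox
JSONs, Kaplan–Meier table, signed gene lists, manifest) land in
`demo/run/`; rerunning with the same config and seed reproduces them
byte-identically.

The library surface mirrors the stages (`average_region_beta`,
`count_decile_membership`, `sam_screen`, `compute_mdf`,
`optimal_cutpoint`, `fit_cox`, `backward_aic`, `pair_gb_cgi`,
`mdf_expression_correlation`, `simulate_methylome`, ...) for use without
the CLI.

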