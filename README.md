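# pmekit

Proteomic characterization of the **peritumor microenvironment (PME)** in
hepatocellular carcinoma (HCC), as a reusable, tested analysis pipeline.

Most tumor-microenvironment studies profile the tumor itself and can only
speak to progression. The PME view instead profiles the *non-tumor* liver
tissue adjacent to an HCC — the "soil" in which tumors arise — and asks two
separate questions: which proteins mark the **occurrence** of HCC
(discriminating peritumor from normal liver), and which mark its
**progression** (associating with patient survival). `pmekit` implements
that full analysis for anyone working with label-free (iBAQ-like)
protein-abundance matrices and matched clinical tables:

- **Preprocessing** — detection filtering (proteins seen in < 50% of samples
  are dropped), half-minimum imputation of detection-limit missing values,
  quantile normalization, log2 transform.
- **Differential proteome** — per-protein two-group tests (equal-variance
  Student *t*, or an empirical-Bayes moderated *t*), with the significance
  rule *fold change* > 1.2 (either direction) and *P* < 0.05.
- **Signatures and risk indices** — an occurrence arm selected by
  normal-vs-peritumor ROC AUC and a progression arm selected by
  median-split Kaplan–Meier log-rank tests; each protein carries one of six
  functional factor categories (immunity, inflammation, angiogenesis,
  metabolism, proliferation & invasion, DNA damage & repair). Per patient,
  a **risk index (RI)** aggregates weighted, direction-aligned abundances
  per category; the cohort-median split defines RI-high vs RI-low groups,
  which are cross-tabulated against clinical covariates (AFP > 300 ng/mL,
  CYP2E1 activity > 1350 pmol/min/mg, ...).
- **Prediction models** — a three-marker logistic **occurrence model**
  (default panel HSPA4L, VIL1, TYMP) with a Youden-optimal threshold, and a
  three-marker Cox **prognostic index (PI)** (default panel CMPK2, TYMP,
  NADSYN1) whose median split stratifies survival; plus the
  occurrence-vs-progression cross-evaluation in four-fold tables
  (chi-square and Fisher exact tests).
- **PME subtypes** — consensus clustering by non-negative matrix
  factorization (NMF) over seeded restarts, with cophenetic-correlation
  model-order selection, consensus-CDF diagnostics, and subtype–feature
  association tests.
- **Synthetic cohorts** — a generator that plants every structure the
  analysis assumes (fold changes, survival effects, latent subtypes,
  detection-limit missingness, covariate coupling) with full ground truth,
  so the entire pipeline is testable end to end without access to patient
  data.

The statistical kernel (ROC/AUC with Youden threshold, Kaplan–Meier,
log-rank, Cox proportional hazards with Breslow ties, logistic regression,
Fisher exact and chi-square tests, rank correlations) is implemented in the
package and cross-checked in the test suite against independent oracles
(pair-counting, permutation nulls, hypergeometric enumeration, lifelines,
statsmodels).

## Core quantities

For protein *i* with abundance *x<sub>ij</sub>* in patient *j* (log2 scale,
rescaled to [0, 10] over the peritumor cohort and reversed for proteins
whose low abundance carries the risk):

- occurrence weight: *w<sub>i</sub>* = 2·(AUC<sub>i</sub> − ½)
- progression weight: *w<sub>i</sub>* = min(−log₁₀ *p<sub>i</sub>*, 4) from the
  per-protein log-rank test
- risk index: RI<sub>j</sub> = Σ<sub>categories</sub> Σ<sub>i∈category</sub>
  *w<sub>i</sub>* · *s<sub>ij</sub>*
- prognostic index: PI<sub>j</sub> = Σ *β<sub>i</sub> x<sub>ij</sub>* (the Cox
  linear predictor), median-split into PI-high/PI-low

## Worked example

```python
from pmekit import RunConfig, run_pipeline

config = RunConfig.synthetic(seed=1, k_range=(2, 3, 4, 5), n_runs=30,
                             nmf_top_n=200, nmf_max_iter=500)
summary = run_pipeline(config, "out")
print(summary["n_differential_significant"])
print(summary["signature_overlap"])
print(summary["prognostic_model"]["logrank_p"])
print(summary["subtyping"]["chosen_k"], summary["subtyping"]["sizes"])
```

prints (seed 1):

```
412
{'shared': ['P00098', 'P00142', 'P00222', 'P02633', 'P02806'],
 'n_shared': 5, 'n_union': 58, 'overlap_percent': 8.62}
5.044356973890874e-05
3 {'1': 21, '2': 16, '3': 24}
```

Reading: of ~4900 retained proteins, 412 pass the differential rule; the
occurrence arm (capped at 40) and progression arm (23 proteins here) share
only 8.6% of their union — occurrence and progression markers are largely
different proteins, which is the study's central observation. The
three-marker prognostic index separates survival strongly (log-rank
*P* ≈ 5×10⁻⁵), and consensus NMF recovers the three planted PME subtypes
(21/16/24 patients; adjusted Rand index vs ground truth = 1.0 in
`summary["subtyping"]["ari_vs_truth"]`).

The same stages are available as a CLI:

```bash
pme simulate --seed 1 --out cohort/
pme preprocess --abundance cohort/abundance.tsv --out pre.tsv
pme differential --abundance pre.tsv --clinical cohort/clinical.csv --out diff.tsv
pme run-all --synthetic --seed 1 --out out/
```

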