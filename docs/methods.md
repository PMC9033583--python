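# Methods

This note documents the models and procedures implemented in `pmekit`, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions that matter for reproducing results.

## Statistical kernel

All downstream stages are built on a small, self-contained kernel
(`pmekit.stats`); scipy supplies only distribution tail functions and rank
utilities.

**ROC / AUC.** The AUC is computed by the rank (Mann–Whitney) formula, so
tied scores count ½ — identical to explicit pair enumeration. The operating
point maximizes Youden's J = sensitivity + specificity − 1 over the
thresholds "call positive when score ≥ t"; among tied maxima the highest
threshold (highest specificity) wins. The curve is returned as ordered
(FPR, TPR) pairs from (0,0) to (1,1); its trapezoidal area equals the
rank AUC.

**Kaplan–Meier.** Product-limit estimator over distinct event times. The
median is the earliest event time at which S(t) ≤ 0.5 and is reported as
not reached when the curve never gets there.

**Log-rank.** Two-group observed−expected statistic with the
hypergeometric variance at each distinct event time; p from a 1-df
chi-square. A permutation version (group labels shuffled) is provided and
used in tests to bound the approximation error on small samples. The signed
O−E of the first group is exposed; the signature module uses it to orient
risk directions.

**Cox proportional hazards.** Breslow tie handling; Newton–Raphson from
β = 0 with step halving, stopping at gradient norm < 1e−8 or 100
iterations. Efron ties, stratification and penalties are out of scope.
Monotone likelihood (perfect risk separation) cannot be detected from
non-convergence alone — the likelihood often "converges" onto a flat
plateau — so a fit is flagged when coefficients run away (|β| > 15) or the
standard errors dwarf the estimates, as well as on genuine non-convergence.

**Logistic regression.** IRLS with intercept, tolerance 1e−8. Singular
information matrices (e.g. a degenerate covariate) fall back to a
least-squares step, which correctly returns β = 0 for a balanced,
uninformative design. Perfect separation is flagged via runaway
coefficients. Fitted probabilities are clipped to (1e−12, 1−1e−12) so
saturated fits still yield usable thresholds.

**Fisher exact.** Two-sided by the minimum-likelihood convention: the sum
of hypergeometric probabilities (margins fixed) of all tables no more
probable than the observed one, with a 1+1e−9 tolerance against floating
ties. Degenerate margins give p = 1. This matches scipy's convention,
which the tests use as an oracle.

**Chi-square.** Pearson Σ(O−E)²/E with df = (R−1)(C−1); zero margins are
an error (callers fall back to Fisher).

**Correlation.** Pearson, and Spearman as Pearson on midranks; p by the
t approximation with n−2 df; |r| = 1 reports p = 0.

## Preprocessing

Order of operations: detection filter → half-minimum imputation →
quantile normalization → log2. Imputation needs per-protein minima on the
linear scale and normalization assumes a complete matrix, which fixes the
order. Details:

- The detection filter keeps proteins observed in ≥ `min_frac` (default
  0.5) of **all** samples — a protein seen in exactly half the samples is
  retained.
- Imputation replaces each missing cell with half the protein's minimal
  observed value — the standard treatment when missingness is
  detection-limit censoring, which is exactly how the synthetic generator
  produces it.
- Quantile normalization maps each column onto the across-column mean of
  order statistics; ties within a column receive the mean of the target
  quantiles they span, so within-column rank order is preserved and a
  second application is a no-op.

## Differential analysis

Per-protein two-sample tests on the preprocessed log2 matrix. The default
is the equal-variance Student *t*; a moderated *t* shrinks per-protein
variances toward a pooled prior whose hyperparameters (prior df d₀ and
prior variance s₀²) are estimated by method of moments from the observed
variance distribution (s²/s₀² ~ F(d, d₀)). Fold changes are ratios of
**linear-scale** group means of the imputed data; the significance rule is
fold change > 1.2 or < 1/1.2 together with raw P < 0.05. No multiple-testing
correction by default (Benjamini–Hochberg behind a flag): the rule is a
screening criterion whose false-positive rate the tests calibrate
explicitly on null cohorts.

A note on the moderated test: shrinkage never fully vanishes at finite
replication, so moderated and Student p-values agree only asymptotically;
at 100 samples per group borderline p-values can still differ by a few
hundredths. The test suite asserts the convergence, not an arbitrary
equality.

## Signatures and risk indices

**Occurrence arm.** Among significant differential proteins, the
discriminative score is max(AUC, 1−AUC) for peritumor vs normal. Proteins
at or above `auc_min` (default 0.8) are kept, capped at 40. At a cohort of
95 samples many strong proteins tie at AUC = 1.0, so ties are broken by the
differential p-value (a weight surrogate) and then protein ID — marker
selection "by AUC and weight".

**Progression arm.** Each significant protein is median-split over the
peritumor cohort (values at the median go low) and the two survival curves
compared by log-rank; proteins with p ≤ 0.05 are kept, ranked by p, capped
at 52. The protein's risk direction is the sign of the log-rank O−E of the
high-abundance arm: "up" means high abundance carries excess deaths. This
matters — orienting progression proteins by their fold-change direction
instead produces a risk index that *anti*-correlates with planted hazard
on synthetic cohorts.

**Risk index.** Per patient and protein: weight × abundance rescaled to
[0, 10] across the peritumor cohort, reversed for risk-decreasing
proteins; weights are 2·(AUC−0.5) (occurrence) or −log₁₀ p capped at 4
(progression). Category RIs sum within each of the six factor categories;
the total RI sums all; the cohort median splits RI-high (> median) from
RI-low. The weighted, direction-aligned, rescaled sum is this package's
parameterized construction of a risk index — published RI ranges from
other datasets are not comparable numerically, and the package makes no
claim to reproduce them.

Category annotation is an input map (protein → category). The synthetic
generator annotates every protein; for real data the user supplies the map
and unannotated proteins are dropped from signatures with a warning.

## Prediction models

The **occurrence model** is a logistic regression of group on the log2
abundances of a three-marker panel, thresholded at the Youden-optimal
fitted probability. Validation applies the frozen coefficients to an
external cohort — never a refit.

The **prognostic index** is the Cox linear predictor of a three-marker
panel on the peritumor cohort, median-split for Kaplan–Meier and log-rank
evaluation. Its ROC uses death before the cohort's median follow-up as the
positive outcome; subjects censored before that horizon are uninformative
and excluded (their count is reported alongside).

The **cross-evaluation** scores every signature protein on both criteria
(occurrence-discriminative: max(AUC, 1−AUC) ≥ 0.8; progression-associated:
median-split log-rank p ≤ 0.05) and tests the arm × criterion four-fold
tables with chi-square and Fisher exact tests (Fisher only when a margin
is empty).

## Consensus subtyping

The NMF uses multiplicative updates for the Frobenius objective
(generalized Kullback–Leibler behind a flag), uniform(0,1]-scaled
initialization deterministic in the seed, stopping at relative error
change < 1e−6 or 2000 iterations. Multiplicative updates are monotone but
crawl near an exact optimum; exact-recovery tests disable the relative
stop and spend iterations instead.

Consensus clustering runs `n_runs` (default 50) seeded restarts per k
(default 2–6) on the significant differential proteins × peritumor
samples (log2 matrix shifted by its global minimum into the non-negative
orthant; at scale, the 300 most variable significant proteins). Each run
assigns samples to their argmax metagene; co-assignment frequencies form
the consensus matrix. The chosen k maximizes the cophenetic correlation of
the consensus; CDF areas and their increments are reported so the
alternative convention can be applied. Final labels come from
average-linkage hierarchical clustering of 1 − consensus. A run is flagged
"weak structure" when the proportion of ambiguous consensus entries
(PAC, entries in (0.1, 0.9)) exceeds 0.3 at the chosen k — on
structure-free input the flag fires; on planted three-block cohorts PAC is
≈ 0.

## Synthetic cohorts

The generator (`pmekit.simulate`) draws, per protein, a base log2
abundance ~ N(20, 2) and a noise SD ~ U(0.3, 0.8), then plants:

- **Differential proteins** (default 300 of 5000): signed linear fold
  changes U(1.5, 4) applied to the 61 peritumor samples (34 normal,
  matching the study layout).
- **Occurrence markers** (40): fold change fixed at 3 with SD 0.2, planted
  on above-median-abundance differential proteins — practical biomarkers
  are reliably detected and distinctly the strongest discriminators.
- **Progression markers** (52, sharing 3 with the occurrence arm):
  per-marker log-hazard magnitudes U(0.1, 0.3) with random signs acting on
  standardized abundance; progression-only markers get a modest fold
  change (1.5) so they carry survival signal without doubling as strong
  occurrence discriminators — the arms are planted arm-specific, as the
  cross-evaluation assumes. Survival is exponential proportional hazards
  with baseline median 400 days and independent exponential censoring
  (~30% censored). The aggregate linear-predictor SD is ≈ 1.5: 52
  markers each with a large marginal hazard would imply survival spreads
  no cohort shows, so the defaults keep the per-marker effects modest and
  the recovery tests plant explicit strong `hazard_betas` on small panels.
- **Subtypes** (3 latent classes): disjoint blocks of ~40 differential
  proteins shifted by +1.5 log2 units in that subtype's samples.
- **Missingness**: per sample, values below a ~10% abundance quantile are
  censored (missing-not-at-random, low-abundance biased), with slightly
  higher detection in peritumor tissue.
- **Clinical covariates**: AFP, CYP2E1 activity, cirrhosis stage, tumor
  diameter and multiplicity are coupled to the planted risk burden
  (occurrence burden + survival linear predictor) through a Gaussian
  copula with ρ = 0.5 — the real joint distribution is unpublished, so
  these strengths are free parameters chosen to give qualitatively
  realistic associations, not estimates.

What passing tests on these cohorts shows: the pipeline recovers planted
structure of the assumed form at the study's sample sizes, and its tests
are calibrated under the null. What it does not show: robustness to batch
effects, peptide-level artifacts, non-proportional hazards, informative
censoring, correlated protein blocks beyond the planted subtypes, or any
claim about the real cohort's specific proteins.

## Reproducibility conventions

One global seed fans out to per-stage seeds via `numpy.random.SeedSequence`;
every iterative fit is deterministic given its inputs; rerunning the
pipeline with the same configuration produces byte-identical summary JSON.
Problem sizes in the acceptance script (5000 × 95 pipeline cohort; n = 500
Cox and n = 2000 logistic recovery; 10 × 61-patient prognostic cohorts;
consensus on the 200 most variable significant proteins with 30 restarts,
k ≤ 5) were chosen so the whole script completes in well under a minute
while keeping every estimate's sampling error far below the tolerances
being checked.

## Known limitations

- The moderated-t prior uses method-of-moments rather than profile
  likelihood; with few proteins the prior df estimate is noisy.
- The Cox implementation handles ties by Breslow only; heavy ties at few
  distinct event times will bias |β| slightly toward zero.
- PAC and cophenetic thresholds for "weak structure" are conventions, not
  calibrated error rates.
- The occurrence model's training metrics on strongly planted synthetic
  markers saturate (AUC = 1.0); they exercise the machinery, not a
  realistic difficulty level.
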