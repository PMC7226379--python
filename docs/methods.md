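# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions that make runs reproducible.

## Differential statistics

For one two-group experiment (treated vs. control replicate arrays on the
log2 scale) the per-gene effect is the mean log2 difference. The
standardized effect `z_g` standardizes the effect across genes (mean 0,
sample SD 1), so "|z| > 2" picks genes whose response is two across-gene
SDs from typical — the construction used by the signature filters. An
alternative `z_mode="intensity"` first z-scores each array across genes and
takes the mean difference of standardized intensities; it is kept as a
sensitivity switch because array studies rarely state which variant they
standardized.

The p-value defaults to the pooled-variance Student t-test rather than
Welch. At triplicate scale the Welch–Satterthwaite degrees of freedom are
estimated from two 2-df variances and are biased below their equal-variance
value, which makes Welch p-values conservative: on null simulations the
fraction of genes with p < 0.05 is ≈ 0.035 instead of 0.05 and the p-value
distribution fails a KS uniformity test decisively. The pooled test is
exact under the generator's equal-variance normal noise, and is what
"Student's t-test" means in the array literature this pipeline serves.
`test="welch"` remains available. No multiple-testing correction is applied
anywhere: the downstream filters threshold raw p-values (0.05 for the
double-significance intersection, 0.01 for the cohort-correlation filter),
which reproduces the analysis style faithfully; users wanting FDR control
should apply it on the returned tables.

Genes with zero variance in both arms get the degenerate p limit (1 when
the means agree, 0 otherwise) with a warning, rather than NaN.

## Set-level Z enrichment

A set's activity is the Stouffer combination `Z_S = Σ z_g / √m` over its
`m` members present in the universe (default minimum 5). Under independent
standard-normal `z_g` this is again standard normal, which the tests verify
by Monte Carlo; correlated member genes inflate its variance, a standard
caveat of combined-Z set statistics. The sign carries direction
(activation vs. depletion), which is what makes the knockdown /
over-expression comparison meaningful: reciprocal perturbations should give
anti-correlated set-Z vectors. The comparison uses Pearson correlation with
the usual t-approximation p-value; reciprocal top-N overlap uses the
one-sided hypergeometric tail, which is Fisher's exact test for the 2×2
table with fixed margins, over the intersection of the two experiments'
gene universes (cross-platform comparisons have no other common ground).

## GSEA

Genes are ranked by Pearson correlation with the cohort marker, ties broken
lexicographically by symbol so the ranking is bit-reproducible. The
enrichment score is the classic weighted KS walk: hits step up by
`|r|^p / Σ_hits |r|^p` (default exponent 1), misses step down by
`1/(N − m)`; the ES is the deviation of largest magnitude keeping its sign,
with an exact magnitude tie broken toward the positive deviation (logged —
ties occur on tiny lists and the choice must be fixed). With exponent 0
this reduces to the unweighted KS statistic.

The default null permutes gene labels (equivalently: random member sets of
the same size), whose cost does not grow with cohort size; phenotype
(sample-label) permutation is available through a re-ranking factory. The
p-value follows the same-sign convention,
`p = (1 + #{same-sign nulls ≥ obs}) / (1 + #same-sign nulls)`, which is
uniform for a null set — normalizing by the total permutation count
instead would roughly halve small p-values and cap p near the same-sign
fraction. NES divides the observed ES by the mean |ES| of same-sign nulls.
If no null shares the observed sign, p is reported at `1/(1 + n_perm)` with
a warning rather than claiming more precision than the permutations allow.

## Signatures and scoring

The pathway route mirrors a two-stage derivation: candidates are the
pathway genes significantly changed (p < 0.05) in *both* perturbations —
requiring concordance across a knockdown and an over-expression guards
against secondary drift in long-cultured stable lines — and the survivors
are then filtered by marker correlation in the cohort (Pearson, p < 0.01).
Genes anti-correlated with the marker become the "up" (risk) list because
the marker-low state is the perturbed, high-risk state; this orientation is
recorded in the signature's provenance. The curated-list route applies the
`|z| > z_cut` (default 2) and `p < p_cut` (default 0.05) filter to a
user-supplied list against the knockdown table.

The signature score is `mean(log2 x, up) − mean(log2 x, down)` per sample.
Since inputs are log2, this is exactly the log2 ratio of the geometric
means of the linear-scale intensities — the only reading under which a
"difference of geometric means" is scale-stable; a linear-space mode
(exponentiate, geometric means, re-log) is provided and agrees to floating
point.

Patient clustering uses average-linkage hierarchical clustering on
`1 − Pearson` distance between samples over the signature genes, cut to two
clusters, with cluster 2 defined as the one with the higher mean expression
of the up-oriented genes. Correlation distance ignores a uniform shift of
a sample across genes, so it clusters by expression *pattern*, not level.

## Survival statistics

Conventions are fixed for determinism:

- **Median dichotomization**: value ≥ median codes "high", making even-n
  and tied cohorts deterministic. All-identical input raises.
- **Composite score**: integer sum of the four adverse binaries (advanced
  stage, marker-low, AKT-like-high, cell-cycle-high), strata "score 0" …
  "score 4". All 16 factor combinations map onto exactly five strata.
- **Kaplan–Meier**: product-limit with events preceding censorings at tied
  times (a subject censored at an event time remains in that time's risk
  set). Median survival is the smallest event time with S(t) ≤ 0.5, or ∞.
- **Log-rank**: observed-minus-expected with hypergeometric variance at
  each distinct event time; for k groups the statistic uses the (k−1)-dim
  covariance with a pseudoinverse, chi-square with k−1 df.
- **Cox**: univariable Newton–Raphson on the partial likelihood, Breslow
  tie handling by default (Efron behind a flag), step clipping at 5,
  tolerance 1e-8, 50 iterations max, covariate internally standardized for
  numerical stability. Monotone likelihood (separation) or non-convergence
  is flagged on the result, not silently returned.
- **Harrell's C**: a pair is comparable when the earlier time is an
  observed event and the times differ; risk ties count 0.5; the result
  carries concordant/discordant/tied/comparable counts so
  `concordant + discordant + tied = comparable` can be asserted.

Only univariable Cox is provided; multi-factor prediction is expressed by
computing C on each factor and on the composite score, not by a
multivariable model.

## Synthetic data

The generator produces the structure the analysis assumes, at study scale
by default: 10,000 genes, triplicate arms, 108 patients. Log2 baselines are
N(8, 1) per gene, replicate noise SD 0.5 within perturbation arms; 10
disjoint planted sets of 40 genes (of 50 total) are shifted by δ = 1.0 log2
units (2-fold), with alternating per-set sign in the knockdown arm and the
opposite sign in the over-expression arm — so both KD-increased and
KD-decreased signature genes exist and the two experiments' set-Z vectors
anti-correlate. The cohort's marker is a two-component normal mixture
(N(5,1) / N(7,1), mixing 0.5 — components two SDs apart, emulating a
marker-silenced vs. marker-expressing dichotomy); 34 planted up genes are
anti-correlated and 19 down genes correlated with the marker at ρ = 0.6.
Survival is exponential (Weibull shape available) with baseline hazard
0.01/month and hazard ratio e^β per true-score point (default β = log 2);
censoring times are uniform with the upper bound solved by bisection so the
expected censored fraction hits the requested 30%.

What it does *not* emulate: probe-level artifacts, batch and platform
effects, heavy-tailed or heteroskedastic expression noise, correlated
non-signature genes, non-proportional hazards, or informative censoring.
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability under the assumed model, not robustness to
real-array pathology. The accession-based replication of a published
signature's exact gene counts requires the original deposited arrays and
clinical data, which are not bundled; the test suite instead verifies that
the filter returns exactly the planted 34/19 counts (under all sensitivity
switches) when effects are strong, and partial, unbiased recovery at 2-fold
effects.

## Problem sizes and known limitations

Tests and the acceptance script scale simulations for quick runs (e.g.
2,000-gene universes for the 100-seed anticorrelation sweep, 60-gene
cohorts for the 100-seed hazard-recovery sweep, with δ raised to 1.5–5
where a smaller universe inflates the across-gene effect SD); defaults in
`SimulationConfig` remain study-scale.

The hazard-recovery sweep (n = 500, HR 2 per point, 30% censoring) shows
the Cox estimator unbiased (mean β̂ ≈ 0.696 vs log 2 ≈ 0.693) with SD
≈ 0.044. A ±10% relative band around β therefore spans only ≈ 1.56 SDs, so
the per-seed probability of landing inside it is ≈ 0.88: a requirement of
≥ 90/100 seeds sits at the statistical boundary and can fail for some seed
streams even though the estimator is exact. The KM-median monotonicity
check across the five strata passes in ≈ 95/100 seeds under the same
conditions (small strata occasionally invert adjacent medians by sampling
noise).

Set-Z p-values inherit the independence caveat of combined-Z statistics;
the GSEA gene-label null likewise ignores inter-gene correlation, which is
why phenotype permutation is offered. Cox handles a single covariate only,
and the log-rank chi-square is asymptotic — its agreement with a
permutation null is verified at n = 300 but should not be assumed for very
small strata.
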