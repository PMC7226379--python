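# sigmark

Perturbation-derived gene signatures and composite prognostic scoring, with
survival evaluation — a reusable implementation of an analytic chain common
in tumor-biology studies that pair reciprocal cell-line perturbations of a
regulator (knockdown and over-expression) with a patient cohort.

The motivating setting is a regulator such as the Pol III noncoding RNA
nc886, which is epigenetically silenced in a fraction of esophageal squamous
cell carcinomas: its loss activates growth pathways (AKT, G1/S cell-cycle
genes), and gene signatures derived from the perturbation experiments can be
combined with pathologic stage and the marker itself into a composite score
that stratifies patient survival. Everything here works on symbol-keyed
log2 expression matrices, GMT gene-set collections, and a per-patient
clinical table, so the chain applies to any regulator/cohort pairing with
that shape.

## What it computes

- **Per-gene differential statistics** for a two-group experiment:
  effect `e_g = mean(treated) − mean(control)` (log2 fold change),
  across-gene standardized effect `z_g = (e_g − ē)/SD(e)`, and a two-sided
  Student's t p-value (Welch behind a switch).
- **Gene-set Z enrichment** (Stouffer combination):
  `Z_S = Σ_{g∈S} z_g / √|S|`, compared between two experiments by Pearson
  correlation of the set-Z vectors, plus reciprocal top-N overlap with a
  one-sided hypergeometric (Fisher) tail.
- **GSEA**: genes ranked by Pearson correlation with a continuous marker;
  weighted Kolmogorov–Smirnov enrichment score
  `ES = signed max_i (P_hit(i) − P_miss(i))` with `|r|^p` hit weights and a
  same-sign permutation p-value and NES.
- **Signature derivation**: (a) pathway route — pathway ∩ genes significant
  in both perturbations, then a cohort marker-correlation filter that splits
  survivors into up (anti-correlated, risk) and down lists; (b) curated-list
  route — `z > 2 & p < 0.05` up, `z < −2 & p < 0.05` down.
- **Signature score** per sample: difference of log2-space means of the up
  and down lists — the log2 ratio of geometric means on the linear scale.
- **Composite prognostic score** 0–4: one point each for advanced stage
  (TNM III–IV), below-median marker, above-median AKT-like score,
  above-median cell-cycle-like score.
- **Survival statistics**: Kaplan–Meier product-limit curves, k-sample
  log-rank test, univariable Cox regression (Newton–Raphson on the Breslow
  partial likelihood; Efron optional), and Harrell's concordance index with
  explicit pair accounting.
- **Synthetic cohorts**: a generator producing paired perturbation
  experiments with opposite-direction planted set effects, and a cohort
  with a bimodal marker, marker-correlated signature genes, and exponential
  survival with hazard `λ·exp(β·score)` — every output a pure function of
  the config and seed.

## Worked example

`examples/03_prognostic_survival.py` simulates a 108-patient cohort with a
true hazard ratio of 2 per score point and evaluates the composite score:

```
108 patients, 80 events (26% censored)
  score 0: n =  20, KM median survival   62.4 mo
  score 1: n =  31, KM median survival   34.0 mo
  score 2: n =   5, KM median survival   10.7 mo
  score 3: n =  27, KM median survival    5.9 mo
  score 4: n =  25, KM median survival    5.2 mo
log-rank across strata: chi2 = 63.2 (df 4), p = 6.06e-13
Cox per score point: HR = 1.98 (beta = 0.683 +- 0.096, Wald p = 1.06e-12)
Harrell's C (stage): 0.525 over 4897 comparable pairs
Harrell's C (composite score): 0.715 over 4897 comparable pairs
```

Median survival falls monotonically with the score, the fitted hazard ratio
(1.98) recovers the simulated truth (2.0), and the composite score
discriminates outcomes (C = 0.715) far better than stage alone (0.525).
The other examples cover the reciprocal-perturbation enrichment comparison
(`01`) and signature derivation plus GSEA (`02`).

A command-line front end wraps the same chain:

```sh
sigmark run-all --seed 7 --out-dir demo_run        # end-to-end demo
sigmark simulate --seed 7 --out-dir inputs         # write synthetic inputs
sigmark diff --expr inputs/expr_kd.tsv --treated KD_T1,KD_T2,KD_T3 \
        --control KD_C1,KD_C2,KD_C3 --out diff_kd.tsv
```

`run-all` writes every intermediate table plus a `summary.json` that is
byte-identical across reruns with the same config and seed.

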