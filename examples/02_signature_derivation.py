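"""Deriving gene signatures and scoring a patient cohort.

Two derivation routes: (1) filter a curated gene list by the knockdown's
standardized effect (|z| > 2, p < 0.05); (2) intersect a pathway's genes
with the genes significant in both perturbations, then keep those whose
cohort expression correlates with the continuous marker (p < 0.01). The
signature score per patient is the difference of log2-space means between
the up and down lists, i.e. the log2 ratio of geometric means. A GSEA run
confirms the up (risk) genes crowd the marker-anticorrelated end of the
cohort ranking.
"""

from sigmark import (
    GeneSet,
    SimulationConfig,
    derive_list_signature,
    derive_pathway_signature,
    differential_table,
    permutation_p,
    rank_by_marker_correlation,
    signature_score,
    simulate_patient_cohort,
    simulate_perturbation_pair,
)

cfg = SimulationConfig(seed=7)
expr_kd, expr_exp, sets, truth = simulate_perturbation_pair(cfg)
expr_cohort, cohort, truth_c = simulate_patient_cohort(cfg)

diff_kd = differential_table(expr_kd, truth["treated"]["KD"], truth["control"]["KD"])
diff_exp = differential_table(expr_exp, truth["treated"]["EXP"], truth["control"]["EXP"])

# route 1: curated list (planted signature genes plus unresponsive decoys)
curated = truth_c["up_genes"] + truth_c["down_genes"]
decoys = [g for g in expr_kd.gene_ids
          if g not in set(truth["planted_genes"])][:184 - len(curated)]
sig = derive_list_signature(curated + decoys, diff_kd, z_cut=2.0, p_cut=0.05,
                            name="akt_like")
print(f"curated-list signature: {len(sig.up_genes)} up / "
      f"{len(sig.down_genes)} down genes pass |z| > 2 and p < 0.05")

# route 2: pathway intersection with the cohort-correlation filter
pathway = GeneSet("G1_like", "planted pathway demo",
                  truth_c["up_genes"][:10] + truth_c["down_genes"][:10]
                  + decoys[:20])
sig_pw = derive_pathway_signature(pathway, diff_kd, diff_exp,
                                  expr_cohort, cohort, name="g1_like")
print(f"pathway signature: {sig_pw.provenance['n_candidates_stage1']} "
      f"doubly-significant candidates -> {len(sig_pw.up_genes)} up / "
      f"{len(sig_pw.down_genes)} down after the cohort-correlation filter")

scores = signature_score(expr_cohort, sig)
print(f"signature scores for {len(scores.scores)} patients: "
      f"mean {scores.scores.mean():+.2f}, SD {scores.scores.std():.2f} (log2 units)")

ranked = rank_by_marker_correlation(expr_cohort, cohort)
res = permutation_p(ranked, GeneSet("risk_up", "", sig.up_genes),
                    n_perm=1000, seed=7)
print(f"GSEA of the up (risk) genes vs marker ranking: ES = {res.es:+.3f}, "
      f"p = {res.p_perm:.3g}")
print("  -> negative ES: risk genes are highest where the marker is lowest")
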