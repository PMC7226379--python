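"""End-to-end orchestration of the analytic chain.

``run_full`` drives: per-gene differential statistics for the two
perturbation experiments -> set-level Z enrichment and the between-
experiment comparison -> reciprocal top-N overlap -> signature derivation
(pathway route and curated-list route) -> per-patient signature scores ->
marker-ranked GSEA of the derived up-list -> composite prognostic score and
survival statistics (KM per stratum, log-rank, univariable Cox, Harrell's C
per factor and for the composite). Every intermediate table is written to
the output directory along with a machine-readable ``summary.json``; the
run is a pure function of the config, so re-running reproduces the summary
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, differential, enrichment, gsea, signature, simulate, survival

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and settings for one full run.

    When the input paths are left unset the pipeline generates synthetic
    inputs from ``sim`` (the demo mode). Thresholds default to the analysis'
    standard values: per-gene p < 0.05, cohort-correlation p < 0.01,
    signature |z| > 2, set-Z cutoff 3, minimum set size 5, top-1000 overlap
    lists.
    """

    out_dir: str = "sigmark_run"
    seed: int = 7

    # file inputs (all-or-none; unset -> simulate)
    expr_kd_path: str | None = None
    expr_exp_path: str | None = None
    gmt_path: str | None = None
    expr_cohort_path: str | None = None
    clinical_path: str | None = None
    curated_list_path: str | None = None
    pathway_set_name: str | None = None
    treated_kd: list[str] = field(default_factory=list)
    control_kd: list[str] = field(default_factory=list)
    treated_exp: list[str] = field(default_factory=list)
    control_exp: list[str] = field(default_factory=list)

    # thresholds
    p_cut: float = 0.05
    p_cut_corr: float = 0.01
    z_cut: float = 2.0
    set_z_cutoff: float = 3.0
    min_set_size: int = 5
    top_n: int = 1000

    # GSEA
    gsea_weight: float = 1.0
    n_perm: int = 1000
    gsea_mode: str = "gene-label"

    make_plots: bool = False

    sim: simulate.SimulationConfig | None = None

    def __post_init__(self) -> None:
        for name in ("p_cut", "p_cut_corr", "z_cut", "set_z_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_set_size < 1 or self.top_n < 1:
            raise ValueError("min_set_size and top_n must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            cfg.sim = simulate.SimulationConfig.from_dict(sim_raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _load_or_simulate(cfg: PipelineConfig):
    file_inputs = [cfg.expr_kd_path, cfg.expr_exp_path, cfg.gmt_path,
                   cfg.expr_cohort_path, cfg.clinical_path]
    if any(file_inputs):
        missing = [p for p in file_inputs if p and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"input file(s) not found: {missing}")
        if not all(file_inputs):
            raise ValueError("provide all five input paths or none (demo mode)")
        expr_kd = data_io.read_expression_matrix(cfg.expr_kd_path)
        expr_exp = data_io.read_expression_matrix(cfg.expr_exp_path)
        sets = data_io.parse_gmt(cfg.gmt_path)
        expr_cohort = data_io.read_expression_matrix(cfg.expr_cohort_path)
        cohort = data_io.read_clinical_table(cfg.clinical_path)
        curated = (data_io.read_gene_list(cfg.curated_list_path)
                   if cfg.curated_list_path else [])
        groups = {
            "treated_kd": cfg.treated_kd, "control_kd": cfg.control_kd,
            "treated_exp": cfg.treated_exp, "control_exp": cfg.control_exp,
        }
        for name, grp in groups.items():
            if len(grp) < 2:
                raise ValueError(f"{name} needs >= 2 sample ids in the config")
        pathway_name = cfg.pathway_set_name or sets.names[0]
        pathway = sets[pathway_name]
        return (expr_kd, expr_exp, sets, expr_cohort, cohort, curated, pathway,
                groups, None)

    sim_cfg = cfg.sim or simulate.SimulationConfig(seed=cfg.seed)
    expr_kd, expr_exp, sets, truth_pert = simulate.simulate_perturbation_pair(sim_cfg)
    expr_cohort, cohort, truth_cohort = simulate.simulate_patient_cohort(sim_cfg)
    groups = {
        "treated_kd": truth_pert["treated"]["KD"],
        "control_kd": truth_pert["control"]["KD"],
        "treated_exp": truth_pert["treated"]["EXP"],
        "control_exp": truth_pert["control"]["EXP"],
    }
    # curated list: the planted signature genes plus unresponsive decoys
    curated = truth_cohort["up_genes"] + truth_cohort["down_genes"]
    planted_all = set(truth_pert["planted_genes"])
    decoys = [g for g in expr_kd.gene_ids if g not in planted_all][: len(curated)]
    curated = curated + decoys
    # demo pathway set: a mixed slice of planted up/down genes plus decoys
    pathway = data_io.GeneSet(
        name="DEMO_PATHWAY", description="synthetic pathway with planted genes",
        members=(truth_cohort["up_genes"][:10] + truth_cohort["down_genes"][:10]
                 + decoys[:20]),
    )
    truth = {"perturbation": truth_pert, "cohort": truth_cohort}
    return (expr_kd, expr_exp, sets, expr_cohort, cohort, curated, pathway,
            groups, truth)


def run_full(cfg: PipelineConfig) -> dict:
    """Execute the full analysis and write results under ``cfg.out_dir``.

    Returns the summary dict (also written as ``summary.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "parameters": {
        "p_cut": cfg.p_cut, "p_cut_corr": cfg.p_cut_corr, "z_cut": cfg.z_cut,
        "set_z_cutoff": cfg.set_z_cutoff, "min_set_size": cfg.min_set_size,
        "top_n": cfg.top_n, "gsea_weight": cfg.gsea_weight, "n_perm": cfg.n_perm,
    }}

    logger.info("stage: inputs")
    (expr_kd, expr_exp, sets, expr_cohort, cohort, curated, pathway, groups,
     truth) = _load_or_simulate(cfg)
    if truth is not None:
        with open(out / "truth.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
    summary["inputs"] = {
        "n_genes_kd": len(expr_kd.gene_ids), "n_genes_exp": len(expr_exp.gene_ids),
        "n_sets": len(sets), "n_patients": len(cohort),
        "n_curated": len(curated), "pathway_set": pathway.name,
    }

    logger.info("stage: differential")
    diff_kd = differential.differential_table(expr_kd, groups["treated_kd"],
                                              groups["control_kd"])
    diff_exp = differential.differential_table(expr_exp, groups["treated_exp"],
                                               groups["control_exp"])
    diff_kd.to_tsv(out / "differential_kd.tsv")
    diff_exp.to_tsv(out / "differential_exp.tsv")

    logger.info("stage: set enrichment")
    zt_kd = enrichment.set_z_scores(diff_kd, sets, min_size=cfg.min_set_size)
    zt_exp = enrichment.set_z_scores(diff_exp, sets, min_size=cfg.min_set_size)
    zt_kd.to_tsv(out / "set_z_kd.tsv")
    zt_exp.to_tsv(out / "set_z_exp.tsv")
    comp = enrichment.compare_z_vectors(zt_kd, zt_exp)
    act_kd, dep_kd = enrichment.select_significant_sets(zt_kd, cfg.set_z_cutoff)
    act_exp, dep_exp = enrichment.select_significant_sets(zt_exp, cfg.set_z_cutoff)
    n_common = len(diff_kd.table.index.intersection(diff_exp.table.index))
    top_n = min(cfg.top_n, n_common // 2)
    if top_n < cfg.top_n:
        logger.warning("top_n reduced to %d for a universe of %d genes",
                       top_n, n_common)
    ov = enrichment.top_n_overlap_test(diff_kd, diff_exp, top_n,
                                       direction_a="up", direction_b="down")
    summary["set_enrichment"] = {
        "z_comparison_r": comp.r, "z_comparison_p": comp.p, "n_common_sets": comp.n,
        "activated_kd": act_kd, "depleted_kd": dep_kd,
        "activated_exp": act_exp, "depleted_exp": dep_exp,
        "top_n": top_n, "overlap": ov.overlap, "overlap_p": ov.p,
    }

    logger.info("stage: signatures")
    sig_pathway = signature.derive_pathway_signature(
        pathway, diff_kd, diff_exp, expr_cohort, cohort,
        p_cut=cfg.p_cut, p_cut_corr=cfg.p_cut_corr, name="pathway_signature")
    if curated:
        sig_list = signature.derive_list_signature(
            curated, diff_kd, z_cut=cfg.z_cut, p_cut=cfg.p_cut,
            name="curated_signature")
    else:
        raise ValueError("no curated gene list available")
    gmt_lines = sig_pathway.to_gmt_lines() + sig_list.to_gmt_lines()
    with open(out / "signatures.gmt", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(gmt_lines) + "\n")
    summary["signatures"] = {
        "pathway_up": sig_pathway.up_genes, "pathway_down": sig_pathway.down_genes,
        "curated_up": sig_list.up_genes, "curated_down": sig_list.down_genes,
    }

    score_akt = signature.signature_score(expr_cohort, sig_list)
    cc_sig = sig_pathway if (sig_pathway.up_genes and sig_pathway.down_genes) else sig_list
    score_cc = signature.signature_score(expr_cohort, cc_sig)
    score_akt.to_tsv(out / "score_curated.tsv")
    score_cc.to_tsv(out / "score_pathway.tsv")

    logger.info("stage: GSEA")
    ranked = gsea.rank_by_marker_correlation(expr_cohort, cohort)
    up_set = data_io.GeneSet(name=f"{sig_list.name}_UP", description="derived up genes",
                             members=[g for g in sig_list.up_genes
                                      if g in set(ranked.gene_ids)])
    es_result = gsea.permutation_p(ranked, up_set, n_perm=cfg.n_perm,
                                   mode=cfg.gsea_mode, seed=cfg.seed,
                                   weight_exponent=cfg.gsea_weight)
    _, profile = gsea.enrichment_score(ranked, up_set, cfg.gsea_weight)
    pd.DataFrame({"position": np.arange(1, len(profile) + 1),
                  "deviation": profile}).to_csv(
        out / "gsea_profile.tsv", sep="\t", index=False)
    summary["gsea"] = {"set": up_set.name, "es": es_result.es, "nes": es_result.nes,
                       "p_perm": es_result.p_perm, "n_perm": es_result.n_perm}

    logger.info("stage: survival")
    t = cohort.table
    marker_high, marker_median = survival.dichotomize_by_median(t["marker"])
    akt_high, akt_median = survival.dichotomize_by_median(
        score_akt.scores.loc[t.index])
    cc_high, cc_median = survival.dichotomize_by_median(score_cc.scores.loc[t.index])
    factors = survival.composite_score(
        t["stage_group"].to_numpy(), 1 - marker_high, akt_high, cc_high,
        sample_ids=t.index)
    ftab = factors.table
    ftab.to_csv(out / "prognostic_factors.tsv", sep="\t")

    strata = {}
    for s in range(5):
        mask = (ftab["prognostic_score"] == s).to_numpy()
        label = f"score {s}"
        if mask.sum() == 0:
            strata[label] = {"n": 0, "median_survival": None}
            continue
        curve = survival.km_estimate(t["time"][mask], t["event"][mask])
        med = survival.median_survival(curve)
        strata[label] = {"n": int(mask.sum()),
                         "n_events": int(t["event"][mask].sum()),
                         "median_survival": None if np.isinf(med) else med}
        pd.DataFrame({"time": curve.times, "at_risk": curve.at_risk,
                      "survival": curve.survival}).to_csv(
            out / f"km_score{s}.tsv", sep="\t", index=False)

    lr_groups = ftab["prognostic_score"].to_numpy()
    lr = survival.log_rank_test(t["time"], t["event"], lr_groups)
    cox = survival.cox_univariable(t["time"], t["event"],
                                   ftab["prognostic_score"].to_numpy())
    c_results = {}
    for name, risk in [("stage", ftab["stage_group"]), ("marker_low", ftab["marker_low"]),
                       ("akt_high", ftab["akt_high"]), ("cc_high", ftab["cc_high"]),
                       ("composite", ftab["prognostic_score"])]:
        c = survival.harrell_c(t["time"], t["event"], risk.to_numpy())
        c_results[name] = c.c_index
    summary["survival"] = {
        "medians": {"marker": marker_median, "akt_score": akt_median,
                    "cc_score": cc_median},
        "strata": strata,
        "log_rank": {"chi_square": lr.chi_square, "df": lr.df, "p": lr.p},
        "cox_per_point": {"beta": cox.beta, "hr": cox.hr, "se": cox.se,
                          "wald_p": cox.wald_p, "converged": cox.converged},
        "c_index": c_results,
    }

    logger.info("stage: clustering")
    cluster_genes = (sig_pathway.up_genes + sig_pathway.down_genes) or \
        (sig_list.up_genes + sig_list.down_genes)
    if len([g for g in cluster_genes if g in expr_cohort.values.index]) >= 2:
        clusters = signature.cluster_two_groups(
            expr_cohort, cluster_genes,
            up_genes=sig_pathway.up_genes or sig_list.up_genes)
        clusters.to_frame().to_csv(out / "clusters.tsv", sep="\t")
        m1 = float(t["marker"][clusters.loc[t.index] == 1].mean())
        m2 = float(t["marker"][clusters.loc[t.index] == 2].mean())
        summary["clusters"] = {"n_cluster1": int((clusters == 1).sum()),
                               "n_cluster2": int((clusters == 2).sum()),
                               "marker_mean_cluster1": m1,
                               "marker_mean_cluster2": m2}

    if cfg.make_plots:
        from . import plotting

        curves = {}
        for s in range(5):
            mask = (ftab["prognostic_score"] == s).to_numpy()
            if mask.sum():
                curves[f"score {s}"] = survival.km_estimate(
                    t["time"][mask], t["event"][mask])
        plotting.plot_km_strata(curves, out / "km_strata.png")
        plotting.plot_z_comparison(comp, out / "set_z_scatter.png",
                                   xlabel="set Z (KD)", ylabel="set Z (EXP)")
        hits = [i + 1 for i, g in enumerate(ranked.gene_ids)
                if g in set(up_set.members)]
        plotting.plot_gsea_profile(profile, hits, out / "gsea_profile.png")

    with open(out / "summary.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out / "summary.json")
    return summary
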