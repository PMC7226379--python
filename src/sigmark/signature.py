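"""Gene-signature derivation, per-sample scoring, and two-group clustering.

Two derivation routes are provided. The pathway route intersects a pathway's
genes with the genes significantly altered in both of a pair of opposite
perturbations, then keeps those whose cohort expression is significantly
correlated with the continuous marker; genes anti-correlated with the marker
form the "up" (risk) list, positively correlated ones the "down" list (the
marker-low state is the high-risk state). The curated-list route filters a
curated gene list by the knockdown's standardized effect (|z| beyond a
cutoff) and p-value.

A signature score is the difference of log2-space means between the up and
down lists — the log2 ratio of geometric means on the linear scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_io import CohortTable, ExpressionMatrix, GeneSet
from .differential import DifferentialTable

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureDefinition",
    "ScoreTable",
    "derive_pathway_signature",
    "derive_list_signature",
    "signature_score",
    "cluster_two_groups",
]


@dataclass
class SignatureDefinition:
    """An up-list and a down-list of gene symbols with derivation provenance."""

    name: str
    up_genes: list[str]
    down_genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down lists overlap")

    @property
    def is_empty(self) -> bool:
        return not (self.up_genes or self.down_genes)

    def to_gmt_lines(self) -> list[str]:
        """Two GMT lines: <name>_UP and <name>_DOWN."""
        lines = []
        if self.up_genes:
            lines.append("\t".join([f"{self.name}_UP", "signature up genes", *self.up_genes]))
        if self.down_genes:
            lines.append("\t".join([f"{self.name}_DOWN", "signature down genes", *self.down_genes]))
        return lines


@dataclass
class ScoreTable:
    """Per-sample signature scores (log2 units); ``scores`` indexed by sample_id."""

    scores: pd.Series
    signature_name: str

    def to_tsv(self, path) -> None:
        df = self.scores.rename("score").to_frame()
        df["signature"] = self.signature_name
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            df.to_csv(fh, sep="\t", index_label="sample_id")


def _marker_correlations(
    expr: ExpressionMatrix, cohort: CohortTable, genes: Sequence[str]
) -> pd.DataFrame:
    shared = [s for s in cohort.sample_ids if s in expr.values.columns]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    marker = cohort.table.loc[shared, "marker"].to_numpy(dtype=float)
    rows = []
    for g in genes:
        x = expr.values.loc[g, shared].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(marker) == 0:
            rows.append((g, 0.0, 1.0))
            continue
        r, p = stats.pearsonr(x, marker)
        rows.append((g, float(r), float(p)))
    return pd.DataFrame(rows, columns=["gene_id", "r", "p"]).set_index("gene_id")


def derive_pathway_signature(
    pathway_set: GeneSet,
    diff_kd: DifferentialTable,
    diff_exp: DifferentialTable,
    expr_cohort: ExpressionMatrix,
    cohort: CohortTable,
    p_cut: float = 0.05,
    p_cut_corr: float = 0.01,
    name: str = "pathway_signature",
) -> SignatureDefinition:
    """Two-stage pathway signature.

    Stage 1: candidates = pathway genes significantly changed (p < ``p_cut``)
    in both perturbation tables. Stage 2: per candidate, Pearson correlation
    between cohort expression and the marker; keep p < ``p_cut_corr``.
    Marker-anticorrelated survivors become up (risk) genes, positively
    correlated ones down genes.
    """
    sig_kd = set(diff_kd.table.index[diff_kd.table["p"] < p_cut])
    sig_exp = set(diff_exp.table.index[diff_exp.table["p"] < p_cut])
    candidates = [g for g in pathway_set.members if g in sig_kd and g in sig_exp]
    if not candidates:
        raise ValueError("no candidate genes: pathway does not intersect the "
                         "doubly-significant genes")
    candidates = [g for g in candidates if g in expr_cohort.values.index]
    if not candidates:
        raise ValueError("no candidate genes present in the cohort matrix")

    corr = _marker_correlations(expr_cohort, cohort, candidates)
    kept = corr[corr["p"] < p_cut_corr]
    up = kept.index[kept["r"] < 0].tolist()
    down = kept.index[kept["r"] > 0].tolist()
    if not (up or down):
        logger.warning("no candidate passed the cohort-correlation filter "
                       "(p < %g); empty signature", p_cut_corr)
    return SignatureDefinition(
        name=name,
        up_genes=up,
        down_genes=down,
        provenance={
            "route": "pathway",
            "pathway_set": pathway_set.name,
            "p_cut": p_cut,
            "p_cut_corr": p_cut_corr,
            "n_candidates_stage1": len(candidates),
            "n_kept_stage2": int(len(kept)),
            "risk_orientation": "marker-anticorrelated genes are up/risk",
        },
    )


def derive_list_signature(
    curated_genes: Sequence[str],
    diff_kd: DifferentialTable,
    z_cut: float = 2.0,
    p_cut: float = 0.05,
    name: str = "list_signature",
) -> SignatureDefinition:
    """Filter a curated gene list by the knockdown's standardized effect.

    up = curated genes with z > ``z_cut`` and p < ``p_cut``;
    down = curated genes with z < -``z_cut`` and p < ``p_cut``.
    """
    if not curated_genes:
        raise ValueError("curated gene list is empty")
    t = diff_kd.table
    up, down = [], []
    for g in curated_genes:
        if g not in t.index:
            continue
        z, p = t.at[g, "z"], t.at[g, "p"]
        if p < p_cut and z > z_cut:
            up.append(g)
        elif p < p_cut and z < -z_cut:
            down.append(g)
    if not (up or down):
        logger.warning("no curated gene passed |z| > %g and p < %g", z_cut, p_cut)
    return SignatureDefinition(
        name=name,
        up_genes=up,
        down_genes=down,
        provenance={"route": "curated-list", "z_cut": z_cut, "p_cut": p_cut,
                    "n_curated": len(curated_genes)},
    )


def signature_score(
    expr: ExpressionMatrix,
    sig: SignatureDefinition,
    space: str = "log2",
) -> ScoreTable:
    """Per-sample signature score.

    With ``space="log2"`` (default) the score is
    mean(log2 x over up genes) - mean(log2 x over down genes), i.e. the log2
    ratio of geometric means of the linear-scale intensities.
    ``space="linear"`` exponentiates first, takes geometric means, and
    returns the log2 of their ratio — identical up to floating point, kept
    as an explicit sensitivity mode.
    """
    if space not in ("log2", "linear"):
        raise ValueError(f"unknown space {space!r}")
    up = [g for g in sig.up_genes if g in expr.values.index]
    down = [g for g in sig.down_genes if g in expr.values.index]
    missing = (len(sig.up_genes) - len(up)) + (len(sig.down_genes) - len(down))
    if missing:
        logger.warning("%d signature genes absent from the matrix", missing)
    if sig.up_genes and not up:
        raise ValueError("no up genes present in the matrix")
    if sig.down_genes and not down:
        raise ValueError("no down genes present in the matrix")
    if not up or not down:
        raise ValueError("signature needs at least one up and one down gene "
                         "present in the matrix")

    if space == "log2":
        score = expr.values.loc[up].mean(axis=0) - expr.values.loc[down].mean(axis=0)
    else:
        lin = 2.0 ** expr.values
        gm_up = np.exp(np.log(lin.loc[up]).mean(axis=0))
        gm_down = np.exp(np.log(lin.loc[down]).mean(axis=0))
        score = np.log2(gm_up / gm_down)
    return ScoreTable(scores=pd.Series(score, index=expr.values.columns, name="score"),
                      signature_name=sig.name)


def cluster_two_groups(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    up_genes: Sequence[str] | None = None,
) -> pd.Series:
    """Unsupervised two-cluster grouping of samples on a gene subset.

    Average-linkage hierarchical clustering with distance
    1 - Pearson correlation between samples, cut to exactly two clusters.
    The cluster with the higher mean expression of ``up_genes`` (default:
    all of ``genes``) is labeled 2, the other 1. Returns a Series mapping
    sample_id -> {1, 2}.
    """
    present = [g for g in genes if g in expr.values.index]
    if len(present) < 2:
        raise ValueError(f"need >= 2 genes present, got {len(present)}")
    if expr.shape[1] < 4:
        raise ValueError(f"need >= 4 samples, got {expr.shape[1]}")
    up = [g for g in (up_genes if up_genes is not None else present)
          if g in expr.values.index] or present

    x = expr.values.loc[present].to_numpy(dtype=float).T  # samples x genes
    corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce symmetry
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
    if len(set(labels)) == 1:  # degenerate tree (e.g. identical samples)
        labels = np.ones_like(labels)
        labels[: len(labels) // 2] = 2

    up_mean = expr.values.loc[up].mean(axis=0).to_numpy()
    mean1 = up_mean[labels == 1].mean()
    mean2 = up_mean[labels == 2].mean()
    if mean1 > mean2:  # relabel so cluster 2 is the up-high cluster
        labels = np.where(labels == 1, 2, 1)
    return pd.Series(labels, index=expr.values.columns, name="cluster")
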