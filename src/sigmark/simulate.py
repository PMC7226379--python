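"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators cover the pipeline's inputs, sharing one gene universe and
one planted design so the full analytic chain can run end to end:

* ``simulate_perturbation_pair`` — a knockdown-like and an over-expression-
  like experiment in which each planted gene set is shifted in one direction
  in the KD arm and the opposite direction in the EXP arm, so set-level
  Z-scores of the two experiments are anti-correlated, as expected for
  reciprocal perturbations of one regulator.
* ``simulate_patient_cohort`` — a cohort whose continuous marker is a
  two-component mixture (marker-silenced vs. marker-expressing tumors),
  whose planted signature genes correlate with the marker (KD-increased
  genes anti-correlated: the marker-low state is the perturbed, high-risk
  state), and whose survival times follow a proportional-hazards model in
  the composite prognostic score.

Every generator is a pure function of the config (including its seed): the
same SimulationConfig reproduces the same data bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .data_io import CohortTable, ExpressionMatrix, GeneSet, GeneSetCollection
from .survival import composite_score, dichotomize_by_median

__all__ = ["SimulationConfig", "simulate_perturbation_pair", "simulate_patient_cohort"]


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic experiments and cohort.

    Expression is on the log2 array scale: per-gene baselines ~
    Normal(baseline_mean, baseline_sd^2), replicate/sample noise with SD
    ``replicate_sd`` within perturbation arms and ``baseline_sd`` across
    patients. Planted sets are shifted by ``delta`` log2 units; planted set
    i carries direction (-1)^i in the KD-like arm (alternating, so both
    KD-increased and KD-decreased signature genes exist) and the opposite
    direction in the EXP-like arm.
    """

    # perturbation experiments
    n_genes: int = 10000
    n_replicates: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    replicate_sd: float = 0.5
    n_sets: int = 50
    set_size: int = 40
    n_planted_sets: int = 10
    delta: float = 1.0                  # log2 units (2-fold)

    # patient cohort
    n_patients: int = 108
    cohort_n_genes: int = 2000
    marker_means: tuple[float, float] = (5.0, 7.0)
    marker_sds: tuple[float, float] = (1.0, 1.0)
    marker_mix: float = 0.5             # fraction in the low (silenced) component
    rho: float = 0.6                    # planted signature-marker correlation
    n_sig_up: int = 34                  # KD-increased, marker-anticorrelated (risk)
    n_sig_down: int = 19                # KD-decreased, marker-correlated
    stage_prob: float = 0.5
    lambda0: float = 0.01               # baseline hazard per month
    beta_per_point: float = float(np.log(2.0))
    censoring_frac: float = 0.3
    weibull_shape: float = 1.0          # 1.0 = exponential baseline

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_sd", "replicate_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(s <= 0 for s in self.marker_sds):
            raise ValueError("marker SDs must be > 0")
        if not (0 <= self.censoring_frac < 1):
            raise ValueError("censoring_frac must be in [0, 1)")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if self.n_planted_sets > self.n_sets:
            raise ValueError("n_planted_sets exceeds n_sets")
        if self.n_sets * self.set_size > self.n_genes:
            raise ValueError("planted sets larger than the gene universe")
        if not -1 < self.rho < 1:
            raise ValueError("rho must be in (-1, 1)")
        if self.n_planted_sets >= 2:
            if self.n_sig_up > self.set_size or self.n_sig_down > self.set_size:
                raise ValueError("signature arm larger than set_size")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("marker_means", "marker_sds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _design(cfg: SimulationConfig):
    """Shared planted design: gene universe, disjoint sets, set directions.

    Deterministic in cfg.seed; used by both generators so that cohort
    signature genes coincide with perturbation-planted genes.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    shuffled = list(rng.permutation(genes))
    sets, directions = [], {}
    for i in range(cfg.n_sets):
        members = sorted(shuffled[i * cfg.set_size:(i + 1) * cfg.set_size])
        planted = i < cfg.n_planted_sets
        name = f"SET_{i:03d}"
        sets.append(GeneSet(name=name,
                            description="planted" if planted else "null",
                            members=members))
        if planted:
            directions[name] = 1 if i % 2 == 0 else -1
    return genes, GeneSetCollection(sets), directions


def _signature_genes(cfg: SimulationConfig, collection: GeneSetCollection,
                     directions: dict) -> tuple[list[str], list[str]]:
    """Planted signature: up genes from a KD-up set, down genes from a KD-down set."""
    up_sets = [n for n, d in directions.items() if d > 0]
    down_sets = [n for n, d in directions.items() if d < 0]
    up: list[str] = []
    for name in up_sets:
        up.extend(collection[name].members[: cfg.n_sig_up - len(up)])
        if len(up) >= cfg.n_sig_up:
            break
    down: list[str] = []
    for name in down_sets:
        down.extend(collection[name].members[: cfg.n_sig_down - len(down)])
        if len(down) >= cfg.n_sig_down:
            break
    if len(up) < cfg.n_sig_up or len(down) < cfg.n_sig_down:
        raise ValueError("not enough planted genes in both directions for the "
                         "requested signature sizes")
    return up, down


def simulate_perturbation_pair(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GeneSetCollection, dict]:
    """Two perturbation experiments with opposite-direction planted set effects.

    Returns ``(expr_kd, expr_exp, sets, truth)``. Each matrix holds
    2 * n_replicates samples (treated then control). Planted set i is
    shifted by dir_i * delta in the KD-like arm and -dir_i * delta in the
    EXP-like arm (dir_i alternates +1/-1 across planted sets); null sets
    are untouched. ``truth`` records planted sets, per-gene directions, and
    the sample groupings.
    """
    genes, collection, directions = _design(cfg)
    rng = np.random.default_rng(cfg.seed + 10_000)

    gene_dir = pd.Series(0, index=genes, dtype=int)
    for name, d in directions.items():
        gene_dir.loc[collection[name].members] = d
    shift = gene_dir.to_numpy() * cfg.delta

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    def one_experiment(sign: int, tag: str) -> ExpressionMatrix:
        n_r = cfg.n_replicates
        cols = [f"{tag}_T{i+1}" for i in range(n_r)] + [f"{tag}_C{i+1}" for i in range(n_r)]
        noise = rng.normal(0.0, cfg.replicate_sd, size=(cfg.n_genes, 2 * n_r))
        vals = baseline[:, None] + noise
        vals[:, :n_r] += sign * shift[:, None]
        return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=cols),
                                platform_tag=f"synthetic-{tag}")

    expr_kd = one_experiment(+1, "KD")
    expr_exp = one_experiment(-1, "EXP")
    truth = {
        "planted_sets": dict(directions),
        "planted_genes": sorted(gene_dir.index[gene_dir != 0]),
        "gene_direction_kd": {g: int(d) for g, d in gene_dir.items() if d != 0},
        "delta": cfg.delta,
        "treated": {"KD": expr_kd.sample_ids[: cfg.n_replicates],
                    "EXP": expr_exp.sample_ids[: cfg.n_replicates]},
        "control": {"KD": expr_kd.sample_ids[cfg.n_replicates:],
                    "EXP": expr_exp.sample_ids[cfg.n_replicates:]},
    }
    return expr_kd, expr_exp, collection, truth


def _calibrate_censoring(event_times: np.ndarray, frac: float) -> float:
    """Upper bound c of U(0, c) censoring giving expected censored fraction ``frac``.

    With C ~ U(0, c) independent of the realized event times T_i, the
    expected censored fraction is mean_i P(C < T_i) = mean_i min(T_i/c, 1),
    monotone decreasing from 1 to 0 in c, so bisection always succeeds for
    0 < frac < 1.
    """
    def expected(c: float) -> float:
        return float(np.mean(np.minimum(event_times / c, 1.0)))

    lo, hi = 1e-9, 1.0
    while expected(hi) > frac:
        hi *= 2.0
        if hi > 1e15:
            raise ValueError(f"censoring fraction {frac} unreachable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) > frac:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_patient_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, CohortTable, dict]:
    """A patient cohort with bimodal marker, planted signature genes, and
    proportional-hazards survival.

    The cohort's gene universe is a ``cohort_n_genes``-sized subset of the
    perturbation universe that contains all planted signature genes. Up
    (KD-increased) signature genes are anti-correlated with the marker at
    strength rho, down genes positively correlated, everything else is
    noise. The true composite score per patient sums advanced stage,
    below-median marker, above-median signature score, and above-median
    up-gene mean; survival times are Weibull (exponential by default) with
    hazard multiplied by exp(beta_per_point * score), censored by
    independent uniform times calibrated to ``censoring_frac``.
    """
    genes_all, collection, directions = _design(cfg)
    up_genes, down_genes = _signature_genes(cfg, collection, directions)
    n_sig = len(up_genes) + len(down_genes)
    if cfg.cohort_n_genes < n_sig:
        raise ValueError("cohort_n_genes smaller than the planted signature")

    sig_set = set(up_genes) | set(down_genes)
    universe = list(up_genes) + list(down_genes)
    for g in genes_all:
        if len(universe) >= cfg.cohort_n_genes:
            break
        if g not in sig_set:
            universe.append(g)
    order = sorted(range(len(universe)), key=lambda i: universe[i])
    genes = [universe[i] for i in order]
    sig_role = np.zeros(len(universe), dtype=int)      # +1 up, -1 down, 0 null
    sig_role[: len(up_genes)] = 1
    sig_role[len(up_genes): n_sig] = -1
    sig_role = sig_role[order]

    rng = np.random.default_rng(cfg.seed + 20_000)
    n = cfg.n_patients
    samples = [f"PT{i:03d}" for i in range(n)]

    low = rng.random(n) < cfg.marker_mix
    marker = np.where(
        low,
        rng.normal(cfg.marker_means[0], cfg.marker_sds[0], size=n),
        rng.normal(cfg.marker_means[1], cfg.marker_sds[1], size=n),
    )
    marker_std = (marker - marker.mean()) / marker.std()

    base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    noise = rng.normal(0.0, 1.0, size=(len(genes), n))
    rho, root = cfg.rho, np.sqrt(1.0 - cfg.rho ** 2)
    corr_sign = -sig_role.astype(float)               # up genes: r < 0 with marker
    scale = np.where(sig_role != 0, root, 1.0)
    vals = (base[:, None]
            + cfg.baseline_sd * (corr_sign[:, None] * rho * marker_std[None, :]
                                 + scale[:, None] * noise))

    vals_df = pd.DataFrame(vals, index=genes, columns=samples)
    up_mean = vals_df.loc[up_genes].mean(axis=0).to_numpy()
    down_mean = vals_df.loc[down_genes].mean(axis=0).to_numpy()
    sig_score = up_mean - down_mean

    stage = (rng.random(n) < cfg.stage_prob).astype(int)
    marker_high, _ = dichotomize_by_median(marker)
    sig_high, _ = dichotomize_by_median(sig_score)
    cc_high, _ = dichotomize_by_median(up_mean)
    factors = composite_score(stage, 1 - marker_high, sig_high, cc_high,
                              sample_ids=samples)
    score = factors.table["prognostic_score"].to_numpy()

    rates = cfg.lambda0 * np.exp(cfg.beta_per_point * score)
    u = rng.random(n)
    # S(t) = exp(-(rate * t)^shape); shape 1 is the exponential model
    event_time = (-np.log(u)) ** (1.0 / cfg.weibull_shape) / rates

    if cfg.censoring_frac > 0:
        c_max = _calibrate_censoring(event_time, cfg.censoring_frac)
        censor_time = rng.uniform(0.0, c_max, size=n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-6)  # CohortTable requires strictly positive times

    expr = ExpressionMatrix(vals_df, platform_tag="synthetic-cohort")
    cohort = CohortTable(pd.DataFrame(
        {"time": time, "event": event, "stage_group": stage, "marker": marker},
        index=pd.Index(samples, name="sample_id"),
    ))
    truth = {
        "up_genes": list(up_genes),
        "down_genes": list(down_genes),
        "rho": cfg.rho,
        "beta_per_point": cfg.beta_per_point,
        "lambda0": cfg.lambda0,
        "true_score": score.tolist(),
        "marker_low_component": low.astype(int).tolist(),
    }
    return expr, cohort, truth
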