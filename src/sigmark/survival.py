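"""Survival statistics for cohort stratification.

The prognostic construction: each of four adverse binary factors — advanced
TNM stage (III-IV), below-median marker, above-median AKT-signature score,
above-median cell-cycle-signature score — contributes one point, giving an
integer composite score 0-4. The statistics here evaluate that score and its
components: the Kaplan-Meier product-limit curve, the log-rank test across
groups, univariable Cox proportional-hazards regression, and Harrell's
concordance index.

Tie conventions are fixed for reproducibility: at a tied time events precede
censorings in the KM risk-set bookkeeping; Cox ties use the Breslow
approximation by default (Efron behind a flag); in the concordance index,
risk ties count 0.5 and pairs with tied times are not comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PrognosticFactors",
    "SurvivalCurve",
    "LogRankResult",
    "CoxResult",
    "ConcordanceResult",
    "dichotomize_by_median",
    "composite_score",
    "km_estimate",
    "median_survival",
    "log_rank_test",
    "cox_univariable",
    "harrell_c",
]


@dataclass
class PrognosticFactors:
    """Per-patient binary risk factors and their 0-4 sum; ``table`` indexed by sample_id."""

    table: pd.DataFrame  # columns: stage_group, marker_low, akt_high, cc_high, prognostic_score

    def __post_init__(self) -> None:
        t = self.table
        for col in ("stage_group", "marker_low", "akt_high", "cc_high"):
            if col not in t.columns:
                raise ValueError(f"missing factor column {col!r}")
            if not t[col].isin([0, 1]).all():
                raise ValueError(f"factor {col!r} must be 0/1")
        expected = t[["stage_group", "marker_low", "akt_high", "cc_high"]].sum(axis=1)
        if "prognostic_score" not in t.columns:
            raise ValueError("missing prognostic_score column")
        if not (t["prognostic_score"] == expected).all():
            raise ValueError("prognostic_score must equal the sum of the four factors")


@dataclass
class SurvivalCurve:
    times: np.ndarray          # distinct event times, ascending
    at_risk: np.ndarray        # risk-set size just before each event time
    survival: np.ndarray       # product-limit S(t) at each event time
    censor_times: np.ndarray   # censoring times (for tick marks)

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p: float


@dataclass
class CoxResult:
    beta: float
    hr: float
    se: float
    wald_p: float
    converged: bool
    n_iter: int = 0


@dataclass
class ConcordanceResult:
    c_index: float
    comparable: int
    concordant: int
    discordant: int
    tied: int

    def __post_init__(self) -> None:
        assert self.concordant + self.discordant + self.tied == self.comparable


def dichotomize_by_median(values) -> tuple[np.ndarray, float]:
    """Split a continuous vector at its median: value >= median -> 1 ("high").

    Returns ``(high_indicator, median)``. The >= rule makes even-n and tied
    cohorts deterministic. All-identical input is a degenerate dichotomy and
    raises.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-d vector with >= 2 values")
    if np.all(v == v[0]):
        raise ValueError("degenerate dichotomy: all values identical")
    med = float(np.median(v))
    return (v >= med).astype(int), med


def composite_score(
    stage_group, marker_low, akt_high, cc_high, sample_ids=None
) -> PrognosticFactors:
    """Sum the four adverse binary factors into the 0-4 prognostic score.

    Each argument is a 0/1 vector: advanced stage, below-median marker,
    above-median AKT score, above-median cell-cycle score. Stratum labels
    are "score 0" ... "score 4".
    """
    arrs = {}
    for name, a in (("stage_group", stage_group), ("marker_low", marker_low),
                    ("akt_high", akt_high), ("cc_high", cc_high)):
        if a is None:
            raise ValueError(f"missing factor {name!r}")
        a = np.asarray(a)
        if not np.isin(a, [0, 1]).all():
            raise ValueError(f"factor {name!r} must be 0/1")
        arrs[name] = a.astype(int)
    lengths = {len(a) for a in arrs.values()}
    if len(lengths) != 1:
        raise ValueError("factor vectors have unequal lengths")
    n = lengths.pop()
    idx = pd.Index(sample_ids if sample_ids is not None else range(n), name="sample_id")
    t = pd.DataFrame(arrs, index=idx)
    t["prognostic_score"] = t.sum(axis=1)
    t["stratum"] = "score " + t["prognostic_score"].astype(str)
    return PrognosticFactors(t)


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("empty survival input")
    if len(t) != len(e):
        raise ValueError("times and events length mismatch")
    if not (t > 0).all():
        raise ValueError("times must be > 0")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return t, e


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i). Subjects
    censored at an event time remain in that time's risk set (events first).
    """
    t, e = _check_surv(times, events)
    event_times = np.unique(t[e == 1])
    at_risk = np.empty(len(event_times))
    surv = np.empty(len(event_times))
    s = 1.0
    for i, ti in enumerate(event_times):
        n_i = int((t >= ti).sum())          # censored at ti still at risk
        d_i = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        at_risk[i] = n_i
        surv[i] = s
    return SurvivalCurve(
        times=event_times,
        at_risk=at_risk,
        survival=surv,
        censor_times=np.sort(t[e == 0]),
    )


def median_survival(curve: SurvivalCurve) -> float:
    """Smallest event time with S(t) <= 0.5, or inf if never reached."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.times[below[0]]) if len(below) else float("inf")


def log_rank_test(times, events, groups) -> LogRankResult:
    """k-sample log-rank test (observed - expected with hypergeometric variance).

    At each distinct event time the events are allocated to groups under the
    null in proportion to the risk sets; the chi-square statistic is
    u' V^+ u over the first k-1 groups with k-1 degrees of freedom.
    """
    t, e = _check_surv(times, events)
    g = np.asarray(groups)
    labels = np.unique(g)
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    for lab in labels:
        if (g == lab).sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
    if e.sum() == 0:
        raise ValueError("need >= 1 event")

    event_times = np.unique(t[e == 1])
    u = np.zeros(k)           # observed - expected per group
    V = np.zeros((k, k))      # covariance of the observed counts
    for ti in event_times:
        at_risk = t >= ti
        n = int(at_risk.sum())
        d = int(((t == ti) & (e == 1)).sum())
        nj = np.array([(at_risk & (g == lab)).sum() for lab in labels], dtype=float)
        dj = np.array([((t == ti) & (e == 1) & (g == lab)).sum() for lab in labels],
                      dtype=float)
        exp_j = d * nj / n
        u += dj - exp_j
        if n > 1:
            c = d * (n - d) / (n - 1) / n**2
            V += c * (np.diag(n * nj) - np.outer(nj, nj))

    u1, V1 = u[:-1], V[:-1, :-1]
    chi2 = float(u1 @ np.linalg.pinv(V1) @ u1) if V1.size else 0.0
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi_square=chi2, df=df, p=p)


def _cox_loglik(beta: float, t, e, x, ties: str):
    """Breslow/Efron partial log-likelihood with first two derivatives."""
    order = np.argsort(-t, kind="stable")  # descending time
    t, e, x = t[order], e[order], x[order]
    eta = beta * x
    w = np.exp(eta)

    ll = 0.0
    d1 = 0.0
    d2 = 0.0
    # cumulative risk-set sums while walking down in time
    s0 = 0.0   # sum w
    s1 = 0.0   # sum w*x
    s2 = 0.0   # sum w*x^2
    i = 0
    n = len(t)
    while i < n:
        ti = t[i]
        j = i
        while j < n and t[j] == ti:
            j += 1
        # everyone with time >= ti enters the risk set (events and censored alike)
        for idx in range(i, j):
            s0 += w[idx]
            s1 += w[idx] * x[idx]
            s2 += w[idx] * x[idx] ** 2
        ev = [idx for idx in range(i, j) if e[idx] == 1]
        d = len(ev)
        if d:
            sum_x = sum(x[idx] for idx in ev)
            if ties == "breslow":
                ll += beta * sum_x - d * np.log(s0)
                d1 += sum_x - d * s1 / s0
                d2 += -d * (s2 / s0 - (s1 / s0) ** 2)
            else:  # efron
                wd = sum(w[idx] for idx in ev)
                wdx = sum(w[idx] * x[idx] for idx in ev)
                wdx2 = sum(w[idx] * x[idx] ** 2 for idx in ev)
                ll += beta * sum_x
                for r in range(d):
                    f = r / d
                    a0 = s0 - f * wd
                    a1 = s1 - f * wdx
                    a2 = s2 - f * wdx2
                    ll -= np.log(a0)
                    d1 -= a1 / a0
                    d2 -= a2 / a0 - (a1 / a0) ** 2
                d1 += sum_x
        i = j
    return ll, d1, d2


def cox_univariable(
    times, events, covariate, ties: str = "breslow",
    tol: float = 1e-8, max_iter: int = 50,
) -> CoxResult:
    """Univariable Cox proportional-hazards fit by Newton-Raphson.

    Maximizes the partial likelihood (Breslow tie handling by default,
    ``ties="efron"`` available). A monotone likelihood (complete separation,
    |beta| diverging) or non-convergence is flagged via ``converged=False``
    rather than raised.
    """
    t, e = _check_surv(times, events)
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(t):
        raise ValueError("covariate length mismatch")
    if e.sum() == 0:
        raise ValueError("need >= 1 event")
    if np.all(x == x[0]):
        raise ValueError("covariate is constant")
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")

    # center and scale for numerical stability; back-transform at the end
    mu, sd = x.mean(), x.std()
    xs = (x - mu) / sd

    beta = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, d1, d2 = _cox_loglik(beta, t, e, xs, ties)
        if d2 >= 0:  # flat or pathological curvature
            break
        step = -d1 / d2
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) > 50:  # monotone likelihood
            break

    _, _, d2 = _cox_loglik(beta, t, e, xs, ties)
    se_s = float(np.sqrt(-1.0 / d2)) if d2 < 0 else float("inf")
    beta_orig = beta / sd
    se_orig = se_s / sd
    wald = beta_orig / se_orig if se_orig > 0 and np.isfinite(se_orig) else 0.0
    p = float(2 * stats.norm.sf(abs(wald)))
    if not converged:
        logger.warning("Cox fit did not converge (beta=%.3g after %d iterations)",
                       beta_orig, n_iter)
    return CoxResult(beta=float(beta_orig), hr=float(np.exp(beta_orig)),
                     se=float(se_orig), wald_p=p, converged=converged, n_iter=n_iter)


def harrell_c(times, events, risk) -> ConcordanceResult:
    """Harrell's concordance index for a per-patient risk score.

    A pair is comparable when the ordering of failure is determinable: the
    earlier time is an observed event and the times differ. Concordant pairs
    have the higher risk failing earlier; risk ties count 0.5.
    """
    t, e = _check_surv(times, events)
    r = np.asarray(risk, dtype=float)
    if len(r) != len(t):
        raise ValueError("risk length mismatch")

    # vectorized pairwise comparison
    dt = t[:, None] - t[None, :]              # t_i - t_j
    ev_i = e[:, None].astype(bool)
    comparable = (dt < 0) & ev_i              # i fails first, with event
    ri, rj = r[:, None], r[None, :]
    concordant = int((comparable & (ri > rj)).sum())
    discordant = int((comparable & (ri < rj)).sum())
    tied = int((comparable & (ri == rj)).sum())
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    c = (concordant + 0.5 * tied) / n_comp
    return ConcordanceResult(c_index=float(c), comparable=n_comp,
                             concordant=concordant, discordant=discordant, tied=tied)
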