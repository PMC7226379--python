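import itertools

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from sigmark.survival import (
    composite_score,
    cox_univariable,
    dichotomize_by_median,
    harrell_c,
    km_estimate,
    log_rank_test,
    median_survival,
)


def brute_force_km(times, events):
    """Oracle: direct product over event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n
        out[t] = s
    return out


def _perm_logrank_chi2(times, events, groups, n_perm, rng, chunk=1000):
    """Independent oracle: log-rank chi-square under label permutations,
    recomputed from cumulative one-hot group counts (vectorized over
    permutations)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    n = len(t)
    labels = np.unique(groups)
    k = len(labels)
    lab_idx = np.searchsorted(labels, groups[order])
    ev_times = np.unique(t[e == 1])
    first_idx = np.searchsorted(t, ev_times, side="left")  # risk set = suffix
    d_tot = np.array([((t == ti) & (e == 1)).sum() for ti in ev_times])
    n_tot = n - first_idx
    ev_rows = [np.nonzero((t == ti) & (e == 1))[0] for ti in ev_times]
    c = d_tot * (n_tot - d_tot) / np.maximum(n_tot - 1, 1) / n_tot ** 2

    chi2 = np.empty(n_perm)
    eye = np.eye(k)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perm = np.tile(lab_idx, (b, 1))
        for row in perm:
            rng.shuffle(row)
        onehot = np.eye(k, dtype=np.int32)[perm]            # (b, n, k)
        prefix = np.cumsum(onehot, axis=1)
        total = prefix[:, -1, :]
        u = np.zeros((b, k))
        v = np.zeros((b, k, k))
        for m in range(len(ev_times)):
            s = first_idx[m]
            nj = total - (prefix[:, s - 1, :] if s > 0 else 0)
            dj = onehot[:, ev_rows[m], :].sum(axis=1)
            u += dj - d_tot[m] * nj / n_tot[m]
            v += c[m] * (n_tot[m] * nj[:, :, None] * eye[None, :, :]
                         - nj[:, :, None] * nj[:, None, :])
        u1, v1 = u[:, :-1], v[:, :-1, :-1]
        sol = np.linalg.solve(v1, u1[..., None])[..., 0]
        chi2[done:done + b] = np.einsum("bj,bj->b", u1, sol)
        done += b
    return chi2


def brute_force_c(times, events, risk):
    """Oracle: exhaustive unordered-pair enumeration."""
    n = len(times)
    conc = disc = tied = comp = 0
    for i, j in itertools.combinations(range(n), 2):
        if times[i] == times[j]:
            continue
        a, b = (i, j) if times[i] < times[j] else (j, i)
        if events[a] != 1:
            continue
        comp += 1
        if risk[a] > risk[b]:
            conc += 1
        elif risk[a] < risk[b]:
            disc += 1
        else:
            tied += 1
    return conc, disc, tied, comp


class TestDichotomize:
    def test_even_split(self):
        high, med = dichotomize_by_median([1, 2, 3, 4])
        assert med == 2.5
        assert high.tolist() == [0, 0, 1, 1]

    def test_tie_at_median_goes_high(self):
        high, med = dichotomize_by_median([1, 2, 3])
        assert med == 2
        assert high.tolist() == [0, 1, 1]

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            dichotomize_by_median([5, 5, 5])


class TestCompositeScore:
    def test_all_adverse_scores_four(self):
        f = composite_score([1], [1], [1], [1])
        assert f.table["prognostic_score"].iloc[0] == 4

    def test_no_adverse_scores_zero(self):
        f = composite_score([0], [0], [0], [0])
        assert f.table["prognostic_score"].iloc[0] == 0

    def test_two_adverse_factors(self):
        f = composite_score([1], [0], [1], [0])
        assert f.table["prognostic_score"].iloc[0] == 2
        assert f.table["stratum"].iloc[0] == "score 2"

    def test_all_sixteen_combinations(self):
        combos = list(itertools.product([0, 1], repeat=4))
        f = composite_score(*(np.array(c) for c in zip(*combos)))
        scores = f.table["prognostic_score"]
        assert sorted(scores.unique()) == [0, 1, 2, 3, 4]
        assert (scores == [sum(c) for c in combos]).all()

    def test_missing_factor_rejected(self):
        with pytest.raises(ValueError, match="missing factor"):
            composite_score([1], None, [1], [1])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            composite_score([2], [0], [0], [0])


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_estimate([1, 2, 3], [1, 1, 0])
        assert curve.survival == pytest.approx([2 / 3, 1 / 3])
        assert curve.survival_at(3) == pytest.approx(1 / 3)
        assert curve.survival_at(0.5) == 1.0

    def test_all_censored(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert len(curve.times) == 0
        assert curve.survival_at(99) == 1.0

    def test_single_event_drops_to_zero(self):
        curve = km_estimate([5], [1])
        assert curve.survival_at(5) == 0.0

    def test_event_before_censoring_at_ties(self):
        # censored subject at t = 2 still in the risk set for the t = 2 event
        curve = km_estimate([2, 2, 3], [1, 0, 1])
        assert curve.survival == pytest.approx([2 / 3, 0.0])

    def test_matches_brute_force_all_small_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 9))
            times = rng.integers(1, 5, n).astype(float)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                continue
            curve = km_estimate(times, events)
            oracle = brute_force_km(times, events)
            for t, s in zip(curve.times, curve.survival):
                assert s == pytest.approx(oracle[t])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(4)
        times = rng.exponential(10, 40) + 0.1
        events = rng.integers(0, 2, 40)
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(kmf.predict(t), abs=1e-9)

    def test_median_survival(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert median_survival(curve) == 2.0
        curve = km_estimate([1, 2, 3, 4], [1, 0, 0, 0])
        assert median_survival(curve) == float("inf")


class TestLogRank:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        groups = [0, 0, 0, 0, 1, 1, 1, 1]
        res = log_rank_test(times, events, groups)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_evaluated_toy_case(self):
        # per-event-time O-E and variance terms evaluated by hand:
        # A events {1,2}, B events {3,4} -> U = 7/6, V = 17/36, chi2 = 2.882
        res = log_rank_test([1, 2, 3, 4], [1, 1, 1, 1], list("AABB"))
        assert res.df == 1
        assert res.chi_square == pytest.approx((7 / 6) ** 2 / (17 / 36), abs=1e-9)
        assert res.chi_square == pytest.approx(2.88, abs=0.01)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(5, 30) + 0.1
        events = rng.integers(0, 2, 30)
        events[0] = 1
        groups = rng.integers(0, 3, 30)
        a = log_rank_test(times, events, groups)
        b = log_rank_test(times, events, 2 - groups)
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-9)

    def test_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(9)
        times = rng.exponential(8, 60) + 0.1
        groups = rng.integers(0, 3, 60)
        times *= 1 + 0.5 * groups
        events = rng.integers(0, 2, 60)
        events[:5] = 1
        ours = log_rank_test(times, events, groups)
        theirs = multivariate_logrank_test(times, groups, events)
        assert ours.chi_square == pytest.approx(theirs.test_statistic, rel=1e-6)
        assert ours.p == pytest.approx(theirs.p_value, rel=1e-6)

    def test_five_group_permutation_oracle(self):
        # the asymptotic p agrees with a 10,000-label-permutation null, and
        # the vectorized oracle reproduces the statistic under the identity
        # permutation (an independent implementation of the chi-square)
        rng = np.random.default_rng(12)
        n = 300
        groups = np.repeat(np.arange(5), n // 5)
        times = rng.exponential(10 * (1 + 0.05 * groups), n) + 0.1
        events = (rng.random(n) < 0.75).astype(int)
        obs = log_rank_test(times, events, groups)

        class _Identity:
            def shuffle(self, x):
                pass

        same = _perm_logrank_chi2(times, events, groups, 1, _Identity())
        assert same[0] == pytest.approx(obs.chi_square, rel=1e-9)

        n_perm = 10_000
        null = _perm_logrank_chi2(times, events, groups, n_perm,
                                  np.random.default_rng(99))
        p_perm = (1 + (null >= obs.chi_square).sum()) / (1 + n_perm)
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / n_perm)
        assert abs(obs.p - p_perm) < max(4 * se, 0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            log_rank_test([1, 2], [1, 1], ["A", "A"])


class TestCox:
    def test_symmetric_groups_beta_zero(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1] * 8
        x = [0, 1, 0, 1, 1, 0, 1, 0]
        res = cox_univariable(times, events, x)
        assert res.beta == pytest.approx(0.0, abs=1e-6)
        assert res.hr == pytest.approx(1.0, abs=1e-6)

    def test_grid_search_oracle_small(self):
        # n = 4, no ties: Newton solution matches a grid maximizer of the
        # Breslow partial likelihood on beta in [-5, 5]
        from sigmark.survival import _cox_loglik

        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        res = cox_univariable(times, events, x)

        xs = (x - x.mean()) / x.std()
        ll = np.array([_cox_loglik(b, times, events, xs, "breslow")[0]
                       for b in np.linspace(-5, 5, 2001)])
        coarse = np.linspace(-5, 5, 2001)[np.argmax(ll)]
        refine = minimize_scalar(
            lambda b: -_cox_loglik(b, times, events, xs, "breslow")[0],
            bounds=(coarse - 0.1, coarse + 0.1), method="bounded",
            options={"xatol": 1e-10})
        beta_scaled = res.beta * x.std()
        assert beta_scaled == pytest.approx(refine.x, abs=1e-3)

    def test_matches_lifelines_untied(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 80
        x = rng.normal(0, 1, n)
        times = rng.exponential(np.exp(-0.7 * x))
        events = (rng.random(n) < 0.8).astype(int)
        res = cox_univariable(times, events, x, ties="efron")
        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": times, "E": events, "x": x}),
            duration_col="T", event_col="E")
        assert res.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-3)

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(6)
        n = 30
        x = rng.normal(0, 1, n)
        times = rng.exponential(np.exp(-0.5 * x))
        events = np.ones(n, dtype=int)
        a = cox_univariable(times, events, x, ties="breslow")
        b = cox_univariable(times, events, x, ties="efron")
        assert a.beta == pytest.approx(b.beta, abs=1e-8)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariable([1, 2], [1, 1], [3, 3])

    def test_separation_flagged_not_silent(self):
        # perfectly separated risk: monotone likelihood
        times = [1, 2, 3, 10, 11, 12]
        events = [1] * 6
        x = [1, 1, 1, 0, 0, 0]
        res = cox_univariable(times, events, x)
        assert not res.converged or abs(res.beta) > 5


class TestHarrellC:
    def test_perfect_concordance(self):
        res = harrell_c([3, 2, 1], [1, 1, 1], [1.0, 2.0, 3.0])
        assert res.c_index == 1.0

    def test_all_risks_equal(self):
        res = harrell_c([1, 2, 3], [1, 1, 1], [5.0, 5.0, 5.0])
        assert res.c_index == 0.5
        assert res.tied == res.comparable

    def test_censoring_limits_comparable_pairs(self):
        # times {1, 2+, 3}, events {1,0,1}, risks {3,1,2}:
        # only (1 vs 2+) and (1 vs 3) comparable, both concordant
        res = harrell_c([1, 2, 3], [1, 0, 1], [3.0, 1.0, 2.0])
        assert res.comparable == 2
        assert res.concordant == 2
        assert res.c_index == 1.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            n = int(rng.integers(5, 51))
            times = rng.integers(1, 20, n).astype(float)
            events = rng.integers(0, 2, n)
            risk = rng.integers(0, 5, n).astype(float)
            conc, disc, tied, comp = brute_force_c(times, events, risk)
            if comp == 0:
                continue
            res = harrell_c(times, events, risk)
            assert (res.concordant, res.discordant, res.tied, res.comparable) == \
                (conc, disc, tied, comp)

    def test_matches_lifelines(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(19)
        n = 60
        risk = rng.normal(0, 1, n)
        times = rng.exponential(np.exp(-risk))
        events = rng.integers(0, 2, n)
        events[:3] = 1
        res = harrell_c(times, events, risk)
        # lifelines orders by predicted survival time (negated risk)
        assert res.c_index == pytest.approx(
            concordance_index(times, -risk, events), abs=1e-9)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c([5, 5], [1, 1], [1.0, 2.0])
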