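"""Mutation scores, Kaplan-Meier, log-rank, min-p cut-points, permutation null,
Cox coefficients and expression risk scores."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import netmodmut as nm
from netmodmut.survival import (
    km_curve,
    logrank_test,
    minp_cutpoint,
    permutation_p,
    sample_score,
)


class TestSampleScore:
    def test_worked_example(self):
        m = pd.DataFrame([[1, -1, 1]], index=["s1"], columns=["a", "b", "c"])
        fr = pd.DataFrame({"heat": [0.3, 0.38, 0.5]}, index=["a", "b", "c"])
        assert sample_score(m, fr, ["a", "b", "c"]).loc["s1"] == pytest.approx(1.18)

    def test_all_neutral_sample_scores_zero(self):
        m = pd.DataFrame([[0, 0]], index=["s1"], columns=["a", "b"])
        fr = pd.DataFrame({"heat": [0.3, 0.4]}, index=["a", "b"])
        assert sample_score(m, fr, ["a", "b"]).loc["s1"] == 0.0

    def test_matches_elementwise_hand_computation(self):
        m = pd.DataFrame(
            [[1, 0, -1, 1], [0, 0, 0, -1], [-1, 1, 1, 0]],
            index=["s1", "s2", "s3"],
            columns=list("abcd"),
        )
        fr = pd.DataFrame({"heat": [0.1, 0.2, 0.3, 0.4]}, index=list("abcd"))
        got = sample_score(m, fr, list("abcd"))
        assert got.loc["s1"] == pytest.approx(0.1 + 0.3 + 0.4)
        assert got.loc["s2"] == pytest.approx(0.4)
        assert got.loc["s3"] == pytest.approx(0.1 + 0.2 + 0.3)

    def test_missing_gene_named_in_error(self):
        m = pd.DataFrame([[1]], index=["s1"], columns=["a"])
        fr = pd.DataFrame({"heat": [0.3]}, index=["a"])
        with pytest.raises(KeyError, match="zz"):
            sample_score(m, fr, ["a", "zz"])


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        ts, s = km_curve([3, 5, 7], [0, 0, 0])
        assert np.allclose(s, 1.0)

    def test_three_events_product_limit_by_hand(self):
        ts, s = km_curve([1, 2, 3], [1, 1, 1])
        assert np.allclose(ts, [0, 1, 2, 3])
        assert np.allclose(s, [1, 2 / 3, 1 / 3, 0])

    def test_single_event_drops_to_zero(self):
        ts, s = km_curve([4.0], [1])
        assert s[-1] == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1.0], [1])

    def test_matches_lifelines_with_censoring_and_ties(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(0)
        t = np.round(rng.exponential(10, 80), 1)
        e = (rng.random(80) < 0.6).astype(int)
        ts, s = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_["KM_estimate"]
        for ti, si in zip(ts, s):
            assert si == pytest.approx(ref.loc[ti], abs=1e-12)

    def test_without_censoring_equals_empirical_survivor(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        ts, s = km_curve(t, np.ones(4, int))
        for ti, si in zip(ts[1:], s[1:]):
            assert si == pytest.approx((t > ti).mean())


class TestLogrank:
    def test_identical_groups_score_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_give_stat_zero_p_one(self):
        stat, p = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        assert stat == 0.0 and p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [1, 1])

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 40)
        e = (rng.random(40) < 0.7).astype(int)
        g = rng.random(40) < 0.4
        s1, p1 = logrank_test(t, e, g)
        s2, p2 = logrank_test(t, e, ~g)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_matches_lifelines_with_ties(self):
        from lifelines.statistics import logrank_test as ll

        rng = np.random.default_rng(3)
        t = np.round(rng.exponential(8, 60), 0) + 1
        e = (rng.random(60) < 0.7).astype(int)
        g = rng.random(60) < 0.5
        stat, p = logrank_test(t, e, g)
        ref = ll(t[g], t[~g], e[g], e[~g])
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_hand_computed_complete_separation(self):
        # group 1 dies at 1, 2, 3; group 0 dies at 10, 11, 12
        t = [1, 2, 3, 10, 11, 12]
        e = [1] * 6
        g = [1, 1, 1, 0, 0, 0]
        # per event time: (n, n1, d): (6,3,1),(5,2,1),(4,1,1),(3,0,1),(2,0,1),(1,0,1)
        exp = [3 / 6, 2 / 5, 1 / 4, 0, 0, 0]
        U = (1 - exp[0]) + (1 - exp[1]) + (1 - exp[2]) - exp[3] - exp[4] - exp[5]
        var = [
            (3 / 6) * (3 / 6) * (6 - 1) / (6 - 1),
            (2 / 5) * (3 / 5) * (5 - 1) / (5 - 1),
            (1 / 4) * (3 / 4) * (4 - 1) / (4 - 1),
            0,
            0,
            0,
        ]
        stat_expected = U**2 / sum(var)
        stat, _ = logrank_test(t, e, g)
        assert stat == pytest.approx(stat_expected, rel=1e-12)


class TestMinpCutpoint:
    def survival_fixture(self):
        rng = np.random.default_rng(1)
        scores = np.repeat([0.0, 1.0, 2.0, 3.0], 10)
        # low scores live long, high scores die early
        t = np.where(scores >= 2, rng.exponential(2, 40), rng.exponential(20, 40))
        e = np.ones(40, int)
        return scores, t, e

    def test_cut_matches_exhaustive_grid_oracle(self):
        scores, t, e = self.survival_fixture()
        res = minp_cutpoint(scores, t, e)
        n = len(scores)
        best = None
        for c in np.unique(scores):
            frac = (scores <= c).mean()
            if not (0.1 <= frac <= 0.9) or frac == 1.0:
                continue
            _, p = logrank_test(t, e, scores > c)
            if best is None or p < best[0] - 1e-15:
                best = (p, c)
        assert res.cutpoint == best[1]
        assert res.p_value == pytest.approx(best[0])
        assert res.cutpoint == 1.0  # separates the two hazard regimes

    def test_degenerate_window_gives_median_split(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        t = [5, 6, 1, 2]
        e = [1, 1, 1, 1]
        res = minp_cutpoint(scores, t, e, lower_q=0.5, upper_q=0.5)
        assert res.cutpoint == 2.0
        assert res.n_high == 2 and res.n_low == 2

    def test_min_p_never_worse_than_median_split(self):
        scores, t, e = self.survival_fixture()
        res = minp_cutpoint(scores, t, e)
        med = np.median(scores)
        cands = np.unique(scores)
        c_med = cands[np.searchsorted(cands, med, side="left")]
        _, p_med = logrank_test(t, e, scores > 1.0)
        assert res.p_value <= p_med + 1e-15

    def test_constant_scores_have_no_admissible_cutpoint(self):
        with pytest.raises(ValueError, match="admissible"):
            minp_cutpoint(np.ones(10), np.arange(1, 11), np.ones(10, int))


class TestPermutationP:
    def tiny_inputs(self, effect, seed=0, n=40):
        cfg = nm.SimConfig(
            n_samples=n, n_genes=24, module_size=3, n_background_edges=40,
            survival_effect=effect, seed=seed,
        )
        b = nm.make_two_cohorts(cfg)
        c = b.discovery
        mat = c.states
        fr = nm.gene_frequencies(mat)
        return b, mat, fr, c.survival["time"].to_numpy(), c.survival["event"].to_numpy()

    def test_perm_p_respects_formula_bounds(self):
        b, mat, fr, t, e = self.tiny_inputs(effect=2.0)
        ps = permutation_p(b.module_genes, mat, fr, t, e, n_perm=50, seed=1)
        assert 1 / 51 <= ps.perm_p <= 1.0
        assert len(ps.permuted_ps) == 50

    def test_extreme_separation_attains_lower_bound(self):
        b, mat, fr, t, e = self.tiny_inputs(effect=2.0)
        ps = permutation_p(b.module_genes, mat, fr, t, e, n_perm=50, seed=1)
        if (ps.permuted_ps > ps.real_p).all():
            assert ps.perm_p == pytest.approx(1 / 51)

    def test_null_perm_p_roughly_uniform_on_its_grid(self):
        # survival independent of all genes: the calibrated p should not
        # pile up near zero (score-preserving permutation unit)
        vals = []
        for s in range(10):
            b, mat, fr, t, e = self.tiny_inputs(effect=0.0, seed=100 + s, n=60)
            ps = permutation_p(
                b.module_genes, mat, fr, t, e, n_perm=200, seed=s, mode="shuffle_values"
            )
            vals.append(ps.perm_p)
        assert np.mean(vals) > 0.2
        assert min(vals) >= 1 / 201

    def test_shuffle_values_mode_runs_and_bounds(self):
        b, mat, fr, t, e = self.tiny_inputs(effect=1.0)
        ps = permutation_p(b.module_genes, mat, fr, t, e, n_perm=30, seed=2, mode="shuffle_values")
        assert 1 / 31 <= ps.perm_p <= 1.0

    def test_oversized_module_rejected(self):
        b, mat, fr, t, e = self.tiny_inputs(effect=0.0)
        with pytest.raises(ValueError):
            permutation_p(list(mat.columns) + ["extra"], mat, fr, t, e, n_perm=1)


class TestCox:
    def test_single_binary_covariate_matches_partial_likelihood_oracle(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.ones(6, int)
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        expr = pd.DataFrame([x], index=["g1"], columns=[f"s{i}" for i in range(6)])
        coef = nm.cox_coefficients(expr, t, e).loc["g1"]

        def neg_log_pl(b):
            risk = np.exp(b * x)
            order = np.argsort(t)
            ll = 0.0
            for k in order:
                if e[k]:
                    at_risk = t >= t[k]
                    ll += b * x[k] - np.log(risk[at_risk].sum())
            return -ll

        ref = minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded").x
        assert coef == pytest.approx(ref, abs=1e-4)

    def test_null_expression_gives_near_zero_coefficients(self):
        rng = np.random.default_rng(11)
        n = 500
        expr = pd.DataFrame(
            rng.normal(size=(3, n)), index=["g1", "g2", "g3"],
            columns=[f"s{i}" for i in range(n)],
        )
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.7).astype(int)
        coefs = nm.cox_coefficients(expr, t, e)
        assert (coefs.abs() < 0.2).all()

    def test_recovers_planted_log_hazard_ratio(self):
        rng = np.random.default_rng(12)
        n = 1000
        x = rng.normal(size=n)
        lam = 0.1 * np.exp(1.0 * x)
        t_ev = rng.exponential(1 / lam)
        c = rng.uniform(0, 30, n)
        t = np.minimum(t_ev, c)
        e = (t_ev <= c).astype(int)
        expr = pd.DataFrame([x], index=["g1"], columns=[f"s{i}" for i in range(n)])
        coef = nm.cox_coefficients(expr, t, e).loc["g1"]
        assert coef == pytest.approx(1.0, abs=0.2)

    def test_constant_expression_column_warns_and_gets_zero(self):
        rng = np.random.default_rng(13)
        n = 50
        expr = pd.DataFrame(
            {"g1": np.ones(n), "g2": rng.normal(size=n)}
        ).T
        expr.columns = [f"s{i}" for i in range(n)]
        t = rng.exponential(5, n)
        e = np.ones(n, int)
        with pytest.warns(UserWarning, match="constant"):
            coefs = nm.cox_coefficients(expr, t, e)
        assert coefs.loc["g1"] == 0.0


class TestExpressionRiskScore:
    def test_zero_coefficients_give_zero_scores(self):
        expr = pd.DataFrame(np.ones((2, 3)), index=["a", "b"], columns=["s1", "s2", "s3"])
        rs = nm.expression_risk_score(expr, pd.Series([0.0, 0.0], index=["a", "b"]))
        assert (rs == 0).all()

    def test_single_unit_coefficient_returns_that_gene(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["a"], columns=["s1", "s2", "s3"])
        rs = nm.expression_risk_score(expr, pd.Series([1.0], index=["a"]))
        assert rs.tolist() == [1.0, 2.0, 3.0]

    def test_three_gene_dot_product_oracle(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(
            rng.normal(size=(3, 4)), index=["a", "b", "c"], columns=list("wxyz")
        )
        coeff = pd.Series([0.5, -1.0, 2.0], index=["a", "b", "c"])
        rs = nm.expression_risk_score(expr, coeff)
        for j, s in enumerate("wxyz"):
            expected = sum(coeff[g] * expr.loc[g, s] for g in "abc")
            assert rs[s] == pytest.approx(expected)

    def test_missing_gene_rejected(self):
        expr = pd.DataFrame([[1.0]], index=["a"], columns=["s1"])
        with pytest.raises(KeyError):
            nm.expression_risk_score(expr, pd.Series([1.0], index=["zz"]))


def test_survival_association_wrapper_outputs_consistent_groups():
    rng = np.random.default_rng(21)
    scores = np.repeat([0.0, 1.0, 2.0], 20)
    t = np.where(scores >= 2, rng.exponential(2, 60), rng.exponential(15, 60))
    e = np.ones(60, int)
    out = nm.survival_association(scores, t, e)
    assert out["high"].sum() + (~out["high"]).sum() == 60
    assert out["logrank_p"] <= 0.05
    # KM curves are proper non-increasing step functions starting at 1
    for key in ("km_high", "km_low"):
        ts, s = out[key]
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)
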