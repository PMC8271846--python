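"""Bland-Altman, Spearman, and GEE method-comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from armuse.stats import (
    bland_altman,
    bonferroni,
    change_score_correlation,
    correlate_walking_difference,
    fit_gee,
    interpret_correlation,
    spearman,
)


class TestBlandAltman:
    def test_hand_computed_instance(self):
        # pairs (10,8), (12,8), (14,11): differences {2, 4, 3}
        mc = bland_altman([10, 12, 14], [8, 8, 11])
        assert mc.D == pytest.approx(3.0)
        assert mc.sd_diff == pytest.approx(1.0)
        assert mc.loa_low == pytest.approx(1.04)
        assert mc.loa_high == pytest.approx(4.96)
        assert mc.d_pct == pytest.approx(100 * 3.0 / 12.0)

    def test_identical_methods_collapse_loa(self):
        mc = bland_altman([5, 9, 13], [5, 9, 13])
        assert mc.D == 0 and mc.sd_diff == 0
        assert (mc.loa_low, mc.loa_high) == (0, 0)

    def test_d_pct_uses_pm_mean(self):
        mc = bland_altman([70, 130], [40, 100])
        assert mc.D == pytest.approx(30.0)
        assert mc.d_pct == pytest.approx(30.0)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError, match="at least 2"):
            bland_altman([10], [8])

    def test_zero_pm_mean_flags_d_pct(self):
        mc = bland_altman([0, 0], [0, 0])
        assert np.isnan(mc.d_pct)

    @given(
        diffs=st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        shift=st.floats(-100, 100),
    )
    def test_translation_equivariance(self, diffs, shift):
        pm = np.array([100 + d for d in diffs])
        ss = np.full(len(diffs), 100.0)
        base = bland_altman(pm, ss)
        both = bland_altman(pm + shift, ss + shift)
        assert both.D == pytest.approx(base.D, abs=1e-9)
        assert both.sd_diff == pytest.approx(base.sd_diff, abs=1e-9)
        assert both.loa_low == pytest.approx(base.loa_low, abs=1e-9)
        pm_only = bland_altman(pm + shift, ss)
        assert pm_only.D == pytest.approx(base.D + shift, abs=1e-9)
        assert pm_only.sd_diff == pytest.approx(base.sd_diff, abs=1e-9)


class TestSpearman:
    def test_monotone_is_perfect(self):
        r = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.r == pytest.approx(1.0)
        assert r.label == "very strong"
        assert spearman([1, 2, 3, 4], [40, 30, 20, 10]).r == pytest.approx(-1.0)

    def test_rank_formula_instance(self):
        # brute force over ranks of (1,2,3,4)/(1,3,2,4): rho = 0.8
        r = correlate_walking_difference([1, 2, 3, 4], [1, 3, 2, 4])
        assert r.r == pytest.approx(0.8)
        assert r.label == "strong"

    def test_constant_vector_is_flagged(self):
        r = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(r.r) and r.label == "undefined"

    @given(data=st.lists(st.tuples(st.integers(-50, 50), st.floats(-50, 50)),
                         min_size=4, max_size=10, unique_by=lambda t: t[0]))
    def test_invariant_under_monotone_transform(self, data):
        x = np.array([a for a, _ in data], dtype=float)
        y = np.array([b for _, b in data])
        base = spearman(x, y)
        trans = spearman(np.exp(x / 25.0), y)
        if base.defined and trans.defined:
            assert trans.r == pytest.approx(base.r, abs=1e-12)

    @pytest.mark.parametrize(
        "r, label",
        [(0.1, "very weak"), (0.3, "weak"), (0.6, "moderate"),
         (0.70, "strong"), (0.89, "strong"), (0.90, "very strong"),
         (-0.95, "very strong"), (1.0, "very strong")],
    )
    def test_interpretation_bands(self, r, label):
        assert interpret_correlation(r) == label


def weekly_table(rows):
    return pd.DataFrame(
        rows, columns=["subject_id", "week", "walk_min", "paretic_PM", "paretic_SS"]
    )


class TestChangeScores:
    def test_concordant_deltas_give_one(self):
        rows = []
        for i, (dw, dd) in enumerate([(5, 10), (10, 30), (20, 60)]):
            rows.append((f"S{i}", 3, 30.0, 100.0, 80.0))
            rows.append((f"S{i}", 26, 30.0 + dw, 100.0 + dd, 80.0))
        r = change_score_correlation(weekly_table(rows), "paretic")
        assert r.r == pytest.approx(1.0) and r.n == 3

    def test_no_change_is_undefined(self):
        rows = []
        for i in range(4):
            rows.append((f"S{i}", 3, 30.0, 100.0 + i, 80.0))
            rows.append((f"S{i}", 26, 30.0, 100.0 + i, 80.0))
        r = change_score_correlation(weekly_table(rows), "paretic")
        assert not r.defined

    def test_requires_three_complete_pairs(self):
        rows = [("S0", 3, 30, 100, 80), ("S0", 26, 40, 120, 80),
                ("S1", 3, 30, 100, 80), ("S2", 26, 40, 120, 80)]
        with pytest.raises(ValueError, match=">= 3 subjects"):
            change_score_correlation(weekly_table(rows), "paretic")


def gee_exchangeable_oracle(y, X, groups, maxit=500, tol=1e-12):
    """Independent iteratively-reweighted estimating-equation solver for a
    Gaussian marginal model with exchangeable working correlation."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    ids = np.asarray(groups)
    idx = [np.where(ids == g)[0] for g in np.unique(ids)]
    n, p = X.shape
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    for _ in range(maxit):
        resid = y - X @ beta
        scale = (resid ** 2).sum() / (n - p)
        num = sum((resid[i].sum() ** 2 - (resid[i] ** 2).sum()) / 2 for i in idx)
        npairs = sum(len(i) * (len(i) - 1) / 2 for i in idx)
        alpha = num / scale / (npairs - p)
        A = np.zeros((p, p))
        b = np.zeros(p)
        for i in idx:
            ni = len(i)
            r_inv = (np.eye(ni) - alpha / (1 + (ni - 1) * alpha) * np.ones((ni, ni))) / (1 - alpha)
            A += X[i].T @ r_inv @ X[i]
            b += X[i].T @ r_inv @ y[i]
        new = np.linalg.solve(A, b)
        done = np.max(np.abs(new - beta)) < tol
        beta = new
        if done:
            break
    return beta, alpha


def simulated_long_table(n_subjects, rng, method_effect=0.0, missing=False):
    rows = []
    week_effect = {3: 0.0, 12: 1.0, 26: 1.8}
    for s in range(n_subjects):
        b = rng.normal(0, 1)
        weeks = [3, 12, 26]
        if missing and s % 3 == 0:
            weeks = weeks[:2]
        for w in weeks:
            for m in ("PM", "SS"):
                val = 10 + b + week_effect[w] + (method_effect if m == "PM" else 0)
                rows.append((f"S{s}", w, m, val + rng.normal(0, 1)))
    return pd.DataFrame(rows, columns=["subject_id", "week", "method", "value"])


class TestGEE:
    def test_identical_methods_give_zero_method_effect(self):
        rng = np.random.default_rng(1)
        df = simulated_long_table(8, rng)
        # force both methods identical per subject-week
        piv = df.pivot_table(index=["subject_id", "week"], columns="method",
                             values="value").reset_index()
        piv["SS"] = piv["PM"]
        df = piv.melt(id_vars=["subject_id", "week"], value_vars=["PM", "SS"],
                      var_name="method", value_name="value")
        res = fit_gee(df)
        method_cols = [ix for ix in res.params.index if "method" in ix]
        assert np.allclose(res.params.loc[method_cols, "coef"], 0.0, atol=1e-10)

    def test_deterministic_shift_recovered_exactly(self):
        rows = []
        for s in range(6):
            for w in (3, 12, 26):
                base = 10 + s + 0.5 * w
                rows.append((f"S{s}", w, "SS", base))
                rows.append((f"S{s}", w, "PM", base + 7.5))
        df = pd.DataFrame(rows, columns=["subject_id", "week", "method", "value"])
        res = fit_gee(df)
        assert res.params.loc["method[PM]", "coef"] == pytest.approx(7.5, abs=1e-8)
        inter = [ix for ix in res.params.index if ":" in ix]
        assert np.allclose(res.params.loc[inter, "coef"], 0.0, atol=1e-8)

    def test_balanced_complete_data_reproduces_ols(self):
        rng = np.random.default_rng(7)
        df = simulated_long_table(10, rng, method_effect=1.0)
        res = fit_gee(df)
        from armuse.stats import _design
        X, *_ = _design(df, [3, 12, 26])
        ols = np.linalg.lstsq(X.to_numpy(), df["value"].to_numpy(), rcond=None)[0]
        assert np.allclose(res.params["coef"].to_numpy(), ols, atol=1e-6)

    def test_matches_independent_solver_on_unbalanced_data(self):
        rng = np.random.default_rng(42)
        df = simulated_long_table(6, rng, method_effect=1.0, missing=True)
        res = fit_gee(df)
        from armuse.stats import _design
        X, *_ = _design(df, sorted(df["week"].unique()))
        beta, alpha = gee_exchangeable_oracle(
            df["value"].to_numpy(), X.to_numpy(), df["subject_id"].to_numpy()
        )
        assert np.allclose(res.params["coef"].to_numpy(), beta, atol=1e-6)
        assert res.working_corr == pytest.approx(alpha, abs=1e-4)

    def test_single_cluster_rejected(self):
        df = simulated_long_table(1, np.random.default_rng(0))
        with pytest.raises(ValueError, match="2 subjects"):
            fit_gee(df)

    def test_posthoc_family_and_bonferroni(self):
        rng = np.random.default_rng(3)
        df = simulated_long_table(12, rng, method_effect=2.0)
        res = fit_gee(df)
        # 3 between-week contrasts per method + method contrast per week
        assert res.n_contrasts == 9
        assert len(res.contrasts) == 9
        assert (res.contrasts["p_bonf"] >= res.contrasts["p"] - 1e-15).all()
        assert (res.contrasts["p_bonf"] <= 1.0).all()

    @given(p=st.floats(0, 1), m=st.integers(1, 50))
    def test_bonferroni_never_below_raw(self, p, m):
        adj = bonferroni(p, m)
        assert adj >= p and adj <= 1.0
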