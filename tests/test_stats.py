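"""Mixed-model inference, ANOVA/Tukey, chi-squared and correlation layer.

The mixed-model fit is cross-checked against a brute-force oracle that
profiles the random-intercept and residual variances on a grid,
computing the marginal Gaussian likelihood with GLS fixed effects from
first principles (numpy only, independent of statsmodels).
"""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from sahc.exceptions import (
    NonNestedModelsError,
    RankDeficiencyError,
    SahcError,
    ZeroVarianceError,
)
from sahc.stats import (
    POSITION_CODE,
    add_position_code,
    build_formula,
    delta_correlation,
    epoch_anova_tukey,
    fit_lmm,
    lmm_effect_test,
    lrt,
    pss_chi_squared,
)


# ---------------------------------------------------------------- oracle

def grid_profile_llf(y, X, groups, tau2_grid, sig2_grid):
    """Max marginal log-likelihood of a random-intercept LMM over a
    variance grid, with GLS beta at each grid point.

    For group i with n_i rows: V_i = sig2*I + tau2*J;
    V_i^-1 = (1/sig2) (I - tau2/(sig2 + n_i tau2) J);
    log|V_i| = (n_i - 1) log sig2 + log(sig2 + n_i tau2).
    """
    ids = np.unique(groups)
    Xg = [X[groups == i] for i in ids]
    yg = [y[groups == i] for i in ids]
    best = -np.inf
    N = len(y)
    for tau2 in tau2_grid:
        for sig2 in sig2_grid:
            XtVX = np.zeros((X.shape[1], X.shape[1]))
            XtVy = np.zeros(X.shape[1])
            logdet = 0.0
            for Xi, yi in zip(Xg, yg):
                ni = len(yi)
                c = tau2 / (sig2 + ni * tau2)
                XtVi = (Xi.T - c * np.outer(Xi.sum(axis=0), np.ones(ni))) / sig2
                XtVX += XtVi @ Xi
                XtVy += XtVi @ yi
                logdet += (ni - 1) * np.log(sig2) + np.log(sig2 + ni * tau2)
            beta = np.linalg.solve(XtVX, XtVy)
            quad = 0.0
            for Xi, yi in zip(Xg, yg):
                ri = yi - Xi @ beta
                ni = len(yi)
                c = tau2 / (sig2 + ni * tau2)
                quad += (ri @ ri - c * ri.sum() ** 2) / sig2
            ll = -0.5 * (logdet + N * np.log(2 * np.pi) + quad)
            best = max(best, ll)
    return best


def toy_lmm_data(seed=7, n_groups=4, n_per=6, tau=2.0, sigma=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_groups):
        b = rng.normal(0, tau)
        t = np.linspace(0, 5, n_per)
        y = 1.0 + 0.5 * t + b + rng.normal(0, sigma, n_per)
        for tj, yj in zip(t, y):
            rows.append({"participant": f"g{i}", "time": tj, "delta": yj})
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_llf_matches_grid_oracle(self):
        table = toy_lmm_data()
        fit = fit_lmm(table, formula="delta ~ time", groups="participant")
        X = np.column_stack([np.ones(len(table)), table["time"].to_numpy()])
        y = table["delta"].to_numpy()
        groups = table["participant"].to_numpy()
        # coarse grid around the fitted variances, then refine
        coarse = grid_profile_llf(
            y, X, groups,
            np.linspace(0.01, 20.0, 200),
            np.linspace(0.05, 5.0, 200),
        )
        t0, s0 = fit.random_intercept_var, fit.residual_var
        fine = grid_profile_llf(
            y, X, groups,
            np.linspace(max(t0 * 0.8, 1e-4), t0 * 1.2 + 1e-3, 200),
            np.linspace(max(s0 * 0.8, 1e-4), s0 * 1.2 + 1e-3, 200),
        )
        oracle = max(coarse, fine)
        assert fit.llf == pytest.approx(oracle, abs=0.01)

    def test_null_effects_within_3se(self):
        rng = np.random.default_rng(42)
        rows = []
        for i in range(30):
            b = rng.normal(0, 1.5)
            for t in range(8):
                rows.append(
                    {
                        "participant": f"s{i}",
                        "time": float(t),
                        "g_foot": rng.choice([1.0, 1.7, 2.4]),
                        "delta": b + rng.normal(0, 1.0),
                    }
                )
        table = pd.DataFrame(rows)
        fit = fit_lmm(table, formula="delta ~ time + g_foot", groups="participant")
        for name in ("time", "g_foot"):
            assert abs(fit.params[name]) < 3 * fit.bse[name]

    def test_zero_group_variance_reduces_to_ols(self):
        # residual pattern identical across groups -> no between-group variance
        resid = np.array([0.3, -0.1, 0.5, -0.4, -0.3, 0.0])
        rows = []
        for i in range(4):
            t = np.arange(6.0)
            y = 1.0 + 2.0 * t + resid
            rows += [
                {"participant": f"s{i}", "time": tj, "delta": yj}
                for tj, yj in zip(t, y)
            ]
        table = pd.DataFrame(rows)
        fit = fit_lmm(table, formula="delta ~ time", groups="participant")
        X = np.column_stack([np.ones(len(table)), table["time"]])
        beta_ols = np.linalg.lstsq(X, table["delta"].to_numpy(), rcond=None)[0]
        assert fit.params["Intercept"] == pytest.approx(beta_ols[0], abs=1e-6)
        assert fit.params["time"] == pytest.approx(beta_ols[1], abs=1e-6)
        assert fit.random_intercept_var == pytest.approx(0.0, abs=1e-6)

    def test_rank_deficiency_names_columns(self):
        table = toy_lmm_data()
        table["time2"] = 2 * table["time"]  # exactly collinear
        with pytest.raises(RankDeficiencyError) as err:
            fit_lmm(table, formula="delta ~ time + time2", groups="participant")
        assert any("time" in c for c in err.value.collinear)

    def test_too_few_participants(self):
        table = toy_lmm_data(n_groups=1)
        with pytest.raises(SahcError):
            fit_lmm(table, formula="delta ~ time", groups="participant")


class TestLrt:
    def test_identical_models_stat_zero_p_one(self):
        table = toy_lmm_data()
        fit = fit_lmm(table, formula="delta ~ time", groups="participant")
        res = lrt(fit, fit)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_chi2_quantile(self):
        assert sps.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=0.001)

    def test_strong_effect_rejected(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(12):
            b = rng.normal(0, 1.0)
            for t in np.linspace(0, 5, 8):
                rows.append(
                    {
                        "participant": f"s{i}",
                        "time": t,
                        "delta": 3.0 * t + b + rng.normal(0, 1.0),
                    }
                )
        table = pd.DataFrame(rows)
        full = fit_lmm(table, formula="delta ~ time", groups="participant")
        red = fit_lmm(table, formula="delta ~ 1", groups="participant")
        res = lrt(full, red, effect="time")
        assert res.df == 1
        assert res.pvalue < 0.001

    def test_non_nested_rejected(self):
        table = toy_lmm_data()
        table["other"] = table["time"] ** 2
        f1 = fit_lmm(table, formula="delta ~ time", groups="participant")
        f2 = fit_lmm(table, formula="delta ~ other", groups="participant")
        with pytest.raises(NonNestedModelsError):
            lrt(f1, f2)

    def test_statistic_invariant_to_affine_response_rescale(self):
        table = toy_lmm_data(seed=11)
        full_a = fit_lmm(table, formula="delta ~ time", groups="participant")
        red_a = fit_lmm(table, formula="delta ~ 1", groups="participant")
        stat_a = lrt(full_a, red_a).statistic
        scaled = table.assign(delta=5.0 * table["delta"] - 17.0)
        full_b = fit_lmm(scaled, formula="delta ~ time", groups="participant")
        red_b = fit_lmm(scaled, formula="delta ~ 1", groups="participant")
        stat_b = lrt(full_b, red_b).statistic
        assert stat_a == pytest.approx(stat_b, abs=1e-3)

    def test_full_model_formula_expansion(self):
        f = build_formula("delta", ("time", "position_code", "g_foot"))
        assert "time:position_code:g_foot" in f
        red = build_formula("delta", ("time", "position_code", "g_foot"), drop="position_code")
        assert "position_code" not in red
        assert "time:g_foot" in red


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        g = {"P1": np.array([1.0, 2, 3]), "P2": np.array([1.0, 2, 3]), "P3": np.array([1.0, 2, 3])}
        res = epoch_anova_tukey(g)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_f(self):
        # means 2, 3, 7; SSB = 42, SSW = 6, df (2, 6) -> F = 21
        g = {
            "A": np.array([1.0, 2, 3]),
            "B": np.array([2.0, 3, 4]),
            "C": np.array([6.0, 7, 8]),
        }
        res = epoch_anova_tukey(g)
        assert res.f_statistic == pytest.approx(21.0, rel=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.pvalue == pytest.approx(sps.f.sf(21.0, 2, 6), rel=1e-9)

    def test_shifted_group_flagged(self, rng):
        g = {
            "P1": rng.normal(0, 0.1, 10),
            "P2": rng.normal(0, 0.1, 10),
            "P3": rng.normal(10, 0.1, 10),
        }
        res = epoch_anova_tukey(g)
        flagged = res.tukey[res.tukey["reject"].astype(bool)]
        pairs = {frozenset((r["group1"], r["group2"])) for _, r in flagged.iterrows()}
        assert frozenset(("P1", "P3")) in pairs
        assert frozenset(("P2", "P3")) in pairs
        assert frozenset(("P1", "P2")) not in pairs

    def test_tukey_symmetric_under_relabeling(self, rng):
        a, b, c = rng.normal(0, 1, 8), rng.normal(1, 1, 8), rng.normal(2, 1, 8)
        res1 = epoch_anova_tukey({"X": a, "Y": b, "Z": c})
        res2 = epoch_anova_tukey({"X": c, "Y": b, "Z": a})
        # the X-Z comparison flips sign but keeps magnitude and CI width
        r1 = res1.tukey.set_index(["group1", "group2"]).loc[("X", "Z")]
        r2 = res2.tukey.set_index(["group1", "group2"]).loc[("X", "Z")]
        assert float(r1["meandiff"]) == pytest.approx(-float(r2["meandiff"]), rel=1e-9)
        w1 = float(r1["upper"]) - float(r1["lower"])
        w2 = float(r2["upper"]) - float(r2["lower"])
        assert w1 == pytest.approx(w2, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(SahcError):
            epoch_anova_tukey({"A": np.array([1.0]), "B": np.array([1.0, 2.0])})


class TestChiSquared:
    def test_equal_proportions_near_zero(self):
        stat, df, p = pss_chi_squared(np.array([[10, 50], [10, 50], [10, 50]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_hand_formula_2x2(self):
        # O = [[10,0],[5,5]]; E = [[7.5,2.5],[7.5,2.5]];
        # chi2 = sum (O-E)^2/E = 2*(2.5^2/7.5 + 2.5^2/2.5) = 20/3
        stat, df, p = pss_chi_squared(np.array([[10, 0], [5, 5]]))
        assert stat == pytest.approx(20.0 / 3.0, rel=1e-12)
        assert df == 1

    def test_zero_margin_error(self):
        with pytest.raises(SahcError):
            pss_chi_squared(np.array([[0, 10], [0, 20]]))

    def test_non_integer_rejected(self):
        with pytest.raises(SahcError):
            pss_chi_squared(np.array([[1.5, 2], [3, 4]]))


class TestCorrelation:
    def test_exact_linear_r_one(self):
        x = np.arange(10.0)
        r, p = delta_correlation(x, 2 * x)
        assert r == pytest.approx(1.0)

    def test_near_perfect_negative(self, rng):
        x = np.arange(20.0)
        r, _ = delta_correlation(x, -x + rng.normal(0, 1e-6, 20))
        assert r == pytest.approx(-1.0, abs=1e-6)

    def test_zero_variance_error(self):
        with pytest.raises(ZeroVarianceError):
            delta_correlation(np.ones(5), np.arange(5.0))

    def test_too_few_points(self):
        with pytest.raises(SahcError):
            delta_correlation(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestPositionCoding:
    def test_codes_are_axis_offsets_in_head_units(self):
        assert POSITION_CODE == {"P1": 2.0, "P2": 1.0, "P3": 0.0}

    def test_add_position_code(self):
        table = pd.DataFrame({"position": ["P1", "P3"]})
        out = add_position_code(table)
        assert list(out["position_code"]) == [2.0, 0.0]

    def test_unknown_position_rejected(self):
        with pytest.raises(SahcError):
            add_position_code(pd.DataFrame({"position": ["P9"]}))
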