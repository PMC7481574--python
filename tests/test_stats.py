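"""Statistical machinery against independent oracles: pingouin for the
repeated-measures ANOVA, statsmodels for the Type-III screen, exhaustive
enumeration for rank statistics, and constructed populations for
correlations, moderation and mediation."""

import numpy as np
import pandas as pd
import pytest

from qeegnfb.stats import (
    bh_adjust,
    correlate,
    log_scores,
    glm_screen,
    lda_wilks,
    mann_whitney,
    mediation_screen,
    moderation_regression,
    rm_anova,
    roc_auc,
)


def _long(y: np.ndarray, labels=None) -> pd.DataFrame:
    n, k = y.shape
    df = pd.DataFrame(
        {
            "s": np.repeat(np.arange(n), k),
            "t": np.tile([f"t{j}" for j in range(k)], n),
            "y": y.ravel(),
        }
    )
    if labels is not None:
        df["g"] = np.repeat(labels, k)
    return df


class TestRmAnova:
    def test_matches_reference_implementation_20x3(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2024)
        y = rng.normal(size=(20, 3)) + np.array([0.0, 0.4, 0.7]) + rng.normal(
            size=(20, 1)
        )
        df = _long(y)
        mine = rm_anova(df, "y", "t", "s").iloc[0]
        ref = pg.rm_anova(data=df, dv="y", within="t", subject="s",
                          correction=True).iloc[0]
        assert mine["F"] == pytest.approx(ref["F"], abs=1e-6)
        assert mine["eps_gg"] == pytest.approx(ref["eps"], abs=1e-6)
        assert mine["df1"] == pytest.approx(ref["ddof1"] * ref["eps"], abs=1e-6)
        assert mine["df2"] == pytest.approx(ref["ddof2"] * ref["eps"], abs=1e-6)
        assert mine["p"] == pytest.approx(ref["p_GG_corr"], abs=1e-6)
        assert mine["p_uncorrected"] == pytest.approx(ref["p_unc"], abs=1e-6)

    def test_mixed_design_matches_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        y = rng.normal(size=(24, 3)) + np.array([0.0, 0.3, 0.6])
        labels = np.repeat(["a", "b"], 12)
        y[12:] += 0.5
        df = _long(y, labels)
        mine = rm_anova(df, "y", "t", "s", between="g")
        ref = pg.mixed_anova(data=df, dv="y", within="t", subject="s", between="g")
        ref_f = {"t": float(ref.loc[ref.Source == "t", "F"].iloc[0]),
                 "t:g": float(ref.loc[ref.Source == "Interaction", "F"].iloc[0]),
                 "g": float(ref.loc[ref.Source == "g", "F"].iloc[0])}
        got = dict(zip(mine["effect"], mine["F"]))
        for k, v in ref_f.items():
            assert got[k] == pytest.approx(v, abs=1e-6)

    def test_no_change_gives_null_result(self):
        y = np.tile(np.arange(10.0)[:, None], (1, 3))
        res = rm_anova(_long(y), "y", "t", "s").iloc[0]
        assert res["F"] == pytest.approx(0.0, abs=1e-10) and res["p"] > 0.99

    def test_two_levels_epsilon_is_one(self, rng):
        y = rng.normal(size=(12, 2))
        res = rm_anova(_long(y), "y", "t", "s").iloc[0]
        assert res["eps_gg"] == 1.0

    def test_correction_off_equals_uncorrected(self, rng):
        y = rng.normal(size=(15, 4))
        on = rm_anova(_long(y), "y", "t", "s", correction=True).iloc[0]
        off = rm_anova(_long(y), "y", "t", "s", correction=False).iloc[0]
        assert off["F"] == pytest.approx(on["F"])
        assert off["p"] == pytest.approx(on["p_uncorrected"])


class TestGlmScreen:
    def test_matches_statsmodels_type3(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.formula.api import ols

        n = 80
        df = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "age": rng.uniform(6, 60, n),
                "remission": rng.random(n) < 0.5,
                "sex": rng.choice(["m", "f"], n),
                "protocol": rng.choice(["SMR", "TBR", "other"], n),
            }
        )
        mine = glm_screen(df, "y", covariate="age", factors=("protocol", "sex"))
        m = ols("y ~ age + C(remission, Sum) * C(sex, Sum) * C(protocol, Sum)",
                df).fit()
        ref = sm.stats.anova_lm(m, typ=3)
        pairs = {
            "remission": "C(remission, Sum)",
            "remission:sex": "C(remission, Sum):C(sex, Sum)",
            "remission:protocol": "C(remission, Sum):C(protocol, Sum)",
            "remission:protocol:sex": "C(remission, Sum):C(sex, Sum):C(protocol, Sum)",
        }
        got = mine.set_index("effect")
        for k, rk in pairs.items():
            assert got.loc[k, "F"] == pytest.approx(ref.loc[rk, "F"], abs=1e-8)
            assert got.loc[k, "p"] == pytest.approx(ref.loc[rk, "PR(>F)"], abs=1e-8)

    def test_constant_predictor_flat(self, rng):
        df = pd.DataFrame(
            {"y": np.ones(30), "age": rng.uniform(6, 60, 30),
             "remission": rng.random(30) < 0.5, "sex": rng.choice(["m", "f"], 30)}
        )
        with pytest.warns(UserWarning, match="constant predictor"):
            tab = glm_screen(df, "y", factors=("sex",))
        assert (tab["F"] <= 1e-10).all()

    def test_constant_covariate_dropped(self, rng):
        df = pd.DataFrame(
            {"y": rng.normal(size=30), "age": np.full(30, 10.0),
             "remission": rng.random(30) < 0.5, "sex": rng.choice(["m", "f"], 30)}
        )
        with pytest.warns(UserWarning, match="constant"):
            glm_screen(df, "y", factors=("sex",))

    def test_injected_group_shift_recovered(self):
        rng = np.random.default_rng(99)
        n = 2000
        remission = rng.random(n) < 0.55
        y = rng.normal(size=n) + np.where(remission, 0.0, 0.56)
        df = pd.DataFrame({"y": y, "remission": remission,
                           "sex": rng.choice(["m", "f"], n)})
        tab = glm_screen(df, "y", covariate=None, factors=("sex",))
        f_rem = float(tab.set_index("effect").loc["remission", "F"])
        # convert the F for the two-level factor back to a standardized d
        n1, n0 = remission.sum(), (~remission).sum()
        d_hat = np.sqrt(f_rem * (1 / n1 + 1 / n0))
        assert d_hat == pytest.approx(0.56, abs=0.1)


class TestWilksRoc:
    def test_lambda_equals_hand_ss_ratio(self, rng):
        x = rng.normal(size=10)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        g0, g1 = x[labels == 0], x[labels == 1]
        ssw = ((g0 - g0.mean()) ** 2).sum() + ((g1 - g1.mean()) ** 2).sum()
        sst = ((x - x.mean()) ** 2).sum()
        res = lda_wilks(x, labels)
        assert res.statistic == pytest.approx(ssw / sst, abs=1e-12)
        n = x.size
        assert res.extra["chi2"] == pytest.approx(
            -(n - 1 - 1.5) * np.log(ssw / sst), abs=1e-12
        )

    def test_identical_groups_lambda_one(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        res = lda_wilks(x, np.array([0, 0, 0, 1, 1, 1]))
        assert res.statistic == pytest.approx(1.0) and res.extra["chi2"] == pytest.approx(0.0)

    def test_lambda_decreases_with_separation(self, rng):
        lams = []
        for shift in (0.0, 1.0, 3.0):
            x = np.concatenate([rng.normal(size=50), rng.normal(size=50) + shift])
            labels = np.repeat([0, 1], 50)
            lams.append(lda_wilks(x, labels).statistic)
        assert lams[0] > lams[1] > lams[2]
        assert all(0 < l <= 1 for l in lams)

    def test_auc_equals_exhaustive_pair_counting(self, rng):
        for _ in range(100):
            s = rng.integers(0, 6, 15).astype(float)  # ties likely
            labels = rng.random(15) < 0.5
            if labels.all() or not labels.any():
                continue
            pos, neg = s[labels], s[~labels]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert roc_auc(s, labels) == pytest.approx(
                wins / (pos.size * neg.size), abs=1e-12
            )

    def test_auc_extremes(self):
        assert roc_auc(np.arange(10.0), np.arange(10) >= 5) == 1.0
        assert roc_auc(np.ones(10), np.arange(10) >= 5) == 0.5

    def test_auc_complement_under_negation(self, rng):
        s = rng.normal(size=40)  # continuous, tie-free
        labels = rng.random(40) < 0.4
        assert roc_auc(s, labels) + roc_auc(-s, labels) == pytest.approx(1.0)

    def test_discriminant_ranking_matches_raw_predictor(self, rng):
        s = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        # any monotone rescaling (a discriminant score is one) keeps the AUC
        assert roc_auc(2.5 * s - 3, labels) == pytest.approx(roc_auc(s, labels))


class TestMannWhitney:
    def test_matches_exhaustive_enumeration(self, rng):
        x = rng.integers(0, 10, 6).astype(float)
        y = rng.integers(0, 10, 5).astype(float)
        u_brute = sum((a > b) + 0.5 * (a == b) for a in x for b in y)
        assert mann_whitney(x, y).statistic == pytest.approx(u_brute)

    def test_identical_groups_midpoint(self):
        x = np.array([1.0, 2.0, 3.0])
        res = mann_whitney(x, x.copy())
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)

    def test_complete_separation_zero(self):
        res = mann_whitney(np.array([1.0, 2.0]), np.array([5.0, 6.0, 7.0]))
        assert res.statistic == 0.0

    def test_p_matches_scipy_asymptotic(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.normal(size=14)
        y = rng.normal(size=11) + 0.5
        res = mann_whitney(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestCorrelate:
    def test_spearman_perfect_under_monotone_transform(self, rng):
        x = rng.normal(size=30)
        y = np.exp(3 * x) + 5  # strictly increasing
        assert correlate(x, y, "spearman").statistic == pytest.approx(1.0)

    def test_partial_matches_construction(self):
        # trivariate normal with r_xz = r_yz = 0.5 and r_xy chosen so the
        # partial correlation of x and y given z is exactly 0.4
        rng = np.random.default_rng(11)
        n = 5000
        r_xy = 0.4 * (1 - 0.25) + 0.25
        cov = np.array([[1.0, r_xy, 0.5], [r_xy, 1.0, 0.5], [0.5, 0.5, 1.0]])
        x, y, z = rng.multivariate_normal(np.zeros(3), cov, size=n).T
        r = correlate(x, y, control=z).statistic
        assert r == pytest.approx(0.4, abs=0.05)

    def test_independent_control_leaves_r_unchanged(self):
        rng = np.random.default_rng(21)
        n = 5000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)  # unrelated
        r0 = correlate(x, y).statistic
        rp = correlate(x, y, control=z).statistic
        assert rp == pytest.approx(r0, abs=0.03)

    def test_df_accounting(self, rng):
        x, y, z = rng.normal(size=(3, 20))
        assert correlate(x, y).df == 18
        assert correlate(x, y, control=z).df == 17

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = correlate(np.ones(10), np.arange(10.0))
        assert np.isnan(res.statistic)


class TestModeration:
    def test_injected_interaction_recovered(self):
        rng = np.random.default_rng(5)
        n = 2000
        a, b = rng.normal(size=(2, n))
        y = 0.3 * a - 0.2 * b + 0.5 * a * b + rng.normal(size=n)
        res = moderation_regression(y, a, b)
        assert res.extra["coef"] == pytest.approx(0.5, abs=0.1)
        assert res.p < 0.001

    def test_null_interaction_not_significant(self):
        rng = np.random.default_rng(6)
        n = 500
        a, b = rng.normal(size=(2, n))
        y = 0.3 * a + 0.2 * b + rng.normal(size=n)
        assert moderation_regression(y, a, b).p > 0.01

    def test_constant_moderator_rejected(self, rng):
        with pytest.raises(ValueError):
            moderation_regression(rng.normal(size=10), rng.normal(size=10),
                                  np.ones(10))


class TestHelpers:
    def test_bh_adjustment_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)

    def test_log_scores_handles_zeros(self):
        assert log_scores([0.0, np.e - 1.0])[1] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            log_scores([-2.0])


class TestMediation:
    def test_full_chain_detected(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.normal(size=n)
        m = 0.6 * x + 0.6 * rng.normal(size=n)
        y = 0.6 * m + 1.2 * rng.normal(size=n)  # no direct x path
        assert mediation_screen(x, m, y)["verdict"] == "mediation"

    def test_unrelated_mediator_rejected(self):
        rng = np.random.default_rng(9)
        n = 500
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        m = rng.normal(size=n)
        res = mediation_screen(x, m, y)
        assert res["verdict"] == "no mediation"
        assert not res["criterion_1_x_affects_m"]

    def test_study_pattern_no_mediation(self):
        """SBD relates to hyperactivity and hyperactivity to response, but
        SBD does not relate to response: the screen must not call mediation."""
        rng = np.random.default_rng(10)
        n = 400
        hyp = rng.normal(size=n)
        sbd = 0.36 * hyp + np.sqrt(1 - 0.36**2) * rng.normal(size=n)
        response = 0.31 * hyp + np.sqrt(1 - 0.31**2) * rng.normal(size=n)
        response = response - 0.31 * 0.36 * sbd  # cancel the induced sbd link
        res = mediation_screen(sbd, hyp, response)
        assert res["verdict"] == "no mediation"
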