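import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from eyeblink.stats_models import (
    ModelSpec,
    compress_proportions,
    fit_beta_mixed,
    fit_cox_frailty,
    fit_lmm,
    fit_trialwise_logistic,
    holm_adjust,
    lr_test,
    power_sample_size,
    t_test_power,
)


class TestLRTest:
    def test_identical_logliks(self):
        stat, df, p = lr_test(-100.0, -100.0, 3, 4)
        assert stat == 0.0 and p == 1.0

    def test_chi2_quantile(self):
        stat, df, p = lr_test(-10.0, -8.08, 1, 2)
        assert stat == pytest.approx(3.84)
        assert p == pytest.approx(sps.chi2.sf(3.84, 1), abs=1e-12)
        assert p == pytest.approx(0.0500, abs=5e-4)

    def test_zero_statistic_many_df(self):
        assert lr_test(-5.0, -5.0, 1, 4)[2] == 1.0

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lr_test(-5.0, -4.0, 4, 4)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            lr_test(-4.0, -5.0, 1, 2)


class TestHolm:
    def test_hand_computed_case(self):
        assert np.allclose(holm_adjust([0.01, 0.04, 0.03]),
                           [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.all(holm_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_dominance_and_monotonicity(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all((adj > 0) & (adj <= 1))
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)
        if len(ps) == 1:  # Holm equals Bonferroni for m = 1
            assert adj[0] == pytest.approx(min(ps[0], 1.0))


class TestPower:
    def test_planning_scenario(self):
        assert power_sample_size(0.2, 0.2, power=0.80, alpha=0.05) == 17

    @pytest.mark.parametrize("d", [0.5, 1.0, 2.0])
    def test_matches_statsmodels_power_oracle(self, d):
        from statsmodels.stats.power import TTestIndPower

        n = power_sample_size(d, 1.0, power=0.80, alpha=0.05)
        n_oracle = TTestIndPower().solve_power(effect_size=d, power=0.80,
                                               alpha=0.05)
        assert n == int(np.ceil(n_oracle))

    def test_monotone_in_effect_size(self):
        assert (power_sample_size(1.0, 1.0) >= power_sample_size(2.0, 1.0))

    def test_power_curve_monotone_in_n(self):
        powers = [t_test_power(0.8, n) for n in range(2, 40)]
        assert np.all(np.diff(powers) > 0)

    def test_impossible_request_rejected(self):
        with pytest.raises(ValueError):
            power_sample_size(1.0, 1.0, power=0.04, alpha=0.05)
        with pytest.raises(ValueError):
            power_sample_size(-1.0, 1.0)


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _trial_table(rng, n_mice=8, days=3, trials=12, re_sd=0.0, geno_or=1.0):
    rows = []
    for geno, shift in (("WT", 0.0), ("NF1_HET", np.log(geno_or))):
        for i in range(n_mice):
            u = rng.normal(0, re_sd) if re_sd else 0.0
            for day in range(1, days + 1):
                p = _invlogit(-1.0 + 0.4 * day + shift + u)
                for t in range(trials):
                    rows.append(dict(mouse=f"{geno}{i}", genotype=geno,
                                     day=day, is_cr=int(rng.random() < p)))
    return pd.DataFrame(rows)


class TestTrialwiseLogistic:
    def test_matches_plain_logit_without_random_effects(self):
        import statsmodels.api as sm

        df = _trial_table(np.random.default_rng(0), n_mice=12, trials=25)
        res = fit_trialwise_logistic(
            df, ModelSpec(outcome="is_cr", family="binomial",
                          random="intercept"))
        from eyeblink.stats_models import _Design
        d = _Design(df, ModelSpec(outcome="is_cr", family="binomial"))
        ref = sm.Logit(df["is_cr"].to_numpy(), d.X).fit(disp=0)
        # zero true RE variance: mixed estimates collapse onto plain logistic
        assert np.allclose(res.coef["estimate"], ref.params, atol=0.05)

    def test_degenerate_outcome_rejected(self):
        df = _trial_table(np.random.default_rng(0), n_mice=2, trials=2)
        df["is_cr"] = 0
        with pytest.raises(ValueError):
            fit_trialwise_logistic(df)

    def test_session_aggregation_matches_trialwise_inference(self):
        df = _trial_table(np.random.default_rng(3), n_mice=6, re_sd=0.5)
        spec = ModelSpec(outcome="is_cr", family="binomial", random="intercept")
        a = fit_trialwise_logistic(df, spec, aggregate="trial")
        b = fit_trialwise_logistic(df, spec, aggregate="session")
        assert np.allclose(a.coef["estimate"], b.coef["estimate"], atol=1e-3)

    def test_posthoc_odds_ratios_recovered(self):
        rng = np.random.default_rng(4)
        df = _trial_table(rng, n_mice=20, days=3, trials=25, re_sd=0.4,
                          geno_or=3.0)
        res = fit_trialwise_logistic(
            df, ModelSpec(outcome="is_cr", family="binomial",
                          random="intercept"))
        ors = res.posthoc["ratio"].to_numpy()
        assert np.all(ors > 1.3) and np.all(ors < 7.0)
        assert np.all(res.posthoc["adj_p"] >= res.posthoc["raw_p"] - 1e-15)


class TestLMM:
    def test_no_group_difference_gives_null_contrasts(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(8):
            u = rng.normal(0, 0.1)
            noise = rng.normal(0, 0.05, 4)
            for geno in ("WT", "NF1_HET"):  # mirrored outcomes, equal groups
                for day in range(1, 5):
                    rows.append(dict(mouse=f"{geno}{i}", genotype=geno,
                                     day=day, y=0.2 + 0.1 * day + u
                                     + noise[day - 1]))
        res = fit_lmm(pd.DataFrame(rows),
                      ModelSpec(outcome="y", family="gaussian",
                                random="intercept"))
        assert np.allclose(res.posthoc["estimate"], 0.0, atol=1e-6)
        assert (res.posthoc["raw_p"] > 0.99).all()
        geno_p = res.terms.set_index("term").loc["genotype", "p"]
        assert geno_p > 0.9

    def test_log_transform_backtranslates_to_geometric_mean(self):
        rng = np.random.default_rng(6)
        vals = np.exp(rng.normal(np.log(50.0), 0.2, 64))
        rows = [dict(mouse=f"m{i % 16}", genotype="WT", day=1 + i % 4,
                     y=vals[i]) for i in range(64)]
        res = fit_lmm(pd.DataFrame(rows),
                      ModelSpec(outcome="y", family="gaussian",
                                transform="log", random="intercept",
                                interaction=False), terms=())
        # intercept-plus-day average on the log scale ~ geometric mean
        names = list(res.coef["name"])
        beta = res.coef["estimate"].to_numpy()
        day_cols = [i for i, n in enumerate(names) if n.startswith("day[")]
        mean_log = beta[0] + np.mean([0.0] + [beta[i] for i in day_cols])
        gm = np.exp(np.mean(np.log(vals)))
        assert np.exp(mean_log) == pytest.approx(gm, rel=0.02)


class TestAgainstGlmerReference:
    def test_random_intercept_logistic_matches_lme4(self):
        # reference values computed with lme4::glmer on the identical
        # seeded dataset: y ~ x + (1 | cl), family = binomial
        rng = np.random.default_rng(1)
        q, m = 24, 50
        b = rng.normal(0, 1.0, q)
        x = rng.normal(0, 1, q * m)
        cl = np.repeat(np.arange(q), m)
        eta = -0.5 + 0.8 * x + b[cl]
        y = (rng.random(q * m) < _invlogit(eta)).astype(float)
        from eyeblink._mixed_glm import MixedGLM

        X = np.column_stack([np.ones(q * m), x])
        fit = MixedGLM(y, X, cl, "binomial").fit()
        assert fit.beta_[0] == pytest.approx(-0.2768711, abs=2e-3)
        assert fit.beta_[1] == pytest.approx(0.8034524, abs=2e-3)
        assert fit.sigma_ == pytest.approx(0.57602, abs=2e-3)
        assert fit.loglik_ == pytest.approx(-730.7815, abs=0.01)
        se = np.sqrt(np.diag(fit.beta_cov()))
        assert se[0] == pytest.approx(0.13399, abs=0.005)

    def test_intercept_plus_day_effects_matches_lme4(self):
        # glmer reference: y ~ day + (1|mouse) + (1|mouse:day)
        rng = np.random.default_rng(11)
        rows = []
        for i in range(20):
            u = rng.normal(0, 0.5)
            sl = rng.normal(0, 0.7, 4)
            for day in range(4):
                for t in range(12):
                    eta = -0.3 + 0.3 * day + u + sl[day]
                    rows.append(dict(mouse=i, day=day,
                                     y=int(rng.random() < _invlogit(eta))))
        df = pd.DataFrame(rows)
        from eyeblink._mixed_glm import MixedGLM

        X = np.column_stack([np.ones(len(df)), df.day == 1, df.day == 2,
                             df.day == 3]).astype(float)
        fit = MixedGLM(df.y.to_numpy(float), X, df.mouse.to_numpy(),
                       "binomial", Z_levels=df.day.to_numpy()).fit()
        assert np.allclose(fit.beta_,
                           [-0.6662991, 0.5021174, 0.8827290, 1.1891269],
                           atol=3e-3)
        assert np.exp(fit.params_[4]) == pytest.approx(0.69293, abs=3e-3)
        assert np.exp(fit.params_[5]) == pytest.approx(0.66111, abs=3e-3)
        assert fit.loglik_ == pytest.approx(-607.9163, abs=0.01)


class TestRandomStructureSelection:
    def test_zero_slope_variance_prefers_intercepts(self):
        chosen = []
        for rep in range(6):
            rng = np.random.default_rng(100 + rep)
            rows = []
            for geno in ("WT", "NF1_HET"):
                for i in range(10):
                    u = rng.normal(0, 0.3)
                    for day in range(1, 5):
                        rows.append(dict(mouse=f"{geno}{i}", genotype=geno,
                                         day=day,
                                         y=u + 0.1 * day + rng.normal(0, 0.2)))
            res = fit_lmm(pd.DataFrame(rows),
                          ModelSpec(outcome="y", family="gaussian",
                                    random="auto"), terms=())
            chosen.append(res.chosen_random_structure)
        assert chosen.count("intercepts_per_mouse") >= 5

    def test_large_slope_variance_prefers_slopes(self):
        chosen = []
        for rep in range(6):
            rng = np.random.default_rng(200 + rep)
            rows = []
            for geno in ("WT", "NF1_HET"):
                for i in range(10):
                    slopes = rng.normal(0, 0.8, 4)
                    for day in range(1, 5):
                        for r in range(3):
                            rows.append(dict(
                                mouse=f"{geno}{i}", genotype=geno, day=day,
                                y=0.1 * day + slopes[day - 1]
                                + rng.normal(0, 0.1)))
            res = fit_lmm(pd.DataFrame(rows),
                          ModelSpec(outcome="y", family="gaussian",
                                    random="auto"), terms=())
            chosen.append(res.chosen_random_structure)
        assert chosen.count("slopes_per_day_per_mouse") >= 5


class TestBetaMixed:
    def test_boundary_value_rejected_with_guidance(self):
        df = pd.DataFrame(dict(mouse=["a", "a", "b", "b"],
                               genotype=["WT"] * 4, day=[1, 2, 1, 2],
                               prop_correct=[0.5, 1.0, 0.4, 0.6]))
        with pytest.raises(ValueError, match="compression"):
            fit_beta_mixed(df)

    def test_compression_rule(self):
        y = np.array([0.0, 0.5, 1.0])
        out = compress_proportions(y)
        assert np.all((out > 0) & (out < 1))
        assert out[1] == pytest.approx(0.5)

    def test_identical_proportions_give_null_genotype_test(self):
        rows = []
        for geno in ("WT", "NF1_HET"):
            for i in range(4):
                for day in (1, 2):
                    rows.append(dict(mouse=f"{geno}{i}", genotype=geno,
                                     day=day, prop_correct=0.7))
        res = fit_beta_mixed(pd.DataFrame(rows), terms=("genotype",))
        stat = res.terms.set_index("term").loc["genotype", "statistic"]
        assert abs(stat) < 0.1

    def test_known_day_effect_recovered(self):
        rng = np.random.default_rng(8)
        rows = []
        for geno in ("WT", "NF1_HET"):
            for i in range(10):
                u = rng.normal(0, 0.3)
                for day in (1, 2, 3):
                    mu = _invlogit(0.3 + 0.5 * (day - 1) + u)
                    for t in range(6):
                        y = np.clip(rng.beta(mu * 12, (1 - mu) * 12),
                                    1e-5, 1 - 1e-5)
                        rows.append(dict(mouse=f"{geno}{i}", genotype=geno,
                                         day=day, prop_correct=float(y)))
        res = fit_beta_mixed(
            pd.DataFrame(rows),
            ModelSpec(outcome="prop_correct", family="beta",
                      random="intercept"), terms=("day",))
        assert res.terms.set_index("term").loc["day", "p"] < 0.001
        day2 = res.coef.set_index("name").loc["day[2]", "estimate"]
        assert 0.2 < day2 < 0.8  # true 0.5 on the logit scale


class TestCoxFrailty:
    def test_hazard_ratio_recovered(self):
        ests = []
        for rep in range(15):
            rng = np.random.default_rng(300 + rep)
            rows = []
            for geno, hr in (("WT", 1.0), ("NF1_HET", 2.0)):
                for i in range(25):
                    for t in range(2):
                        lat = rng.exponential(1.0 / (0.01 * hr))
                        rows.append(dict(mouse=f"{geno}{i}", genotype=geno,
                                         day=1, latency_s=lat,
                                         censored=False))
            res = fit_cox_frailty(pd.DataFrame(rows))
            hr_est = np.exp(res.coef.set_index("name")
                            .loc["genotype[NF1_HET]", "estimate"])
            ests.append(hr_est)
        assert 1.6 < np.mean(ests) < 2.5

    def test_all_censored_rejected(self):
        df = pd.DataFrame(dict(mouse=["a", "b"], genotype=["WT", "NF1_HET"],
                               day=[1, 1], latency_s=[300.0, 300.0],
                               censored=[True, True]))
        with pytest.raises(ValueError):
            fit_cox_frailty(df)

    def test_matches_lifelines_when_frailty_vanishes(self):
        from lifelines import CoxPHFitter

        from eyeblink._cox_frailty import CoxFrailty

        rng = np.random.default_rng(9)
        n = 120
        grp = (np.arange(n) % 2).astype(float)
        lat = rng.exponential(1.0 / (0.02 * np.exp(0.5 * grp)))
        model = CoxFrailty(lat, np.ones(n, bool), grp.reshape(-1, 1),
                           np.arange(n) % 10)
        beta0, _, _ = model._fit_coefs(1e-10)
        ref = CoxPHFitter().fit(
            pd.DataFrame(dict(T=lat, E=1, g=grp)), "T", "E")
        assert beta0[0] == pytest.approx(ref.params_.iloc[0], abs=1e-6)
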