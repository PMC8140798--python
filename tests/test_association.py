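"""ANOVA/Tukey and DCR-logistic stages against hand values and oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methcascade import anova_tukey, fit_dcr_logistic, select_response_probes
from methcascade.association import (AnovaTukeySelector, DcrLogisticSelector,
                                     anova_tukey_matrix, fit_dcr_matrix)
from methcascade.errors import DataError


def test_identical_groups_give_zero_f():
    r = anova_tukey([1, 2, 3, 1, 2, 3, 1, 2, 3],
                    ["PD"] * 3 + ["SD"] * 3 + ["PR"] * 3)
    assert r.f_statistic == 0.0
    assert r.p_anova == 1.0


def test_f_statistic_hand_computation():
    # SSB/2 = 0.08, SSW/3 = 0.005 -> F = 16
    r = anova_tukey([0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
                    ["PD", "PD", "SD", "SD", "PR", "PR"])
    assert r.f_statistic == pytest.approx(16.0, rel=1e-12)
    assert r.p_anova == pytest.approx(stats.f.sf(16.0, 2, 3), rel=1e-12)


def test_f_invariant_under_constant_shift(rng):
    betas = rng.uniform(0.1, 0.9, 30)
    groups = np.repeat(["PD", "SD", "PR"], 10)
    f1 = anova_tukey(betas, groups).f_statistic
    f2 = anova_tukey(betas + 5.0, groups).f_statistic
    assert f1 == pytest.approx(f2, rel=1e-9)


def test_anova_p_matches_permutation_null(rng):
    betas = rng.normal(0.5, 0.1, 24)
    betas[:8] += 0.05
    groups = np.repeat(["PD", "SD", "PR"], 8)
    obs = anova_tukey(betas, groups)
    splits = [betas[groups == g] for g in ("PD", "SD", "PR")]
    assert obs.f_statistic == pytest.approx(stats.f_oneway(*splits).statistic)
    perm_f = np.empty(10_000)
    for i in range(10_000):
        perm = rng.permutation(betas)
        perm_f[i] = stats.f_oneway(perm[:8], perm[8:16], perm[16:]).statistic
    p_perm = np.mean(perm_f >= obs.f_statistic - 1e-12)
    se = np.sqrt(p_perm * (1 - p_perm) / 10_000)
    assert abs(obs.p_anova - p_perm) < max(4 * se, 0.01)


def test_tukey_adjusted_p_not_below_pairwise_t(rng):
    betas = rng.normal(0.4, 0.15, 30)
    groups = np.repeat(["PD", "SD", "PR"], 10)
    r = anova_tukey(betas, groups)
    for (a, b), p_adj in r.tukey_p.items():
        ga, gb = betas[groups == a], betas[groups == b]
        p_t = stats.ttest_ind(ga, gb).pvalue
        assert p_adj >= p_t - 1e-9


def test_tukey_p_against_monte_carlo_studentized_range(rng):
    """Studentized-range tail from scipy agrees with direct simulation."""
    k, df_w, n_per = 3, 27, 10
    q_obs = 3.2
    draws = rng.normal(size=(20_000, k))
    chi = rng.chisquare(df_w, size=20_000) / df_w
    q_sim = (draws.max(axis=1) - draws.min(axis=1)) / np.sqrt(chi)
    p_mc = np.mean(q_sim >= q_obs)
    p_num = stats.studentized_range.sf(q_obs, k, df_w)
    assert abs(p_mc - p_num) < 4 * np.sqrt(p_mc * (1 - p_mc) / 20_000) + 0.005


def test_small_group_flagged_and_pair_excluded():
    r = anova_tukey([0.1, 0.2, 0.3, 0.4, 0.5],
                    ["PD", "PD", "SD", "SD", "PR"])
    assert any("PR" in f for f in r.flags)
    assert np.isnan(r.tukey_p[("PD", "PR")])


def test_matrix_anova_matches_per_probe(small_cohort):
    _, samples, meth, _, _, _ = small_cohort
    sub = meth.iloc[:, :25]
    mat = anova_tukey_matrix(sub, samples["response"].to_numpy())
    for pid in sub.columns[:10]:
        r = anova_tukey(sub[pid].to_numpy(), samples["response"].to_numpy())
        assert mat.loc[pid, "f_statistic"] == pytest.approx(r.f_statistic, rel=1e-9)
        assert mat.loc[pid, "p_anova"] == pytest.approx(r.p_anova, rel=1e-9)
        for (a, b), p in r.tukey_p.items():
            assert mat.loc[pid, f"tukey_p_{a}_{b}"] == pytest.approx(p, rel=1e-6)


def test_binary_predictor_coefficient_is_log_odds_ratio():
    # 2x2 table: exposed 20 events / 5 non-events, unexposed 10 / 15 -> OR 6
    x = np.array([1] * 25 + [0] * 25, dtype=float)
    y = np.array([1] * 20 + [0] * 5 + [1] * 10 + [0] * 15, dtype=float)
    r = fit_dcr_logistic(x, y)
    assert r.converged
    assert r.coef_univariate == pytest.approx(np.log(6.0), abs=1e-6)


def test_random_binary_predictors_match_table_log_or(rng):
    for _ in range(25):
        while True:
            x = rng.integers(0, 2, 60).astype(float)
            y = rng.integers(0, 2, 60).astype(float)
            a = np.sum((x == 1) & (y == 1)); b = np.sum((x == 1) & (y == 0))
            c = np.sum((x == 0) & (y == 1)); d = np.sum((x == 0) & (y == 0))
            if min(a, b, c, d) > 0:
                break
        r = fit_dcr_logistic(x, y)
        assert r.coef_univariate == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)


def test_constant_predictor_flagged():
    r = fit_dcr_logistic(np.full(20, 0.4), [0, 1] * 10)
    assert not r.converged and "constant_predictor" in r.flags
    assert np.isnan(r.p_univariate)


def test_perfect_separation_flagged():
    beta = np.linspace(0.1, 0.9, 20)
    y = (beta > 0.5).astype(int)
    r = fit_dcr_logistic(beta, y)
    assert not r.converged and "separation" in r.flags
    assert np.isnan(r.p_univariate)


def test_wald_and_lr_p_agree_for_moderate_effects(rng):
    x = rng.normal(0, 1, 400)
    y = (rng.random(400) < 1 / (1 + np.exp(-0.5 * x))).astype(float)
    r_lr = fit_dcr_logistic(x, y, p_method="lr")
    r_wald = fit_dcr_logistic(x, y, p_method="wald")
    assert r_lr.coef_univariate == pytest.approx(r_wald.coef_univariate, rel=1e-9)
    assert np.log10(r_lr.p_univariate) == pytest.approx(
        np.log10(r_wald.p_univariate), abs=0.3)


def test_single_class_labels_rejected():
    with pytest.raises(DataError):
        fit_dcr_logistic([0.1, 0.2, 0.3], [1, 1, 1])


def test_vacuous_thresholds_retain_all_converged(small_cohort):
    _, samples, meth, _, _, _ = small_cohort
    sub = meth.iloc[:, :30]
    assoc = anova_tukey_matrix(sub, samples["response"].to_numpy())
    models = fit_dcr_matrix(sub, samples["dcr"].to_numpy(),
                            samples[["egfr_mutant", "sex_male", "smoker"]])
    kept, counts = select_response_probes(assoc, models, 1.0, 1.0)
    assert set(kept) == set(models.index[models["converged"]])
    assert counts["n_input"] == 30


def test_planted_probes_recovered_through_both_stages(small_cohort):
    _, samples, meth, _, _, truth = small_cohort
    info = sorted(truth.informative_probe_ids)
    sub = meth[info]
    assoc = anova_tukey_matrix(sub, samples["response"].to_numpy())
    models = fit_dcr_matrix(sub, samples["dcr"].to_numpy(),
                            samples[["egfr_mutant", "sex_male", "smoker"]])
    kept, _ = select_response_probes(assoc, models, 0.05, 0.05)
    assert len(kept) / len(info) >= 0.6


def test_selectors_compose_with_sklearn_params(small_cohort):
    _, samples, meth, _, _, _ = small_cohort
    sub = meth.iloc[:, :40]
    sel = AnovaTukeySelector(alpha=0.2).fit(sub, samples["response"].to_numpy())
    assert sel.get_params()["alpha"] == 0.2
    out = sel.transform(sub)
    assert out.shape[1] == sel.get_support().sum()
    sel2 = DcrLogisticSelector(alpha=0.5).fit(out, samples["dcr"].to_numpy(),
                                              covariates=samples)
    assert set(sel2.retained_) <= set(out.columns)
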