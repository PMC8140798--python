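"""ROC/Youden/odds-ratio/rank-sum machinery against enumeration oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methcascade import (TwoByTwo, evaluate_marker, odds_ratio_exact,
                         quartile_summary, rank_sum_one_sided, roc_auc,
                         stratified_evaluation, youden_cutoff)
from methcascade.errors import DataError
from methcascade.simulate import generate_validation_cohort


def cross_pair_auc(pos, neg):
    """Independent AUROC oracle: enumerate every positive/negative pair."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_auc_perfect_separation_is_one():
    assert roc_auc([5, 6, 1, 2], [1, 1, 0, 0]) == 1.0


def test_auc_hand_enumerated_cross_pairs():
    values = [0.3, 0.5, 0.1, 0.2, 0.4]
    labels = [1, 1, 0, 0, 0]
    assert roc_auc(values, labels) == pytest.approx(5 / 6)


def test_auc_matches_cross_pair_oracle_random(rng):
    for _ in range(300):
        n1, n0 = rng.integers(2, 12, 2)
        pos = np.round(rng.normal(0.5, 0.3, n1), 1)  # rounding forces ties
        neg = np.round(rng.normal(0.3, 0.3, n0), 1)
        values = np.concatenate([pos, neg])
        labels = np.r_[np.ones(n1), np.zeros(n0)]
        assert roc_auc(values, labels) == pytest.approx(
            cross_pair_auc(pos, neg), abs=1e-12)


def test_auc_label_flip_complements(rng):
    values = rng.normal(size=30)  # continuous, tie-free
    labels = rng.integers(0, 2, 30)
    if len(set(labels)) < 2:
        labels[0], labels[1] = 0, 1
    assert roc_auc(values, labels) == pytest.approx(
        1 - roc_auc(values, 1 - labels), abs=1e-12)


def test_auc_and_youden_invariant_under_monotone_transform(rng):
    values = rng.uniform(0.01, 0.99, 40)
    labels = rng.integers(0, 2, 40)
    labels[:2] = [0, 1]
    f = lambda v: np.log(v / (1 - v))
    assert roc_auc(values, labels) == pytest.approx(roc_auc(f(values), labels))
    c1 = youden_cutoff(values, labels)
    c2 = youden_cutoff(f(values), labels)
    assert c1[3] == pytest.approx(c2[3], abs=1e-12)  # same maximal J
    assert c2[0] == pytest.approx(f(np.array([c1[0]]))[0])


def test_youden_enumerates_observed_thresholds():
    values = [0.3, 0.5, 0.1, 0.2, 0.4]
    labels = [1, 1, 0, 0, 0]
    cut, sens, spec, j = youden_cutoff(values, labels)
    assert cut == pytest.approx(0.3)
    assert sens == 1.0
    assert spec == pytest.approx(2 / 3)
    assert j == pytest.approx(2 / 3)


def test_youden_perfect_marker_cut_at_smallest_positive():
    cut, sens, spec, j = youden_cutoff([5, 6, 1, 2], [1, 1, 0, 0])
    assert (cut, sens, spec, j) == (5.0, 1.0, 1.0, 1.0)


def test_external_cutoff_classification_rule():
    ev = evaluate_marker([0.1, 0.2, 0.3, 0.05], [0, 1, 1, 0], cutoff=0.15)
    # 0.1 negative, 0.2 positive at cutoff .15
    assert ev.table.a == 2 and ev.table.d == 2
    assert ev.sensitivity == 1.0 and ev.specificity == 1.0
    assert ev.youden_j == pytest.approx(ev.sensitivity + ev.specificity - 1)


def test_odds_ratio_arithmetic_and_symmetric_table():
    orr, lo, hi, p = odds_ratio_exact(TwoByTwo(20, 10, 5, 15))
    assert orr == pytest.approx(6.0)
    assert lo <= orr <= hi
    orr2, _, _, p2 = odds_ratio_exact(TwoByTwo(5, 5, 5, 5))
    assert orr2 == pytest.approx(1.0)
    assert p2 == pytest.approx(1.0)


def test_or_transpose_and_row_swap_relations():
    t = TwoByTwo(12, 7, 4, 9)
    orr = odds_ratio_exact(t)[0]
    assert odds_ratio_exact(TwoByTwo(12, 4, 7, 9))[0] == pytest.approx(orr)
    assert odds_ratio_exact(TwoByTwo(4, 9, 12, 7))[0] == pytest.approx(1 / orr)


def test_woolf_ci_consistent_with_significance():
    for t in (TwoByTwo(20, 10, 5, 15), TwoByTwo(8, 8, 7, 9), TwoByTwo(30, 5, 6, 29)):
        orr, lo, hi, _ = odds_ratio_exact(t)
        se = math.sqrt(sum(1 / x for x in (t.a, t.b, t.c, t.d)))
        excludes_one = lo > 1 or hi < 1
        assert excludes_one == (abs(math.log(orr)) > 1.959963984540054 * se)


def test_zero_cell_gets_haldane_correction():
    orr, lo, hi, p = odds_ratio_exact(TwoByTwo(10, 0, 3, 12))
    expected = (10.5 * 12.5) / (0.5 * 3.5)
    assert orr == pytest.approx(expected)
    assert lo <= orr <= hi
    # exact p computed on the uncorrected table
    assert p == pytest.approx(stats.fisher_exact([[10, 0], [3, 12]])[1])


def test_zero_margin_is_an_error():
    with pytest.raises(DataError):
        odds_ratio_exact(TwoByTwo(0, 0, 3, 12))


def fisher_two_sided_oracle(a, b, c, d):
    """Sum of hypergeometric probabilities <= that of the observed table."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    obs = stats.hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= obs * (1 + 1e-7)].sum())


def test_fisher_p_matches_enumeration_small_margins(rng):
    for _ in range(200):
        a, b, c, d = rng.integers(1, 12, 4)
        p = odds_ratio_exact(TwoByTwo(int(a), int(b), int(c), int(d)))[3]
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-12)


def test_rank_sum_exact_enumeration_small():
    stat, p = rank_sum_one_sided([4, 5, 6], [1, 2, 3])
    assert p == pytest.approx(1 / 20)  # C(6,3) = 20 equally likely splits


def test_rank_sum_identical_multisets_near_half():
    _, p = rank_sum_one_sided([1, 2, 3], [1, 2, 3])
    assert p > 0.4


def test_rank_sum_large_sample_matches_permutation_mc(rng):
    x = rng.normal(0.5, 1.0, 30)
    y = rng.normal(0.0, 1.0, 40)
    stat, p = rank_sum_one_sided(x, y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    obs = ranks[:30].sum()
    n_mc = 100_000
    sums = np.empty(n_mc)
    for i in range(n_mc):
        idx = rng.permutation(70)[:30]
        sums[i] = ranks[idx].sum()
    p_mc = np.mean(sums >= obs - 1e-9)
    se = np.sqrt(p_mc * (1 - p_mc) / n_mc)
    assert abs(p - p_mc) <= 3 * se + 1e-4


def test_quartile_summary_top_quartile_pd_first():
    values = np.arange(1.0, 9.0)
    labels = np.array(["DC"] * 6 + ["PD"] * 2)
    df, flags = quartile_summary(values, labels)
    top = df[df["quartile"] == 4]
    assert set(top["group"]) == {"PD"}
    assert top["pd_first"].all()
    assert flags == ()


def test_quartile_summary_degenerate_values_flagged():
    df, flags = quartile_summary(np.ones(8), ["PD"] * 4 + ["DC"] * 4)
    assert "bins_merged" in flags


def test_stratified_single_stratum_matches_unstratified(rng):
    values = rng.uniform(0, 1, 40)
    labels = rng.integers(0, 2, 40)
    labels[:2] = [0, 1]
    whole = evaluate_marker(values, labels)
    strat = stratified_evaluation(values, labels, np.repeat("all", 40))
    assert strat["all"].odds_ratio == pytest.approx(whole.odds_ratio)
    assert strat["all"].cutoff == pytest.approx(whole.cutoff)


def test_stratified_identical_strata_identical_ors(rng):
    values = np.tile(rng.uniform(0, 1, 20), 2)
    labels = np.tile(np.r_[np.ones(8), np.zeros(12)].astype(int), 2)
    strat = np.repeat(["A", "B"], 20)
    out = stratified_evaluation(values, labels, strat)
    assert out["A"].odds_ratio == pytest.approx(out["B"].odds_ratio)


def test_stratified_missing_class_not_evaluable():
    values = np.r_[np.arange(10) / 10, np.arange(10) / 10]
    labels = np.r_[np.zeros(5), np.ones(5), np.zeros(10)].astype(int)
    out = stratified_evaluation(values, labels, np.repeat(["A", "B"], 10))
    assert out["B"] is None and out["A"] is not None


def test_stratified_equal_effect_log_ors_compatible():
    """Same planted shift in both strata -> per-stratum log-ORs within 2 SE."""
    ok = 0
    n_rep = 200
    for seed in range(n_rep):
        samples, pct = generate_validation_cohort(seed, n_samples=200,
                                                  pd_fraction=0.3, shift=8.0,
                                                  sd=5.0)
        labels = (samples["response"] == "PD").astype(int).to_numpy()
        strat = np.tile(["A", "B"], 100)
        out = stratified_evaluation(pct.to_numpy(), labels, strat)
        if out["A"] is None or out["B"] is None:
            continue
        lors, ses = [], []
        for s in ("A", "B"):
            t = out[s].table
            a, b, c, d = [x + 0.5 if min(t.a, t.b, t.c, t.d) == 0 else x
                          for x in (t.a, t.b, t.c, t.d)]
            lors.append(math.log(a * d / (b * c)))
            ses.append(math.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
        se = math.sqrt(ses[0] ** 2 + ses[1] ** 2)
        ok += abs(lors[0] - lors[1]) <= 2 * se
    assert ok / n_rep >= 0.90


def test_single_class_inputs_rejected():
    with pytest.raises(DataError):
        roc_auc([1, 2, 3], [1, 1, 1])
    with pytest.raises(DataError):
        youden_cutoff([1, 2, 3], [0, 0, 0])
    with pytest.raises(DataError):
        rank_sum_one_sided([], [1.0])
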