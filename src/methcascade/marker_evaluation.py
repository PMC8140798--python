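"""Single-site biomarker evaluation: ROC, Youden cutoff, odds ratio, rank tests.

Evaluates one candidate methylation site as a predictor of progressive
disease (PD) under EGFR-TKI therapy: AUROC over all positive/negative
cross-pairs (ties half-weighted), the Youden-index cutoff (maximising
sensitivity + specificity - 1 over observed values), the 2x2 odds ratio
with a Woolf (log-normal) 95% CI and a two-sided Fisher exact p, stratified
re-evaluation with the cohort-level cutoff, the one-sided Wilcoxon rank-sum
test used for validation cohorts, and a marker-quartile group summary.

The default orientation is that HIGHER marker values predict PD (markers
gaining methylation in poor responders); pass ``direction="low"`` for
hypomethylated markers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import DataError

Z95 = 1.959963984540054


@dataclass
class TwoByTwo:
    """Counts with rows = marker high/low and columns = PD/disease-control."""

    a: int  # high & PD
    b: int  # high & DC
    c: int  # low & PD
    d: int  # low & DC

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("2x2 counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise DataError("2x2 table is empty")


@dataclass
class MarkerEvaluation:
    auroc: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_exact: float
    table: TwoByTwo

    def to_dict(self) -> dict:
        d = asdict(self)
        d["table"] = asdict(self.table)
        return d


def _check_classes(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise DataError("need both classes present (labels 0 and 1)")
    return values, labels


def roc_auc(values, labels) -> float:
    """AUROC = P(marker_PD > marker_DC) + 0.5 P(tie); labels 1 = PD."""
    values, labels = _check_classes(values, labels)
    return float(roc_auc_score(labels, values))


def youden_cutoff(values, labels, direction: str = "high"):
    """Cutoff maximising Youden's J over the observed marker values.

    Predict PD when value >= cutoff (``direction="high"``; the complementary
    rule for ``"low"``).  Ties in J break toward the smallest cutoff.
    Returns ``(cutoff, sensitivity, specificity, youden_j)``.
    """
    values, labels = _check_classes(values, labels)
    best = None
    for t in np.unique(values):  # ascending, so first max wins the tie-break
        sens, spec = _sens_spec(values, labels, t, direction)
        j = sens + spec - 1.0
        if best is None or j > best[3] + 1e-12:
            best = (float(t), sens, spec, j)
    return best


def _sens_spec(values, labels, cutoff, direction="high"):
    pos = values >= cutoff if direction == "high" else values <= cutoff
    pd_mask = labels == 1
    sens = float(np.mean(pos[pd_mask]))
    spec = float(np.mean(~pos[~pd_mask]))
    return sens, spec


def odds_ratio_exact(table: TwoByTwo):
    """Odds ratio with Woolf 95% CI and two-sided Fisher exact p.

    OR = ad/bc.  Any zero cell gets the Haldane-Anscombe +0.5 correction
    for the OR and CI; the exact p is computed on the uncorrected table
    (two-sided rule: sum of hypergeometric probabilities <= observed).
    A zero row or column margin is an error.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DataError("odds ratio undefined: a 2x2 margin is zero")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = float(orr * np.exp(-Z95 * se))
    ci_high = float(orr * np.exp(Z95 * se))
    return float(orr), ci_low, ci_high, p


def two_by_two(values, labels, cutoff, direction: str = "high") -> TwoByTwo:
    """Tabulate marker high/low vs PD/DC at a cutoff (high means >= cutoff)."""
    values, labels = _check_classes(values, labels)
    pos = values >= cutoff if direction == "high" else values <= cutoff
    return TwoByTwo(
        a=int(np.sum(pos & (labels == 1))),
        b=int(np.sum(pos & (labels == 0))),
        c=int(np.sum(~pos & (labels == 1))),
        d=int(np.sum(~pos & (labels == 0))),
    )


def evaluate_marker(values, labels, cutoff="auto", direction: str = "high") -> MarkerEvaluation:
    """Full single-marker evaluation; ``cutoff`` is Youden-optimal or external.

    An external cutoff classifies value >= cutoff as marker-high (for
    ``direction="high"``), so a cutoff of 0.15 calls 0.1 negative and 0.2
    positive.
    """
    values, labels = _check_classes(values, labels)
    score = values if direction == "high" else -values
    auc = roc_auc(score, labels)
    if cutoff == "auto":
        cut, sens, spec, j = youden_cutoff(values, labels, direction)
    else:
        cut = float(cutoff)
        sens, spec = _sens_spec(values, labels, cut, direction)
        j = sens + spec - 1.0
    tab = two_by_two(values, labels, cut, direction)
    orr, lo, hi, p = odds_ratio_exact(tab)
    return MarkerEvaluation(auc, cut, sens, spec, j, orr, lo, hi, p, tab)


def stratified_evaluation(values, labels, stratum, direction: str = "high") -> dict:
    """Per-stratum evaluation with the cutoff fitted on ALL samples.

    Returns a dict stratum -> MarkerEvaluation, or None for strata missing
    a class (reported not-evaluable, the rest unaffected).
    """
    values, labels = _check_classes(values, labels)
    stratum = np.asarray(stratum)
    cut = youden_cutoff(values, labels, direction)[0]
    out = {}
    for s in pd.unique(stratum):
        m = stratum == s
        if len(set(labels[m])) < 2:
            out[s] = None
            continue
        try:
            out[s] = evaluate_marker(values[m], labels[m], cutoff=cut,
                                     direction=direction)
        except DataError:
            out[s] = None
    return out


def rank_sum_one_sided(group_pd, group_dc):
    """One-sided Wilcoxon rank-sum: PD stochastically greater than DC.

    Exact enumeration when m + n <= 20 with no ties; otherwise the normal
    approximation with midrank tie correction and continuity correction.
    Returns ``(U statistic of the PD group, p)``.
    """
    x = np.asarray(group_pd, dtype=float)
    y = np.asarray(group_dc, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def quartile_summary(values, labels, pd_label: str = "PD"):
    """Group composition and means within marker-quartile bins.

    Bins samples into quartiles of the marker; within each bin reports the
    per-response-group count and mean marker value and the rank of the PD
    group by mean (1 = highest).  Returns ``(DataFrame, flags)``; when too
    few distinct values exist, bins are merged and flagged.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if len(values) < 4:
        raise DataError("need at least 4 samples for quartiles")
    flags = []
    try:
        bins = pd.qcut(values, 4, labels=False, duplicates="raise")
    except ValueError:
        bins = pd.qcut(values, 4, labels=False, duplicates="drop")
        flags.append("bins_merged")
    df = pd.DataFrame({"bin": bins, "group": labels, "value": values})
    rows = []
    for b, sub in df.groupby("bin"):
        means = sub.groupby("group")["value"].mean()
        counts = sub.groupby("group")["value"].size()
        if means.nunique() < len(means):
            flags.append(f"rank_ties_bin_{int(b)}")
        ranks = means.rank(ascending=False, method="min")
        for g in means.index:
            rows.append({"quartile": int(b) + 1, "group": g,
                         "count": int(counts[g]), "mean": float(means[g]),
                         "rank_by_mean": float(ranks[g]),
                         "pd_first": bool(pd_label in ranks and ranks[pd_label] == 1.0)})
    return pd.DataFrame(rows), tuple(dict.fromkeys(flags))
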