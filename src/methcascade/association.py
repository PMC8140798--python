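"""Response-association testing and disease-control logistic selection.

Two consecutive cascade stages operate on the CV-filtered probes:

1. One-way fixed-effects ANOVA of beta values across the three RECIST
   response groups (PD/SD/PR), with Tukey HSD (Tukey-Kramer for unequal
   group sizes) pairwise adjusted p-values from the studentized-range
   distribution.  Tukey results are reported, not used as a filter.
2. Logistic regression of the disease-control outcome (DCR: SD/PR/CR = 1
   vs PD = 0) on each probe's beta values, univariate and multivariate
   (beta + clinical covariates), fitted by IRLS; a probe survives when the
   ANOVA p and BOTH logistic p-values clear their thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DataError

PAIRS = (("PD", "SD"), ("PD", "PR"), ("SD", "PR"))

DEFAULT_COVARIATES = ("egfr_mutant", "sex_male", "smoker")


@dataclass
class ResponseAssociation:
    probe_id: str
    f_statistic: float
    p_anova: float
    tukey_p: dict            # pair -> adjusted p (NaN + flag if not testable)
    flags: tuple = ()


@dataclass
class DcrModelResult:
    probe_id: str
    coef_univariate: float
    p_univariate: float
    coef_multivariate: float
    p_multivariate: float
    converged: bool
    flags: tuple = ()


def _anova_f(groups_values):
    """(F, p, mse, df_within) for a list of per-group arrays."""
    k = len(groups_values)
    ns = np.array([len(g) for g in groups_values])
    n = ns.sum()
    means = np.array([g.mean() for g in groups_values])
    grand = np.concatenate(groups_values).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups_values, means)))
    dfb, dfw = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0, 0.0, dfw
        return np.inf, 0.0, 0.0, dfw
    msb, msw = ssb / dfb, ssw / dfw
    f = msb / msw
    return f, float(stats.f.sf(f, dfb, dfw)), msw, dfw


def anova_tukey(betas, groups) -> ResponseAssociation:
    """One-way ANOVA + Tukey HSD of one probe's betas across response groups.

    Groups with fewer than 2 samples are dropped from the F test and their
    pairs flagged untestable.  With zero within-group variance everywhere
    and equal means, F = 0 and p = 1.
    """
    betas = np.asarray(betas, dtype=float)
    groups = np.asarray(groups, dtype=object)
    keep = ~np.isnan(betas)
    betas, groups = betas[keep], groups[keep]
    labels = [g for g in dict.fromkeys(groups)]
    by = {g: betas[groups == g] for g in labels}
    usable = {g: v for g, v in by.items() if len(v) >= 2}
    flags = tuple(f"group_too_small:{g}" for g in by if g not in usable)
    if len(usable) < 2 or sum(len(v) for v in usable.values()) <= len(usable):
        raise DataError("need >=2 samples in >=2 groups for ANOVA")
    f, p, msw, dfw = _anova_f(list(usable.values()))

    k = len(usable)
    tukey = {}
    for a, b in PAIRS:
        if a in usable and b in usable:
            na, nb = len(usable[a]), len(usable[b])
            diff = abs(usable[a].mean() - usable[b].mean())
            if msw == 0.0:
                tukey[(a, b)] = 1.0 if diff == 0.0 else 0.0
                continue
            se = np.sqrt(msw / 2.0 * (1.0 / na + 1.0 / nb))
            q = diff / se
            tukey[(a, b)] = float(stats.studentized_range.sf(q, k, dfw))
        elif a in by and b in by:
            tukey[(a, b)] = float("nan")
    return ResponseAssociation("", float(f), float(p), tukey, flags)


def anova_tukey_matrix(matrix: pd.DataFrame, groups,
                       tukey: bool = True) -> pd.DataFrame:
    """Vectorised ANOVA F/p for every probe, plus Tukey HSD pairwise p.

    The F statistics are computed with matrix arithmetic over all probes at
    once; the studentized-range survival function is evaluated per pair
    (skipped entirely with ``tukey=False``, e.g. for large null
    calibrations where only the F test matters).  Returns a DataFrame
    indexed by probe_id.
    """
    groups = np.asarray(groups, dtype=object)
    labels = [g for g in ("PD", "SD", "PR") if (groups == g).sum() >= 2]
    if len(labels) < 2:
        raise DataError("need >=2 response groups with >=2 samples")
    masks = [groups == g for g in labels]
    X = matrix.to_numpy(dtype=float)
    ns = np.array([m.sum() for m in masks], dtype=float)
    n = ns.sum()
    k = len(labels)
    means = np.stack([X[m].mean(axis=0) for m in masks])      # k x p
    grand = (means * ns[:, None]).sum(axis=0) / n
    ssb = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    sse = np.stack([((X[m] - means[i]) ** 2).sum(axis=0) for i, m in enumerate(masks)])
    ssw = sse.sum(axis=0)
    dfb, dfw = k - 1, int(n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    zero_w = ssw == 0
    f = np.where(zero_w & (ssb == 0), 0.0, f)
    f = np.where(zero_w & (ssb > 0), np.inf, f)
    p = stats.f.sf(f, dfb, dfw)
    p = np.where(zero_w & (ssb == 0), 1.0, p)

    out = pd.DataFrame({"f_statistic": f, "p_anova": p},
                       index=matrix.columns.rename("probe_id"))
    if not tukey:
        return out
    msw = np.where(zero_w, np.nan, ssw / dfw)
    for a, b in PAIRS:
        col = f"tukey_p_{a}_{b}"
        if a in labels and b in labels:
            ia, ib = labels.index(a), labels.index(b)
            diff = np.abs(means[ia] - means[ib])
            se = np.sqrt(msw / 2.0 * (1.0 / ns[ia] + 1.0 / ns[ib]))
            with np.errstate(divide="ignore", invalid="ignore"):
                q = diff / se
            pv = stats.studentized_range.sf(q, k, dfw)
            pv = np.where(zero_w, np.where(diff == 0, 1.0, 0.0), pv)
            out[col] = pv
        else:
            out[col] = np.nan
    return out


def fit_dcr_logistic(beta, dcr, covariates=None, probe_id: str = "",
                     p_method: str = "lr") -> DcrModelResult:
    """Univariate and multivariate logistic fits of disease control on beta.

    Maximum-likelihood fit by IRLS (tolerance 1e-8, at most 100 iterations).
    The reported significance of the probe term is a likelihood-ratio test
    against the model without it (``p_method="lr"``, default): near-separated
    strong predictors inflate the Wald standard error (Hauck-Donner), so the
    Wald test loses exactly the strongest markers.  ``p_method="wald"`` gives
    the classical Wald p instead.  Complete separation and constant
    predictors are flagged, not raised; non-converged fits carry NaN
    p-values.
    """
    if p_method not in ("lr", "wald"):
        raise DataError("p_method must be 'lr' or 'wald'")
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(dcr, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise DataError("dcr labels must contain both classes (0 and 1)")
    flags = []
    if np.nanstd(beta) <= 1e-12 * max(1.0, abs(float(np.nanmean(beta)))):
        return DcrModelResult(probe_id, np.nan, np.nan, np.nan, np.nan, False,
                              ("constant_predictor",))
    lo1, hi0 = beta[y == 1].min(), beta[y == 0].max()
    lo0, hi1 = beta[y == 0].min(), beta[y == 1].max()
    if hi0 < lo1 or hi1 < lo0:
        return DcrModelResult(probe_id, np.nan, np.nan, np.nan, np.nan, False,
                              ("separation",))

    def _glm(design):
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8)
            res.llf, res.pvalues  # force lazy evaluation inside the filter
            if not np.isfinite(res.llf):
                # IRLS can overflow under quasi-complete separation; a
                # bounded direct maximisation of the likelihood recovers
                # the supremum (llf -> 0) that the LR test needs
                res = sm.Logit(y, design).fit(method="lbfgs", maxiter=500,
                                              disp=0)
                res.llf, res.pvalues
        ok = np.all(np.isfinite(res.params)) and np.isfinite(res.llf)
        return res, bool(ok)

    def _fit(extra):
        """(coef, p, ok) for the beta term on top of `extra` columns."""
        full = sm.add_constant(np.column_stack([beta] + extra)
                               if extra else beta[:, None])
        res, ok = _glm(full)
        coef = float(res.params[1])
        if p_method == "wald":
            p = float(res.pvalues[1])
        else:
            null = sm.add_constant(np.column_stack(extra)) if extra \
                else np.ones((len(y), 1))
            res0, ok0 = _glm(null)
            lr = max(0.0, 2.0 * (res.llf - res0.llf))
            p = float(stats.chi2.sf(lr, 1))
            ok = ok and ok0
        return coef, p, ok

    try:
        c1, p1, ok1 = _fit([])
    except Exception:
        c1, p1, ok1 = np.nan, np.nan, False
    c2, p2, ok2 = c1, p1, ok1
    if covariates is not None and len(getattr(covariates, "columns", [])) > 0:
        cov = np.asarray(covariates, dtype=float)
        try:
            c2, p2, ok2 = _fit([cov])
        except Exception:
            c2, p2, ok2 = np.nan, np.nan, False
    converged = ok1 and ok2
    if not converged:
        flags.append("not_converged")
        p1 = p2 = np.nan
    return DcrModelResult(probe_id, c1, p1, c2, p2, converged, tuple(flags))


def fit_dcr_matrix(matrix: pd.DataFrame, dcr, covariates=None,
                   p_method: str = "lr") -> pd.DataFrame:
    """Per-probe logistic fits over a matrix; returns a probe-indexed frame."""
    rows = []
    for pid in matrix.columns:
        r = fit_dcr_logistic(matrix[pid].to_numpy(), dcr, covariates,
                             probe_id=pid, p_method=p_method)
        rows.append(
            {"probe_id": pid, "coef_univariate": r.coef_univariate,
             "p_univariate": r.p_univariate, "coef_multivariate": r.coef_multivariate,
             "p_multivariate": r.p_multivariate, "converged": r.converged,
             "flags": ";".join(r.flags)}
        )
    return pd.DataFrame(rows).set_index("probe_id")


def select_response_probes(assoc: pd.DataFrame, models: pd.DataFrame,
                           alpha_anova: float = 0.05,
                           alpha_logistic: float = 0.05):
    """Probes significant by ANOVA AND by both logistic models.

    Returns ``(probe Index, counts dict)`` where counts records the
    per-condition survivor numbers.
    """
    if not assoc.index.equals(models.index):
        common = assoc.index.intersection(models.index)
        if len(common) != len(assoc) or len(common) != len(models):
            raise DataError("association and model tables cover different probes")
        models = models.loc[assoc.index]
    pass_anova = assoc["p_anova"] <= alpha_anova
    pass_uni = models["p_univariate"] <= alpha_logistic
    pass_multi = models["p_multivariate"] <= alpha_logistic
    keep = pass_anova & pass_uni & pass_multi & models["converged"].astype(bool)
    counts = {
        "n_input": int(len(assoc)),
        "n_pass_anova": int(pass_anova.sum()),
        "n_pass_univariate": int((pass_anova & pass_uni).sum()),
        "n_retained": int(keep.sum()),
    }
    return assoc.index[keep], counts


class AnovaTukeySelector(BaseEstimator):
    """Selects probes whose betas differ across response groups (ANOVA p < alpha).

    Tukey HSD pairwise p-values are computed and reported for every probe
    but do not participate in the selection.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y) -> "AnovaTukeySelector":
        self.results_ = anova_tukey_matrix(X, y)
        self.retained_ = self.results_.index[self.results_["p_anova"] <= self.alpha]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def get_support(self) -> np.ndarray:
        kept = set(self.retained_)
        return np.array([p in kept for p in self.feature_names_in_])

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, self.retained_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


class DcrLogisticSelector(BaseEstimator):
    """Selects probes significant in univariate AND multivariate DCR logistic fits."""

    def __init__(self, alpha: float = 0.05, covariate_columns=DEFAULT_COVARIATES,
                 p_method: str = "lr"):
        self.alpha = alpha
        self.covariate_columns = covariate_columns
        self.p_method = p_method

    def fit(self, X: pd.DataFrame, y, covariates: pd.DataFrame | None = None):
        cov = None
        if covariates is not None and self.covariate_columns:
            cols = [c for c in self.covariate_columns if c in covariates.columns]
            cov = covariates[cols] if cols else None
        self.results_ = fit_dcr_matrix(X, y, cov, p_method=self.p_method)
        keep = (
            (self.results_["p_univariate"] <= self.alpha)
            & (self.results_["p_multivariate"] <= self.alpha)
            & self.results_["converged"].astype(bool)
        )
        self.retained_ = self.results_.index[keep]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def get_support(self) -> np.ndarray:
        kept = set(self.retained_)
        return np.array([p in kept for p in self.feature_names_in_])

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, self.retained_]
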