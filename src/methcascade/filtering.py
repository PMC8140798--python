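"""Variance-based probe pre-selection: keep the top q fraction by CV.

The coefficient of variation (CV = sd/mean, with the n-1 sample standard
deviation) is computed per probe on beta values over non-missing samples.
The retained count is floor(q * N) over the FULL probe universe — with
q = 0.05 on a 482,421-probe array this is exactly 24,121 probes — and the
highest-CV probes among the eligible ones fill it, with probe-id order as
the deterministic tie-break.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigError, DataError

#: minimum non-missing observations for a probe to receive a CV
MIN_OBS = 3


def compute_cv(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-probe variability of a samples x probes beta matrix.

    Returns a DataFrame indexed by probe_id with columns ``mean_beta``,
    ``sd_beta``, ``cv`` and ``excluded``.  Probes with fewer than 3
    non-missing values or a zero mean are flagged excluded (cv = NaN)
    rather than raising.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise DataError("methylation matrix is empty")
    values = matrix.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(values), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=0)
        sd = np.nanstd(values, axis=0, ddof=1)
    excluded = (n_obs < MIN_OBS) | (mean == 0) | np.isnan(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(excluded, np.nan, sd / mean)
    out = pd.DataFrame(
        {"mean_beta": mean, "sd_beta": sd, "cv": cv, "excluded": excluded},
        index=matrix.columns.rename("probe_id"),
    )
    return out


def select_top_variable(variability: pd.DataFrame, q: float) -> pd.Index:
    """Retain the floor(q * N_total) highest-CV probes.

    N_total counts every probe, excluded ones included, so the retained
    count is a fixed fraction of the array.  Ordering is CV descending with
    probe_id ascending as tie-break; the returned Index is in that order.
    """
    if not 0.0 < q < 1.0:
        raise ConfigError("q must be strictly inside (0, 1)")
    n_total = len(variability)
    k = math.floor(q * n_total)
    eligible = variability.loc[~variability["excluded"]]
    if eligible.empty:
        raise DataError("all probes excluded; nothing to select")
    # stable sort on CV after an index sort -> ties break probe_id-ascending
    order = eligible.sort_index().sort_values("cv", ascending=False, kind="mergesort")
    return order.index[:k]


class CVFilter(BaseEstimator):
    """Top-q coefficient-of-variation probe filter (feature selector).

    Parameters
    ----------
    q : float, default 0.05
        Fraction of the full probe universe to retain.

    Attributes
    ----------
    variability_ : DataFrame with mean_beta, sd_beta, cv, excluded per probe.
    retained_ : Index of retained probe ids, CV-descending.
    """

    def __init__(self, q: float = 0.05):
        self.q = q

    def fit(self, X: pd.DataFrame, y=None) -> "CVFilter":
        X = _as_frame(X)
        self.variability_ = compute_cv(X)
        self.retained_ = select_top_variable(self.variability_, self.q)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        kept = set(self.retained_)
        return np.array([p in kept for p in self.feature_names_in_])

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return _as_frame(X).loc[:, self.retained_]

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)

    def report(self) -> pd.DataFrame:
        """Stage report: probe_id, mean_beta, sd_beta, cv, retained (0/1)."""
        rep = self.variability_.copy()
        rep["retained"] = rep.index.isin(self.retained_).astype(int)
        return rep


def _as_frame(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(X)
        X.columns = [str(c) for c in X.columns]
    return X
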