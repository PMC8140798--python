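"""Transcription-repressive site screen: methylation vs expression.

A CpG site is called transcription-repressive when its beta values are
significantly negatively Spearman-correlated with the expression of the
gene it annotates to (cis only; the probe->gene map comes from the
manifest).  rho is the Pearson correlation of midranks; the p-value uses
the t approximation, replaced by exact permutation enumeration for n <= 9
where the approximation is poor.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DataError

MIN_PAIRS = 4
EXACT_MAX_N = 9


@dataclass
class RepressionScreenResult:
    probe_id: str
    gene_symbol: str | None
    rho: float
    p_rho: float
    n_pairs: int
    is_repressive: bool
    flags: tuple = ()


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def spearman_meth_expr(beta, expr):
    """Spearman rank correlation between one probe's betas and expression.

    Returns ``(rho, p, n)`` over complete pairs.  Two-sided p by the t
    approximation; exact enumeration over all rank permutations when
    n <= 9.  Fewer than 4 complete pairs or a zero-variance vector raises
    :class:`DataError`.
    """
    beta = np.asarray(beta, dtype=float)
    expr = np.asarray(expr, dtype=float)
    keep = ~(np.isnan(beta) | np.isnan(expr))
    beta, expr = beta[keep], expr[keep]
    n = len(beta)
    if n < MIN_PAIRS:
        raise DataError(f"need >= {MIN_PAIRS} complete pairs, got {n}")
    if np.std(beta) == 0 or np.std(expr) == 0:
        raise DataError("zero variance: Spearman correlation undefined")
    rx = stats.rankdata(beta)
    ry = stats.rankdata(expr)
    rho = _rho_of_ranks(rx, ry)
    if n <= EXACT_MAX_N:
        target = abs(rho) - 1e-12
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
        rho_all = (perms - ry.mean()) @ rxc / denom
        p = float(np.mean(np.abs(rho_all) >= target))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
            p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0), n


def repression_screen(meth: pd.DataFrame, expression: pd.DataFrame,
                      manifest: pd.DataFrame, rho_max: float = -0.3,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Screen every probe of ``meth`` against its gene's expression.

    Probes without a mapped gene, without expression data for the gene, or
    with too few complete pairs are flagged and never called repressive.
    Samples are matched on the shared index of the two matrices.
    """
    shared = meth.index.intersection(expression.index)
    if len(shared) < MIN_PAIRS:
        raise DataError("fewer than 4 samples shared by methylation and expression")
    rows = []
    for pid in meth.columns:
        gene = manifest["gene_symbol"].get(pid) if pid in manifest.index else None
        gene = None if pd.isna(gene) else gene
        rho = p = np.nan
        n_pairs = 0
        flags = []
        if gene is None:
            flags.append("no_gene")
        elif gene not in expression.columns:
            flags.append("no_expression")
        else:
            try:
                rho, p, n_pairs = spearman_meth_expr(
                    meth.loc[shared, pid], expression.loc[shared, gene])
            except DataError as exc:
                flags.append("insufficient" if "pairs" in str(exc) else "undefined")
        is_rep = bool(not flags and rho <= rho_max and p <= alpha)
        rows.append({"probe_id": pid, "gene_symbol": gene, "rho": rho, "p_rho": p,
                     "n_pairs": n_pairs, "is_repressive": is_rep,
                     "flags": ";".join(flags)})
    return pd.DataFrame(rows).set_index("probe_id")


def select_repressive(screen: pd.DataFrame, rho_max: float = -0.3,
                      alpha: float = 0.05):
    """Probes with rho <= rho_max and p <= alpha (gene-mapped only).

    Returns ``(probe Index, counts dict)``; unmapped probes are counted
    separately, never retained.
    """
    mapped = screen["gene_symbol"].notna() & (screen["flags"] == "")
    keep = mapped & (screen["rho"] <= rho_max) & (screen["p_rho"] <= alpha)
    counts = {
        "n_input": int(len(screen)),
        "n_unmapped": int((~mapped).sum()),
        "n_retained": int(keep.sum()),
    }
    return screen.index[keep], counts


class RepressionScreen(BaseEstimator):
    """Feature selector keeping transcription-repressive probes.

    ``fit(X, expression=..., manifest=...)`` screens every probe of X; the
    retained set has rho <= rho_max and p < alpha against its own gene.
    """

    def __init__(self, rho_max: float = -0.3, alpha: float = 0.05):
        self.rho_max = rho_max
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y=None, *, expression: pd.DataFrame,
            manifest: pd.DataFrame) -> "RepressionScreen":
        self.screen_ = repression_screen(X, expression, manifest,
                                         self.rho_max, self.alpha)
        self.retained_, self.counts_ = select_repressive(
            self.screen_, self.rho_max, self.alpha)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def get_support(self) -> np.ndarray:
        kept = set(self.retained_)
        return np.array([p in kept for p in self.feature_names_in_])

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, self.retained_]
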