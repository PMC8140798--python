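"""Annotation-class and term-map enrichment statistics.

Enrichment of a flagged annotation class (e.g. transcription-factor
probes) in a selected probe set against a background universe, and
GO-slim-style term enrichment over a user-supplied term -> gene map.
Three test variants are supported and must be chosen explicitly —
``binomial_exact`` (upper-tail P(X >= k), X ~ Binomial(n, K/N)),
``proportion_z`` (two-sided normal test of the selected proportion
against the background proportion) and ``hypergeometric`` (upper tail of
the 2x2) — because published enrichment p-values rarely state which
variant produced them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

METHODS = ("binomial_exact", "proportion_z", "hypergeometric")


def proportion_report(k: int, n: int) -> float:
    """Percentage 100*k/n truncated (floored) to 2 decimals.

    Matches the convention of printed EWAS proportion reports, e.g.
    30/216 -> 13.88 and 34,129/482,421 -> 7.07.  Exact Fraction arithmetic
    avoids float-rounding artefacts at the boundary.
    """
    if n <= 0:
        raise DataError("denominator must be positive")
    if not 0 <= k <= n:
        raise DataError("need 0 <= k <= n")
    return math.floor(Fraction(10_000 * k, n)) / 100.0


@dataclass
class EnrichmentResult:
    k: int
    n: int
    K: int
    N: int
    prop_selected: float
    prop_background: float
    fold: float
    p_value: float
    method: str


def _p_value(k: int, n: int, K: int, N: int, method: str) -> float:
    if method == "binomial_exact":
        return float(stats.binom.sf(k - 1, n, K / N))
    if method == "proportion_z":
        p0 = K / N
        if p0 in (0.0, 1.0):
            return 1.0 if k / n == p0 else 0.0
        z = (k / n - p0) / math.sqrt(p0 * (1.0 - p0) / n)
        return float(2.0 * stats.norm.sf(abs(z)))
    if method == "hypergeometric":
        return float(stats.hypergeom.sf(k - 1, N, K, n))
    raise DataError(f"unknown enrichment method {method!r}; choose from {METHODS}")


def enrichment_from_counts(k: int, n: int, K: int, N: int, method: str) -> EnrichmentResult:
    """Enrichment statistic from pre-tabulated counts."""
    if n <= 0 or N <= 0:
        raise DataError("selection and background must be nonempty")
    if not (0 <= k <= n and 0 <= K <= N):
        raise DataError("counts must satisfy 0 <= k <= n and 0 <= K <= N")
    if K == 0 and k > 0:
        raise DataError("impossible configuration: flagged in selection but not background")
    prop_s, prop_b = k / n, K / N
    fold = prop_s / prop_b if prop_b > 0 else float("nan")
    return EnrichmentResult(k, n, K, N, prop_s, prop_b, fold,
                            _p_value(k, n, K, N, method), method)


def annotation_enrichment(selection, flag, background, method: str) -> EnrichmentResult:
    """Enrichment of an annotation flag in ``selection`` vs ``background``.

    ``flag`` is either a set of flagged probe ids or a predicate over probe
    ids; ``selection`` must be a subset of ``background``.
    """
    selection = set(selection)
    background = set(background)
    if not selection:
        raise DataError("selection is empty")
    if not selection <= background:
        raise DataError("selection must be a subset of the background universe")
    pred = (lambda p: p in flag) if isinstance(flag, (set, frozenset)) else flag
    k = sum(1 for p in selection if pred(p))
    K = sum(1 for p in background if pred(p))
    return enrichment_from_counts(k, len(selection), K, len(background), method)


def term_enrichment(gene_set, background_genes, term_map: pd.DataFrame,
                    method: str = "hypergeometric") -> pd.DataFrame:
    """Per-term enrichment of a gene set over a term -> gene map.

    ``term_map`` needs columns term_id, term_name, gene_symbol (one row per
    term-gene link).  k counts distinct genes; terms are ranked by p
    ascending, then fold descending.  Genes in ``gene_set`` missing from
    the background raise an error listing the offenders.
    """
    gene_set = set(gene_set)
    background = set(background_genes)
    missing = gene_set - background
    if missing:
        raise DataError(f"genes absent from background: {sorted(missing)[:10]}")
    if term_map.empty:
        raise DataError("term map is empty")
    N, n = len(background), len(gene_set)
    rows = []
    for (term_id, term_name), sub in term_map.groupby(["term_id", "term_name"], sort=False):
        term_genes = set(sub["gene_symbol"]) & background
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & gene_set)
        r = enrichment_from_counts(k, n, K, N, method)
        fold = 0.0 if k == 0 else r.fold
        rows.append({"term_id": term_id, "term_name": term_name, "k": k, "n": n,
                     "K": K, "N": N, "fold": fold, "p_value": r.p_value})
    out = pd.DataFrame(rows)
    return out.sort_values(["p_value", "fold"], ascending=[True, False],
                           kind="mergesort").reset_index(drop=True)


def read_term_map(path) -> pd.DataFrame:
    """Read a term-map TSV with columns term_id, term_name, gene_symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"term_id", "term_name", "gene_symbol"}
    if not need <= set(df.columns):
        raise DataError(f"term map must have columns {sorted(need)}")
    return df
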