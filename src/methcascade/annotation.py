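"""Probe annotation model and genomic-context summaries.

A probe manifest assigns every CpG probe a single gene-region category
(promoter subregions TSS1500/TSS200, 5'UTR, first exon, gene body, 3'UTR,
or intergenic) and a single CpG-island context (island, shore, shelf, open
sea), plus optional transcription-factor and enhancer flags.  Illumina-style
manifests often list several region annotations per probe; here a probe
carries exactly one, collapsed by a fixed promoter-first precedence rule so
that category proportions over a probe set are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ManifestError

GENE_REGIONS = ("TSS1500", "TSS200", "UTR5", "FirstExon", "Body", "UTR3", "Intergenic")
CPG_CONTEXTS = ("Island", "Shore", "Shelf", "OpenSea")

#: promoter-first precedence used to collapse multi-region annotations
REGION_PRECEDENCE = ("TSS200", "TSS1500", "UTR5", "FirstExon", "Body", "UTR3")

MANIFEST_COLUMNS = (
    "probe_id",
    "gene_symbol",
    "chromosome",
    "position",
    "gene_region",
    "cpg_context",
    "is_tf",
    "is_enhancer",
)

_REQUIRED = ("probe_id", "gene_region", "cpg_context")


def collapse_gene_region(regions) -> str:
    """Collapse several gene-region annotations to one by promoter-first precedence.

    ``TSS200 > TSS1500 > UTR5 > FirstExon > Body > UTR3``; an empty input
    collapses to ``Intergenic``.
    """
    regions = [r for r in regions if r and r != "Intergenic"]
    if not regions:
        return "Intergenic"
    for cand in REGION_PRECEDENCE:
        if cand in regions:
            return cand
    raise ManifestError(f"unknown gene_region values: {sorted(set(regions))}")


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an annotation table (one row per probe).

    Returns a copy indexed by ``probe_id`` with categorical region/context
    columns and boolean flags.  Raises :class:`ManifestError` on duplicate
    probe ids, unknown categories, or gene/intergenic inconsistency.
    """
    df = manifest.copy()
    for col in _REQUIRED:
        if col not in df.columns and df.index.name != col:
            raise ManifestError(f"manifest is missing required column {col!r}")
    if df.index.name != "probe_id":
        df = df.set_index("probe_id")

    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ManifestError(f"duplicate probe_id {dup[0]!r} in manifest")

    for col, allowed in (("gene_region", GENE_REGIONS), ("cpg_context", CPG_CONTEXTS)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ManifestError(
                f"unknown {col} {df[col].iloc[i]!r} for probe {df.index[i]!r} "
                f"(line {i + 2})"  # 1-based, after the header
            )
        df[col] = pd.Categorical(df[col], categories=allowed)

    if "gene_symbol" not in df.columns:
        df["gene_symbol"] = pd.NA
    df["gene_symbol"] = df["gene_symbol"].replace("", pd.NA)
    for col in ("is_tf", "is_enhancer"):
        if col not in df.columns:
            df[col] = False
        df[col] = df[col].fillna(0).astype(int).astype(bool)
    if "chromosome" not in df.columns:
        df["chromosome"] = pd.NA
    if "position" not in df.columns:
        df["position"] = pd.NA

    intergenic = df["gene_region"] == "Intergenic"
    has_gene = df["gene_symbol"].notna()
    bad = intergenic & has_gene
    if bad.any():
        raise ManifestError(
            f"probe {df.index[bad][0]!r} is Intergenic but carries a gene symbol"
        )
    bad = ~intergenic & ~has_gene
    if bad.any():
        raise ManifestError(
            f"probe {df.index[bad][0]!r} has a gene region but no gene symbol"
        )
    return df[[c for c in MANIFEST_COLUMNS if c != "probe_id"]]


def read_manifest(path) -> pd.DataFrame:
    """Read a probe-annotation TSV and return the validated table.

    Required columns: probe_id, gene_region, cpg_context.  Optional:
    gene_symbol, chromosome, position, is_tf, is_enhancer (0/1; default 0).
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str})
    return validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    """Write a validated annotation table as TSV (booleans serialised 0/1)."""
    out = manifest.reset_index()
    out["is_tf"] = out["is_tf"].astype(int)
    out["is_enhancer"] = out["is_enhancer"].astype(int)
    out["gene_symbol"] = out["gene_symbol"].fillna("")
    out.to_csv(path, sep="\t", index=False)


@dataclass
class ContextDistribution:
    """Category counts and proportions of a probe set over both groupings."""

    total: int
    region_counts: dict = field(default_factory=dict)
    region_proportions: dict = field(default_factory=dict)
    cpg_counts: dict = field(default_factory=dict)
    cpg_proportions: dict = field(default_factory=dict)
    undefined: bool = False  # True when the probe set is empty

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"grouping": "gene_region", "category": k, "count": v,
             "proportion": self.region_proportions.get(k, float("nan"))}
            for k, v in self.region_counts.items()
        ] + [
            {"grouping": "cpg_context", "category": k, "count": v,
             "proportion": self.cpg_proportions.get(k, float("nan"))}
            for k, v in self.cpg_counts.items()
        ]
        return pd.DataFrame(rows)


def context_distribution(probes, manifest: pd.DataFrame) -> ContextDistribution:
    """Genomic-context distribution (gene region and CpG context) of a probe set.

    Parameters
    ----------
    probes : iterable of probe ids; must all be present in the manifest.
    manifest : validated annotation table indexed by probe_id.
    """
    probes = pd.Index(pd.unique(pd.Index(probes)))
    missing = probes.difference(manifest.index)
    if len(missing):
        raise DataError(f"probes absent from manifest: {sorted(missing)[:10]}")
    sub = manifest.loc[probes]
    total = len(sub)
    region_counts = sub["gene_region"].value_counts().reindex(GENE_REGIONS, fill_value=0)
    cpg_counts = sub["cpg_context"].value_counts().reindex(CPG_CONTEXTS, fill_value=0)
    if total == 0:
        nan = {k: float("nan") for k in GENE_REGIONS}
        return ContextDistribution(
            total=0,
            region_counts=region_counts.to_dict(),
            region_proportions=nan,
            cpg_counts=cpg_counts.to_dict(),
            cpg_proportions={k: float("nan") for k in CPG_CONTEXTS},
            undefined=True,
        )
    return ContextDistribution(
        total=total,
        region_counts=region_counts.to_dict(),
        region_proportions=(region_counts / total).to_dict(),
        cpg_counts=cpg_counts.to_dict(),
        cpg_proportions=(cpg_counts / total).to_dict(),
    )
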