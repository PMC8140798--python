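"""End-to-end probe-selection cascade.

Fixed stage order: CV filter -> response ANOVA (+ Tukey report) -> DCR
logistic selection -> optional cis-repression screen -> optional
TF-annotation filter -> optional genomic-context filter (promoter regions
and/or enhancer flag) -> single-marker evaluation of the survivors.
Stages are individually skippable but never reordered; retained sets can
only shrink, and identical config + inputs reproduce identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import datetime as _dt
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import context_distribution, read_manifest
from .association import (AnovaTukeySelector, DcrLogisticSelector,
                          DEFAULT_COVARIATES)
from .cis_repression import RepressionScreen
from .errors import ConfigError, DataError, EmptyStageError
from .filtering import CVFilter
from .marker_evaluation import evaluate_marker

log = logging.getLogger("methcascade")


@dataclass
class CascadeConfig:
    """Flat configuration of the cascade; every threshold has a default."""

    cv_enabled: bool = True
    cv_q: float = 0.05
    anova_enabled: bool = True
    alpha_anova: float = 0.05
    logistic_enabled: bool = True
    alpha_logistic: float = 0.05
    covariates: tuple = DEFAULT_COVARIATES
    repression_enabled: bool = False
    rho_max: float = -0.3
    rho_alpha: float = 0.05
    tf_filter_enabled: bool = False
    context_filter_enabled: bool = False
    context_regions: tuple = ("TSS1500", "TSS200")
    require_enhancer: bool = False
    evaluate_markers: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "CascadeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariates", "context_regions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(d["covariates"])
        d["context_regions"] = list(d["context_regions"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class CascadeResult:
    """Ordered stage records plus the final annotated candidate list."""

    stages: list = field(default_factory=list)
    final_probes: list = field(default_factory=list)
    candidates: dict = field(default_factory=dict)   # probe_id -> annotation/eval
    provenance: dict = field(default_factory=dict)

    def add_stage(self, name, n_input, retained, params):
        if self.stages and len(retained) > self.stages[-1]["n_retained"]:
            raise DataError("stage retained more probes than its input")
        self.stages.append({
            "name": name, "n_input": int(n_input), "n_retained": int(len(retained)),
            "parameters": params, "retained": list(map(str, retained)),
        })
        log.info("stage %-18s %7d -> %7d", name, n_input, len(retained))
        if len(retained) == 0:
            raise EmptyStageError(name)

    def to_json(self, path=None) -> str:
        payload = {
            "stages": self.stages,
            "final_probes": self.final_probes,
            "candidates": self.candidates,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=1, sort_keys=True, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def _covariate_report(meth, samples, columns):
    """Per-probe OLS slope p-values against each clinical characteristic.

    Purely descriptive: flags probes whose betas track a covariate at
    p < .05; never used as a filter.
    """
    import statsmodels.api as sm

    out = pd.DataFrame(index=meth.columns)
    for col in columns:
        if col not in samples.columns:
            continue
        x = sm.add_constant(samples[col].to_numpy(dtype=float))
        ps = []
        for pid in meth.columns:
            try:
                ps.append(float(sm.OLS(meth[pid].to_numpy(dtype=float), x).fit().pvalues[1]))
            except Exception:
                ps.append(np.nan)
        out[f"p_{col}"] = ps
        out[f"flag_{col}"] = (out[f"p_{col}"] < 0.05).astype(int)
    return out


def run_cascade(meth: pd.DataFrame, samples: pd.DataFrame, manifest: pd.DataFrame,
                expression: pd.DataFrame | None = None,
                config: CascadeConfig | None = None,
                outdir=None) -> CascadeResult:
    """Run the full selection cascade on in-memory inputs.

    ``meth`` is samples x probes in [0,1]; ``samples`` needs a ``response``
    column (PD/SD/PR[/CR]) from which the binary disease-control label is
    derived; ``manifest`` a validated annotation table.  ``expression``
    (samples x genes) is required only when the cis-repression stage is on.
    Stage reports are written under ``outdir`` when given.
    """
    config = config or CascadeConfig()
    if "response" not in samples.columns:
        raise ConfigError("sample table lacks a 'response' column")
    missing = [c for c in config.covariates if c not in samples.columns]
    if config.logistic_enabled and missing:
        raise ConfigError(f"sample table lacks covariate columns {missing}")
    samples = samples.loc[meth.index]
    response = samples["response"].to_numpy(dtype=object)
    dcr = (response != "PD").astype(int)
    if config.repression_enabled and expression is None:
        raise ConfigError("cis-repression stage enabled but no expression matrix given")

    result = CascadeResult(provenance={
        "config_hash": config.digest(), "seed": config.seed,
        "n_samples": int(meth.shape[0]), "n_probes": int(meth.shape[1]),
        "created": _dt.datetime.now().isoformat(timespec="seconds"),
    })
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    current = meth
    if config.cv_enabled:
        stage = CVFilter(q=config.cv_q).fit(current)
        result.add_stage("cv_filter", current.shape[1], stage.retained_,
                         {"q": config.cv_q})
        if out is not None:
            stage.report().to_csv(out / "stage_cv.tsv", sep="\t")
        current = stage.transform(current)

    if config.anova_enabled:
        stage = AnovaTukeySelector(alpha=config.alpha_anova).fit(current, response)
        result.add_stage("anova_tukey", current.shape[1], stage.retained_,
                         {"alpha": config.alpha_anova})
        if out is not None:
            stage.results_.to_csv(out / "stage_anova.tsv", sep="\t")
        current = stage.transform(current)

    if config.logistic_enabled:
        stage = DcrLogisticSelector(
            alpha=config.alpha_logistic, covariate_columns=config.covariates
        ).fit(current, dcr, covariates=samples)
        result.add_stage("dcr_logistic", current.shape[1], stage.retained_,
                         {"alpha": config.alpha_logistic,
                          "covariates": list(config.covariates)})
        if out is not None:
            stage.results_.to_csv(out / "stage_logistic.tsv", sep="\t")
        current = stage.transform(current)

    if config.repression_enabled:
        stage = RepressionScreen(rho_max=config.rho_max, alpha=config.rho_alpha).fit(
            current, expression=expression, manifest=manifest)
        result.add_stage("cis_repression", current.shape[1], stage.retained_,
                         {"rho_max": config.rho_max, "alpha": config.rho_alpha})
        if out is not None:
            stage.screen_.to_csv(out / "stage_repression.tsv", sep="\t")
        current = stage.transform(current)

    ann = manifest.reindex(current.columns)
    if config.tf_filter_enabled:
        keep = current.columns[ann["is_tf"].fillna(False).astype(bool)]
        result.add_stage("tf_filter", current.shape[1], keep, {})
        current = current.loc[:, keep]
        ann = manifest.reindex(current.columns)

    if config.context_filter_enabled:
        mask = ann["gene_region"].isin(config.context_regions)
        if config.require_enhancer:
            mask &= ann["is_enhancer"].fillna(False).astype(bool)
        keep = current.columns[mask.to_numpy(dtype=bool)]
        result.add_stage("context_filter", current.shape[1], keep,
                         {"regions": list(config.context_regions),
                          "require_enhancer": config.require_enhancer})
        current = current.loc[:, keep]

    result.final_probes = list(map(str, current.columns))
    known = [p for p in current.columns if p in manifest.index]
    for pid in current.columns:
        entry = {}
        if pid in manifest.index:
            row = manifest.loc[pid]
            entry.update({
                "gene_symbol": None if pd.isna(row["gene_symbol"]) else row["gene_symbol"],
                "gene_region": str(row["gene_region"]),
                "cpg_context": str(row["cpg_context"]),
                "is_tf": bool(row["is_tf"]), "is_enhancer": bool(row["is_enhancer"]),
            })
        if config.evaluate_markers:
            ev = evaluate_marker(current[pid].to_numpy(), (response == "PD").astype(int))
            entry["evaluation"] = ev.to_dict()
        result.candidates[str(pid)] = entry
    if known:
        dist = context_distribution(known, manifest)
        result.provenance["final_context"] = {
            "gene_region": dist.region_proportions,
            "cpg_context": dist.cpg_proportions,
        }
    if out is not None:
        result.to_json(out / "cascade_result.json")
    return result


def run_cascade_from_paths(meth_path, samples_path, manifest_path,
                           expression_path=None, config_path=None, outdir=None):
    """Path-based wrapper used by the CLI; TSV matrices with sample-id rows."""
    meth = pd.read_csv(meth_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    manifest = read_manifest(manifest_path)
    expr = (pd.read_csv(expression_path, sep="\t", index_col=0)
            if expression_path else None)
    config = (CascadeConfig.from_yaml(config_path) if config_path
              else CascadeConfig())
    bad = ((meth < 0) | (meth > 1)).to_numpy()
    if np.nansum(bad) > 0:
        raise DataError("beta values outside [0, 1] in methylation matrix")
    return run_cascade(meth, samples, manifest, expr, config, outdir)


def density_contrast(meth: pd.DataFrame, response, probe_set=None):
    """Per-probe mean beta in PD vs PR and the above-diagonal summary.

    Returns ``(DataFrame with mean_pd/mean_pr/above_diagonal, summary dict)``
    where the summary holds the count and fraction of probes whose PD mean
    exceeds their PR mean (methylation gain in progressive disease).
    """
    response = np.asarray(response, dtype=object)
    if probe_set is not None:
        probe_set = list(probe_set)
        if len(probe_set) == 0:
            raise DataError("empty probe set")
        meth = meth.loc[:, probe_set]
    for g in ("PD", "PR"):
        if (response == g).sum() == 0:
            raise DataError(f"no samples in group {g}")
    mean_pd = meth.loc[response == "PD"].mean(axis=0)
    mean_pr = meth.loc[response == "PR"].mean(axis=0)
    df = pd.DataFrame({"mean_pd": mean_pd, "mean_pr": mean_pr})
    df["above_diagonal"] = (df["mean_pd"] > df["mean_pr"]).astype(int)
    summary = {
        "n_probes": int(len(df)),
        "n_above_diagonal": int(df["above_diagonal"].sum()),
        "fraction_above_diagonal": float(df["above_diagonal"].mean()),
    }
    return df, summary


def covariate_report(meth: pd.DataFrame, samples: pd.DataFrame,
                     columns=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Descriptive probe-vs-characteristic regression flags (never a filter)."""
    return _covariate_report(meth, samples.loc[meth.index], columns)
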