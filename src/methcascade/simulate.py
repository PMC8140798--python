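"""Synthetic 450K-like cohorts with known ground truth.

The generator emulates the statistical structure the discovery cascade
assumes: a samples x probes beta-value matrix where a planted minority of
"informative" probes is differentially methylated in progressive-disease
(PD) patients — most gaining methylation in PD, a small fraction (default
6%, mirroring a 13-of-216 minority) losing it — plus covariate-coupled
probes, negative methylation->expression coupling for a subset of
informative probes, and an independent pyrosequencing-style validation
cohort on the percent scale.

Beta values are drawn as the inverse logit of a Gaussian: each probe has a
baseline logit-mean, PD samples on informative probes are shifted by
``effect_delta`` on the logit scale, and i.i.d. logit-scale noise of
standard deviation ``noise_sd`` is added.  The logit-normal choice makes
the planted group effect additive on the scale where it is defined and
keeps every beta strictly inside (0, 1).

Hyper-direction informative probes get low baseline methylation
(logit-mean around -2): clinically useful methylation markers of poor
response tend to gain methylation from a near-unmethylated base, which is
also what makes them pass a coefficient-of-variation screen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError

RESPONSE_GROUPS = ("PD", "SD", "PR")

# background genomic-context frequencies (450K-array-like); informative
# probes are drawn island/promoter-enriched, matching the enrichment the
# cascade is meant to surface
_CPG_BG = {"Island": 0.3115, "Shore": 0.22, "Shelf": 0.1096, "OpenSea": 0.3589}
_CPG_INFO = {"Island": 0.8194, "Shore": 0.09, "Shelf": 0.035, "OpenSea": 0.0556}
_REGION_BG = {"TSS1500": 0.1165, "TSS200": 0.10, "UTR5": 0.06, "FirstExon": 0.05,
              "Body": 0.37, "UTR3": 0.05, "Intergenic": 0.2535}
_REGION_INFO = {"TSS1500": 0.1806, "TSS200": 0.16, "UTR5": 0.07, "FirstExon": 0.06,
                "Body": 0.42, "UTR3": 0.05, "Intergenic": 0.0594}


@dataclass
class SimulationConfig:
    """Parameters of the discovery-cohort generator.

    Defaults describe a 79-patient pretreatment cohort with three RECIST
    response groups (PD/SD/PR; complete responders are not generated in the
    discovery setting), ~25% progressive disease, and a planted logit-scale
    hypermethylation effect in PD.
    """

    seed: int = 0
    n_samples: int = 79
    group_probabilities: dict = field(
        default_factory=lambda: {"PD": 0.25, "SD": 0.35, "PR": 0.40})
    n_probes: int = 5000
    n_informative: int = 100
    hypo_fraction: float = 0.06        # minority methylated LOWER in PD
    effect_delta: float = 2.0          # logit-scale PD shift on informative probes
    noise_sd: float = 0.5              # logit-scale residual sd
    tf_fraction: float = 0.0707        # background TF-annotation rate
    tf_fraction_informative: float = 0.1388
    enhancer_fraction: float = 0.10
    enhancer_fraction_informative: float = 0.30
    n_repressive: int = 20             # informative probes coupled to expression
    repression_slope: float = -5.0     # expression units per beta unit
    expression_noise_sd: float = 0.5
    covariate_effect: float = 1.0      # logit shift tied to EGFR-mutant status
    n_covariate: int = 50              # probes carrying the covariate effect
    n_expression_genes: int | None = None  # None = every annotated gene

    def validate(self) -> None:
        p = self.group_probabilities
        if set(p) != set(RESPONSE_GROUPS):
            raise ConfigError(f"group_probabilities must cover {RESPONSE_GROUPS}")
        if any(v < 0 for v in p.values()) or abs(sum(p.values()) - 1.0) > 1e-9:
            raise ConfigError("group_probabilities must be a simplex over PD/SD/PR")
        if min(self.n_samples, self.n_probes) <= 0:
            raise ConfigError("n_samples and n_probes must be positive")
        if not 0 <= self.n_informative <= self.n_probes:
            raise ConfigError("need 0 <= n_informative <= n_probes")
        if not 0 <= self.n_repressive <= self.n_informative:
            raise ConfigError("need 0 <= n_repressive <= n_informative")
        if not 0.0 <= self.hypo_fraction <= 1.0:
            raise ConfigError("hypo_fraction must be in [0, 1]")
        if self.noise_sd <= 0 or self.expression_noise_sd <= 0:
            raise ConfigError("noise standard deviations must be positive")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, for parameter-recovery tests."""

    informative_probe_ids: set
    direction: dict                    # probe_id -> "hyper" | "hypo"
    repressive_probe_ids: set
    covariate_probe_ids: set

    def to_json(self, path) -> None:
        payload = {
            "informative_probe_ids": sorted(self.informative_probe_ids),
            "direction": dict(sorted(self.direction.items())),
            "repressive_probe_ids": sorted(self.repressive_probe_ids),
            "covariate_probe_ids": sorted(self.covariate_probe_ids),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            informative_probe_ids=set(d["informative_probe_ids"]),
            direction=d["direction"],
            repressive_probe_ids=set(d["repressive_probe_ids"]),
            covariate_probe_ids=set(d["covariate_probe_ids"]),
        )


def assign_groups(n: int, probabilities: dict, rng: np.random.Generator) -> np.ndarray:
    """Deterministic group sizes, randomised order.

    Sample slot i (0-based) gets the group whose cumulative-probability
    bracket contains (i + 0.5)/n; the slot->sample mapping is then shuffled
    with the supplied generator.  Group sizes therefore depend only on n and
    the probabilities, never on the random stream.
    """
    labels = list(probabilities)
    cum = np.cumsum([probabilities[g] for g in labels])
    mid = (np.arange(n) + 0.5) / n
    idx = np.searchsorted(cum, mid, side="right").clip(max=len(labels) - 1)
    out = np.array([labels[i] for i in idx], dtype=object)
    rng.shuffle(out)
    return out


def _probe_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:08d}" for i in range(1, n + 1)], name="probe_id")


def _choice(rng, cats_probs, size):
    cats = list(cats_probs)
    p = np.array([cats_probs[c] for c in cats])
    return rng.choice(cats, size=size, p=p / p.sum())


def generate_cohort(config: SimulationConfig):
    """Generate one discovery cohort.

    Returns ``(samples, meth, manifest, expression, truth)``:

    samples : DataFrame indexed by sample_id with ``response`` (PD/SD/PR),
        ``dcr`` (1 = disease control, 0 = PD) and binary covariates
        egfr_mutant, sex_male, smoker, stage_iv.
    meth : samples x probes beta-value DataFrame, all values in (0, 1).
    manifest : validated probe-annotation table.
    expression : samples x genes DataFrame; genes of repressive probes are
        negatively coupled to their probe's beta values.
    truth : :class:`GroundTruth` with the planted probe sets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_probes

    # --- samples ---------------------------------------------------------
    groups = assign_groups(n, {g: config.group_probabilities[g] for g in RESPONSE_GROUPS}, rng)
    sample_ids = pd.Index([f"S{i:04d}" for i in range(1, n + 1)], name="sample_id")
    samples = pd.DataFrame(
        {
            "response": groups,
            "dcr": (groups != "PD").astype(int),
            "egfr_mutant": rng.binomial(1, 0.7, n),
            "sex_male": rng.binomial(1, 0.5, n),
            "smoker": rng.binomial(1, 0.3, n),
            "stage_iv": rng.binomial(1, 0.85, n),
        },
        index=sample_ids,
    )

    # --- planted probe sets ----------------------------------------------
    probes = _probe_ids(m)
    perm = rng.permutation(m)
    informative_pos = np.sort(perm[: config.n_informative])
    rest = perm[config.n_informative:]
    covariate_pos = np.sort(rest[: min(config.n_covariate, len(rest))])

    n_hypo = int(round(config.hypo_fraction * config.n_informative))
    hypo_pos = set(rng.choice(informative_pos, size=n_hypo, replace=False)) if n_hypo else set()
    direction = np.zeros(m)
    direction[informative_pos] = 1.0
    for j in hypo_pos:
        direction[j] = -1.0

    # --- annotation -------------------------------------------------------
    is_info = np.zeros(m, dtype=bool)
    is_info[informative_pos] = True
    region = np.where(is_info, _choice(rng, _REGION_INFO, m), _choice(rng, _REGION_BG, m))
    cpg = np.where(is_info, _choice(rng, _CPG_INFO, m), _choice(rng, _CPG_BG, m))
    tf_p = np.where(is_info, config.tf_fraction_informative, config.tf_fraction)
    enh_p = np.where(is_info, config.enhancer_fraction_informative, config.enhancer_fraction)
    is_tf = rng.random(m) < tf_p
    is_enh = rng.random(m) < enh_p

    # repressive probes need a mapped gene: pick among non-intergenic informative
    info_genic = informative_pos[region[informative_pos] != "Intergenic"]
    if len(info_genic) < config.n_repressive:
        # force enough informative probes into a genic region
        need = config.n_repressive - len(info_genic)
        fixable = informative_pos[region[informative_pos] == "Intergenic"][:need]
        region[fixable] = "TSS1500"
        info_genic = informative_pos[region[informative_pos] != "Intergenic"]
    repressive_pos = np.sort(rng.choice(info_genic, size=config.n_repressive, replace=False))

    gene = np.array([f"GENE{i:06d}" if region[i] != "Intergenic" else "" for i in range(m)],
                    dtype=object)
    manifest = pd.DataFrame(
        {
            "probe_id": probes,
            "gene_symbol": gene,
            "chromosome": rng.choice([f"chr{c}" for c in range(1, 23)], m),
            "position": rng.integers(10_000, 240_000_000, m),
            "gene_region": region,
            "cpg_context": cpg,
            "is_tf": is_tf.astype(int),
            "is_enhancer": is_enh.astype(int),
        }
    )
    from .annotation import validate_manifest

    manifest = validate_manifest(manifest)

    # --- beta values ------------------------------------------------------
    mu = rng.normal(0.0, 1.5, m)
    mu[informative_pos] = np.where(
        direction[informative_pos] > 0,
        rng.normal(-2.0, 0.5, len(informative_pos)),
        rng.normal(+2.0, 0.5, len(informative_pos)),
    )
    is_pd = (groups == "PD").astype(float)[:, None]
    logit = mu[None, :] + config.effect_delta * is_pd * direction[None, :]
    cov_term = np.zeros(m)
    cov_term[covariate_pos] = config.covariate_effect
    logit = logit + samples["egfr_mutant"].to_numpy(float)[:, None] * cov_term[None, :]
    logit = logit + rng.normal(0.0, config.noise_sd, (n, m))
    meth = pd.DataFrame(expit(logit), index=sample_ids, columns=probes)

    # --- expression -------------------------------------------------------
    repressive_genes = [gene[i] for i in repressive_pos]
    all_genes = pd.unique(gene[gene != ""])
    if config.n_expression_genes is None:
        expr_genes = list(all_genes)
    else:
        others = [g for g in all_genes if g not in set(repressive_genes)]
        k_extra = max(0, config.n_expression_genes - len(repressive_genes))
        expr_genes = repressive_genes + list(
            rng.choice(others, size=min(k_extra, len(others)), replace=False))
    expr = pd.DataFrame(
        rng.normal(8.0, 1.0, (n, len(expr_genes))), index=sample_ids, columns=expr_genes
    )
    for i, g in zip(repressive_pos, repressive_genes):
        expr[g] = (
            8.0
            + config.repression_slope * meth.iloc[:, i].to_numpy()
            + rng.normal(0.0, config.expression_noise_sd, n)
        )

    truth = GroundTruth(
        informative_probe_ids=set(probes[informative_pos]),
        direction={probes[i]: ("hypo" if direction[i] < 0 else "hyper")
                   for i in informative_pos},
        repressive_probe_ids=set(probes[repressive_pos]),
        covariate_probe_ids=set(probes[covariate_pos]),
    )
    return samples, meth, manifest, expr, truth


def generate_validation_cohort(
    seed: int,
    n_samples: int = 163,
    pd_fraction: float = 25 / 163,
    shift: float = 5.0,
    base_mean: float = 5.0,
    sd: float = 4.0,
):
    """Pyrosequencing-style validation cohort on the percent (0-100) scale.

    PD samples are drawn Normal(base_mean + shift, sd), disease-control
    samples Normal(base_mean, sd); values are clamped to [0, 100].  Group
    sizes are deterministic (bracket rule of :func:`assign_groups`): the
    defaults give 25 PD and 138 disease-control patients out of 163.

    Returns ``(samples, percent)`` where samples carries ``response``
    (PD/SD/PR/CR) and ``dcr``, and percent is a Series of methylation
    percentages aligned to the sample index.
    """
    if not 0.0 < pd_fraction < 1.0:
        raise ConfigError("pd_fraction must be strictly inside (0, 1)")
    if n_samples <= 0:
        raise ConfigError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    dc = 1.0 - pd_fraction
    groups = assign_groups(
        n_samples,
        {"PD": pd_fraction, "SD": 0.50 * dc, "PR": 0.45 * dc, "CR": 0.05 * dc},
        rng,
    )
    sample_ids = pd.Index([f"V{i:04d}" for i in range(1, n_samples + 1)], name="sample_id")
    samples = pd.DataFrame(
        {"response": groups, "dcr": (groups != "PD").astype(int)}, index=sample_ids
    )
    mean = np.where(groups == "PD", base_mean + shift, base_mean)
    percent = np.clip(rng.normal(mean, sd), 0.0, 100.0)
    return samples, pd.Series(percent, index=sample_ids, name="methylation_percent")


def write_cohort(outdir, samples, meth, manifest, expression=None, truth=None) -> None:
    """Serialise a simulated cohort bundle as TSV/JSON under ``outdir``."""
    from pathlib import Path
    from .annotation import write_manifest

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    samples.to_csv(out / "samples.tsv", sep="\t")
    meth.to_csv(out / "methylation.tsv", sep="\t")
    write_manifest(manifest, out / "manifest.tsv")
    if expression is not None:
        expression.to_csv(out / "expression.tsv", sep="\t")
    if truth is not None:
        truth.to_json(out / "ground_truth.json")
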