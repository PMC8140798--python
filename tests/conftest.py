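import numpy as np
import pandas as pd
import pytest

from methcascade import SimulationConfig, generate_cohort
from methcascade.annotation import validate_manifest


@pytest.fixture(scope="session")
def small_cohort():
    """150-sample, 2,000-probe cohort with 50 planted informative probes."""
    cfg = SimulationConfig(seed=11, n_samples=150, n_probes=2000,
                           n_informative=50, n_repressive=10)
    samples, meth, manifest, expr, truth = generate_cohort(cfg)
    return cfg, samples, meth, manifest, expr, truth


@pytest.fixture()
def toy_manifest():
    return validate_manifest(pd.DataFrame({
        "probe_id": [f"cg{i:04d}" for i in range(10)],
        "gene_symbol": ["G1", "G2", "G3", "G4", "", "G6", "G7", "G8", "G9", ""],
        "chromosome": ["chr1"] * 10,
        "position": np.arange(1000, 11000, 1000),
        "gene_region": ["TSS200", "TSS1500", "Body", "UTR5", "Intergenic",
                        "FirstExon", "Body", "UTR3", "TSS200", "Intergenic"],
        "cpg_context": ["Island"] * 8 + ["OpenSea"] * 2,
        "is_tf": [1, 0, 0, 1, 0, 0, 0, 0, 1, 0],
        "is_enhancer": [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
    }))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
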