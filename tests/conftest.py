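import numpy as np
import pandas as pd
import pytest

from renometh.preprocess import MethylationMatrix, ProbeManifest
from renometh.synthdata import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-sample, 400-probe cohort with planted signal for both traits."""
    cfg = SimulationConfig(
        n_samples=120,
        n_probes=400,
        n_causal_baseline=5,
        n_causal_slope=5,
        effect_size_sd=2.0,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted methylation signal on either trait."""
    cfg = SimulationConfig(
        n_samples=100, n_probes=300, n_causal_baseline=0, n_causal_slope=0, seed=43
    )
    return simulate_cohort(cfg)


@pytest.fixture
def toy_manifest():
    """Ten-probe manifest: 2 SNP-flagged, 1 non-CpG, 1 chrX (plus one probe
    both SNP-flagged and on chrX to exercise first-rule attribution)."""
    probes = [f"p{i}" for i in range(10)]
    table = pd.DataFrame(
        {
            "chromosome": ["chr1"] * 8 + ["chrX", "chr2"],
            "position": np.arange(1, 11) * 1000,
            "context": ["CpG"] * 5 + ["non-CpG"] + ["CpG"] * 4,
            "snp_overlap": [True, True] + [False] * 8,
            "genes": [[] for _ in range(10)],
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return ProbeManifest(table)


@pytest.fixture
def toy_matrix(toy_manifest):
    """10 probes x 4 samples of valid betas; probe p7 has one missing value."""
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.uniform(0.1, 0.9, size=(4, 10)),
        index=[f"s{i}" for i in range(4)],
        columns=toy_manifest.probe_ids,
    )
    vals.loc["s2", "p7"] = np.nan
    return MethylationMatrix(vals, scale="beta")
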