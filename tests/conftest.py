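import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from heteroshift import io

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def small_manifest():
    frame = pd.DataFrame({
        "probe_id": [f"cg{i:03d}" for i in range(8)],
        "chromosome": ["chr1"] * 5 + ["chr2"] * 3,
        "position": [100, 200, 300, 400, 500, 50, 150, 250],
        "gene_labels": ["GENEA"] * 4 + ["GENEB"] + ["GENEC"] * 3,
    })
    frame["gene_labels"] = frame["gene_labels"].astype(str)
    return io.manifest_from_frame(frame)


@pytest.fixture
def two_group_matrix():
    """6 test + 6 control samples, 8 probes, constant values per group."""
    rng = np.random.default_rng(7)
    samples = [f"t{i}" for i in range(6)] + [f"c{i}" for i in range(6)]
    vals = np.clip(rng.normal(0.5, 0.05, (8, 12)), 0.001, 0.999)
    values = pd.DataFrame(vals, index=[f"cg{i:03d}" for i in range(8)],
                          columns=samples)
    design = pd.DataFrame(
        {"mutation_type": ["mut13"] * 6 + ["mut13"] * 6,
         "load": ["high"] * 6 + ["low"] * 6},
        index=pd.Index(samples, name="sample_id"))
    return io.BetaMatrix(values=values, design=design)


@pytest.fixture
def synthetic_msmlpa_table():
    """Synthetic stand-in for an MS-MLPA site x group table at the study's
    dimensions: 52 CpG sites across 5 groups, of which 17 are 0% methylated
    in every group and 3 of the remainder carry a missing group value.
    Constructed data, not the study's measurements."""
    rng = np.random.default_rng(42)
    groups = ["WT", "13L", "13H", "8L", "8H"]
    vals = rng.uniform(0.05, 0.95, (52, 5))
    vals[:17] = 0.0                      # zero in all groups -> excluded
    for i, g in zip((20, 30, 40), (1, 3, 4)):
        vals[i, g] = np.nan              # missing group value -> eliminated
    return pd.DataFrame(vals, index=[f"site{i:02d}" for i in range(52)],
                        columns=groups)
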