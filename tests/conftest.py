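import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import phylosym as ps

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

GLOBAL_SEED = 20240901


@pytest.fixture
def rng():
    return np.random.default_rng(GLOBAL_SEED)


@pytest.fixture
def toy_tree():
    """Balanced 4-leaf tree with unit branches: ((A:1,B:1):1,(C:1,D:1):1)."""
    return ps.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def small_table():
    """3 populations x 2 samples, 6 OTUs, with taxonomy."""
    counts = pd.DataFrame(
        {
            "P1_s1": [30, 10, 5, 0, 0, 55],
            "P1_s2": [25, 15, 0, 3, 0, 57],
            "P2_s1": [5, 40, 10, 5, 0, 40],
            "P2_s2": [8, 35, 12, 0, 0, 45],
            "P3_s1": [2, 5, 50, 20, 23, 0],
            "P3_s2": [1, 8, 45, 25, 21, 0],
        },
        index=[f"OTU_{i}" for i in range(1, 7)],
    )
    taxonomy = pd.Series(
        [
            "k__Bacteria; g__Acinetobacter; s__",
            "k__Bacteria; g__Citrobacter; s__",
            "k__Bacteria; g__Lactobacillus; s__",
            "k__Bacteria; g__Serratia; s__",
            "k__Bacteria; g__Pseudomonas; s__",
            "k__Bacteria; g__Wolbachia; s__",
        ],
        index=counts.index,
    )
    return ps.OTUTable(counts, taxonomy)


@pytest.fixture
def small_metadata():
    frame = pd.DataFrame(
        {
            "population": ["P1", "P1", "P2", "P2", "P3", "P3"],
            "endosymbiont_status": ["infected"] * 4 + ["uninfected"] * 2,
        },
        index=["P1_s1", "P1_s2", "P2_s1", "P2_s2", "P3_s1", "P3_s2"],
    )
    return ps.SampleMetadata(frame)
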