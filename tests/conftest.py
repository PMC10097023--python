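import numpy as np
import pandas as pd
import pytest

from longicore.abundance_io import RANKS, AbundanceTable
from longicore.synthetic import SyntheticDesign, generate_abundance


@pytest.fixture(scope="session")
def small_cohort():
    """One modest planted cohort reused by read-only tests."""
    design = SyntheticDesign(
        n_samples=120,
        n_otus=400,
        modules=((40, 0.8), (30, 0.7)),
        trait_module_index=0,
        trait_effect=0.5,
        seed=11,
    )
    return generate_abundance(design)


@pytest.fixture
def toy_table():
    """Tiny hand-checkable abundance table: 3 samples x 4 OTUs."""
    counts = pd.DataFrame(
        [[3, 4, 0, 2], [1, 0, 5, 0], [2, 2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["o1", "o2", "o3", "o4"],
        dtype=float,
    )
    taxonomy = pd.DataFrame("", index=counts.columns, columns=list(RANKS))
    taxonomy["kingdom"] = "Bacteria"
    taxonomy["phylum"] = ["Firmicutes", "Firmicutes", "Bacteroidetes",
                          "Proteobacteria"]
    taxonomy["genus"] = ["Blautia", "Blautia", "Bacteroides", ""]
    return AbundanceTable(counts=counts, taxonomy=taxonomy)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
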