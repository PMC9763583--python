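import numpy as np
import pandas as pd
import pytest

from micropod.otu_io import OtuTable, TaxonomyMap
from micropod.synth import SyntheticSpec, generate_cohort


@pytest.fixture
def tiny_table():
    return OtuTable(["s1", "s2"], ["o1", "o2", "o3"],
                    np.array([[5, 0, 1], [2, 2, 2]]))


@pytest.fixture
def tiny_taxonomy():
    return TaxonomyMap({
        "o1": ("Bacteria", "Firmicutes", "c", "o", "f", "Prevotella"),
        "o2": ("Bacteria", "Bacteroidetes", "c", "o", "f", "Prevotella"),
        # o3 unannotated
    })


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced synthetic cohort reused by several modules (session-scoped
    because generation is deterministic and read-only)."""
    spec = SyntheticSpec(n_case=15, n_control=16, n_otus=80, n_effect=6)
    return generate_cohort(spec, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default design: 30 cases / 31 controls, 200 OTUs, 8 effects."""
    return generate_cohort(SyntheticSpec(), seed=1)
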