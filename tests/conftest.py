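import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from replistool import (CountTable, PhyloTree, SampleMetadata, SyntheticParams,
                        TaxonomyMap, generate_study)


@pytest.fixture
def three_leaf_tree():
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_leaf_tree():
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def small_counts():
    return CountTable(pd.DataFrame(
        [[3, 0], [1, 2]], index=["s1", "s2"], columns=["o1", "o2"]))


@pytest.fixture
def small_metadata():
    rows = []
    for subj in ("subj01", "subj02"):
        for rep in (1, 2, 3):
            rows.append((f"{subj}.rnalater.t0.r{rep}", subj, "rnalater", 0, rep))
    df = pd.DataFrame(rows, columns=["sample_id", "subject_id", "medium",
                                     "time_days", "replicate"])
    return SampleMetadata(df.set_index("sample_id"))


@pytest.fixture(scope="session")
def default_study():
    """One shared synthetic study at the reference design and defaults."""
    return generate_study(SyntheticParams(seed=42))


@pytest.fixture(scope="session")
def small_study():
    """A cut-down study for fast end-to-end checks."""
    return generate_study(SyntheticParams(n_subjects=4, n_otus=40,
                                          depth=4000, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
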