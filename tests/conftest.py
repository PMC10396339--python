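import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from crossatlas.io_formats import CountMatrix
from crossatlas.synthetic_data import SynthConfig, generate_paired_datasets


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 genes x 2 cells with a known layout."""
    mat = sp.csc_matrix(np.array([[4, 0], [0, 2], [1, 3]]))
    return CountMatrix(mat, ["g1", "g2", "g3"], ["c1", "c2"], species="A")


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Down-scaled paired design: fast enough for per-test regeneration."""
    return SynthConfig(
        n_types_shared=4,
        n_types_specific_A=1,
        n_types_specific_B=1,
        cells_per_type_per_timepoint=30,
        n_timepoints=2,
        genes_per_species=900,
        n_one2one=600,
        n_one2many=40,
        program_size=15,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_pair(small_config):
    return generate_paired_datasets(small_config)


@pytest.fixture(scope="session")
def default_pair():
    """The full default design (used by the recovery-style tests)."""
    return generate_paired_datasets(SynthConfig(seed=1))


def truth_assignment(cm):
    """Cluster assignment from ground-truth cell types, plus category names."""
    from crossatlas.atlas import ClusterAssignment

    types = cm.cell_meta["cell_type"].astype("category")
    return (
        ClusterAssignment(
            labels=types.cat.codes.to_numpy(), resolution=0.0, seed=0
        ),
        list(types.cat.categories),
    )
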