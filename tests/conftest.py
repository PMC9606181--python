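import numpy as np
import pandas as pd
import pytest

from fosnet.correlation import CorrelationMatrix
from fosnet.design import StudyDesign
from fosnet.simulate import RegionActivityTable


def make_table(values, regions=None, group="WT:vehicle:naive", animals=None):
    values = np.asarray(values, dtype=float)
    regions = regions or [f"R{i+1}" for i in range(values.shape[1])]
    animals = animals or [f"a{i+1}" for i in range(values.shape[0])]
    return RegionActivityTable(
        group_label=group,
        values=pd.DataFrame(values, index=animals, columns=regions),
    )


def make_corr(matrix, regions=None, group="g", n_animals=10):
    matrix = np.asarray(matrix, dtype=float)
    regions = regions or [f"R{i+1}" for i in range(matrix.shape[0])]
    return CorrelationMatrix(
        group_label=group,
        r=pd.DataFrame(matrix, index=regions, columns=regions),
        n_animals=n_animals,
    )


def one_group_design(regions, n=40, seed=0):
    label = "WT:vehicle:naive"
    return StudyDesign(
        genotypes=("WT",),
        treatments=("vehicle",),
        stress_conditions=("naive",),
        n_per_cell={label: n},
        region_names=tuple(regions),
        seed=seed,
    ), label


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
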