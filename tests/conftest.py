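"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from dairygp.io_formats import (GenotypeSet, MarkerMap, PedigreeTable,
                                PhenotypeTable)
from dairygp.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def tiny_map():
    return MarkerMap(np.array(["1", "1", "2", "2"], object),
                     np.array([100, 500, 100, 900]),
                     np.array(["m1", "m2", "m3", "m4"], object))


@pytest.fixture
def tiny_genotypes(tiny_map):
    d = np.array([[0.0, 1.0, 2.0, 1.0],
                  [1.0, 1.0, 0.0, 0.0],
                  [2.0, 1.0, 1.0, 2.0]])
    return GenotypeSet(d, ["a1", "a2", "a3"], tiny_map,
                       np.array(["A", "A", "B"], object))


@pytest.fixture
def trio_pedigree():
    return PedigreeTable(pd.DataFrame(
        {"id": ["s", "d", "o"], "sire": ["0", "0", "s"],
         "dam": ["0", "0", "d"]}))


@pytest.fixture
def two_record_phenotypes():
    return PhenotypeTable(pd.DataFrame({
        "animal_id": ["b1", "c1"],
        "trait": ["MY", "MY"],
        "value": [1.2, -0.4],
        "record_type": ["bull", "cow"],
        "d": [50.0, np.nan],
        "r": [np.nan, 3.0],
        "breed": ["A", "A"],
        "sex": ["M", "F"],
    }))


def small_bundle(seed=0, **overrides):
    """A fast three-breed bundle for integration-style tests."""
    kwargs = dict(
        m=400, n_chrom=2,
        n_cows={"A": 60, "B": 40, "C": 15},
        n_bulls={"A": 30, "B": 20, "C": 10},
        n_validation={"A": 20, "B": 20},
        n_large_qtl=3, seed=seed)
    kwargs.update(overrides)
    return simulate_dataset(SimulationConfig(**kwargs))


@pytest.fixture(scope="session")
def shared_bundle():
    return small_bundle(seed=7)
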