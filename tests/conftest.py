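import numpy as np
import pandas as pd
import pytest

from rosette_omics.core_io import OmicsMatrix
from rosette_omics.simulate import (
    MethylLink,
    PlantedSet,
    SimulationConfig,
    generate_multiomics,
    generate_ontology,
)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic case series (16 ETMR, 9 AT/RT, 15 MB) with
    one planted +1.5 log2 set and two methylation-linked genes."""
    cfg = SimulationConfig(
        seed=7,
        methyl_link=[MethylLink("GENE0001"), MethylLink("GENE0002", sign=-1)],
        n_pairs=3,
    )
    return generate_multiomics(cfg)


@pytest.fixture(scope="session")
def small_ontology():
    return generate_ontology(n_terms=25, depth=3, seed=11)


@pytest.fixture()
def random_matrix():
    rng = np.random.default_rng(42)
    vals = pd.DataFrame(
        rng.normal(size=(100, 10)),
        index=[f"G{i:03d}" for i in range(100)],
        columns=[f"S{j:02d}" for j in range(10)],
    )
    return OmicsMatrix(vals, "proteome")
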