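import numpy as np
import pandas as pd
import pytest

import metagut as mg


@pytest.fixture(scope="session")
def small_catalog_truth():
    """50 ORFs from 10 parents at 2% substitution, with the true partition."""
    orfs, truth = mg.generate_catalog(
        n_parents=10, copies_per_parent=5, substitution_rate=0.02, seed=101,
        length_range=(150, 400),
    )
    return orfs, truth


@pytest.fixture(scope="session")
def community_with_effects():
    genes = [f"gene{i:03d}" for i in range(120)]
    return mg.generate_community(
        genes, seed=202, effects=mg.PlantedEffects(diet_fold=4.0, strain_fold=2.0)
    )


@pytest.fixture(scope="session")
def null_community():
    genes = [f"gene{i:03d}" for i in range(80)]
    return mg.generate_community(
        genes, seed=303, effects=mg.PlantedEffects(diet_fold=1.0, strain_fold=1.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(4242)


def group_frames(truth, strain, diet):
    design = truth.design
    mask = (design["strain"] == strain) & (design["diet"] == diet)
    return truth.abundances.loc[design.index[mask]]
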