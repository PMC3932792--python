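import numpy as np
import pytest

import metscore as m
from metscore.trait_prep import TRAITS, apply_transform_spec, build_transform_spec, standardize


@pytest.fixture(scope="session")
def cohort5k():
    """One large default-config cohort shared across tests."""
    config = m.SyntheticConfig(n_individuals=5000, seed=42)
    pheno, genotypes, truth = m.generate_cohort(config)
    return config, pheno, genotypes, truth


@pytest.fixture(scope="session")
def zmatrix5k(cohort5k):
    _, pheno, _, _ = cohort5k
    traits = pheno[list(TRAITS)]
    spec = build_transform_spec(traits)
    z, _, _ = standardize(apply_transform_spec(traits, spec))
    return z


@pytest.fixture(scope="session")
def model5k(zmatrix5k):
    return m.fit_score_model(zmatrix5k)
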