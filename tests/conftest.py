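"""Shared fixtures: one desk-scale linked cohort and its fitted fusion.

Session-scoped because the fusion fit is the expensive object most tests
interrogate; everything is seeded so the suite is deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from parafuse.datatypes import MODALITIES
from parafuse.fusion import FusionConfig, fit_parafusion
from parafuse.prep import prepare_features
from parafuse.synthetic import CohortConfig, generate_linked_cohort

COHORT_SEED = 5
FUSION_SEED = 11


@pytest.fixture(scope="session")
def cohort_config() -> CohortConfig:
    return CohortConfig(n_subjects=400, n_sites=2)


@pytest.fixture(scope="session")
def cohort(cohort_config):
    """(features, phenotypes, truth) with the planted 0.75/0.17/0.17 triplet."""
    return generate_linked_cohort(cohort_config, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def prepared(cohort):
    feats, pheno, _ = cohort
    return {m: prepare_features(feats[m], pheno) for m in MODALITIES}


@pytest.fixture(scope="session")
def fitted(prepared, cohort_config):
    """FusionResult on the session cohort at the default coupling weight."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_parafusion(
            prepared[MODALITIES[0]],
            prepared[MODALITIES[1]],
            prepared[MODALITIES[2]],
            cohort_config.n_components,
            FusionConfig(seed=FUSION_SEED),
        )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
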