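"""Shared fixtures: a default config, small deterministic trees, and the
seeded 24-lesion cohort with its full paired-wire study results (computed
once per session; several tests and the acceptance checks share them)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import coroflow as cf

COHORT_SEED = 1


@pytest.fixture(scope="session")
def config() -> cf.PipelineConfig:
    return cf.PipelineConfig(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def patient() -> cf.PatientRecord:
    return cf.load_patient_fixtures()[0]  # MAP 93.33 mmHg, CO 6.0 L/min


@pytest.fixture()
def small_tree() -> cf.CoronaryTree:
    return cf.generate_tree(3, 0.15, seed=7)


@pytest.fixture()
def stenotic_tree(small_tree) -> cf.CoronaryTree:
    return cf.add_stenosis(small_tree, 1, 0.7)


@pytest.fixture(scope="session")
def cohort(config) -> list[cf.CohortLesion]:
    return cf.generate_cohort(n_per_class=6, seed=COHORT_SEED, config=config)


@pytest.fixture(scope="session")
def study_results(cohort, config):
    """Paired wire-absent/wire-included transient runs, both flow setups."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cf.paired_wire_study(cohort, config=config)
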