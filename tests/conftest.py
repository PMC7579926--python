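"""Shared fixtures: small simulated cohorts reused across test modules.

The base cohort is desk-scale (600 genes, 240 patients, two cohorts) so the
expensive pieces (seed reference, normalization) are computed once per
session.
"""

import numpy as np
import pandas as pd
import pytest

from gsclassifier.normalize import build_seed_reference, normalize_counts
from gsclassifier.simulate import SimConfig, simulate_cohort


def small_config(**overrides) -> SimConfig:
    base = dict(
        n_genes=600,
        n_samples={"AEGIS": 120, "Registry": 120},
        n_cancer_genes=60,
        n_smoking_genes=50,
        n_cohort_genes=30,
        n_inhaled_genes=30,
        n_celltype_genes=20,
        n_chrx_genes=20,
        patients_per_plate=60,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def patients(cohort):
    return cohort.clinical.index[cohort.clinical["role"] == "patient"]


@pytest.fixture(scope="session")
def seed_ref(cohort, patients):
    seed_ids = patients[:80]
    return build_seed_reference(cohort.counts[seed_ids], cohort.clinical)


@pytest.fixture(scope="session")
def vst(cohort, seed_ref):
    vst, _ = normalize_counts(cohort.counts, seed_ref)
    return vst


@pytest.fixture(scope="session")
def clinical(cohort, patients):
    return cohort.clinical.loc[patients]
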