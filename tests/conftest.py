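"""Shared fixtures.

The three-group cohort fixture runs the full synthesis -> preprocessing ->
feature-extraction chain once per session (it is the expensive part of the
suite) and is shared between the pipeline-level tests.
"""

import numpy as np
import pytest

import eegdx


@pytest.fixture(scope="session")
def two_group_spec():
    """Tiny two-group synthetic cohort spec (fast downstream stages)."""
    return eegdx.default_cohort_spec(
        seed=11, duration_s=120.0,
        groups=("control", "alzheimer"), n_subjects=3)


@pytest.fixture(scope="session")
def three_group_features():
    """Feature matrix of a 3 x 10-subject cohort with strong group structure.

    Control, Alzheimer and schizophrenia profiles differ in oscillation
    frequency/amplitude, 1/f slope and irregularity, so the downstream
    selection and classification stages have real signal to find.
    """
    spec = eegdx.default_cohort_spec(
        seed=7, duration_s=120.0,
        groups=("control", "alzheimer", "schizophrenia"), n_subjects=10)
    cohort = [eegdx.preprocess(r) for r in eegdx.generate_cohort(spec)]
    return eegdx.build_matrix(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
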