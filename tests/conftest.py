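"""Shared fixtures: a small synthetic cohort, its store, and annotations.

The "small" cohort (105 samples x 300 features, one hub with 30 responders
at loading 0.8, 5 PCR miRNAs) keeps unit tests fast; acceptance tests build
the full mini preset themselves.
"""

import numpy as np
import pytest

import corrbrowser as cb


@pytest.fixture(scope="session")
def small_spec() -> cb.SimulationSpec:
    return cb.SimulationSpec(
        n_samples=105,
        n_features=300,
        hubs=(cb.HubSpec("HUB01", 30, 0.8),),
        pcr_block=cb.PcrBlockSpec(n_mirna=5, coupling=-0.6, ct_dropout_rate=0.05),
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    matrix, truth = cb.simulate_cohort(small_spec)
    matrix = cb.simulate_mirna_layer(small_spec, truth, matrix)
    return matrix, truth


@pytest.fixture(scope="session")
def small_store(small_cohort, tmp_path_factory) -> cb.CorrelationStore:
    matrix, _ = small_cohort
    path = tmp_path_factory.mktemp("store") / "small.h5"
    return cb.build_store(matrix, path)


@pytest.fixture(scope="session")
def small_annotation(small_cohort) -> cb.AnnotationTable:
    _, truth = small_cohort
    return cb.AnnotationTable(cb.build_annotation_frame(truth))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
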