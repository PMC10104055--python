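import numpy as np
import pytest

from spex import (
    build_all_tensors,
    fixture_distal_effect,
    fixture_null,
    make_design,
    simulate,
    strip_spatial,
)


@pytest.fixture(scope="session")
def distal_sim():
    """The frozen positive-control simulation (distal enhancers informative)."""
    return simulate(fixture_distal_effect())


@pytest.fixture(scope="session")
def null_sim():
    """The frozen null simulation (loops exist, zero distal weight)."""
    return simulate(fixture_null())


def _designs(sim):
    spatial = build_all_tensors(sim.genes, sim.predictor(), sim.contacts)
    baseline = {g: strip_spatial(t) for g, t in spatial.items()}
    db = make_design(baseline, sim.expression, sim.gene_chroms)
    ds = make_design(spatial, sim.expression, sim.gene_chroms)
    return db, ds, spatial


@pytest.fixture(scope="session")
def distal_designs(distal_sim):
    """(baseline design, spatial design, spatial tensors) for the positive fixture."""
    return _designs(distal_sim)


@pytest.fixture(scope="session")
def null_designs(null_sim):
    return _designs(null_sim)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
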