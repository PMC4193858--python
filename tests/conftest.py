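import pytest

import arraysmith as ars


@pytest.fixture(scope="session")
def sim_spec():
    """The default synthetic study conditions (fixed seed)."""
    return ars.SimulationSpec(seed=1)


@pytest.fixture(scope="session")
def dataset(sim_spec):
    return ars.simulate(sim_spec)


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    return ars.run_pipeline(
        dataset.records, dataset.genome, dataset.panel, dataset.map_points,
        scores=dataset.scores,
    )


@pytest.fixture(scope="session")
def panel14(dataset):
    """The 14-diploid + 2-DH panel used throughout."""
    return dataset.panel
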