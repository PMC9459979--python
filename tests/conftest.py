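import pytest

from stype.simulate import (
    SimulationConfig,
    simulate_genotype_panel,
    simulate_reference_panel,
    study_composition,
)
from stype.workflow import run_typing_workflow


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(rng_seed=11)


@pytest.fixture(scope="session")
def reference_panel(sim_config):
    """23 synthetic references (19 Class I + 4 Class II) with planted truth."""
    return simulate_reference_panel(sim_config)


@pytest.fixture(scope="session")
def study_panel(reference_panel, sim_config):
    """79-genotype panel mirroring the study composition (48/13/17 + 1 none)."""
    references, _ = reference_panel
    composition = study_composition(references)
    return simulate_genotype_panel(references, sim_config, composition)


@pytest.fixture(scope="session")
def workflow_result(reference_panel, study_panel):
    """One full pipeline run shared by the end-to-end tests."""
    references, _ = reference_panel
    return run_typing_workflow(references, study_panel.sequences)
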