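import pytest

from clonescape import (
    SimulationConfig,
    assign_clones,
    collapse_subject,
    filter_eligible,
    simulate_repertoire,
)


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated two-replicate subject used across test modules."""
    cfg = SimulationConfig(seed=7, n_clones=60, cells_sampled_per_replicate=400)
    return simulate_repertoire(cfg)


@pytest.fixture(scope="session")
def sim_pipeline(sim_small):
    """Collapse + eligibility + clonal assignment run on the small subject."""
    useqs = collapse_subject(sim_small.rearrangements)
    eligible, reports = filter_eligible(useqs)
    clones = assign_clones(eligible)
    return {
        "useqs": useqs,
        "eligible": eligible,
        "reports": reports,
        "clones": clones,
    }
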