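import pytest

from ipsc_integrity import simulate as sm
from ipsc_integrity import somatic as so


@pytest.fixture(scope="session")
def cohort():
    """A small synthetic cohort shared across tests: 4 donors with default
    generator settings, reads sampled and classified."""
    config = sm.SimConfig(n_donors=4, seed=11)
    truth, metas = sm.simulate_cohort(config)
    observations = sm.sample_reads(truth)
    calls = so.subtract_germline(observations, metas)
    calls = so.exclude_factor_loci(calls, truth.genome.factor_regions)
    calls = so.classify_calls(calls)
    return {
        "config": config,
        "truth": truth,
        "metas": metas,
        "observations": observations,
        "calls": calls,
        "fixed": [c for c in calls if c.somatic_class == "fixed"],
    }


@pytest.fixture(scope="session")
def coverage_profiles(cohort):
    return sm.simulate_coverage_profiles(cohort["truth"])
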