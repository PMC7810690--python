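import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth():
    """A small unclustered dataset with planted overlaps, noiseless."""
    from rdnakit.synthetic import SimConfig, simulate_dataset

    config = SimConfig(n_units=60, n_bacs=4, stickiness=0.0,
                       overlap_plan=[(0, 1, 3), (2, 3, 2)], jitter_bp=0, seed=7)
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def small_fasta(small_truth):
    from rdnakit.synthetic import emit_fasta

    return emit_fasta(small_truth)


@pytest.fixture
def toy_catalog():
    return {
        "F2J17": ["2001(EZ)", "2001(EZ)", "3001(EU)"],
        "F2C3": ["3111(EEV)", "2001(EZ)"],
    }
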