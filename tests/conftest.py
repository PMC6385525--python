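import pytest

from poolburden import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """Small but fully featured cohort: pooled cases + controls, three
    panels, all artifact classes injected."""
    return CohortConfig(
        n_cases=100,
        n_controls=20,
        pool_size=10,
        n_genes=10,
        variants_per_gene=6,
        af_range=(1e-3, 0.05),
        artifact_rates={"single_strand": 0.06, "low_depth": 0.06, "low_gq": 0.06},
        spanish_missing_rate=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)
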