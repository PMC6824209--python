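import pytest
from hypothesis import HealthCheck, settings

from taxorank import SimulationConfig, generate_benchmark_fixture, table1_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """The published Glaucium grandiflorum worked example."""
    return table1_fixture()


@pytest.fixture(scope="session")
def strong_signal_fixture():
    """Synthetic benchmark with a strong chemotaxonomic signal."""
    return generate_benchmark_fixture(
        SimulationConfig(
            seed=11,
            n_queries=120,
            candidates_per_query=12,
            p_true_source_species=0.6,
            p_true_source_genus=0.25,
            p_true_source_family=0.1,
            p_decoy_match=0.05,
        )
    )


@pytest.fixture(scope="session")
def no_signal_fixture():
    """Synthetic benchmark where sources carry no information about the query."""
    return generate_benchmark_fixture(
        SimulationConfig(
            seed=11,
            n_queries=120,
            candidates_per_query=12,
            p_true_source_species=0.0,
            p_true_source_genus=0.0,
            p_true_source_family=0.0,
            p_decoy_match=0.0,
        )
    )
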