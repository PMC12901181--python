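import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def single_cassette_sim():
    """One class-1 integron: attI1 | ORF | ΔattI1-11, mutation-free."""
    from integronkit.simulate import (
        CassettePlan,
        SyntheticIntegronSpec,
        generate_integron,
    )

    spec = SyntheticIntegronSpec(
        integron_id="sim1",
        cassette_plan=(CassettePlan(downstream_site="dattI1:-11"),),
        seed=11,
    )
    return generate_integron(spec)
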