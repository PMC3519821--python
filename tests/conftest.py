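import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def worked():
    """The hand-computed 120-residue regression bundle and expected report."""
    from metannot.fixtures import worked_example

    return worked_example()


@pytest.fixture()
def query80():
    from metannot.iofmt import QuerySequence

    return QuerySequence(id="q80", residues="ACDEFGHIKLMNPQRSTVWY" * 4)
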