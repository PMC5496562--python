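import pytest
from hypothesis import HealthCheck, settings

from dtsb.simulate import figure3_fixture, protruding_ends_fixture

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fig3():
    """The 8-species x 8-position worked-example panel."""
    return figure3_fixture()


@pytest.fixture(scope="session")
def staggered():
    """Three sequences with protruding terminal gaps."""
    return protruding_ends_fixture()


@pytest.fixture
def toy_fasta(tmp_path):
    """Write a 2-record aligned FASTA and return its path."""
    path = tmp_path / "toy.fasta"
    path.write_text(">alpha\nACGT\n>beta\nACGA\n")
    return path
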