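import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from scoremr.pipeline import fixture_path
from scoremr.summary_data import LINEAR, LNOR, SD, read_summary_table


@pytest.fixture(scope="session")
def hcy_assocs():
    """Per-SNP exposure (ln homocysteine, SD units) associations."""
    return read_summary_table(fixture_path("table1_hcy.tsv"), scale=SD)


@pytest.fixture(scope="session")
def t2d_assocs():
    return read_summary_table(fixture_path("table1_t2d.tsv"), scale=LNOR)


@pytest.fixture(scope="session")
def glucose_assocs():
    return read_summary_table(fixture_path("table1_glucose.tsv"), scale=LINEAR)


@pytest.fixture(scope="session")
def insulin_assocs():
    return read_summary_table(fixture_path("table1_insulin.tsv"), scale=LINEAR)
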