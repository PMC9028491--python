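import pytest
from hypothesis import HealthCheck, settings

from kdrseq.bundled import bundled_gene_model
from kdrseq.reference import kdr_catalog

settings.register_profile(
    "kdrseq",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("kdrseq")


@pytest.fixture(scope="session")
def model():
    return bundled_gene_model()


@pytest.fixture(scope="session")
def catalog():
    return kdr_catalog()
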