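import pytest

from umbrannot.annotate import annotate_genome
from umbrannot.config import RunConfig
from umbrannot.synth import GenomeDesign, generate_genome


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def uv_genome(config):
    """One fully planted UV-architecture genome plus its ground truth."""
    record, manifest = generate_genome(GenomeDesign(), seed=1, config=config)
    return record, manifest


@pytest.fixture(scope="session")
def uv_report(uv_genome, config):
    record, _ = uv_genome
    return annotate_genome(record, config)
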