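import pytest

from kleptorecept.annotation_io import PipelineConfig
from kleptorecept.synthetic_data import ProteomePlan, generate_proteome


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_proteome(tmp_path_factory):
    """A written-to-disk synthetic proteome shared across parser tests."""
    out = tmp_path_factory.mktemp("proteome")
    return generate_proteome(ProteomePlan(rng_seed=11), out_dir=out)
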