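import pytest

from genomictk.genome import GenomeAssembly
from genomictk.synthetic import GeneratorConfig, gen_assembly


@pytest.fixture
def toy_assembly() -> GenomeAssembly:
    return GenomeAssembly.from_pairs([("chr1", 100), ("chr2", 50)])


@pytest.fixture
def cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=20240915)


@pytest.fixture
def assembly(cfg) -> GenomeAssembly:
    return gen_assembly(cfg)
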