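import pytest
from hypothesis import HealthCheck, settings

import meltdown as m

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_corpus():
    """The generator's default corpus: the study conditions in miniature."""
    return m.generate_corpus(m.SyntheticConfig())


@pytest.fixture(scope="session")
def corpus_dir(default_corpus, tmp_path_factory):
    """Default corpus emitted to disk in standard formats."""
    out = tmp_path_factory.mktemp("corpus")
    m.emit_truth_and_files(default_corpus, out)
    return out
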