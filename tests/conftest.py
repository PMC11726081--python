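import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

import snpmeta as sm


@pytest.fixture(scope="session")
def corpus() -> sm.StudyCorpus:
    return sm.load_cdkn2a_corpus()


@pytest.fixture(scope="session")
def by_id(corpus):
    return {r.study_id: r for r in corpus}
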