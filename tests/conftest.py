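import pytest

from npforge import fixturegen


@pytest.fixture(scope="session")
def np_like_corpus():
    """300 unique, valid, stereo-free NP-flavoured fixture molecules."""
    return fixturegen.generate_clean_corpus(300, seed=101, pool="np_like")


@pytest.fixture(scope="session")
def druglike_corpus():
    """200 unique, valid, stereo-free druglike fixture molecules."""
    return fixturegen.generate_clean_corpus(200, seed=202, pool="druglike")
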