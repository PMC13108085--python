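import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from comodnet import demo_corpus, read_corpus, write_default_fixture
from comodnet.simulate import ANCHOR

FIXTURE_SEED = 17


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The documented default synthetic fixture, written once per session."""
    out = tmp_path_factory.mktemp("fixture")
    paths, truth, config = write_default_fixture(out, seed=FIXTURE_SEED)
    return paths, truth, config


@pytest.fixture(scope="session")
def fixture_corpus(fixture_bundle):
    paths, _, _ = fixture_bundle
    return read_corpus(paths["profiling"], paths["differential"])


@pytest.fixture(scope="session")
def fixture_truth(fixture_bundle):
    return fixture_bundle[1]


@pytest.fixture(scope="session")
def annotation_paths(fixture_bundle):
    return fixture_bundle[0]


@pytest.fixture(scope="session")
def demo():
    """Deterministic overlay-demonstration corpus."""
    return demo_corpus()


@pytest.fixture(scope="session")
def anchor():
    return ANCHOR
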