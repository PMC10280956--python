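import hypothesis
import pytest

from cif2pdb.model import WANTED_CATEGORIES, build_document
from cif2pdb.reader import parse_categories, tokenize

hypothesis.settings.register_profile(
    "fixed", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("fixed")


def parse_doc(text: str):
    """mmCIF text -> StructureDoc, the whole reading pipeline."""
    return build_document(parse_categories(tokenize(text), WANTED_CATEGORIES))


@pytest.fixture
def in_tmp(tmp_path, monkeypatch):
    """Run a test with the working directory inside tmp_path."""
    monkeypatch.chdir(tmp_path)
    return tmp_path
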