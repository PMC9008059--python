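import pytest

from fairschema.fixtures import make_mini_schema
from fairschema.io import write_bundle


@pytest.fixture
def mini_schema():
    """Fresh desk-scale nine-module schema (mutable per test)."""
    return make_mini_schema()


@pytest.fixture
def mini_bundle(tmp_path, mini_schema):
    """The mini schema written to disk as a bundle directory."""
    root = tmp_path / "bundle"
    write_bundle(mini_schema, root)
    return root
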