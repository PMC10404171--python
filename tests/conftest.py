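import pytest

from protreact import load_dataset, load_domains


@pytest.fixture(scope="session")
def records():
    """The bundled 106-chemical study dataset."""
    return load_dataset()


@pytest.fixture(scope="session")
def domains():
    """Bundled mechanistic-domain annotations (synthetic reconstruction)."""
    return load_domains()


@pytest.fixture(scope="session")
def by_index(records):
    return {r.index: r for r in records}
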