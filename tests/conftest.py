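from __future__ import annotations

import pytest

from icuqi.catalog import load_default_catalog
from icuqi.terminology import Registry


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def registry(catalog):
    return Registry.from_catalog(catalog)
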