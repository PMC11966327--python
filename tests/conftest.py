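import warnings

import pytest

from aki_cea import ModelBundle, load_model


@pytest.fixture(scope="session")
def bundle() -> ModelBundle:
    """Canonical model inputs (30-day rows already renormalized)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_model()


@pytest.fixture(scope="session")
def bundle_dict(bundle) -> dict:
    """JSON-mode dump of the canonical bundle, for building variants."""
    return bundle.model_dump(mode="json")
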