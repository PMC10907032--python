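import pytest

from cardiopes import variants


@pytest.fixture(scope="session")
def registry():
    """Process-wide variant registry: calibrations run once per session."""
    return variants.VariantRegistry()


@pytest.fixture(scope="session")
def control(registry):
    return registry.get("control")
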