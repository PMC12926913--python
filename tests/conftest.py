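import pytest

from polcensus import homology
from polcensus.registry import load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def profiles(registry):
    return homology.build_profiles(registry)


@pytest.fixture(scope="session")
def domain_profiles(registry, profiles):
    """Domain profiles only (profile-mode motifs excluded), as used by the
    architecture scan."""
    return [p for name, p in profiles.items() if name in registry.domains]
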