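import pytest

from rankrecovery.pipeline import analyze_case
from rankrecovery.simulate import make_case


@pytest.fixture(scope="session")
def tiny_bundle():
    """One deterministic tiny study shared across the suite."""
    return make_case(seed=1)


@pytest.fixture(scope="session")
def tiny_result(tiny_bundle):
    """Full analysis of the tiny study's region-mode foreground."""
    return analyze_case(tiny_bundle, seed=1)
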