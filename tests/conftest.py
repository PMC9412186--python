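import pytest

from crcscreen import base_case_parameter_set
from crcscreen.synthetic import GeneratorConfig, generate_parameter_set


@pytest.fixture(scope="session")
def base_params():
    return base_case_parameter_set()


@pytest.fixture()
def params(base_params):
    """A mutable copy of the packaged base case."""
    return base_params.copy()


@pytest.fixture(scope="session")
def synth_params():
    return generate_parameter_set(GeneratorConfig(seed=11))


def all_point(ps):
    """Collapse every uncertainty spec to a point at the current value."""
    from crcscreen.parameters import DistributionSpec

    out = ps.copy()
    for path, p in out.iter_uncertain():
        p.spec = DistributionSpec("point", p.value, p.value, p.value)
    return out
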