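import pytest

from ctdna_cea.parameters import ParameterSet
from ctdna_cea.synthetic import SyntheticProfile, generate_parameter_set


def strip_uncertainty(ps: ParameterSet) -> ParameterSet:
    """All distributions collapsed to their point estimates (degenerate PSA)."""
    d = ps.model_dump()

    def fix(node):
        if isinstance(node, dict):
            if node.get("kind") in ("beta", "gamma"):
                node["kind"] = "fixed"
                node["se"] = 0.0
            if "median_se" in node:
                node["median_se"] = 0.0
            for v in node.values():
                fix(v)
        elif isinstance(node, list):
            for v in node:
                fix(v)

    fix(d)
    return ParameterSet.model_validate(d)


@pytest.fixture(scope="session")
def base_ps() -> ParameterSet:
    return generate_parameter_set(SyntheticProfile("base_like"))


@pytest.fixture(scope="session")
def fixed_ps(base_ps) -> ParameterSet:
    return strip_uncertainty(base_ps)


@pytest.fixture(scope="session")
def null_ps() -> ParameterSet:
    return generate_parameter_set(SyntheticProfile("null_effect", seed=7))


@pytest.fixture(scope="session")
def strong_ps() -> ParameterSet:
    return generate_parameter_set(SyntheticProfile("strong_effect", seed=11))
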