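import pytest

from leaffba.synthetic import (
    build_core_leaf_model,
    build_fixture_network,
    core_constraints,
    fixture_constraints,
)


@pytest.fixture(scope="session")
def core_model():
    model, manifest = build_core_leaf_model()
    return model, manifest


@pytest.fixture(scope="session")
def core_model_constraints(core_model):
    model, _ = core_model
    return core_constraints(model=model)


@pytest.fixture()
def chain3():
    model, manifest = build_fixture_network("chain", n=3, demand=1.0)
    return model, manifest, fixture_constraints(manifest)


@pytest.fixture()
def diamond():
    model, manifest = build_fixture_network("diamond", demand=1.0)
    return model, manifest, fixture_constraints(manifest)


@pytest.fixture()
def equal_parallel():
    model, manifest = build_fixture_network("equal_parallel", demand=1.0)
    return model, manifest, fixture_constraints(manifest)
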