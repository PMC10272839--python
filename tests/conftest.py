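import numpy as np
import pytest

from nfkbfp.core_model import CoreModelConfig, build_nfkb_model
from nfkbfp.network import CompiledModel, ModelSpec, Parameter, Reaction, Species


@pytest.fixture(scope="session")
def core_spec() -> ModelSpec:
    return build_nfkb_model()


@pytest.fixture(scope="session")
def core_model(core_spec) -> CompiledModel:
    return CompiledModel(core_spec)


@pytest.fixture(scope="session")
def core_steady(core_model):
    from nfkbfp.network import run_to_steady_state

    res = run_to_steady_state(core_model)
    assert res.converged
    # reset compiled parameters in case a test mutated them
    core_model.set_parameters(core_model.spec.parameter_values())
    return res.state


def make_birth_death(k_s=2.0, k_d=0.5, a0=0.0) -> ModelSpec:
    """Birth-death toy: 0 -> A at k_s (nM/h), A -> 0 at k_d (/h)."""
    return ModelSpec(
        (Species("A", "cytoplasm", a0),),
        (Parameter("k_s", k_s, "expression"), Parameter("k_d", k_d, "degradation")),
        (
            Reaction("syn", {}, {"A": 1}, "constant_source", ("k_s",)),
            Reaction("deg", {"A": 1}, {}, "mass_action", ("k_d",)),
        ),
    )


def make_binding(k_on=2.0, k_off=0.5, a0=5.0, b0=3.0) -> ModelSpec:
    """Reversible heterodimerisation toy: A + B <-> AB."""
    return ModelSpec(
        (
            Species("A", "cytoplasm", a0),
            Species("B", "cytoplasm", b0),
            Species("AB", "cytoplasm", 0.0),
        ),
        (Parameter("k_on", k_on, "binding"), Parameter("k_off", k_off, "binding")),
        (
            Reaction("on", {"A": 1, "B": 1}, {"AB": 1}, "mass_action", ("k_on",)),
            Reaction("off", {"AB": 1}, {"A": 1, "B": 1}, "mass_action", ("k_off",)),
        ),
    )


@pytest.fixture()
def birth_death():
    return make_birth_death()


@pytest.fixture()
def binding_model():
    return make_binding()
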