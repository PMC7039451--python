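import pytest

from chloromod import (
    GPRRule,
    OrganelleModule,
    build_calvin_mini_model,
    build_photosynthesis_module,
    build_toy_exo_model,
)
from chloromod.modes import register_mode


@pytest.fixture
def mini_model():
    """Photosynthesis + Calvin-Benson mini-model (fresh copy per test)."""
    return build_calvin_mini_model()


@pytest.fixture
def etc_module():
    return build_photosynthesis_module()


@pytest.fixture
def toy_exo():
    return build_toy_exo_model()


@pytest.fixture
def three_mode_model():
    """Tiny tagged model whose three organism modes grow at distinct rates.

    An untagged precursor source feeds organism-specific conversion
    reactions of different yield, each paired with a registered biomass.
    """
    m = OrganelleModule(id="three_mode", compartments={"h": "stroma"})
    m.new_metabolite("p_h", compartment="h")
    m.new_metabolite("b_h", compartment="h")
    m.new_reaction("p_source", {"p_h": +1}, lower_bound=0.0, upper_bound=10.0)
    for org, yield_ in (("Nan", 1.0), ("Chl", 0.9), ("Pha", 1.5)):
        m.new_reaction(
            f"@{org}_conv_h",
            {"p_h": -1.0, "b_h": +yield_},
            lower_bound=0.0,
            gpr=GPRRule.from_string(f"conv{org}"),
        )
        m.new_reaction(f"@{org}_biomass_h", {"b_h": -1.0}, lower_bound=0.0)
        register_mode(m, org, f"@{org}_biomass_h")
    return m
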