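"""Photosynthesis/Calvin-Benson fixture builders: reaction inventory,
per-complex net sums, electron/proton balance, biomass composition."""

import pytest

from chloromod import (
    BiomassSpec,
    ETCSpec,
    build_calvin_mini_model,
    build_photosynthesis_module,
    compose_biomass,
    flux_at_objective_optimum,
    optimize,
)
from chloromod.builders import (
    B6F_NET_MULTIPLIERS,
    BIOMASS_COEFFICIENTS,
    FNR_NET_MULTIPLIERS,
    PHOTOSYNTHESIS_SUBSYSTEM,
    PSI_NET_MULTIPLIERS,
    PSII_NET_MULTIPLIERS,
)
from chloromod.explore import subsystem_summary
from chloromod.modes import set_mode

TRIOSE_OPT = 125.0 / 3.0


# -- inventory --------------------------------------------------------------


def test_photosynthesis_subsystem_has_33_reactions(etc_module):
    counts = subsystem_summary(etc_module)
    assert counts[PHOTOSYNTHESIS_SUBSYSTEM] == 33
    assert counts["PSII"] == 10
    assert counts["cytochrome b6f"] == 7
    assert counts["PSI"] == 8
    assert counts["FNR"] == 3
    assert counts["ATP synthase"] == 1
    assert counts["PQ transport"] == 2
    assert counts["cyclic electron transport"] == 1
    # photon import is an exchange, outside the photosynthetic count
    assert "photosynthesis" not in [
        s for s in etc_module.get_reaction("photon_import").subsystems
    ]


def test_photon_cap_and_cyclic_defaults(etc_module):
    assert etc_module.get_reaction("photon_import").upper_bound == 1000.0
    assert etc_module.get_reaction("cyclic_electron_transport").bounds == (0.0, 0.0)


def test_etc_module_validates(etc_module):
    assert etc_module.validate().passed


# -- per-complex net sums ---------------------------------------------------


def _net(model, multipliers):
    net = {}
    for rid, k in multipliers.items():
        for mid, coeff in model.get_reaction(rid).stoichiometry.items():
            net[mid] = net.get(mid, 0.0) + k * coeff
    return {mid: c for mid, c in net.items() if abs(c) > 1e-12}


def test_psii_net_sum(etc_module):
    """Per 4 photons: 2 H2O + 2 PQ + 4 H+(stroma) -> O2 + 4 H+(lumen) + 2 PQH2."""
    assert _net(etc_module, PSII_NET_MULTIPLIERS) == {
        "h2o_h": -2, "photon_psii_h": -4, "pq_a_h": -2, "h_h": -4,
        "o2_h": +1, "h_u": +4, "pqh2_a_h": +2,
    }


def test_b6f_net_sum(etc_module):
    """Q cycle, per PQH2: PQH2 + 2 PC_ox + 2 H+(stroma) -> PQ + 2 PC_red + 4 H+(lumen)."""
    assert _net(etc_module, B6F_NET_MULTIPLIERS) == {
        "pqh2_b_h": -1, "pc_ox_u": -2, "h_h": -2,
        "pq_b_h": +1, "pc_red_u": +2, "h_u": +4,
    }


def test_psi_net_sum(etc_module):
    assert _net(etc_module, PSI_NET_MULTIPLIERS) == {
        "photon_h": -1, "pc_red_u": -1, "fd_ox_h": -1,
        "pc_ox_u": +1, "fd_red_h": +1,
    }


def test_fnr_net_sum(etc_module):
    assert _net(etc_module, FNR_NET_MULTIPLIERS) == {
        "fd_red_h": -2, "nadp_h": -1, "h_h": -1,
        "fd_ox_h": +2, "nadph_h": +1,
    }


def test_linear_flow_atp_nadph_ratio():
    """Per 4 electrons: 12 lumen protons -> 3 ATP and 2 NADPH (ratio 1.5)."""
    spec = ETCSpec()
    assert spec.lumen_protons_per_4_electrons == 12
    assert spec.lumen_protons_per_4_electrons / spec.h_per_atp == 3.0
    m = build_calvin_mini_model(spec)
    atp = flux_at_objective_optimum(m, None, "ATP_synthase", "max")
    nadph = flux_at_objective_optimum(m, None, "FNR_3_nadph_formation", "max")
    assert atp / nadph == pytest.approx(1.5, rel=1e-5)


def test_balance_audit_every_etc_reaction_conserves_H_O_charge(etc_module):
    """Automated electron/proton balance audit over the carrier bookkeeping:
    summing (H, O, charge) with stoichiometric weights gives zero for every
    reaction of the chain (photons carry neither mass nor charge)."""
    table = etc_module._etc_balance_table
    for rxn in etc_module.reactions:
        totals = [0.0, 0.0, 0.0]
        for mid, coeff in rxn.stoichiometry.items():
            vec = table[mid]
            for k in range(3):
                totals[k] += coeff * vec[k]
        assert all(abs(t) < 1e-9 for t in totals), (rxn.id, totals)


# -- configurable chain length ---------------------------------------------


def test_step_counts_below_minimum_are_rejected():
    with pytest.raises(ValueError, match="at least"):
        build_photosynthesis_module(ETCSpec(psii_steps=5))


def test_extra_relay_steps_keep_the_optimum():
    spec = ETCSpec(psii_steps=12, b6f_steps=8, psi_steps=10, fnr_steps=4)
    m = build_calvin_mini_model(spec)
    counts = subsystem_summary(m)
    assert counts["PSII"] == 12
    assert counts["cytochrome b6f"] == 8
    assert counts["PSI"] == 10
    assert counts["FNR"] == 4
    assert optimize(m).objective_value == pytest.approx(TRIOSE_OPT, rel=1e-6)


# -- mini-model energetics --------------------------------------------------


def test_mini_model_has_no_cofactor_transport(mini_model):
    """ATP, ADP, Pi, NADPH and NADP+ are strictly internal."""
    internal = {"atp_h", "adp_h", "pi_h", "nadph_h", "nadp_h"}
    for rxn in mini_model.reactions:
        if rxn.is_border or rxn.id == "photon_import":
            assert not internal & set(rxn.stoichiometry), rxn.id
        touched = internal & set(rxn.stoichiometry)
        if touched:
            comps = {
                mini_model.get_metabolite(mid).compartment
                for mid in rxn.stoichiometry
            }
            assert comps <= {"h", "u"} or rxn.id == "TPT_triose_phosphate_translocator"


def test_mini_model_flux_ratios(mini_model):
    sol = optimize(mini_model)
    triose = sol.objective_value
    assert triose == pytest.approx(TRIOSE_OPT, rel=1e-9)
    atp = flux_at_objective_optimum(mini_model, None, "ATP_synthase", "max")
    nadph = flux_at_objective_optimum(mini_model, None, "FNR_3_nadph_formation", "max")
    assert atp / triose == pytest.approx(9.0, rel=1e-6)
    assert nadph / triose == pytest.approx(6.0, rel=1e-6)


def test_cyclic_stays_zero_when_relaxed(mini_model):
    mini_model.get_reaction("cyclic_electron_transport").bounds = (0.0, 1000.0)
    assert optimize(mini_model).objective_value == pytest.approx(TRIOSE_OPT, rel=1e-9)
    cyc = flux_at_objective_optimum(mini_model, None, "cyclic_electron_transport", "max")
    assert cyc == pytest.approx(0.0, abs=1e-4)


def test_photon_cap_doubling_doubles_the_optimum():
    """LP homogeneity: the triose optimum scales linearly with the cap."""
    base = optimize(build_calvin_mini_model(ETCSpec(photon_cap=1000.0))).objective_value
    double = optimize(build_calvin_mini_model(ETCSpec(photon_cap=2000.0))).objective_value
    assert double == pytest.approx(2.0 * base, rel=1e-9)


def test_triose_yield_is_monotone_in_atp_cost():
    """Sanity sweep over the H+/ATP ratio with cyclic transport available:
    4 H+/ATP matches the Calvin-Benson demand exactly; a costlier ATP
    (14/3) needs cyclic flow and yields less triose; a cheaper ATP (3)
    over-produces ATP that has no sink, collapsing the optimum."""
    def opt(h):
        m = build_calvin_mini_model(ETCSpec(h_per_atp=h, cyclic_bounds=(0.0, 1000.0)))
        return optimize(m).objective_value

    assert opt(4.0) == pytest.approx(TRIOSE_OPT, rel=1e-9)
    assert opt(14.0 / 3.0) < TRIOSE_OPT - 1.0
    assert opt(14.0 / 3.0) > 0.0
    assert opt(3.0) == pytest.approx(0.0, abs=1e-6)


# -- biomass composition ----------------------------------------------------


def test_biomass_reaction_coefficients():
    """10 ATP + 5 H2O + 5 NADPH + 5 H+ + 2.5 O2 + CPr + CML + CPi ->
    10 ADP + 10 Pi + 5 NADP+."""
    reactions = compose_biomass(BiomassSpec.default_for("Nan"), "Nan")
    biomass = reactions[-1]
    assert biomass.is_biomass and biomass.biomass_organism == "Nan"
    st = biomass.stoichiometry
    assert st["atp_h"] == -10 and st["h2o_h"] == -5 and st["nadph_h"] == -5
    assert st["h_h"] == -5 and st["o2_h"] == -2.5
    assert st["adp_h"] == +10 and st["pi_h"] == +10 and st["nadp_h"] == +5
    assert st["cpr_nan_h"] == -1 and st["cml_nan_h"] == -1 and st["cpi_nan_h"] == -1
    assert set(BIOMASS_COEFFICIENTS) == {
        "atp_h", "h2o_h", "nadph_h", "h_h", "o2_h", "cpr", "cml", "cpi",
        "adp_h", "pi_h", "nadp_h",
    }


def test_single_pigment_cpi_assembly():
    spec = BiomassSpec.default_for("Pha")
    assert spec.pigment_fractions == {"chla": 1.0}
    reactions = compose_biomass(spec, "Pha")
    cpi = next(r for r in reactions if "CPi" in r.id)
    assert cpi.stoichiometry == {"chla_h": -1.0, "cpi_pha_h": +1.0}


def test_cml_assembly_normalization():
    spec = BiomassSpec(
        amino_acid_fractions={"leu": 1.0},
        lipid_class_fractions={"mgdg": 0.5, "dgdg": 0.3, "sqdg": 0.2},
        pigment_fractions={"chla": 1.0},
    )
    reactions = compose_biomass(spec, "Nan")
    cml = next(r for r in reactions if "CML" in r.id)
    assert cml.stoichiometry == {
        "mgdg_h": -0.5, "dgdg_h": -0.3, "sqdg_h": -0.2, "cml_nan_h": +1.0,
    }


def test_fraction_tables_must_sum_to_one():
    spec = BiomassSpec(
        amino_acid_fractions={"leu": 0.7},
        lipid_class_fractions={"mgdg": 1.0},
        pigment_fractions={"chla": 1.0},
    )
    with pytest.raises(ValueError, match="sum"):
        compose_biomass(spec, "Nan")
    with pytest.raises(ValueError, match="negative"):
        BiomassSpec(pigment_fractions={"chla": 1.5, "chlb": -0.5}).validate()


def test_compose_biomass_registers_mode(mini_model):
    compose_biomass(BiomassSpec.default_for("Nan"), "Nan", model=mini_model)
    assert "Nan" in mini_model.mode_registry
    biomass_id = mini_model.mode_registry["Nan"].biomass_id
    assert mini_model.get_reaction(biomass_id).organism_tags == frozenset({"Nan"})
    assert mini_model.validate().passed
    set_mode(mini_model, "Nan")
    assert mini_model.objective_id == biomass_id


def test_default_fraction_tables_validate():
    for org in ("Nan", "Chl", "Pha"):
        BiomassSpec.default_for(org).validate()


# -- toy exo-model ----------------------------------------------------------


def test_toy_exo_is_infeasible_alone_but_kegg_ready(toy_exo):
    assert len(toy_exo.reactions) <= 15
    assert optimize(toy_exo).objective_value == pytest.approx(0.0, abs=1e-9)
    annotated = [m for m in toy_exo.metabolites if m.kegg_id]
    assert len(annotated) >= 5
    assert toy_exo.validate().passed
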