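"""Fixture builders: fine-grained photosynthesis, the Calvin-Benson
mini-model, organism biomass composition, and a toy cytosolic exo-model.

The photosynthetic electron transport chain is modelled one electron
transfer at a time instead of one reaction per complex: 10 transfers inside
PSII, 7 inside the cytochrome b6f complex, 8 inside PSI and 3 at FNR, plus
ATP synthase, two plastoquinone/plastoquinol shuttle reactions between PSII
and b6f, one cyclic-electron-transport reaction (closed by default), and a
photon-partitioning reaction feeding PSII -- 33 reactions in the
photosynthesis subsystem, fed by a general photon import capped at
1000 mmol gDW-1 h-1.

Proton bookkeeping uses a full Q cycle (2 lumen protons per electron at
b6f) plus 1 lumen proton per electron from water oxidation, and an ATP
synthase translocating 4 H+ per ATP.  Per 4 electrons of linear flow this
yields 12 lumen protons -> 3 ATP and 2 NADPH, i.e. ATP:NADPH = 3:2 --
exactly the 9:6 demand of the Calvin-Benson cycle, which is why the
mini-model needs no cyclic electron transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .gpr import GPRRule
from .model import Metabolite, OrganelleModule, Reaction, assemble_reaction_id
from .modes import register_mode

__all__ = [
    "ETCSpec",
    "BiomassSpec",
    "build_photosynthesis_module",
    "build_calvin_mini_model",
    "compose_biomass",
    "build_toy_exo_model",
    "etc_species_balance_table",
    "PHOTOSYNTHESIS_SUBSYSTEM",
    "PSII_NET_MULTIPLIERS",
    "B6F_NET_MULTIPLIERS",
    "PSI_NET_MULTIPLIERS",
    "FNR_NET_MULTIPLIERS",
]

PHOTOSYNTHESIS_SUBSYSTEM = "photosynthesis"

# canonical per-complex chain lengths
_MIN_STEPS = {"psii": 10, "b6f": 7, "psi": 8, "fnr": 3}


@dataclass
class ETCSpec:
    """Tunable stoichiometry of the electron transport chain.

    ``h_per_atp`` protons are translocated from the thylakoid lumen back to
    the stroma per ATP synthesized.  ``qcycle_protons_per_electron`` (full Q
    cycle: 2) and ``water_protons_per_electron`` (1) fix the lumen-proton
    yield: 4 * (2 + 1) = 12 per 4 electrons of linear flow.  The photon
    import cap is the paper-scale 1000 mmol gDW-1 h-1; cyclic electron
    transport is closed, (0, 0), by default.
    """

    psii_steps: int = 10
    b6f_steps: int = 7
    psi_steps: int = 8
    fnr_steps: int = 3
    h_per_atp: float = 4.0
    qcycle_protons_per_electron: int = 2
    water_protons_per_electron: int = 1
    photon_cap: float = 1000.0
    cyclic_bounds: tuple = (0.0, 0.0)

    def validate(self) -> None:
        for key, minimum in _MIN_STEPS.items():
            steps = getattr(self, f"{key}_steps")
            if steps < minimum:
                raise ValueError(
                    f"{key} needs at least {minimum} electron-transfer steps "
                    f"(requested {steps}): the carrier chain cannot be shorter"
                )
        if self.h_per_atp <= 0:
            raise ValueError("h_per_atp must be positive")
        if self.photon_cap < 0:
            raise ValueError("photon_cap must be non-negative")

    @property
    def lumen_protons_per_4_electrons(self) -> int:
        return 4 * (self.water_protons_per_electron + self.qcycle_protons_per_electron)


# Net-sum multipliers: scaling each step's flux by its multiplier and summing
# cancels every internal carrier, leaving the per-complex net reaction.
# (Per 4 electrons for PSII; per PQH2 for b6f; per electron for PSI;
# per NADPH for FNR.)
PSII_NET_MULTIPLIERS = {
    "PSII_1_antenna_excitation": 4,
    "PSII_2_energy_transfer": 4,
    "PSII_3_charge_separation": 4,
    "PSII_4_p680_rereduction": 4,
    "PSII_5_water_oxidation": 1,
    "PSII_6_qa_reduction": 4,
    "PSII_7_qb_first_reduction": 2,
    "PSII_8_qb_second_reduction": 2,
    "PSII_9_qb_protonation": 2,
    "PSII_10_pq_exchange": 2,
}
B6F_NET_MULTIPLIERS = {
    "B6F_1_qo_oxidation": 2,
    "B6F_2_isp_to_cytf": 2,
    "B6F_3_cytf_to_pc": 2,
    "B6F_4_bl_to_bh": 2,
    "B6F_5_qi_first_reduction": 1,
    "B6F_6_qi_second_reduction": 1,
    "B6F_7_qi_exchange": 1,
}
PSI_NET_MULTIPLIERS = {
    "PSI_1_p700_excitation": 1,
    "PSI_2_charge_separation": 1,
    "PSI_3_pc_oxidation": 1,
    "PSI_4_a0_to_a1": 1,
    "PSI_5_a1_to_fx": 1,
    "PSI_6_fx_to_fa": 1,
    "PSI_7_fa_to_fb": 1,
    "PSI_8_fd_reduction": 1,
}
FNR_NET_MULTIPLIERS = {
    "FNR_1_first_electron": 1,
    "FNR_2_second_electron": 1,
    "FNR_3_nadph_formation": 1,
}

# (H atoms, O atoms, charge) relative bookkeeping per ETC species, used by
# the balance audit.  Redox states differ by whole electrons (charge) and
# protonation states by (H, charge); photons carry nothing.
_ETC_SPECIES_BALANCE = {
    "photon_h": (0, 0, 0),
    "photon_psii_h": (0, 0, 0),
    "h_h": (1, 0, +1),
    "h_u": (1, 0, +1),
    "h2o_h": (2, 1, 0),
    "o2_h": (0, 2, 0),
    "nadp_h": (0, 0, +1),
    "nadph_h": (1, 0, 0),
    "adp_h": (0, 0, 0),
    "pi_h": (0, 0, 0),
    "atp_h": (-2, -1, 0),  # ADP + Pi -> ATP + H2O condensation reference
    # PSII
    "psii_ant_h": (0, 0, 0),
    "psii_antx_h": (0, 0, 0),
    "p680_h": (0, 0, 0),
    "p680x_h": (0, 0, 0),
    "p680p_h": (0, 0, +1),
    "pheo_h": (0, 0, 0),
    "pheo_r_h": (0, 0, -1),
    "yz_h": (0, 0, 0),
    "yz_ox_h": (0, 0, +1),
    "qa_h": (0, 0, 0),
    "qa_r_h": (0, 0, -1),
    "qb_h": (0, 0, 0),
    "qb_r_h": (0, 0, -1),
    "qb_rr_h": (0, 0, -2),
    "qbh2_h": (2, 0, 0),
    "pq_a_h": (0, 0, 0),
    "pqh2_a_h": (2, 0, 0),
    "pq_b_h": (0, 0, 0),
    "pqh2_b_h": (2, 0, 0),
    # b6f
    "isp_h": (0, 0, 0),
    "isp_r_h": (0, 0, -1),
    "cytf_h": (0, 0, 0),
    "cytf_r_h": (0, 0, -1),
    "bl_h": (0, 0, 0),
    "bl_r_h": (0, 0, -1),
    "bh_h": (0, 0, 0),
    "bh_r_h": (0, 0, -1),
    "qi_pq_h": (0, 0, 0),
    "qi_sq_h": (0, 0, -1),
    "qi_pqh2_h": (2, 0, 0),
    # PSI
    "p700_h": (0, 0, 0),
    "p700x_h": (0, 0, 0),
    "p700p_h": (0, 0, +1),
    "a0_h": (0, 0, 0),
    "a0_r_h": (0, 0, -1),
    "a1_h": (0, 0, 0),
    "a1_r_h": (0, 0, -1),
    "fx_h": (0, 0, 0),
    "fx_r_h": (0, 0, -1),
    "fa_h": (0, 0, 0),
    "fa_r_h": (0, 0, -1),
    "fb_h": (0, 0, 0),
    "fb_r_h": (0, 0, -1),
    "pc_ox_u": (0, 0, +1),
    "pc_red_u": (0, 0, 0),
    "fd_ox_h": (0, 0, 0),
    "fd_red_h": (0, 0, -1),
    # FNR
    "fnr_h": (0, 0, 0),
    "fnr_sq_h": (0, 0, -1),
    "fnr_red_h": (0, 0, -2),
}


def etc_species_balance_table() -> dict:
    """(H, O, charge) bookkeeping per ETC species, including relay carriers.

    Relays inserted for step counts above the canonical 10/7/8/3 are single
    one-electron carriers: oxidized (0,0,0), reduced (0,0,-1)."""
    return dict(_ETC_SPECIES_BALANCE)


_ETC_METABOLITES = [
    # (id, name, compartment, kegg)
    ("photon_h", "photon", "h", None),
    ("photon_psii_h", "photon partitioned to PSII", "h", None),
    ("h_h", "H+ (stroma)", "h", "C00080"),
    ("h_u", "H+ (thylakoid lumen)", "u", "C00080"),
    ("h2o_h", "H2O", "h", "C00001"),
    ("o2_h", "O2", "h", "C00007"),
    ("nadp_h", "NADP+", "h", "C00006"),
    ("nadph_h", "NADPH", "h", "C00005"),
    ("adp_h", "ADP", "h", "C00008"),
    ("atp_h", "ATP", "h", "C00002"),
    ("pi_h", "orthophosphate", "h", "C00009"),
    ("psii_ant_h", "PSII antenna (ground)", "h", None),
    ("psii_antx_h", "PSII antenna (excited)", "h", None),
    ("p680_h", "P680", "h", None),
    ("p680x_h", "P680*", "h", None),
    ("p680p_h", "P680+", "h", None),
    ("pheo_h", "pheophytin", "h", None),
    ("pheo_r_h", "pheophytin-", "h", None),
    ("yz_h", "tyrosine Z", "h", None),
    ("yz_ox_h", "tyrosine Z (oxidized)", "h", None),
    ("qa_h", "QA", "h", None),
    ("qa_r_h", "QA-", "h", None),
    ("qb_h", "QB", "h", None),
    ("qb_r_h", "QB-", "h", None),
    ("qb_rr_h", "QB2-", "h", None),
    ("qbh2_h", "QBH2", "h", None),
    ("pq_a_h", "plastoquinone (PSII side)", "h", None),
    ("pqh2_a_h", "plastoquinol (PSII side)", "h", None),
    ("pq_b_h", "plastoquinone (b6f side)", "h", None),
    ("pqh2_b_h", "plastoquinol (b6f side)", "h", None),
    ("isp_h", "Rieske ISP", "h", None),
    ("isp_r_h", "Rieske ISP (reduced)", "h", None),
    ("cytf_h", "cytochrome f", "h", None),
    ("cytf_r_h", "cytochrome f (reduced)", "h", None),
    ("bl_h", "cytochrome bL", "h", None),
    ("bl_r_h", "cytochrome bL (reduced)", "h", None),
    ("bh_h", "cytochrome bH", "h", None),
    ("bh_r_h", "cytochrome bH (reduced)", "h", None),
    ("qi_pq_h", "Qi-site plastoquinone", "h", None),
    ("qi_sq_h", "Qi-site semiquinone", "h", None),
    ("qi_pqh2_h", "Qi-site plastoquinol", "h", None),
    ("p700_h", "P700", "h", None),
    ("p700x_h", "P700*", "h", None),
    ("p700p_h", "P700+", "h", None),
    ("a0_h", "A0", "h", None),
    ("a0_r_h", "A0-", "h", None),
    ("a1_h", "A1 (phylloquinone)", "h", None),
    ("a1_r_h", "A1-", "h", None),
    ("fx_h", "FX", "h", None),
    ("fx_r_h", "FX (reduced)", "h", None),
    ("fa_h", "FA", "h", None),
    ("fa_r_h", "FA (reduced)", "h", None),
    ("fb_h", "FB", "h", None),
    ("fb_r_h", "FB (reduced)", "h", None),
    ("pc_ox_u", "plastocyanin (oxidized)", "u", None),
    ("pc_red_u", "plastocyanin (reduced)", "u", None),
    ("fd_ox_h", "ferredoxin (oxidized)", "h", None),
    ("fd_red_h", "ferredoxin (reduced)", "h", None),
    ("fnr_h", "FNR", "h", None),
    ("fnr_sq_h", "FNR semiquinone", "h", None),
    ("fnr_red_h", "FNR (reduced)", "h", None),
]

_PSII_GPR = "psbA and psbB and psbC and psbD"
_B6F_GPR = "petA and petB and petC and petD"
_PSI_GPR = "psaA and psaB and psaC"
_FNR_GPR = "petH"
_ATPASE_GPR = "atpA and atpB and atpE and atpF and atpH"


def _relay_chain(prefix, complex_name, donor_red, donor_ox, acceptor_ox,
                 acceptor_red, n_extra, gpr, balance):
    """Replace the 1-electron hop donor_red + acceptor_ox -> donor_ox +
    acceptor_red by a chain through n_extra relay carriers, returning the
    (metabolites, reactions) to add.  Each relay adds one reaction."""
    mets = []
    rxns = []
    chain = []
    for k in range(1, n_extra + 1):
        ox = f"{prefix}relay{k}_h"
        red = f"{prefix}relay{k}_r_h"
        mets.append(Metabolite(ox, name=f"{complex_name} relay carrier {k}", compartment="h"))
        mets.append(Metabolite(red, name=f"{complex_name} relay carrier {k} (reduced)", compartment="h"))
        balance[ox] = (0, 0, 0)
        balance[red] = (0, 0, -1)
        chain.append((ox, red))
    hops = [(donor_red, donor_ox)] + [(red, ox) for ox, red in chain]
    targets = [(ox, red) for ox, red in chain] + [(acceptor_ox, acceptor_red)]
    for k, ((d_red, d_ox), (a_ox, a_red)) in enumerate(zip(hops, targets), start=1):
        rxns.append(
            Reaction(
                id=f"{prefix}relay_hop_{k}" if n_extra else f"{prefix}hop",
                name=f"{complex_name} electron relay hop {k}",
                stoichiometry={d_red: -1, a_ox: -1, d_ox: +1, a_red: +1},
                lower_bound=0.0,
                gpr=GPRRule.from_string(gpr),
                subsystems=[PHOTOSYNTHESIS_SUBSYSTEM, complex_name],
            )
        )
    return mets, rxns


def build_photosynthesis_module(spec: Optional[ETCSpec] = None) -> OrganelleModule:
    """Build the fine-grained photosynthetic electron transport chain.

    Per-complex net sums (guaranteed by construction, with the flux
    multipliers in ``*_NET_MULTIPLIERS``):

    * PSII, per 4 photons: ``2 H2O + 4 photon_PSII + 2 PQ + 4 H+_stroma ->
      O2 + 4 H+_lumen + 2 PQH2``
    * b6f, per PQH2 (Q cycle): ``PQH2 + 2 PC_ox + 2 H+_stroma ->
      PQ + 2 PC_red + 4 H+_lumen``
    * PSI, per photon: ``photon + PC_red + Fd_ox -> PC_ox + Fd_red``
    * FNR, per NADPH: ``2 Fd_red + NADP+ + H+ -> 2 Fd_ox + NADPH``

    plus ATP synthase (``h_per_atp`` lumen protons + ADP + Pi -> ATP + H2O,
    protons returned to the stroma), two PQ/PQH2 shuttle reactions, cyclic
    electron transport (2 Fd_red + PQ + 2 H+_stroma -> 2 Fd_ox + PQH2;
    closed by default), the PSII photon-partition reaction, and the general
    photon import (capped at ``photon_cap``).
    """
    spec = spec or ETCSpec()
    spec.validate()
    model = OrganelleModule(id="photosynthesis_module", name="photosynthetic ETC")
    balance = dict(_ETC_SPECIES_BALANCE)
    for mid, name, comp, kegg in _ETC_METABOLITES:
        model.new_metabolite(mid, name=name, compartment=comp, kegg_id=kegg)

    def rx(id, stoich, name="", gpr="", subsystems=None, lb=0.0, ub=1000.0):
        model.new_reaction(
            id,
            stoich,
            name=name,
            lower_bound=lb,
            upper_bound=ub,
            gpr=GPRRule.from_string(gpr),
            subsystems=list(subsystems or [PHOTOSYNTHESIS_SUBSYSTEM]),
        )

    # photon supply: general import (exchange) + partition to PSII
    rx(
        "photon_import",
        {"photon_h": +1},
        name="general photon import",
        subsystems=["photon exchange"],
        lb=0.0,
        ub=spec.photon_cap,
    )
    rx(
        "PSII_photon",
        {"photon_h": -1, "photon_psii_h": +1},
        name="photon partitioning to PSII",
        ub=max(1000.0, spec.photon_cap),
    )

    wp = spec.water_protons_per_electron
    # PSII: 10 electron transfers
    psii = [
        ("PSII_1_antenna_excitation", {"photon_psii_h": -1, "psii_ant_h": -1, "psii_antx_h": +1}),
        ("PSII_2_energy_transfer", {"psii_antx_h": -1, "p680_h": -1, "psii_ant_h": +1, "p680x_h": +1}),
        ("PSII_3_charge_separation", {"p680x_h": -1, "pheo_h": -1, "p680p_h": +1, "pheo_r_h": +1}),
        ("PSII_4_p680_rereduction", {"p680p_h": -1, "yz_h": -1, "p680_h": +1, "yz_ox_h": +1}),
        (
            "PSII_5_water_oxidation",
            {"h2o_h": -2, "yz_ox_h": -4, "o2_h": +1, "h_u": +4 * wp, "yz_h": +4},
        ),
        ("PSII_6_qa_reduction", {"pheo_r_h": -1, "qa_h": -1, "pheo_h": +1, "qa_r_h": +1}),
        ("PSII_7_qb_first_reduction", {"qa_r_h": -1, "qb_h": -1, "qa_h": +1, "qb_r_h": +1}),
        ("PSII_8_qb_second_reduction", {"qa_r_h": -1, "qb_r_h": -1, "qa_h": +1, "qb_rr_h": +1}),
        ("PSII_9_qb_protonation", {"qb_rr_h": -1, "h_h": -2, "qbh2_h": +1}),
        ("PSII_10_pq_exchange", {"qbh2_h": -1, "pq_a_h": -1, "qb_h": +1, "pqh2_a_h": +1}),
    ]
    for rid, st in psii:
        rx(rid, st, gpr=_PSII_GPR, subsystems=[PHOTOSYNTHESIS_SUBSYSTEM, "PSII"])

    # plastoquinone shuttle between PSII and b6f
    rx("PQ_transport_pqh2", {"pqh2_a_h": -1, "pqh2_b_h": +1},
       name="plastoquinol shuttle PSII->b6f",
       subsystems=[PHOTOSYNTHESIS_SUBSYSTEM, "PQ transport"])
    rx("PQ_transport_pq", {"pq_b_h": -1, "pq_a_h": +1},
       name="plastoquinone shuttle b6f->PSII",
       subsystems=[PHOTOSYNTHESIS_SUBSYSTEM, "PQ transport"])

    qp = spec.qcycle_protons_per_electron
    # cytochrome b6f: 7 electron transfers with Q cycle
    b6f = [
        (
            "B6F_1_qo_oxidation",
            {"pqh2_b_h": -1, "isp_h": -1, "bl_h": -1,
             "pq_b_h": +1, "isp_r_h": +1, "bl_r_h": +1, "h_u": +qp},
        ),
        ("B6F_2_isp_to_cytf", {"isp_r_h": -1, "cytf_h": -1, "isp_h": +1, "cytf_r_h": +1}),
        ("B6F_3_cytf_to_pc", {"cytf_r_h": -1, "pc_ox_u": -1, "cytf_h": +1, "pc_red_u": +1}),
        ("B6F_4_bl_to_bh", {"bl_r_h": -1, "bh_h": -1, "bl_h": +1, "bh_r_h": +1}),
        ("B6F_5_qi_first_reduction", {"bh_r_h": -1, "qi_pq_h": -1, "bh_h": +1, "qi_sq_h": +1}),
        ("B6F_6_qi_second_reduction", {"bh_r_h": -1, "qi_sq_h": -1, "h_h": -2, "bh_h": +1, "qi_pqh2_h": +1}),
        ("B6F_7_qi_exchange", {"qi_pqh2_h": -1, "pq_b_h": -1, "qi_pq_h": +1, "pqh2_b_h": +1}),
    ]
    for rid, st in b6f:
        rx(rid, st, gpr=_B6F_GPR, subsystems=[PHOTOSYNTHESIS_SUBSYSTEM, "cytochrome b6f"])

    # PSI: 8 electron transfers
    psi = [
        ("PSI_1_p700_excitation", {"photon_h": -1, "p700_h": -1, "p700x_h": +1}),
        ("PSI_2_charge_separation", {"p700x_h": -1, "a0_h": -1, "p700p_h": +1, "a0_r_h": +1}),
        ("PSI_3_pc_oxidation", {"p700p_h": -1, "pc_red_u": -1, "p700_h": +1, "pc_ox_u": +1}),
        ("PSI_4_a0_to_a1", {"a0_r_h": -1, "a1_h": -1, "a0_h": +1, "a1_r_h": +1}),
        ("PSI_5_a1_to_fx", {"a1_r_h": -1, "fx_h": -1, "a1_h": +1, "fx_r_h": +1}),
        ("PSI_6_fx_to_fa", {"fx_r_h": -1, "fa_h": -1, "fx_h": +1, "fa_r_h": +1}),
        ("PSI_7_fa_to_fb", {"fa_r_h": -1, "fb_h": -1, "fa_h": +1, "fb_r_h": +1}),
        ("PSI_8_fd_reduction", {"fb_r_h": -1, "fd_ox_h": -1, "fb_h": +1, "fd_red_h": +1}),
    ]
    for rid, st in psi:
        rx(rid, st, gpr=_PSI_GPR, subsystems=[PHOTOSYNTHESIS_SUBSYSTEM, "PSI"])

    # FNR: 3 steps regenerating NADPH
    fnr = [
        ("FNR_1_first_electron", {"fd_red_h": -1, "fnr_h": -1, "fd_ox_h": +1, "fnr_sq_h": +1}),
        ("FNR_2_second_electron", {"fd_red_h": -1, "fnr_sq_h": -1, "fd_ox_h": +1, "fnr_red_h": +1}),
        ("FNR_3_nadph_formation", {"fnr_red_h": -1, "nadp_h": -1, "h_h": -1, "fnr_h": +1, "nadph_h": +1}),
    ]
    for rid, st in fnr:
        rx(rid, st, gpr=_FNR_GPR, subsystems=[PHOTOSYNTHESIS_SUBSYSTEM, "FNR"])

    # ATP synthase: lumen protons drive ADP + Pi condensation
    n = spec.h_per_atp
    rx(
        "ATP_synthase",
        {"h_u": -n, "adp_h": -1, "pi_h": -1, "atp_h": +1, "h2o_h": +1, "h_h": +n},
        name="ATP synthase",
        gpr=_ATPASE_GPR,
        subsystems=[PHOTOSYNTHESIS_SUBSYSTEM, "ATP synthase"],
    )

    # cyclic electron transport around PSI (closed by default)
    model.new_reaction(
        "cyclic_electron_transport",
        {"fd_red_h": -2, "pq_b_h": -1, "h_h": -2, "fd_ox_h": +2, "pqh2_b_h": +1},
        name="cyclic electron transport around PSI",
        lower_bound=spec.cyclic_bounds[0],
        upper_bound=spec.cyclic_bounds[1],
        subsystems=[PHOTOSYNTHESIS_SUBSYSTEM, "cyclic electron transport"],
    )

    # optional extra relay steps beyond the canonical chain lengths
    extra_specs = [
        ("psii_", "PSII", "pheo_r_h", "pheo_h", "qa_h", "qa_r_h",
         spec.psii_steps - _MIN_STEPS["psii"], _PSII_GPR, "PSII_6_qa_reduction"),
        ("b6f_", "cytochrome b6f", "isp_r_h", "isp_h", "cytf_h", "cytf_r_h",
         spec.b6f_steps - _MIN_STEPS["b6f"], _B6F_GPR, "B6F_2_isp_to_cytf"),
        ("psi_", "PSI", "fx_r_h", "fx_h", "fa_h", "fa_r_h",
         spec.psi_steps - _MIN_STEPS["psi"], _PSI_GPR, "PSI_6_fx_to_fa"),
        ("fnr_", "FNR", "fd_red_h", "fd_ox_h", "fnr_h", "fnr_sq_h",
         spec.fnr_steps - _MIN_STEPS["fnr"], _FNR_GPR, "FNR_1_first_electron"),
    ]
    for prefix, cname, d_red, d_ox, a_ox, a_red, n_extra, gpr, replaced in extra_specs:
        if n_extra <= 0:
            continue
        model.remove_reaction(replaced)
        mets, rxns = _relay_chain(prefix, cname, d_red, d_ox, a_ox, a_red,
                                  n_extra, gpr, balance)
        for m in mets:
            model.add_metabolite(m)
        for r in rxns:
            model.add_reaction(r)

    model._etc_balance_table = balance  # consumed by the balance audit
    return model


def build_calvin_mini_model(spec: Optional[ETCSpec] = None) -> OrganelleModule:
    """Photosynthetic ETC + lumped Calvin-Benson cycle mini-model.

    The Calvin-Benson cycle is lumped into RuBisCO carboxylation
    (CO2 + RuBP -> 2 3-PGA, the probe reaction) plus one
    reduction/regeneration reaction consuming 9 ATP and 6 NADPH per triose
    (3:9:6 totals).  ATP, ADP, Pi, NADPH and NADP+ have *no* transport or
    exchange reactions: the closed cofactor balance forces the ETC to supply
    ATP:NADPH at exactly 9:6.  Cytosolic CO2, O2, orthophosphate and the
    DHAP product are exchanged through border ('B_') reactions; the
    objective maximizes triose export (B_dhap_c).
    """
    spec = spec or ETCSpec()
    model = build_photosynthesis_module(spec)
    model.id = "calvin_mini_model"
    model.name = "photosynthesis + Calvin-Benson mini-model"

    plastid = [
        ("co2_h", "CO2", "h", "C00011"),
        ("rubp_h", "ribulose-1,5-bisphosphate", "h", "C01182"),
        ("pga_h", "3-phospho-D-glycerate", "h", "C00197"),
        ("dhap_h", "dihydroxyacetone phosphate", "h", "C00111"),
    ]
    cytosol = [
        ("co2_c", "CO2", "c", "C00011"),
        ("o2_c", "O2", "c", "C00007"),
        ("pi_c", "orthophosphate", "c", "C00009"),
        ("dhap_c", "dihydroxyacetone phosphate", "c", "C00111"),
    ]
    for mid, name, comp, kegg in plastid + cytosol:
        model.new_metabolite(mid, name=name, compartment=comp, kegg_id=kegg)

    model.new_reaction(
        "RuBisCO_carboxylation",
        {"co2_h": -1, "rubp_h": -1, "pga_h": +2},
        name="RuBisCO-driven CO2 fixation",
        lower_bound=0.0,
        gpr=GPRRule.from_string("rbcL and rbcS"),
        subsystems=["Calvin-Benson cycle"],
    )
    # 6 PGA + 9 ATP + 6 NADPH -> 1 DHAP + 3 RuBP: reduction + regeneration
    # lump.  6 H+ accompany NADPH oxidation; 3 H2O and the 8-vs-9 Pi split
    # close the water/phosphate balance (the 9th Pi returns through the
    # triose-phosphate translocator).
    model.new_reaction(
        "CBB_reduction_regeneration",
        {
            "pga_h": -6, "atp_h": -9, "nadph_h": -6, "h_h": -6, "h2o_h": -3,
            "dhap_h": +1, "rubp_h": +3, "adp_h": +9, "pi_h": +8, "nadp_h": +6,
        },
        name="Calvin-Benson reduction and regeneration (lumped)",
        lower_bound=0.0,
        gpr=GPRRule.from_string("cbbA"),
        subsystems=["Calvin-Benson cycle"],
    )
    model.new_reaction(
        "TPT_triose_phosphate_translocator",
        {"dhap_h": -1, "pi_c": -1, "dhap_c": +1, "pi_h": +1},
        name="triose phosphate/Pi translocator",
        lower_bound=0.0,
        subsystems=["transport"],
    )
    model.new_reaction(
        "CO2_transport",
        {"co2_c": -1, "co2_h": +1},
        name="CO2 diffusion into the plastid",
        lower_bound=-1000.0,
        subsystems=["transport"],
    )
    model.new_reaction(
        "O2_transport",
        {"o2_h": -1, "o2_c": +1},
        name="O2 diffusion out of the plastid",
        lower_bound=-1000.0,
        subsystems=["transport"],
    )
    # border reactions: free exchange of the cytosolic metabolites
    for mid in ("co2_c", "o2_c", "pi_c"):
        model.new_reaction(
            f"B_{mid}",
            {mid: -1},
            name=f"border exchange of {mid}",
            lower_bound=-1000.0,
            subsystems=["border exchange"],
        )
    model.new_reaction(
        "B_dhap_c",
        {"dhap_c": -1},
        name="border export of triose (objective)",
        lower_bound=0.0,
        subsystems=["border exchange"],
    )
    model.set_objective("B_dhap_c", "max")
    return model


def _default_fraction_tables():
    # Illustrative organism fraction tables (placeholders, config-overridable):
    # amino-acid, lipid-class, per-class fatty-acid and pigment molar fractions.
    aa_common = {
        "lys": 0.12, "met": 0.05, "thr": 0.12, "phe": 0.09, "tyr": 0.07,
        "trp": 0.03, "leu": 0.22, "ile": 0.13, "val": 0.17,
    }
    fa_common = {"c16_0": 0.45, "c16_1": 0.25, "c20_5": 0.30}
    return {
        "Nan": dict(
            amino_acid_fractions=dict(aa_common),
            lipid_class_fractions={"mgdg": 0.55, "dgdg": 0.25, "sqdg": 0.20},
            fatty_acid_fractions={
                "mgdg": dict(fa_common),
                "dgdg": {"c16_0": 0.60, "c16_1": 0.25, "c20_5": 0.15},
                "sqdg": {"c16_0": 0.80, "c16_1": 0.20},
            },
            pigment_fractions={"chla": 0.70, "violaxanthin": 0.20, "vaucheriaxanthin": 0.10},
        ),
        "Chl": dict(
            amino_acid_fractions=dict(aa_common),
            lipid_class_fractions={"mgdg": 0.50, "dgdg": 0.30, "sqdg": 0.20},
            fatty_acid_fractions={
                "mgdg": {"c16_0": 0.30, "c18_3": 0.70},
                "dgdg": {"c16_0": 0.50, "c18_3": 0.50},
                "sqdg": {"c16_0": 0.85, "c18_3": 0.15},
            },
            pigment_fractions={"chla": 0.55, "chlb": 0.25, "lutein": 0.12, "bcarotene": 0.08},
        ),
        "Pha": dict(
            amino_acid_fractions=dict(aa_common),
            lipid_class_fractions={"mgdg": 0.60, "dgdg": 0.20, "sqdg": 0.20},
            fatty_acid_fractions={
                "mgdg": dict(fa_common),
                "dgdg": dict(fa_common),
                "sqdg": {"c16_0": 0.70, "c16_1": 0.30},
            },
            # Phaeodactylum's specific carotenoid pathways are not modelled;
            # its pigment pool contains chlorophyll a only.
            pigment_fractions={"chla": 1.0},
        ),
    }


#: Eq-style chloroplast biomass coefficients: energy + macromolecule demand.
BIOMASS_COEFFICIENTS = {
    "atp_h": -10.0,
    "h2o_h": -5.0,
    "nadph_h": -5.0,
    "h_h": -5.0,
    "o2_h": -2.5,
    "cpr": -1.0,
    "cml": -1.0,
    "cpi": -1.0,
    "adp_h": +10.0,
    "pi_h": +10.0,
    "nadp_h": +5.0,
}


@dataclass
class BiomassSpec:
    """Organism-specific chloroplast biomass composition.

    The biomass reaction itself is fixed (10 ATP + 5 H2O + 5 NADPH + 5 H+ +
    2.5 O2 + 1 CPr + 1 CML + 1 CPi -> 10 ADP + 10 Pi + 5 NADP+); the CPr
    (chloroplast protein), CML (membrane lipid) and CPi (pigment)
    pseudo-metabolites are assembled from organism-specific molar fraction
    tables, each summing to 1.  The shipped per-organism tables are
    illustrative placeholders, overridable by config.
    """

    amino_acid_fractions: dict = field(default_factory=dict)
    lipid_class_fractions: dict = field(default_factory=dict)
    fatty_acid_fractions: dict = field(default_factory=dict)
    pigment_fractions: dict = field(default_factory=dict)

    @classmethod
    def default_for(cls, organism: str) -> "BiomassSpec":
        tables = _default_fraction_tables()
        if organism not in tables:
            raise KeyError(
                f"no default biomass composition for {organism!r} "
                f"(have {sorted(tables)}); supply a BiomassSpec"
            )
        return cls(**tables[organism])

    def validate(self, tol: float = 1e-9) -> None:
        tables = [
            ("amino_acid_fractions", self.amino_acid_fractions),
            ("lipid_class_fractions", self.lipid_class_fractions),
            ("pigment_fractions", self.pigment_fractions),
        ] + [
            (f"fatty_acid_fractions[{cls}]", fr)
            for cls, fr in self.fatty_acid_fractions.items()
        ]
        for label, table in tables:
            if not table:
                continue
            if any(v < 0 for v in table.values()):
                raise ValueError(f"{label}: negative fraction")
            total = sum(table.values())
            if abs(total - 1.0) > tol:
                raise ValueError(f"{label}: fractions sum to {total}, not 1")


def compose_biomass(
    spec: BiomassSpec,
    organism: str,
    model: Optional[OrganelleModule] = None,
) -> list:
    """Build the organism-tagged assembly + biomass reactions.

    Returns ``[CPr assembly, CML assembly (preceded by per-lipid-class
    assemblies when fatty-acid fractions are given), CPi assembly, biomass]``.
    When *model* is given, missing component metabolites are created, the
    reactions are added, and the biomass is registered as the organism's
    mode.
    """
    spec.validate()

    def tagged(core):
        return assemble_reaction_id(core, [organism])

    def component(mid):
        return f"{mid}_{organism.lower()}_h"

    reactions = []
    mets_needed: dict = {}

    def pseudo(mid, name):
        mets_needed[mid] = Metabolite(mid, name=name, compartment="h")
        return mid

    # CPr: amino acids -> chloroplast protein fraction
    cpr = pseudo(component("cpr"), f"chloroplast protein fraction ({organism})")
    st = {f"{aa}_h": -frac for aa, frac in spec.amino_acid_fractions.items()}
    for aa in spec.amino_acid_fractions:
        mets_needed.setdefault(f"{aa}_h", Metabolite(f"{aa}_h", name=aa, compartment="h"))
    st[cpr] = +1.0
    reactions.append(
        Reaction(
            id=tagged("CPr_assembly_h"),
            name=f"chloroplast protein assembly ({organism})",
            stoichiometry=st,
            lower_bound=0.0,
            subsystems=["biomass assembly"],
        )
    )

    # per-class lipid assemblies from fatty acids (when given), then CML
    for cls_name, fa_table in spec.fatty_acid_fractions.items():
        cls_met = f"{cls_name}_{organism.lower()}_h"
        mets_needed[cls_met] = Metabolite(cls_met, name=f"{cls_name} ({organism})", compartment="h")
        st = {f"{fa}_h": -frac for fa, frac in fa_table.items()}
        for fa in fa_table:
            mets_needed.setdefault(f"{fa}_h", Metabolite(f"{fa}_h", name=fa, compartment="h"))
        st[cls_met] = +1.0
        reactions.append(
            Reaction(
                id=tagged(f"{cls_name.upper()}_assembly_h"),
                name=f"{cls_name.upper()} assembly ({organism})",
                stoichiometry=st,
                lower_bound=0.0,
                subsystems=["biomass assembly"],
            )
        )
    cml = pseudo(component("cml"), f"chloroplast membrane lipid fraction ({organism})")
    st = {}
    for cls_name, frac in spec.lipid_class_fractions.items():
        cls_met = (
            f"{cls_name}_{organism.lower()}_h"
            if cls_name in spec.fatty_acid_fractions
            else f"{cls_name}_h"
        )
        mets_needed.setdefault(cls_met, Metabolite(cls_met, name=cls_name, compartment="h"))
        st[cls_met] = -frac
    st[cml] = +1.0
    reactions.append(
        Reaction(
            id=tagged("CML_assembly_h"),
            name=f"chloroplast membrane lipid assembly ({organism})",
            stoichiometry=st,
            lower_bound=0.0,
            subsystems=["biomass assembly"],
        )
    )

    # CPi: pigments -> pigment fraction
    cpi = pseudo(component("cpi"), f"chloroplast pigment fraction ({organism})")
    st = {f"{p}_h": -frac for p, frac in spec.pigment_fractions.items()}
    for p in spec.pigment_fractions:
        mets_needed.setdefault(f"{p}_h", Metabolite(f"{p}_h", name=p, compartment="h"))
    st[cpi] = +1.0
    reactions.append(
        Reaction(
            id=tagged("CPi_assembly_h"),
            name=f"chloroplast pigment assembly ({organism})",
            stoichiometry=st,
            lower_bound=0.0,
            subsystems=["biomass assembly"],
        )
    )

    # the chloroplast biomass reaction itself
    st = dict(BIOMASS_COEFFICIENTS)
    st[cpr] = st.pop("cpr")
    st[cml] = st.pop("cml")
    st[cpi] = st.pop("cpi")
    for mid, name, kegg in [
        ("atp_h", "ATP", "C00002"), ("adp_h", "ADP", "C00008"),
        ("pi_h", "orthophosphate", "C00009"), ("h2o_h", "H2O", "C00001"),
        ("nadph_h", "NADPH", "C00005"), ("nadp_h", "NADP+", "C00006"),
        ("h_h", "H+ (stroma)", "C00080"), ("o2_h", "O2", "C00007"),
    ]:
        mets_needed.setdefault(mid, Metabolite(mid, name=name, compartment="h", kegg_id=kegg))
    biomass = Reaction(
        id=tagged("biomass_chloroplast_h"),
        name=f"chloroplast biomass ({organism})",
        stoichiometry=st,
        lower_bound=0.0,
        subsystems=["biomass"],
        is_biomass=True,
        biomass_organism=organism,
    )
    reactions.append(biomass)

    if model is not None:
        model.organisms.add(organism)
        for mid, met in mets_needed.items():
            if not model.has_metabolite(mid):
                model.add_metabolite(met)
        for r in reactions:
            model.add_reaction(r)
        register_mode(model, organism, biomass.id)
    return reactions


def build_toy_exo_model() -> OrganelleModule:
    """A minimal cytosolic exo-model for fusion tests.

    KEGG-annotated cytosolic species (CO2, O2, Pi, NH3, DHAP, pyruvate,
    alanine), free nutrient exchanges, and a biomass reaction consuming the
    triose (directly and via alanine).  Alone the biomass optimum is 0 --
    there is no triose source -- but fusing in the chloroplast mini-model
    makes it feasible.
    """
    model = OrganelleModule(
        id="toy_exo_model",
        name="toy cytosolic exo-model",
        compartments={"c": "cytosol"},
        organisms=set(),
    )
    for mid, name, kegg in [
        ("co2_cyt", "CO2", "C00011"),
        ("o2_cyt", "O2", "C00007"),
        ("pi_cyt", "orthophosphate", "C00009"),
        ("nh3_cyt", "ammonia", "C00014"),
        ("dhap_cyt", "dihydroxyacetone phosphate", "C00111"),
        ("pyr_cyt", "pyruvate", "C00022"),
        ("ala_cyt", "L-alanine", "C00041"),
    ]:
        model.new_metabolite(mid, name=name, compartment="c", kegg_id=kegg)
    for mid in ("co2_cyt", "o2_cyt", "pi_cyt", "nh3_cyt"):
        model.new_reaction(
            f"EX_{mid}", {mid: -1}, name=f"exchange of {mid}",
            lower_bound=-1000.0, subsystems=["exchange"],
        )
    model.new_reaction(
        "lower_glycolysis",
        {"dhap_cyt": -1, "pyr_cyt": +1, "pi_cyt": +1},
        name="lower glycolysis (lumped)",
        lower_bound=0.0,
        gpr=GPRRule.from_string("gapC or gapN"),
        subsystems=["glycolysis"],
    )
    model.new_reaction(
        "ala_synthesis",
        {"pyr_cyt": -1, "nh3_cyt": -1, "ala_cyt": +1},
        name="alanine synthesis",
        lower_bound=0.0,
        gpr=GPRRule.from_string("alaT"),
        subsystems=["amino acid synthesis"],
    )
    model.new_reaction(
        "Biomass_exo",
        {"dhap_cyt": -1.0, "ala_cyt": -0.5},
        name="exo-model biomass",
        lower_bound=0.0,
        subsystems=["biomass"],
        is_biomass=True,
    )
    model.set_objective("Biomass_exo", "max")
    return model
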