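"""Fusing the organelle module into an exo-model.

The standalone module exchanges a set of cytosolic metabolites with its
environment through free border ('B_') reactions.  Fusion plugs the module
into a whole-cell exo-model instead: each cytosolic *exchange metabolite*
is matched to the exo-model species with the same KEGG compound id, the
module's species are renamed into the exo-model namespace, the border
reactions and the module's own biomass reactions are deleted (the
exo-model's biomass prevails), and the remaining reactions are merged.
Exchange metabolites without a unique KEGG match are kept, disconnected,
and reported so the user can debug the combined model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import OrganelleModule

__all__ = [
    "MetaboliteMatch",
    "FusionReport",
    "FusionError",
    "identify_exchange_metabolites",
    "match_exchange_metabolites",
    "fuse",
    "DEFAULT_CYTOSOL_SYMBOLS",
    "COLLISION_PREFIX",
]

#: compartment symbols treated as "cytosol" in exo-models
DEFAULT_CYTOSOL_SYMBOLS = frozenset({"c", "cytosol", "cytoplasm", "cyt"})

#: prefix applied to module reactions whose id collides with an exo reaction
COLLISION_PREFIX = "CHL__"


class FusionError(RuntimeError):
    pass


@dataclass
class MetaboliteMatch:
    module_id: str
    exo_id: str
    matched_by: str = "kegg_id"  # or 'manual'
    kegg_id: Optional[str] = None


@dataclass
class FusionReport:
    matches: list = field(default_factory=list)
    unmatched: list = field(default_factory=list)  # (module met id, reason)
    deleted_border_reactions: list = field(default_factory=list)
    deleted_biomass_reactions: list = field(default_factory=list)
    renamed_metabolites: dict = field(default_factory=dict)  # old -> new
    id_collisions: list = field(default_factory=list)  # (module id, merged id)

    def to_tsv(self) -> str:
        lines = ["event\tdetail"]
        for m in self.matches:
            lines.append(f"matched\t{m.module_id} -> {m.exo_id} ({m.matched_by})")
        for met_id, reason in self.unmatched:
            lines.append(f"unmatched\t{met_id}: {reason}")
        for rid in self.deleted_border_reactions:
            lines.append(f"deleted-border\t{rid}")
        for rid in self.deleted_biomass_reactions:
            lines.append(f"deleted-biomass\t{rid}")
        for old, new in self.renamed_metabolites.items():
            lines.append(f"renamed\t{old} -> {new}")
        for old, new in self.id_collisions:
            lines.append(f"collision\t{old} kept as {new}")
        return "\n".join(lines) + "\n"


def identify_exchange_metabolites(module: OrganelleModule) -> set:
    """Cytosol-compartment metabolites that take part in >=1 border reaction."""
    border_mets: set = set()
    for rxn in module.reactions:
        if rxn.is_border:
            border_mets.update(rxn.stoichiometry)
    return {
        mid
        for mid in border_mets
        if module.has_metabolite(mid)
        and module.get_metabolite(mid).compartment == "c"
    }


def match_exchange_metabolites(
    module: OrganelleModule,
    exo_model: OrganelleModule,
    cytosol_symbols: Iterable[str] = DEFAULT_CYTOSOL_SYMBOLS,
) -> tuple:
    """Pair module exchange metabolites with exo-model species by KEGG id.

    Returns ``(matches, unmatched)``.  A match requires exactly one
    cytosolic exo species with the same KEGG compound id; zero candidates,
    several candidates (ambiguity) and missing annotation all land in
    *unmatched* with a reason, so the user is notified for debugging.
    """
    cytosol = set(cytosol_symbols)
    exo_by_kegg: dict = {}
    for met in exo_model.metabolites:
        if met.kegg_id and met.compartment in cytosol:
            exo_by_kegg.setdefault(met.kegg_id, []).append(met.id)
    matches: list = []
    unmatched: list = []
    for mid in sorted(identify_exchange_metabolites(module)):
        met = module.get_metabolite(mid)
        if not met.kegg_id:
            unmatched.append((mid, "no KEGG annotation on module metabolite"))
            continue
        candidates = exo_by_kegg.get(met.kegg_id, [])
        if not candidates:
            unmatched.append(
                (mid, f"KEGG id {met.kegg_id} not present in the exo-model cytosol")
            )
        elif len(candidates) > 1:
            unmatched.append(
                (mid, f"ambiguous: {len(candidates)} exo species share {met.kegg_id} "
                      f"({sorted(candidates)})")
            )
        else:
            matches.append(
                MetaboliteMatch(module_id=mid, exo_id=candidates[0], kegg_id=met.kegg_id)
            )
    return matches, unmatched


def fuse(
    module: OrganelleModule,
    exo_model: OrganelleModule,
    manual_matches: Optional[dict] = None,
    cytosol_symbols: Iterable[str] = DEFAULT_CYTOSOL_SYMBOLS,
) -> tuple:
    """Merge *module* into *exo_model*; returns ``(merged, FusionReport)``.

    Inputs are not mutated.  Matched module metabolites are renamed to the
    exo ids; border reactions and module biomass reactions are deleted; the
    exo biomass stays the objective; reaction-id collisions keep both
    reactions, the module copy renamed with ``CHL__``.  Unmatched exchange
    metabolites survive as disconnected module-namespace species (reported).
    """
    if exo_model.objective_id is None:
        raise FusionError("exo-model has no objective/biomass reaction; cannot fuse")
    report = FusionReport()
    matches, unmatched = match_exchange_metabolites(module, exo_model, cytosol_symbols)
    manual_matches = dict(manual_matches or {})
    matched_ids = {m.module_id for m in matches}
    for old, new in manual_matches.items():
        if not exo_model.has_metabolite(new):
            raise FusionError(f"manual match target {new!r} not in exo-model")
        if old in matched_ids:
            matches = [m for m in matches if m.module_id != old]
        matches.append(MetaboliteMatch(module_id=old, exo_id=new, matched_by="manual"))
        matched_ids.add(old)
    unmatched = [(mid, why) for mid, why in unmatched if mid not in matched_ids]
    report.matches = matches
    report.unmatched = unmatched

    merged = exo_model.copy()
    merged.id = f"{exo_model.id}+{module.id}"
    merged.name = f"{exo_model.name} with {module.name}"
    module = module.copy()

    rename = {m.module_id: m.exo_id for m in matches}
    exo_met_ids = {m.id for m in merged.metabolites}
    for met in module.metabolites:
        if met.id in rename:
            continue
        new_id = met.id
        if new_id in exo_met_ids:
            new_id = COLLISION_PREFIX + new_id
            report.renamed_metabolites[met.id] = new_id
            rename[met.id] = new_id
    report.renamed_metabolites.update(
        {m.module_id: m.exo_id for m in matches if m.module_id != m.exo_id}
    )

    for met in module.metabolites:
        if met.id in {m.module_id for m in matches}:
            continue
        new = met.copy()
        new.id = rename.get(met.id, met.id)
        merged.add_metabolite(new)
    for comp, name in module.compartments.items():
        merged.compartments.setdefault(comp, name)
    merged.organisms |= module.organisms

    exo_rxn_ids = {r.id for r in merged.reactions}
    for rxn in module.reactions:
        if rxn.is_border:
            report.deleted_border_reactions.append(rxn.id)
            continue
        if rxn.is_biomass:
            report.deleted_biomass_reactions.append(rxn.id)
            continue
        new = rxn.copy()
        new.stoichiometry = {
            rename.get(mid, mid): coeff for mid, coeff in rxn.stoichiometry.items()
        }
        if new.id in exo_rxn_ids:
            merged_id = COLLISION_PREFIX + new.id
            report.id_collisions.append((new.id, merged_id))
            renamed = new.copy()
            renamed.id = merged_id
            renamed.stoichiometry = new.stoichiometry
            # re-derive tag/border flags from the prefixed id is wrong; keep
            # the original parse
            renamed.organism_tags = new.organism_tags
            renamed.is_border = new.is_border
            renamed.core_id = new.core_id
            new = renamed
        merged.add_reaction(new)

    merged.is_fused = True
    merged.mode_registry = dict(exo_model.mode_registry)
    merged.set_objective(exo_model.objective_id, exo_model.objective_direction)
    merged.active_mode = None

    audit = merged.validate()
    if not audit.passed:
        raise FusionError(
            f"merged model failed validation:\n{audit.summary()}\n"
            f"fusion report:\n{report.to_tsv()}"
        )
    return merged, report
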