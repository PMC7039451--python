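"""Organism-mode switching.

An organelle module runs in one organism mode at a time: reactions tagged
for the active organism (and all untagged, mode-insensitive reactions) are
enabled at their default bounds, reactions tagged only for other organisms
are closed to (0, 0), and the active organism's biomass reaction becomes
the objective while all other biomass reactions are closed.  In a fused
model the tag toggling still applies but the objective is left to the
exo-model's biomass reaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .model import ModeEntry, OrganelleModule

__all__ = ["register_mode", "set_mode", "mode_report", "ModeReport"]


def register_mode(
    model: OrganelleModule,
    organism: str,
    biomass_id: str,
    bound_overrides: dict | None = None,
) -> OrganelleModule:
    """Register (or replace) an organism mode.

    The biomass reaction must exist; it is flagged ``is_biomass`` and bound
    to the organism.  The organism symbol joins the model's registered set,
    so ``@<organism>_`` tags become parseable.  Mutates and returns *model*.
    """
    if not model.has_reaction(biomass_id):
        raise KeyError(
            f"cannot register mode {organism!r}: biomass reaction {biomass_id!r} "
            "not in model"
        )
    if organism in model.mode_registry:
        warnings.warn(
            f"re-registering organism mode {organism!r} "
            f"(was {model.mode_registry[organism].biomass_id!r})",
            stacklevel=2,
        )
    rxn = model.get_reaction(biomass_id)
    rxn.is_biomass = True
    rxn.biomass_organism = organism
    model.organisms.add(organism)
    model.mode_registry[organism] = ModeEntry(
        biomass_id=biomass_id, bound_overrides=dict(bound_overrides or {})
    )
    return model


def set_mode(model: OrganelleModule, organism: str) -> OrganelleModule:
    """Switch the module to *organism* mode (idempotent; mutates in place).

    Tagged reactions: enabled at default bounds (or the mode's override) if
    tagged with *organism*, closed otherwise.  Biomass handling: the
    registered biomass for *organism* is enabled and becomes the objective;
    every other biomass reaction is closed.  In a fused model the objective
    is never touched.  Untagged, non-biomass reactions are untouched;
    stoichiometry is never altered.
    """
    if organism not in model.mode_registry and not (
        model.is_fused and organism in model.organisms
    ):
        raise KeyError(
            f"organism {organism!r} is not a registered mode "
            f"(registered: {sorted(model.mode_registry)})"
        )
    entry = model.mode_registry.get(organism)
    overrides = entry.bound_overrides if entry else {}
    for rxn in model.reactions:
        if rxn.is_biomass:
            continue
        if rxn.organism_tags:
            if organism in rxn.organism_tags:
                rxn.bounds = overrides.get(rxn.id, rxn.default_bounds)
            else:
                rxn.bounds = (0.0, 0.0)
    if not model.is_fused and entry is not None:
        for rxn in model.reactions:
            if not rxn.is_biomass:
                continue
            if rxn.id == entry.biomass_id:
                rxn.bounds = overrides.get(rxn.id, rxn.default_bounds)
            else:
                rxn.bounds = (0.0, 0.0)
        model.set_objective(entry.biomass_id, "max")
    model.active_mode = organism
    return model


@dataclass
class ModeReport:
    """Tag census of a module."""

    total_reactions: int = 0
    untagged: int = 0
    single_tag: dict = field(default_factory=dict)  # organism -> count
    multi_tag: dict = field(default_factory=dict)  # frozenset of organisms -> count
    enabled_tagged: int = 0
    disabled_tagged: int = 0

    @property
    def organism_specific(self) -> int:
        return sum(self.single_tag.values()) + sum(self.multi_tag.values())

    def to_tsv(self) -> str:
        lines = ["category\tcount"]
        lines.append(f"total\t{self.total_reactions}")
        lines.append(f"mode-insensitive\t{self.untagged}")
        lines.append(f"organism-specific\t{self.organism_specific}")
        for org in sorted(self.single_tag):
            lines.append(f"specific:{org}\t{self.single_tag[org]}")
        for tags in sorted(self.multi_tag, key=sorted):
            lines.append(f"shared:{'+'.join(sorted(tags))}\t{self.multi_tag[tags]}")
        lines.append(f"tagged-enabled\t{self.enabled_tagged}")
        lines.append(f"tagged-disabled\t{self.disabled_tagged}")
        return "\n".join(lines) + "\n"


def mode_report(model: OrganelleModule) -> ModeReport:
    """Count mode-insensitive, organism-specific and shared reactions, plus
    how many tagged reactions are currently enabled (non-zero bounds)."""
    rep = ModeReport(total_reactions=len(model.reactions))
    for rxn in model.reactions:
        tags = rxn.organism_tags
        if not tags:
            rep.untagged += 1
            continue
        if len(tags) == 1:
            (org,) = tags
            rep.single_tag[org] = rep.single_tag.get(org, 0) + 1
        else:
            rep.multi_tag[tags] = rep.multi_tag.get(tags, 0) + 1
        if rxn.lower_bound == 0.0 and rxn.upper_bound == 0.0:
            rep.disabled_tagged += 1
        else:
            rep.enabled_tagged += 1
    return rep
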