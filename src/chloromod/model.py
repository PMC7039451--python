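"""Core stoichiometric data structures for organelle modules.

An :class:`OrganelleModule` is a compartmented stoichiometric model whose
reaction identifiers carry two kinds of structural prefixes:

* ``@Xxx_`` — organism tags.  A reaction prefixed ``@Nan_`` belongs to the
  *Nannochloropsis* organism mode only; a reaction carrying no tag is common
  to every mode.  Reactions shared by several (but not all) organisms stack
  prefixes, e.g. ``@Chl_@Pha_DHA_syn_h``; the canonical serialisation orders
  tags alphabetically.
* ``B_`` — border reactions: free import/export reactions that let the
  standalone module exchange its cytosolic metabolites with the environment.
  They are deleted when the module is fused into an exo-model.

The module also keeps a *mode registry* mapping organism symbols to their
organism-specific biomass reaction, which is how the model switches between
organism modes.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from scipy import sparse

from .gpr import GPRRule

__all__ = [
    "Metabolite",
    "Reaction",
    "OrganelleModule",
    "ValidationReport",
    "TagError",
    "DEFAULT_ORGANISMS",
    "KEGG_COMPOUND_RE",
    "parse_reaction_id",
    "assemble_reaction_id",
    "stoichiometric_matrix",
    "validate",
]

#: Organism symbols registered by default (Nannochloropsis gaditana,
#: Chlamydomonas reinhardtii, Phaeodactylum tricornutum).
DEFAULT_ORGANISMS = frozenset({"Nan", "Chl", "Pha"})

KEGG_COMPOUND_RE = re.compile(r"^C\d{5}$")

_TAG_RE = re.compile(r"^@([A-Za-z][A-Za-z0-9]*)_")


class TagError(ValueError):
    """Raised for malformed or unregistered organism-tag prefixes."""


def parse_reaction_id(
    full_id: str, organisms: Optional[Iterable[str]] = None
) -> tuple[frozenset, bool, str]:
    """Split a reaction id into ``(organism_tags, is_border, core_id)``.

    Leading ``@Xxx_`` prefixes are consumed into the (order-insensitive) tag
    set and a leading ``B_`` prefix into the border flag; whatever remains is
    the core id.  When *organisms* is given, an ``@`` prefix naming an
    unregistered symbol is a :class:`TagError`; when it is ``None`` any
    well-formed ``@Xxx_`` prefix is accepted (lenient mode, used while a
    model is still being assembled).

    >>> parse_reaction_id('@Nan_R05345_h')
    (frozenset({'Nan'}), False, 'R05345_h')
    """
    if not full_id:
        raise ValueError("reaction id must be non-empty")
    registered = None if organisms is None else set(organisms)
    tags: set = set()
    is_border = False
    rest = full_id
    while True:
        if rest.startswith("@"):
            m = _TAG_RE.match(rest)
            if not m:
                raise TagError(
                    f"malformed organism tag at {rest!r} in reaction id {full_id!r}"
                )
            sym = m.group(1)
            if registered is not None and sym not in registered:
                raise TagError(
                    f"unregistered organism symbol '@{sym}_' in reaction id "
                    f"{full_id!r} (registered: {sorted(registered)})"
                )
            tags.add(sym)
            rest = rest[m.end():]
        elif rest.startswith("B_") and not is_border:
            is_border = True
            rest = rest[2:]
        else:
            break
    if not rest:
        raise ValueError(f"reaction id {full_id!r} has no core id after prefixes")
    return frozenset(tags), is_border, rest


def assemble_reaction_id(
    core_id: str, organism_tags: Iterable[str] = (), is_border: bool = False
) -> str:
    """Build the canonical full id: alphabetical ``@Tag_`` prefixes, then ``B_``."""
    prefix = "".join(f"@{t}_" for t in sorted(organism_tags))
    if is_border:
        prefix += "B_"
    return prefix + core_id


@dataclass
class Metabolite:
    """A model species.

    Compartments follow the module convention: ``h`` chloroplast stroma,
    ``u`` thylakoid lumen, ``c`` cytosol.  ``kegg_id`` is the KEGG compound
    accession (``C`` + five digits) and is the key used to match metabolites
    across models at fusion time.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    kegg_id: Optional[str] = None
    charge: Optional[int] = None
    formula: Optional[str] = None

    def copy(self) -> "Metabolite":
        return _copy.copy(self)


@dataclass
class Reaction:
    """A tagged stoichiometric reaction.

    ``stoichiometry`` maps metabolite ids to signed coefficients (negative =
    consumed, positive = produced).  ``default_bounds`` are the bounds a
    reaction is restored to when its organism mode enables it; they are
    captured from the initial bounds unless given explicitly.
    """

    id: str
    name: str = ""
    stoichiometry: dict = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    default_bounds: Optional[tuple] = None
    gpr: GPRRule = field(default_factory=GPRRule)
    subsystems: list = field(default_factory=list)
    is_biomass: bool = False
    biomass_organism: Optional[str] = None
    # derived from id (lenient parse); re-derived against the model registry
    # by OrganelleModule.validate
    organism_tags: frozenset = field(init=False)
    is_border: bool = field(init=False)
    core_id: str = field(init=False)

    def __post_init__(self):
        self.organism_tags, self.is_border, self.core_id = parse_reaction_id(self.id)
        if self.default_bounds is None:
            self.default_bounds = (self.lower_bound, self.upper_bound)
        else:
            self.default_bounds = tuple(self.default_bounds)

    @property
    def bounds(self) -> tuple:
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, value) -> None:
        self.lower_bound, self.upper_bound = value

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def genes(self) -> frozenset:
        return self.gpr.genes

    def knock(self) -> None:
        """Disable the reaction (both bounds to zero)."""
        self.bounds = (0.0, 0.0)

    def restore(self) -> None:
        """Restore the enabled bounds."""
        self.bounds = self.default_bounds

    def copy(self) -> "Reaction":
        r = Reaction(
            id=self.id,
            name=self.name,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            default_bounds=self.default_bounds,
            gpr=self.gpr.copy(),
            subsystems=list(self.subsystems),
            is_biomass=self.is_biomass,
            biomass_organism=self.biomass_organism,
        )
        return r


@dataclass
class ValidationReport:
    """Structural audit of a model; ``passed`` iff every problem list is empty."""

    duplicate_ids: list = field(default_factory=list)
    dangling_refs: list = field(default_factory=list)
    bound_violations: list = field(default_factory=list)
    unregistered_tags: list = field(default_factory=list)
    unregistered_biomass: list = field(default_factory=list)
    bad_kegg_ids: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not (
            self.duplicate_ids
            or self.dangling_refs
            or self.bound_violations
            or self.unregistered_tags
            or self.unregistered_biomass
            or self.bad_kegg_ids
        )

    def summary(self) -> str:
        lines = [f"validation: {'PASS' if self.passed else 'FAIL'}"]
        for label in (
            "duplicate_ids",
            "dangling_refs",
            "bound_violations",
            "unregistered_tags",
            "unregistered_biomass",
            "bad_kegg_ids",
        ):
            items = getattr(self, label)
            if items:
                lines.append(f"  {label}: {items}")
        return "\n".join(lines)


@dataclass
class ModeEntry:
    """Per-organism mode registration: the biomass reaction and optional
    per-mode bound overrides (reaction id -> (lb, ub))."""

    biomass_id: str
    bound_overrides: dict = field(default_factory=dict)


class OrganelleModule:
    """A stoichiometric module with organism tags, modes and border reactions.

    Also serves as the generic model container for exo-models and merged
    (fused) models; a model with no tags and no registry is just an ordinary
    constraint-based model.
    """

    def __init__(
        self,
        id: str = "module",
        name: str = "",
        compartments: Optional[Mapping[str, str]] = None,
        organisms: Optional[Iterable[str]] = None,
    ):
        self.id = id
        self.name = name or id
        self.compartments: dict = dict(
            compartments
            if compartments is not None
            else {"h": "chloroplast stroma", "u": "thylakoid lumen", "c": "cytosol"}
        )
        self.organisms: set = set(organisms if organisms is not None else DEFAULT_ORGANISMS)
        self._metabolites: list = []
        self._reactions: list = []
        self._met_index: dict = {}
        self._rxn_index: dict = {}
        self.mode_registry: dict = {}
        self.active_mode: Optional[str] = None
        self.objective_id: Optional[str] = None
        self.objective_direction: str = "max"
        #: set by fusion: a fused model's objective belongs to the exo-model
        #: and is never touched by mode switching.
        self.is_fused: bool = False

    # -- containers ---------------------------------------------------------

    @property
    def metabolites(self) -> Sequence[Metabolite]:
        return tuple(self._metabolites)

    @property
    def reactions(self) -> Sequence[Reaction]:
        return tuple(self._reactions)

    @property
    def genes(self) -> frozenset:
        out: set = set()
        for r in self._reactions:
            out |= r.genes
        return frozenset(out)

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        self._metabolites.append(met)
        self._met_index.setdefault(met.id, met)
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        self._reactions.append(rxn)
        self._rxn_index.setdefault(rxn.id, rxn)
        return rxn

    def get_metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}") from None

    def get_reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}") from None

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def remove_reaction(self, rxn_id: str) -> Reaction:
        rxn = self.get_reaction(rxn_id)
        self._reactions = [r for r in self._reactions if r is not rxn]
        self._rxn_index.pop(rxn_id, None)
        for r in self._reactions:  # a duplicate id may shadow
            self._rxn_index.setdefault(r.id, r)
        return rxn

    def remove_metabolite(self, met_id: str) -> Metabolite:
        met = self.get_metabolite(met_id)
        self._metabolites = [m for m in self._metabolites if m is not met]
        self._met_index.pop(met_id, None)
        for m in self._metabolites:
            self._met_index.setdefault(m.id, m)
        return met

    def rename_metabolite(self, old_id: str, new_id: str) -> None:
        """Rename a species and rewrite every stoichiometry referencing it."""
        met = self.get_metabolite(old_id)
        met.id = new_id
        self._met_index.pop(old_id, None)
        self._met_index[new_id] = met
        for r in self._reactions:
            if old_id in r.stoichiometry:
                r.stoichiometry[new_id] = r.stoichiometry.pop(old_id)

    def copy(self) -> "OrganelleModule":
        return _copy.deepcopy(self)

    # -- convenience constructors ------------------------------------------

    def new_metabolite(self, id: str, **kwargs) -> Metabolite:
        return self.add_metabolite(Metabolite(id=id, **kwargs))

    def new_reaction(self, id: str, stoichiometry=None, **kwargs) -> Reaction:
        return self.add_reaction(
            Reaction(id=id, stoichiometry=dict(stoichiometry or {}), **kwargs)
        )

    # -- objective ----------------------------------------------------------

    def set_objective(self, rxn_id: str, direction: str = "max") -> None:
        self.get_reaction(rxn_id)
        if direction not in ("max", "min"):
            raise ValueError("objective direction must be 'max' or 'min'")
        self.objective_id = rxn_id
        self.objective_direction = direction

    # -- analysis views -----------------------------------------------------

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        return stoichiometric_matrix(self)

    def validate(self) -> ValidationReport:
        return validate(self)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<OrganelleModule {self.id}: {len(self._reactions)} reactions, "
            f"{len(self._metabolites)} metabolites, mode={self.active_mode}>"
        )


def stoichiometric_matrix(model: OrganelleModule) -> sparse.csr_matrix:
    """The M x N stoichiometric matrix S.

    Rows follow the model's metabolite order, columns its reaction order
    (disabled reactions included); ``S[i, j]`` is the signed coefficient of
    metabolite *i* in reaction *j* (positive = produced).
    """
    mets = model.metabolites
    rxns = model.reactions
    row_of = {m.id: i for i, m in enumerate(mets)}
    rows, cols, data = [], [], []
    for j, r in enumerate(rxns):
        for met_id, coeff in r.stoichiometry.items():
            rows.append(row_of[met_id])
            cols.append(j)
            data.append(float(coeff))
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(mets), len(rxns)), dtype=float
    )


def validate(model: OrganelleModule) -> ValidationReport:
    """Structural audit.  Never raises on content problems."""
    report = ValidationReport()
    seen_m: set = set()
    for m in model.metabolites:
        if m.id in seen_m:
            report.duplicate_ids.append(m.id)
        seen_m.add(m.id)
        if m.kegg_id is not None and not KEGG_COMPOUND_RE.match(m.kegg_id):
            report.bad_kegg_ids.append((m.id, m.kegg_id))
    seen_r: set = set()
    for r in model.reactions:
        if r.id in seen_r:
            report.duplicate_ids.append(r.id)
        seen_r.add(r.id)
        for met_id in r.stoichiometry:
            if met_id not in seen_m and not model.has_metabolite(met_id):
                report.dangling_refs.append((r.id, met_id))
        if r.lower_bound > r.upper_bound:
            report.bound_violations.append((r.id, r.bounds))
        if r.default_bounds[0] > r.default_bounds[1]:
            report.bound_violations.append((r.id, r.default_bounds))
        for tag in r.organism_tags:
            if tag not in model.organisms:
                report.unregistered_tags.append((r.id, tag))
        if r.is_biomass and r.biomass_organism is not None:
            entry = model.mode_registry.get(r.biomass_organism)
            if entry is None or entry.biomass_id != r.id:
                report.unregistered_biomass.append(r.id)
    for org, entry in model.mode_registry.items():
        if not model.has_reaction(entry.biomass_id):
            report.unregistered_biomass.append(entry.biomass_id)
        elif not model.get_reaction(entry.biomass_id).is_biomass:
            report.unregistered_biomass.append(entry.biomass_id)
    return report
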