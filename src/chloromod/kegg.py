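"""Offline KEGG support: REACTION flat-file parsing and compound-id lookup.

Reactions are imported from KEGG flat-file records (the text a
``/get/Rxxxxx`` request returns), with the EQUATION line parsed into signed
stoichiometry over KEGG compound ids.  Metabolite KEGG annotation uses a
file-based alias -> compound-id lookup table (two-column delimited text),
since KEGG ids are the basis for matching metabolites between a module and
an exo-model at fusion time.  No network access is performed anywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .model import KEGG_COMPOUND_RE, Metabolite, OrganelleModule, Reaction, assemble_reaction_id

__all__ = [
    "KEGGParseError",
    "parse_kegg_reaction_record",
    "annotate_kegg_ids",
    "load_kegg_lookup",
    "AnnotationReport",
]


class KEGGParseError(ValueError):
    pass


_TERM_RE = re.compile(r"^(?:(\d+|[a-z](?:\+\d+)?)\s+)?(C\d{5})(?:\(.*\))?$")


def _parse_side(side: str, sign: int, record_id: str) -> dict:
    stoich: dict = {}
    for term in side.split(" + "):
        term = term.strip()
        if not term:
            continue
        m = _TERM_RE.match(term)
        if not m:
            raise KEGGParseError(
                f"{record_id}: cannot parse equation term {term!r}"
            )
        coeff_text, compound = m.groups()
        if coeff_text is None:
            coeff = 1
        elif coeff_text.isdigit():
            coeff = int(coeff_text)
        else:
            raise KEGGParseError(
                f"{record_id}: non-integer coefficient {coeff_text!r} for "
                f"{compound} (polymeric 'n' stoichiometry is rejected)"
            )
        stoich[compound] = stoich.get(compound, 0) + sign * coeff
    return stoich


def parse_kegg_reaction_record(
    text: str,
    compartment: str = "h",
    organism: Optional[str] = None,
) -> tuple:
    """Parse one KEGG REACTION record into a draft reaction + metabolites.

    The reaction id is the KEGG R-number suffixed with *compartment* and
    prefixed with the organism tag when given, e.g. record R05345 imported
    with ``organism='Nan'`` and ``compartment='h'`` becomes
    ``@Nan_R05345_h``.  Returns ``(Reaction, [Metabolite, ...])`` with
    ``kegg_id`` set on every metabolite; EC numbers from the ENZYME line are
    recorded on ``reaction.ec_numbers`` and appended to the name.
    """
    fields: dict = {}
    current = None
    for line in text.splitlines():
        if not line.strip():
            continue
        if line[:1] not in (" ", "\t"):
            parts = line.split(None, 1)
            current = parts[0].rstrip(":")
            fields.setdefault(current, [])
            if len(parts) > 1:
                fields[current].append(parts[1].strip())
        elif current:
            fields[current].append(line.strip())
    if "ENTRY" not in fields or not fields["ENTRY"]:
        raise KEGGParseError("record has no ENTRY line")
    entry_tokens = fields["ENTRY"][0].split()
    rnumber = entry_tokens[0]
    if "EQUATION" not in fields or not fields["EQUATION"]:
        raise KEGGParseError(f"{rnumber}: record has no EQUATION line")
    equation = " ".join(fields["EQUATION"])
    if "<=>" in equation:
        lhs, rhs = equation.split("<=>")
        reversible = True
    elif "=>" in equation:
        lhs, rhs = equation.split("=>")
        reversible = False
    else:
        raise KEGGParseError(f"{rnumber}: equation has no arrow: {equation!r}")
    stoich = _parse_side(lhs, -1, rnumber)
    for cid, coeff in _parse_side(rhs, +1, rnumber).items():
        stoich[cid] = stoich.get(cid, 0) + coeff
    stoich = {cid: c for cid, c in stoich.items() if c != 0}

    ec_numbers = " ".join(fields.get("ENZYME", [])).split()
    name = " ".join(fields.get("NAME", [])) or rnumber
    if ec_numbers:
        name = f"{name} [EC {' '.join(ec_numbers)}]"

    met_ids = {}
    metabolites = []
    new_stoich = {}
    for cid, coeff in stoich.items():
        mid = f"{cid}_{compartment}"
        met_ids[cid] = mid
        metabolites.append(
            Metabolite(id=mid, name=cid, compartment=compartment, kegg_id=cid)
        )
        new_stoich[mid] = float(coeff)

    rxn_id = assemble_reaction_id(
        f"{rnumber}_{compartment}", [organism] if organism else []
    )
    reaction = Reaction(
        id=rxn_id,
        name=name,
        stoichiometry=new_stoich,
        lower_bound=-1000.0 if reversible else 0.0,
        upper_bound=1000.0,
    )
    reaction.ec_numbers = ec_numbers
    return reaction, metabolites


def load_kegg_lookup(path, delimiter: Optional[str] = None) -> dict:
    """Read a two-column (alias, compound id) text table into a lookup dict.

    Aliases are lowercased; an alias mapping to several distinct compound
    ids is kept as a set (reported as ambiguous at annotation time).
    """
    lookup: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                continue
            alias, cid = parts[0].strip().lower(), parts[1].strip()
            lookup.setdefault(alias, set()).add(cid)
    return {alias: cids for alias, cids in lookup.items()}


@dataclass
class AnnotationReport:
    annotated: int = 0
    unresolved: list = field(default_factory=list)  # (metabolite id, reason)
    conflicts: list = field(default_factory=list)  # existing kegg kept


_COMPARTMENT_SUFFIX_RE = re.compile(r"(_[a-z]|\[[a-z]\])$")


def annotate_kegg_ids(model: OrganelleModule, lookup: dict) -> AnnotationReport:
    """Fill in missing metabolite KEGG ids from an alias lookup table.

    Matching is case-insensitive on the metabolite name (falling back to the
    compartment-stripped id).  Existing KEGG ids are never overwritten; an
    alias with two candidate compounds is left unresolved and reported for
    the manual path.
    """
    report = AnnotationReport()
    for met in model.metabolites:
        keys = []
        if met.name:
            keys.append(met.name.lower())
        keys.append(_COMPARTMENT_SUFFIX_RE.sub("", met.id).lower())
        candidates = None
        for key in keys:
            if key in lookup:
                cids = lookup[key]
                candidates = cids if isinstance(cids, set) else {cids}
                break
        if candidates is None:
            if met.kegg_id is None:
                report.unresolved.append((met.id, "no alias match"))
            continue
        if met.kegg_id is not None:
            if met.kegg_id not in candidates:
                report.conflicts.append((met.id, met.kegg_id, sorted(candidates)))
            continue
        if len(candidates) > 1:
            report.unresolved.append(
                (met.id, f"ambiguous alias: {sorted(candidates)}")
            )
            continue
        (cid,) = candidates
        if not KEGG_COMPOUND_RE.match(cid):
            report.unresolved.append((met.id, f"malformed compound id {cid!r}"))
            continue
        met.kegg_id = cid
        report.annotated += 1
    return report
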