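"""Network inspection: metabolite path following, SIF export, connectivity
and subsystem summaries.

A stoichiometric model is a bipartite graph between metabolites and
reactions; these helpers walk and export that graph for gap hunting and
for visual inspection in Cytoscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .model import OrganelleModule

__all__ = [
    "PathStep",
    "follow_metabolite",
    "export_sif",
    "connectivity_report",
    "subsystem_summary",
    "ConnectivityReport",
    "UNLABELED_SUBSYSTEM",
]

UNLABELED_SUBSYSTEM = "(unlabeled)"


@dataclass
class PathStep:
    """One node of a metabolite-following tree."""

    depth: int
    metabolite: str
    reaction: Optional[str] = None  # reaction traversed to reach this node
    direction: Optional[str] = None  # 'as-substrate' | 'as-product'
    children: list = field(default_factory=list)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


def _consuming(model, met_id):
    """Reactions that can consume met_id (forward on the substrate side, or
    backward on the product side of a reversible reaction)."""
    out = []
    for rxn in model.reactions:
        coeff = rxn.stoichiometry.get(met_id)
        if coeff is None:
            continue
        if (coeff < 0 and rxn.upper_bound > 0) or (coeff > 0 and rxn.lower_bound < 0):
            out.append((rxn, coeff))
    return out


def _producing(model, met_id):
    out = []
    for rxn in model.reactions:
        coeff = rxn.stoichiometry.get(met_id)
        if coeff is None:
            continue
        if (coeff > 0 and rxn.upper_bound > 0) or (coeff < 0 and rxn.lower_bound < 0):
            out.append((rxn, coeff))
    return out


def follow_metabolite(
    model: OrganelleModule,
    start: str,
    direction: str = "substrate",
    max_depth: int = 3,
) -> PathStep:
    """Breadth-first path following from *start*.

    ``direction='substrate'`` treats the metabolite as a substrate: follow
    reactions that consume it to the metabolites they produce.
    ``direction='product'`` walks the other way: follow the reactions that
    produce it back to their substrates.  Reversible reactions are followed
    both ways.  Visited metabolites are not re-expanded; the tree is capped
    at *max_depth*.
    """
    model.get_metabolite(start)
    if direction not in ("substrate", "product"):
        raise ValueError("direction must be 'substrate' or 'product'")
    root = PathStep(depth=0, metabolite=start)
    visited = {start}
    frontier = [root]
    for depth in range(1, max_depth + 1):
        next_frontier = []
        for node in frontier:
            if direction == "substrate":
                edges = _consuming(model, node.metabolite)
            else:
                edges = _producing(model, node.metabolite)
            for rxn, coeff in edges:
                # does the reaction run forward (positive flux) in this use?
                forward = coeff < 0 if direction == "substrate" else coeff > 0
                for other_id, other_coeff in rxn.stoichiometry.items():
                    if other_id in visited:
                        continue
                    if direction == "substrate":
                        # land on what the reaction produces in this run
                        wanted = (other_coeff > 0) == forward
                    else:
                        # land on what the reaction consumes in this run
                        wanted = (other_coeff < 0) == forward
                    if not wanted:
                        continue
                    visited.add(other_id)
                    child = PathStep(
                        depth=depth,
                        metabolite=other_id,
                        reaction=rxn.id,
                        direction="as-substrate" if direction == "substrate" else "as-product",
                    )
                    node.children.append(child)
                    next_frontier.append(child)
        frontier = next_frontier
        if not frontier:
            break
    return root


def export_sif(model: OrganelleModule, path) -> None:
    """Write the bipartite incidence as a Cytoscape SIF file.

    One line per nonzero of S: ``<metabolite> consumed_by <reaction>`` for
    negative coefficients, ``<reaction> produces <metabolite>`` for positive
    ones.  The line count equals ``nnz(S)``.
    """
    with open(path, "w") as fh:
        for rxn in model.reactions:
            for met_id, coeff in rxn.stoichiometry.items():
                if coeff < 0:
                    fh.write(f"{met_id}\tconsumed_by\t{rxn.id}\n")
                elif coeff > 0:
                    fh.write(f"{rxn.id}\tproduces\t{met_id}\n")


def bipartite_graph(model: OrganelleModule) -> nx.Graph:
    """Undirected metabolite-reaction incidence graph."""
    g = nx.Graph()
    for met in model.metabolites:
        g.add_node(("M", met.id))
    for rxn in model.reactions:
        g.add_node(("R", rxn.id))
        for met_id in rxn.stoichiometry:
            g.add_edge(("R", rxn.id), ("M", met_id))
    return g


@dataclass
class ConnectivityReport:
    components: list = field(default_factory=list)  # (n_metabolites, n_reactions, members)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def connected(self) -> bool:
        return self.n_components == 1


def connectivity_report(model: OrganelleModule) -> ConnectivityReport:
    """Connected components of the bipartite graph, largest first."""
    g = bipartite_graph(model)
    report = ConnectivityReport()
    for comp in sorted(nx.connected_components(g), key=len, reverse=True):
        mets = sorted(name for kind, name in comp if kind == "M")
        rxns = sorted(name for kind, name in comp if kind == "R")
        report.components.append((len(mets), len(rxns), mets + rxns))
    return report


def subsystem_summary(model: OrganelleModule) -> dict:
    """Reaction counts per subsystem label; a reaction with several labels
    counts in each, unlabeled reactions under :data:`UNLABELED_SUBSYSTEM`."""
    counts: dict = {}
    for rxn in model.reactions:
        labels = rxn.subsystems or [UNLABELED_SUBSYSTEM]
        for label in labels:
            counts[label] = counts.get(label, 0) + 1
    return counts
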