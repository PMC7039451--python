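"""Flux balance analysis: LP optimization, knockout scans, phase planes.

FBA finds a flux vector v maximizing (or minimizing) the flux of an
objective reaction subject to the steady-state constraint S.v = 0 and the
per-reaction bounds.  The LP is solved with the HiGHS solver via
scipy.optimize.linprog; the objective value of an LP is unique, individual
fluxes at an optimal vertex are not, so single-flux reports go through
:func:`flux_at_objective_optimum`, which fixes the objective at its optimum
and runs a second LP over the probe flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .gpr import GPRRule
from .model import OrganelleModule, stoichiometric_matrix

__all__ = [
    "FluxSolution",
    "KnockoutResult",
    "PhasePlaneGrid",
    "optimize",
    "flux_at_objective_optimum",
    "evaluate_gpr",
    "single_gene_deletion_scan",
    "phase_plane",
    "solution_to_tsv",
]

#: numerical slack used when fixing the objective in the secondary LP
OBJECTIVE_FIX_TOL = 1e-7
#: below this absolute growth a knockout is lethal
LETHAL_TOL = 1e-6
#: a knockout with growth below (1 - REDUCED_TOL) * wildtype is "reduced"
REDUCED_TOL = 1e-3


@dataclass
class FluxSolution:
    status: str  # 'optimal' | 'infeasible' | 'unbounded'
    objective_value: Optional[float]
    fluxes: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class KnockoutResult:
    gene: str
    knockout_growth: float
    wildtype_growth: float
    classification: str  # 'lethal' | 'reduced' | 'neutral'


@dataclass
class PhasePlaneGrid:
    """Objective optima over a grid of two fixed-flux control reactions.

    ``matrix[i, j]`` is the optimum with axis A fixed at ``a_values[i]`` and
    axis B at ``b_values[j]``; NaN marks infeasible grid points.
    """

    axis_a: str
    axis_b: str
    a_values: np.ndarray
    b_values: np.ndarray
    matrix: np.ndarray


def _resolve_objective(model, objective):
    if objective is None:
        if model.objective_id is None:
            raise ValueError("model has no objective and none was given")
        return model.objective_id, model.objective_direction
    if isinstance(objective, tuple):
        rxn_id, direction = objective
    else:
        rxn_id, direction = objective, "max"
    model.get_reaction(rxn_id)  # existence check
    return rxn_id, direction


def _solve(S, bounds, c, sense, extra_A=None, extra_lb=None, extra_ub=None):
    """min/max c.v  s.t.  S.v = 0, bounds, optional extra row constraints."""
    n = S.shape[1]
    A_eq = S
    b_eq = np.zeros(S.shape[0])
    A_ub = None
    b_ub = None
    if extra_A is not None:
        rows = []
        rhs = []
        for row, lo, hi in zip(extra_A, extra_lb, extra_ub):
            if hi is not None:
                rows.append(row)
                rhs.append(hi)
            if lo is not None:
                rows.append([-x for x in row])
                rhs.append(-lo)
        if rows:
            A_ub = sparse.csr_matrix(np.asarray(rows, dtype=float))
            b_ub = np.asarray(rhs, dtype=float)
    obj = np.asarray(c, dtype=float)
    if sense == "max":
        obj = -obj
    res = linprog(
        obj,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if res.status == 0:
        value = float(res.fun)
        if sense == "max":
            value = -value
        return "optimal", value, np.asarray(res.x)
    if res.status == 3:
        return "unbounded", None, None
    return "infeasible", None, None


def optimize(model: OrganelleModule, objective=None, direction: Optional[str] = None) -> FluxSolution:
    """Solve the FBA problem; infeasible/unbounded are reported in
    ``status``, never raised.

    *objective* may be a reaction id, an ``(id, direction)`` tuple, or
    ``None`` to use the model's registered objective.
    """
    rxn_id, sense = _resolve_objective(model, objective)
    if direction is not None:
        sense = direction
    rxns = model.reactions
    S = stoichiometric_matrix(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in rxns]
    c = np.zeros(len(rxns))
    c[[i for i, r in enumerate(rxns) if r.id == rxn_id]] = 1.0
    status, value, x = _solve(S, bounds, c, sense)
    if status != "optimal":
        return FluxSolution(status=status, objective_value=None)
    return FluxSolution(
        status="optimal",
        objective_value=value,
        fluxes={r.id: float(x[i]) for i, r in enumerate(rxns)},
    )


def flux_at_objective_optimum(
    model: OrganelleModule,
    objective,
    probe: str,
    sense: str = "max",
) -> float:
    """Probe flux at the objective optimum (two-LP scheme).

    First the objective LP is solved; then the objective flux is pinned to
    its optimum (within a small numerical band) and the probe reaction's
    flux is maximized or minimized.  This resolves alternate-optima
    ambiguity when a single flux value is reported.
    """
    obj_id, obj_sense = _resolve_objective(model, objective)
    model.get_reaction(probe)
    first = optimize(model, (obj_id, obj_sense))
    if not first.ok:
        raise RuntimeError(f"objective LP is {first.status}; cannot probe fluxes")
    opt = first.objective_value
    rxns = model.reactions
    S = stoichiometric_matrix(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in rxns]
    obj_row = [1.0 if r.id == obj_id else 0.0 for r in rxns]
    tol = OBJECTIVE_FIX_TOL * max(1.0, abs(opt))
    c = np.zeros(len(rxns))
    c[[i for i, r in enumerate(rxns) if r.id == probe]] = 1.0
    status, value, _ = _solve(
        S,
        bounds,
        c,
        sense,
        extra_A=[obj_row],
        extra_lb=[opt - tol],
        extra_ub=[opt + tol],
    )
    if status != "optimal":  # pragma: no cover - fixed point is feasible by construction
        raise RuntimeError(f"probe LP is {status}")
    return value


def evaluate_gpr(rule: GPRRule, knocked: Iterable[str] = ()) -> bool:
    """Boolean GPR evaluation: knocked genes false, all other genes true;
    an empty rule is true."""
    return rule.evaluate(knocked)


def single_gene_deletion_scan(
    model: OrganelleModule,
    objective=None,
    lethal_tol: float = LETHAL_TOL,
    reduced_tol: float = REDUCED_TOL,
) -> list:
    """Knock out each gene in turn and classify the growth outcome.

    A reaction is disabled (bounds (0, 0)) whenever its GPR evaluates false
    under the knockout; bounds are restored after each gene.  Raises if the
    wildtype problem is not optimal (the scan is meaningless then).
    """
    genes = sorted(model.genes)
    if not genes:
        return []
    wt = optimize(model, objective)
    if not wt.ok:
        raise RuntimeError(f"wildtype optimization is {wt.status}; cannot scan")
    wt_growth = wt.objective_value
    results = []
    for gene in genes:
        knocked = {gene}
        affected = [
            r for r in model.reactions if r.gpr and not r.gpr.evaluate(knocked)
        ]
        saved = [(r, r.bounds) for r in affected]
        for r in affected:
            r.knock()
        sol = optimize(model, objective)
        for r, b in saved:
            r.bounds = b
        growth = sol.objective_value if sol.ok else 0.0
        if abs(growth) < lethal_tol:
            cls = "lethal"
        elif growth < (1.0 - reduced_tol) * wt_growth:
            cls = "reduced"
        else:
            cls = "neutral"
        results.append(
            KnockoutResult(
                gene=gene,
                knockout_growth=growth,
                wildtype_growth=wt_growth,
                classification=cls,
            )
        )
    return results


def phase_plane(
    model: OrganelleModule,
    objective,
    axis_a: tuple,
    axis_b: tuple,
) -> PhasePlaneGrid:
    """Phenotype phase plane over two fixed-flux control reactions.

    Each axis is ``(reaction_id, min, max, steps)``.  At every grid point
    both control reactions are pinned (lower = upper = grid value), the
    model re-optimized, and bounds restored; infeasible points are NaN.
    """
    id_a, lo_a, hi_a, n_a = axis_a
    id_b, lo_b, hi_b, n_b = axis_b
    ra = model.get_reaction(id_a)
    rb = model.get_reaction(id_b)
    a_values = np.linspace(lo_a, hi_a, int(n_a))
    b_values = np.linspace(lo_b, hi_b, int(n_b))
    matrix = np.full((len(a_values), len(b_values)), np.nan)
    saved = (ra.bounds, rb.bounds)
    try:
        for i, va in enumerate(a_values):
            ra.bounds = (va, va)
            for j, vb in enumerate(b_values):
                rb.bounds = (vb, vb)
                sol = optimize(model, objective)
                if sol.ok:
                    matrix[i, j] = sol.objective_value
    finally:
        ra.bounds, rb.bounds = saved
    return PhasePlaneGrid(
        axis_a=id_a, axis_b=id_b, a_values=a_values, b_values=b_values, matrix=matrix
    )


def solution_to_tsv(solution: FluxSolution, path) -> None:
    """Write a flux table (reaction id, flux) as TSV."""
    with open(path, "w") as fh:
        fh.write("reaction\tflux\n")
        for rxn_id, flux in solution.fluxes.items():
            fh.write(f"{rxn_id}\t{flux:.10g}\n")
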