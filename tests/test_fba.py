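"""FBA engine: LP correctness against a vertex-enumeration oracle,
objective-fixed flux probing, knockout scans, and phase planes."""

from itertools import combinations, product

import numpy as np
import pytest

from chloromod import (
    GPRRule,
    OrganelleModule,
    flux_at_objective_optimum,
    optimize,
    phase_plane,
    single_gene_deletion_scan,
)

TRIOSE_OPT = 125.0 / 3.0


# -- brute-force LP oracle --------------------------------------------------


def brute_force_lp(S, lb, ub, c, sense="max"):
    """Enumerate candidate vertices of {v : S v = 0, lb <= v <= ub} and take
    the best objective.  Valid for bounded polytopes (finite bounds): every
    optimum is attained at a vertex, and every vertex fixes enough variables
    at bounds to make the remaining equality system uniquely solvable."""
    S = np.asarray(S, dtype=float)
    n = S.shape[1]
    best = None
    for k in range(n + 1):
        for fixed in combinations(range(n), k):
            free = [j for j in range(n) if j not in fixed]
            for pattern in product(*[(lb[j], ub[j]) for j in fixed]):
                v = np.zeros(n)
                for j, val in zip(fixed, pattern):
                    v[j] = val
                if free:
                    A = S[:, free]
                    rhs = -S[:, fixed] @ np.asarray(pattern) if fixed else np.zeros(S.shape[0])
                    if np.linalg.matrix_rank(A) < len(free):
                        continue  # not a vertex: free part underdetermined
                    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                    for j, val in zip(free, sol):
                        v[j] = val
                if np.max(np.abs(S @ v)) > 1e-8:
                    continue
                if np.any(v < np.asarray(lb) - 1e-8) or np.any(v > np.asarray(ub) + 1e-8):
                    continue
                value = float(np.dot(c, v))
                if best is None or (value > best if sense == "max" else value < best):
                    best = value
    return best


def _model_from_matrix(S, lb, ub):
    m = OrganelleModule(id="rand", compartments={"c": "cytosol"})
    S = np.asarray(S)
    for i in range(S.shape[0]):
        m.new_metabolite(f"m{i}", compartment="c")
    for j in range(S.shape[1]):
        st = {f"m{i}": float(S[i, j]) for i in range(S.shape[0]) if S[i, j] != 0}
        m.new_reaction(f"r{j}", st, lower_bound=lb[j], upper_bound=ub[j])
    return m


def test_optimize_matches_vertex_enumeration_oracle():
    """On random <=6-reaction networks with finite integer bounds, the LP
    objective equals exhaustive vertex enumeration to 1e-6."""
    rng = np.random.default_rng(4242)
    for trial in range(25):
        n = int(rng.integers(2, 7))
        mrows = int(rng.integers(1, 4))
        S = rng.integers(-2, 3, size=(mrows, n))
        lb = [float(rng.integers(-2, 1)) for _ in range(n)]
        ub = [float(lb[j] + rng.integers(0, 4)) for j in range(n)]
        c = np.zeros(n)
        c[int(rng.integers(0, n))] = 1.0
        model = _model_from_matrix(S, lb, ub)
        obj_rxn = f"r{int(np.argmax(c))}"
        sol = optimize(model, (obj_rxn, "max"))
        expected = brute_force_lp(S, lb, ub, c, "max")
        # bounds may exclude the origin, making the box-and-steady-state
        # polytope empty; the oracle then finds no vertex at all
        assert (sol.status == "optimal") == (expected is not None), trial
        if expected is not None:
            assert sol.objective_value == pytest.approx(expected, abs=1e-6), trial


# -- direct contracts -------------------------------------------------------


def test_mini_model_triose_optimum(mini_model):
    sol = optimize(mini_model)
    assert sol.ok
    assert sol.objective_value == pytest.approx(TRIOSE_OPT, rel=1e-9)


def test_steady_state_and_bounds_hold_at_optimum(mini_model):
    sol = optimize(mini_model)
    S = mini_model.stoichiometric_matrix().toarray()
    v = np.array([sol.fluxes[r.id] for r in mini_model.reactions])
    assert np.max(np.abs(S @ v)) < 1e-6
    for r in mini_model.reactions:
        assert r.lower_bound - 1e-6 <= sol.fluxes[r.id] <= r.upper_bound + 1e-6


def test_zero_bounded_objective_gives_zero(mini_model):
    mini_model.get_reaction("B_dhap_c").bounds = (0.0, 0.0)
    sol = optimize(mini_model)
    assert sol.ok and sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_unproducible_objective_metabolite_gives_zero():
    m = OrganelleModule(id="t", compartments={"c": "cytosol"})
    m.new_metabolite("orphan", compartment="c")
    m.new_reaction("sink", {"orphan": -1}, lower_bound=0.0)
    sol = optimize(m, ("sink", "max"))
    assert sol.ok and sol.objective_value == pytest.approx(0.0, abs=1e-12)


def test_infeasible_status_is_reported_not_raised():
    m = OrganelleModule(id="t", compartments={"c": "cytosol"})
    m.new_metabolite("x", compartment="c")
    m.new_reaction("forced_in", {"x": +1}, lower_bound=1.0, upper_bound=1.0)
    m.new_reaction("no_out", {"x": -1}, lower_bound=0.0, upper_bound=0.0)
    sol = optimize(m, ("forced_in", "max"))
    assert sol.status == "infeasible"
    assert sol.objective_value is None


def test_relaxing_an_upper_bound_never_decreases_the_optimum(mini_model):
    base = optimize(mini_model).objective_value
    mini_model.get_reaction("photon_import").bounds = (0.0, 1500.0)
    assert optimize(mini_model).objective_value >= base - 1e-9


def test_probe_is_objective_itself(mini_model):
    value = flux_at_objective_optimum(mini_model, None, "B_dhap_c", "max")
    assert value == pytest.approx(TRIOSE_OPT, rel=1e-6)


def test_probe_fluxes_at_mini_model_optimum(mini_model):
    rubisco = flux_at_objective_optimum(mini_model, None, "RuBisCO_carboxylation", "max")
    psii = flux_at_objective_optimum(mini_model, None, "PSII_photon", "max")
    cyclic = flux_at_objective_optimum(mini_model, None, "cyclic_electron_transport", "max")
    assert rubisco == pytest.approx(125.0, rel=1e-5)
    assert psii == pytest.approx(500.0, rel=1e-5)
    assert cyclic == pytest.approx(0.0, abs=1e-4)


def test_mini_model_agrees_with_cobra_oracle(mini_model, tmp_path):
    """Dual-route check: the same model solved by cobrapy (GLPK) gives the
    same optimum as our HiGHS-based engine."""
    cobra = pytest.importorskip("cobra")
    from chloromod import write_sbml

    path = tmp_path / "mini.xml"
    write_sbml(mini_model, str(path))
    cb = cobra.io.read_sbml_model(str(path))
    sol = cb.optimize()
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(
        optimize(mini_model).objective_value, rel=1e-6
    )


# -- knockout scan ----------------------------------------------------------


def _knockout_fixture():
    m = OrganelleModule(id="ko", compartments={"c": "cytosol"})
    for mid in ("s", "atp", "b", "dead"):
        m.new_metabolite(mid, compartment="c")
    m.new_reaction("src", {"s": +1}, lower_bound=0.0, upper_bound=10.0)
    m.new_reaction(
        "atp_synthase", {"s": -1, "atp": +1}, lower_bound=0.0,
        gpr=GPRRule.from_string("gX and gY"),
    )
    m.new_reaction(
        "alt_path", {"s": -1, "atp": +1}, lower_bound=0.0, upper_bound=0.0,
        gpr=GPRRule.from_string("gAlt"),
    )
    m.new_reaction("grow", {"atp": -1, "b": +1}, lower_bound=0.0)
    m.new_reaction(
        "dead_end", {"dead": +1}, lower_bound=0.0, upper_bound=0.0,
        gpr=GPRRule.from_string("gDead"),
    )
    m.new_reaction("sink_b", {"b": -1}, lower_bound=0.0)
    m.set_objective("sink_b", "max")
    return m


def test_single_gene_deletion_classification():
    results = {r.gene: r for r in single_gene_deletion_scan(_knockout_fixture())}
    assert results["gX"].classification == "lethal"  # sole AND-gene of the ATP source
    assert results["gY"].classification == "lethal"
    assert results["gDead"].classification == "neutral"  # isolated dead end
    assert results["gAlt"].classification == "neutral"
    assert results["gX"].wildtype_growth == pytest.approx(10.0)


def test_scan_restores_bounds():
    m = _knockout_fixture()
    before = {r.id: r.bounds for r in m.reactions}
    single_gene_deletion_scan(m)
    assert {r.id: r.bounds for r in m.reactions} == before


def test_scan_without_gprs_returns_all_neutral():
    m = _knockout_fixture()
    for r in m.reactions:
        r.gpr = GPRRule()
    assert single_gene_deletion_scan(m) == []


def test_scan_requires_feasible_wildtype():
    m = _knockout_fixture()
    m.get_reaction("sink_b").bounds = (5.0, 10.0)
    m.get_reaction("src").bounds = (0.0, 0.0)
    with pytest.raises(RuntimeError):
        single_gene_deletion_scan(m)


# -- phase plane ------------------------------------------------------------


def test_phase_plane_corner_cases(mini_model):
    grid = phase_plane(
        mini_model,
        None,
        ("PSII_photon", 0.0, 500.0, 2),
        ("RuBisCO_carboxylation", 0.0, 125.0, 2),
    )
    assert grid.matrix.shape == (2, 2)
    # no light, no fixation -> zero growth
    assert grid.matrix[0, 0] == pytest.approx(0.0, abs=1e-9)
    # fixation without light is stoichiometrically impossible
    assert np.isnan(grid.matrix[0, 1])
    # the unconstrained optimizer's operating point recovers the optimum
    assert grid.matrix[1, 1] == pytest.approx(TRIOSE_OPT, rel=1e-6)


def test_phase_plane_restores_bounds(mini_model):
    before = {r.id: r.bounds for r in mini_model.reactions}
    phase_plane(mini_model, None, ("PSII_photon", 0, 500, 2), ("RuBisCO_carboxylation", 0, 125, 2))
    assert {r.id: r.bounds for r in mini_model.reactions} == before


def test_phase_plane_axis_swap_transposes(mini_model):
    a = ("PSII_photon", 0.0, 500.0, 3)
    b = ("RuBisCO_carboxylation", 0.0, 125.0, 4)
    g1 = phase_plane(mini_model, None, a, b)
    g2 = phase_plane(mini_model, None, b, a)
    assert np.allclose(g1.matrix, g2.matrix.T, equal_nan=True)
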