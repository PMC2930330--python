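"""Flux balance analysis: the steady-state LP and derived analyses.

FBA maximizes the flux through an objective reaction (here the biomass
demand reaction, so the optimum is the specific growth rate in h⁻¹)
subject to S·v = 0 and per-reaction bounds.  The LP is solved with the
HiGHS solvers behind :func:`scipy.optimize.linprog`, which is
deterministic for fixed inputs.

Only the objective value is contract-stable: the flux vector of a
degenerate LP may be any optimal vertex.  :func:`flux_variability` can
certify which individual fluxes are unique at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import Medium, MetabolicModel, apply_medium, stoichiometric_matrix

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-7


class SolverError(RuntimeError):
    """Raised when the LP solver fails for a reason other than infeasibility."""


@dataclass
class FluxSolution:
    """Optimal flux vector + objective value + solver status."""

    objective: float
    status: str  # optimal / infeasible / unbounded
    fluxes: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class RobustnessCurve:
    """Objective value as a function of one scanned exchange bound."""

    parameter: str
    grid: np.ndarray
    objective: np.ndarray

    def limiting_breakpoint(self) -> float:
        """Smallest grid value at which the objective reaches its plateau."""
        plateau = self.objective[-1]
        for g, obj in zip(self.grid, self.objective):
            if obj >= plateau * (1 - 1e-6):
                return float(g)
        return float(self.grid[-1])


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded"}


def solve_fba(
    model: MetabolicModel,
    medium: Medium | dict | None = None,
    objective_rxn_id: str | None = None,
    maximize: bool = True,
) -> FluxSolution:
    """Solve the FBA LP; returns the solution or a non-optimal status.

    Solver failure is propagated as a status / exception, never as silent
    zero fluxes.
    """
    if medium is not None:
        model = apply_medium(model, medium)
    obj_id = objective_rxn_id or model.objective_rxn_id
    if obj_id is None or obj_id not in model.reactions:
        raise ValueError(f"objective reaction {obj_id!r} not in model")

    S, _met_index, rxn_index = stoichiometric_matrix(model)
    n = len(rxn_index)
    c = np.zeros(n)
    c[rxn_index[obj_id]] = -1.0 if maximize else 1.0
    bounds = [(r.lb, r.ub) for r in model.reactions.values()]

    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": OPTIMALITY_TOL},
    )
    status = _STATUS.get(res.status, "failed")
    if status in ("failed", "iteration limit"):
        raise SolverError(f"LP solver failure: {res.message}")
    if status != "optimal":
        return FluxSolution(objective=float("nan"), status=status)
    fluxes = {rxn_id: float(res.x[j]) for rxn_id, j in rxn_index.items()}
    objective = fluxes[obj_id]
    return FluxSolution(objective=objective, status="optimal", fluxes=fluxes)


def knockout(
    model: MetabolicModel,
    genes: set[str] | frozenset[str],
    medium: Medium | dict | None = None,
) -> FluxSolution:
    """Re-solve FBA with the given genes deleted.

    Every reaction whose GPR evaluates inactive under the knockout gets
    bounds (0, 0); non-gene-associated reactions are untouched.
    """
    missing = set(genes) - set(model.genes)
    if missing:
        raise KeyError(f"unknown genes: {sorted(missing)}")
    ko = model.copy()
    for rxn in ko.reactions.values():
        if not rxn.gpr.empty and not rxn.gpr.is_active(genes):
            rxn.lb, rxn.ub = 0.0, 0.0
    return solve_fba(ko, medium=medium)


def robustness_scan(
    model: MetabolicModel,
    medium: Medium | dict,
    exchange_id: str,
    uptake_grid,
) -> RobustnessCurve:
    """Objective as a function of the uptake allowance of one exchange.

    Grid values are uptake allowances (non-negative); each grid point sets
    ``lb = -value`` on the exchange and re-optimizes.
    """
    grid = np.asarray(uptake_grid, dtype=float)
    base = apply_medium(model, medium)
    if exchange_id not in base.reactions:
        raise KeyError(f"unknown exchange {exchange_id!r}")
    objective = np.empty_like(grid)
    for i, allowance in enumerate(grid):
        scan = base.copy()
        scan.reactions[exchange_id].lb = -abs(float(allowance))
        sol = solve_fba(scan)
        objective[i] = sol.objective if sol.optimal else 0.0
    return RobustnessCurve(parameter=exchange_id, grid=grid, objective=objective)


def gross_carbon_imports(
    solution: FluxSolution, model: MetabolicModel, tol: float = 1e-9
) -> dict[str, float]:
    """Gross imported carbon (mmol C/gDCW/h) per carbon-importing exchange."""
    if not solution.optimal:
        raise ValueError("carbon accounting requires an optimal solution")
    imports: dict[str, float] = {}
    for rxn in model.exchanges():
        (met_id,) = rxn.stoich.keys()
        met = model.metabolites[met_id]
        flux = solution.fluxes.get(rxn.rxn_id, 0.0)
        if flux >= -tol:
            continue  # not a net importer
        n_carbon = met.elements().get("C", 0.0)  # raises if formula missing
        if n_carbon == 0.0:
            continue
        imports[rxn.rxn_id] = -flux * n_carbon
    return imports


def carbon_fractions(
    solution: FluxSolution,
    model: MetabolicModel,
    tol: float = 1e-9,
) -> dict[str, float]:
    """Mole fraction of assimilated (biomass) carbon per carbon source.

    Each import exchange is a source injecting ``uptake × C-atoms`` of
    carbon; active reactions propagate carbon from the metabolites they
    consume to the carbon-bearing metabolites they produce under a
    well-mixed-pool assumption, giving a linear mixing system for the
    per-metabolite source composition.  The reported fractions are the
    source composition of the carbon consumed by the biomass (demand)
    reaction.  Carbon that merely passes through — e.g. a chlorinated
    electron acceptor imported and re-secreted one chlorine down — never
    reaches the biomass and therefore contributes nothing, which is why
    this attribution, rather than a gross exchange-flux ratio, reproduces
    the "fraction of carbon fixed into biomass" reading.
    """
    imports = gross_carbon_imports(solution, model, tol=tol)
    if not imports:
        return {}
    sources = sorted(imports)
    source_index = {s: k for k, s in enumerate(sources)}
    carbons = {
        met_id: met.elements().get("C", 0.0) if met.formula is not None else 0.0
        for met_id, met in model.metabolites.items()
    }
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    n_mets, n_src = len(met_index), len(sources)

    # inflow[j] = total carbon flowing into pool j; A x = b mixing system
    inflow = np.zeros(n_mets)
    inject = np.zeros((n_mets, n_src))  # direct injections from exchanges
    flows: list[tuple[list[tuple[int, float]], list[tuple[int, float]]]] = []

    for rxn in model.reactions.values():
        v = solution.fluxes.get(rxn.rxn_id, 0.0)
        if abs(v) <= tol:
            continue
        if rxn.kind == "exchange":
            if rxn.rxn_id in imports:
                (met_id,) = rxn.stoich.keys()
                j = met_index[met_id]
                inflow[j] += imports[rxn.rxn_id]
                inject[j, source_index[rxn.rxn_id]] += imports[rxn.rxn_id]
            continue
        consumed: list[tuple[int, float]] = []
        produced: list[tuple[int, float]] = []
        for met_id, coeff in rxn.stoich.items():
            rate = coeff * v  # >0 produced, <0 consumed (handles reversals)
            carbon = carbons[met_id]
            if carbon == 0.0:
                continue
            if rate < -tol:
                consumed.append((met_index[met_id], -rate * carbon))
            elif rate > tol:
                produced.append((met_index[met_id], rate * carbon))
        if consumed and produced:
            flows.append((consumed, produced))
            for j, c_out in produced:
                inflow[j] += c_out

    A = np.eye(n_mets * n_src)
    b = np.zeros(n_mets * n_src)
    for j in range(n_mets):
        if inflow[j] <= tol:
            continue  # pool without carbon inflow: composition stays zero
        b[j * n_src:(j + 1) * n_src] = inject[j] / inflow[j]
    for consumed, produced in flows:
        c_total = sum(c for _, c in consumed)
        for j, c_out in produced:
            if inflow[j] <= tol:
                continue
            w_out = c_out / inflow[j]
            for i, c_in in consumed:
                w = w_out * c_in / c_total
                for k in range(n_src):
                    A[j * n_src + k, i * n_src + k] -= w
    x = np.linalg.lstsq(A, b, rcond=None)[0].reshape(n_mets, n_src)

    bio = model.objective
    totals = np.zeros(n_src)
    v_bio = solution.fluxes.get(bio.rxn_id, 0.0)
    for met_id, coeff in bio.stoich.items():
        rate = coeff * v_bio
        carbon = carbons[met_id]
        if rate < -tol and carbon > 0.0:
            totals += (-rate * carbon) * x[met_index[met_id]]
    grand = totals.sum()
    if grand <= 0:
        return {}
    return {s: float(totals[k] / grand) for s, k in source_index.items()}


def flux_variability(
    model: MetabolicModel,
    medium: Medium | dict | None = None,
    reactions: list[str] | None = None,
    fraction_of_optimum: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Min/max flux per reaction with the objective held at its optimum.

    A plumbing utility to certify flux uniqueness where analyses need it
    (a reaction is unique at the optimum iff min == max).
    """
    if medium is not None:
        model = apply_medium(model, medium)
    base = solve_fba(model)
    if not base.optimal:
        raise SolverError(f"FVA base problem not optimal: {base.status}")
    fixed = model.copy()
    obj = fixed.objective
    obj.lb = base.objective * fraction_of_optimum - FEASIBILITY_TOL
    targets = reactions if reactions is not None else list(fixed.reactions)
    out: dict[str, tuple[float, float]] = {}
    for rxn_id in targets:
        lo = solve_fba(fixed, objective_rxn_id=rxn_id, maximize=False)
        hi = solve_fba(fixed, objective_rxn_id=rxn_id, maximize=True)
        out[rxn_id] = (lo.objective, hi.objective)
    return out
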