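"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the LP oracle
enumerates basic solutions directly, the carbon oracle propagates source
fractions by fixed-point iteration, and the GPR oracle evaluates the rule
text with Python's own boolean operators.
"""

from __future__ import annotations

import itertools

import numpy as np

from panfba.model import MetabolicModel, stoichiometric_matrix


def vertex_enumeration_optimum(model: MetabolicModel) -> float | None:
    """Max objective flux over all vertices of {v: Sv=0, lb<=v<=ub}.

    Every vertex has at least n - rank(S) variables at a bound; we try all
    ways of pinning n - m variables to a bound and solving the remaining
    square-ish system, keeping feasible solutions.  Exponential, fine for
    n <= 8.  Returns None when no vertex is feasible (cannot happen when
    0 is within all bounds).
    """
    S, _mets, rxns = stoichiometric_matrix(model)
    m_eq, n = S.shape
    lb = np.array([r.lb for r in model.reactions.values()])
    ub = np.array([r.ub for r in model.reactions.values()])
    c = np.zeros(n)
    c[list(rxns).index(model.objective_rxn_id)] = 1.0

    best: float | None = None
    tol = 1e-7
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_free = min(rank, n)
    for free in itertools.combinations(range(n), n_free):
        fixed = [j for j in range(n) if j not in free]
        for pattern in itertools.product((0, 1), repeat=len(fixed)):
            v = np.empty(n)
            for j, at_ub in zip(fixed, pattern):
                v[j] = ub[j] if at_ub else lb[j]
            if n_free:
                A = S[:, list(free)]
                rhs = -S[:, fixed] @ v[fixed] if fixed else np.zeros(m_eq)
                sol, residual, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                v[list(free)] = sol
            if np.max(np.abs(S @ v)) > 1e-6:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    return best


def carbon_fractions_power_iteration(
    solution, model: MetabolicModel, n_iter: int = 2000, tol: float = 1e-12
) -> dict[str, float]:
    """Biomass carbon attribution by fixed-point propagation.

    Repeatedly recomputes each carbon pool's source composition from the
    compositions of the pools feeding it until convergence — the
    brute-force counterpart of the linear-solve implementation.
    """
    from panfba.fba import gross_carbon_imports

    imports = gross_carbon_imports(solution, model)
    sources = sorted(imports)
    carbons = {
        met_id: (met.elements().get("C", 0.0) if met.formula is not None else 0.0)
        for met_id, met in model.metabolites.items()
    }
    x = {met_id: np.zeros(len(sources)) for met_id in model.metabolites}

    active = []
    for rxn in model.reactions.values():
        v = solution.fluxes.get(rxn.rxn_id, 0.0)
        if abs(v) <= 1e-9 or rxn.kind == "exchange":
            continue
        consumed = [(m, -coeff * v * carbons[m]) for m, coeff in rxn.stoich.items()
                    if coeff * v < -1e-9 and carbons[m] > 0]
        produced = [(m, coeff * v * carbons[m]) for m, coeff in rxn.stoich.items()
                    if coeff * v > 1e-9 and carbons[m] > 0]
        if consumed and produced:
            active.append((consumed, produced))

    inject = {m: np.zeros(len(sources)) for m in model.metabolites}
    inflow = {m: 0.0 for m in model.metabolites}
    for k, ex in enumerate(sources):
        (met_id,) = model.reactions[ex].stoich.keys()
        inject[met_id][k] += imports[ex]
        inflow[met_id] += imports[ex]
    for consumed, produced in active:
        for met_id, c_out in produced:
            inflow[met_id] += c_out

    for _ in range(n_iter):
        new = {m: inject[m].copy() for m in x}
        for consumed, produced in active:
            c_total = sum(c for _, c in consumed)
            mix = sum((c / c_total) * x[m] for m, c in consumed)
            for met_id, c_out in produced:
                new[met_id] += c_out * mix
        delta = 0.0
        for met_id in x:
            if inflow[met_id] > 0:
                new[met_id] /= inflow[met_id]
            else:
                new[met_id][:] = 0.0
            delta = max(delta, float(np.max(np.abs(new[met_id] - x[met_id]))))
        x = new
        if delta < tol:
            break

    bio = model.objective
    v_bio = solution.fluxes[bio.rxn_id]
    totals = np.zeros(len(sources))
    for met_id, coeff in bio.stoich.items():
        rate = coeff * v_bio
        if rate < -1e-12 and carbons[met_id] > 0:
            totals += (-rate * carbons[met_id]) * x[met_id]
    if totals.sum() <= 0:
        return {}
    return {s: float(t / totals.sum()) for s, t in zip(sources, totals)}


def gpr_truth_table_active(rule: str, knocked_out: set[str], genes: set[str]) -> bool:
    """Evaluate a GPR rule string with Python's own boolean machinery."""
    if not rule.strip():
        return True
    expr = rule
    # longest-first replacement so gene names that prefix each other are safe
    for gene in sorted(genes, key=len, reverse=True):
        expr = expr.replace(gene, "True" if gene not in knocked_out else "False")
    return bool(eval(expr.lower(), {"__builtins__": {}}, {"true": True, "false": False}))
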