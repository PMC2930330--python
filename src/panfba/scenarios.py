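"""Growth-scenario pipelines over a constraint-based model.

Each scenario reproduces one of the classic *Dehalococcoides* growth
experiments in silico: the citrate-synthase topology comparison, the
cobalamin salvage/fraction surface, the de novo cobalamin synthesis cost,
amino-acid supplementation, hydrogen-flux scaling and the acetate ×
energy-transfer-efficiency yield grid.  Results carry both growth rate
(h⁻¹) and yield (gDCW per eeq of donor) plus a provenance block so any
row can be recomputed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomass import (
    EnergyConfig,
    growth_yield,
    max_atp_per_h2,
    rescale_cobalamin,
)
from .fba import FluxSolution, solve_fba
from .model import DEFAULT_BOUND, Medium, MetabolicModel, Reaction, apply_medium

#: the seven amino acids opened individually in the supplementation figure
SINGLE_SUPPLEMENT_AA = ("tyr", "glu", "gln", "gly", "ala", "thr", "asp")

YIELD_CONVENTION = "gDCW per eeq of H2 donor (2 eeq per mmol H2)"


@dataclass
class ScenarioResult:
    """Tidy per-condition table (+ optional grid) with provenance."""

    name: str
    table: pd.DataFrame
    grid: np.ndarray | None = None
    axes: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    yield_convention: str = YIELD_CONVENTION


def _provenance(model: MetabolicModel, medium, **params) -> dict:
    digest = hashlib.sha1(model.to_json().encode()).hexdigest()[:12]
    return {
        "model_id": model.model_id,
        "model_hash": digest,
        "medium": {k: list(v) for k, v in Medium.from_dict(dict(medium)).items()},
        "parameters": params,
    }


def _solve_row(
    model: MetabolicModel, medium, donor: str = "EX_h2_e"
) -> tuple[FluxSolution, float, float]:
    sol = solve_fba(model, medium=medium)
    if not sol.optimal:
        return sol, 0.0, 0.0
    mu = sol.objective
    if mu <= 0:
        return sol, 0.0, 0.0
    y = growth_yield(sol, model, donor_exchange_id=donor).yield_gdcw_per_eeq
    return sol, mu, y


def cs_comparison(
    model: MetabolicModel,
    medium,
    cs_reaction: Reaction | str = "CS",
    reductive_rxn_ids: tuple[str, ...] = ("RTCA",),
    disable_reductive_with_cs: bool = True,
) -> ScenarioResult:
    """Growth with vs. without the citrate-synthase (oxidative) route.

    In the "without CS" arm the 2-oxoglutarate precursor comes through the
    reductive TCA arm; in the "with CS" arm the CS lump is opened and the
    reductive-arm reactions (succinyl-CoA synthetase / 2-oxoglutarate
    synthase lump) are optionally closed, mirroring the oxidative-topology
    reading of the isotope-labelling evidence.  Both arms are reported
    explicitly rather than asserting which one is "the" model.
    """
    without = model.copy()
    if isinstance(cs_reaction, str):
        if cs_reaction in without.reactions:
            without.reactions[cs_reaction].lb = 0.0
            without.reactions[cs_reaction].ub = 0.0
        cs_id = cs_reaction
        with_cs = model.copy()
        if cs_id not in with_cs.reactions:
            raise KeyError(f"model has no reaction {cs_id!r} to toggle")
        with_cs.reactions[cs_id].lb = 0.0
        with_cs.reactions[cs_id].ub = DEFAULT_BOUND
    else:
        cs_id = cs_reaction.rxn_id
        with_cs = model.copy()
        with_cs.add_reaction(cs_reaction.copy())
    if disable_reductive_with_cs:
        for rid in reductive_rxn_ids:
            if rid in with_cs.reactions:
                with_cs.reactions[rid].lb = 0.0
                with_cs.reactions[rid].ub = 0.0

    rows = []
    for label, arm in (("without_CS", without), ("with_CS", with_cs)):
        _sol, mu, y = _solve_row(arm, medium)
        rows.append({"condition": label, "growth_rate": mu, "yield": y})
    return ScenarioResult(
        name="citrate_synthase_comparison",
        table=pd.DataFrame(rows),
        provenance=_provenance(model, medium, cs_reaction=cs_id,
                               disable_reductive_with_cs=disable_reductive_with_cs),
    )


def _with_cobalamin_fraction(model: MetabolicModel, multiplier: float) -> MetabolicModel:
    """Rebuild the biomass for a cobalamin-fraction multiplier.

    Uses the attached composition when available, otherwise scales the
    cobalamin coefficient of the biomass reaction directly.
    """
    from .biomass import assemble_biomass  # deferred: cycle

    new = model.copy()
    comp = new.meta.get("biomass_composition")
    bio = new.objective
    if comp is not None:
        comp2 = rescale_cobalamin(comp, multiplier)
        rebuilt = assemble_biomass(
            comp2, float(new.meta.get("gam", 0.0)), rxn_id=bio.rxn_id, model=new,
            currency=new.meta.get("currency"),
        )
        bio.stoich = rebuilt.stoich
        new.meta["biomass_composition"] = comp2
    else:
        cbl = next((m for m in bio.stoich if "cbl" in m.lower()), None)
        if cbl is None:
            raise KeyError("biomass reaction has no cobalamin term to rescale")
        bio.stoich[cbl] *= multiplier
    return new


def cobalamin_surface(
    model: MetabolicModel,
    medium,
    salvage_grid,
    fraction_multipliers,
    salvage_exchange: str = "EX_cbl1_e",
) -> ScenarioResult:
    """Growth rate over (cobalamin fraction multiplier × salvage rate).

    For each biomass cobalamin fraction the growth rate is zero below the
    stoichiometric salvage minimum (μ × cobalamin coefficient) and
    plateaus above it; the limiting salvage rate therefore grows with the
    fraction.
    """
    salvage_grid = np.asarray(salvage_grid, dtype=float)
    fraction_multipliers = np.asarray(fraction_multipliers, dtype=float)
    grid = np.zeros((len(fraction_multipliers), len(salvage_grid)))
    rows = []
    for i, mult in enumerate(fraction_multipliers):
        scaled = _with_cobalamin_fraction(model, float(mult))
        base = apply_medium(scaled, medium)
        for j, salvage in enumerate(salvage_grid):
            scan = base.copy()
            scan.reactions[salvage_exchange].lb = -abs(float(salvage))
            sol = solve_fba(scan)
            mu = sol.objective if sol.optimal else 0.0
            grid[i, j] = max(mu, 0.0)
            rows.append({"fraction_multiplier": float(mult),
                         "salvage_rate": float(salvage), "growth_rate": grid[i, j]})
    return ScenarioResult(
        name="cobalamin_robustness_surface",
        table=pd.DataFrame(rows),
        grid=grid,
        axes={"fraction_multiplier": fraction_multipliers, "salvage_rate": salvage_grid},
        provenance=_provenance(model, medium, salvage_exchange=salvage_exchange),
    )


def denovo_cost(
    model: MetabolicModel,
    medium,
    denovo_rxn_ids: tuple[str, ...] = ("CBLDN", "COBALTt"),
    cobalt_exchange: str = "EX_cobalt2_e",
    salvage_exchange: str = "EX_cbl1_e",
    fraction_multipliers=(1.0, 10.0),
) -> ScenarioResult:
    """Yield of salvage-only vs. de-novo-only cobalamin provisioning.

    The de novo arm closes cobalamin uptake, opens the cobalt source and
    the lumped synthesis pathway; the penalty is the ATP/precursor cost of
    synthesis and grows with the biomass cobalamin fraction.
    """
    missing = [r for r in denovo_rxn_ids if r not in model.reactions]
    if missing or cobalt_exchange not in model.reactions:
        raise KeyError(
            f"model lacks the de novo pathway pieces: {missing or cobalt_exchange}"
        )
    rows = []
    for mult in fraction_multipliers:
        scaled = _with_cobalamin_fraction(model, float(mult))
        base = apply_medium(scaled, medium)

        salvage = base.copy()
        for rid in denovo_rxn_ids:
            salvage.reactions[rid].lb = 0.0
            salvage.reactions[rid].ub = 0.0
        _s, mu_s, y_s = _solve_row(salvage, dict_of(salvage))

        denovo = base.copy()
        denovo.reactions[salvage_exchange].lb = 0.0
        denovo.reactions[cobalt_exchange].lb = -DEFAULT_BOUND
        _d, mu_d, y_d = _solve_row(denovo, dict_of(denovo))

        for arm, mu, y in (("salvage", mu_s, y_s), ("de_novo", mu_d, y_d)):
            rows.append({"fraction_multiplier": float(mult), "arm": arm,
                         "growth_rate": mu, "yield": y})
    return ScenarioResult(
        name="denovo_cobalamin_cost",
        table=pd.DataFrame(rows),
        provenance=_provenance(model, medium,
                               fraction_multipliers=list(fraction_multipliers)),
    )


def dict_of(model: MetabolicModel) -> dict:
    """Current exchange bounds of a model as a medium dict (identity medium)."""
    return {r.rxn_id: (r.lb, r.ub) for r in model.exchanges()}


def supplementation_yield(
    model: MetabolicModel,
    medium,
    aa_exchange_ids: tuple[str, ...] | None = None,
    h2_flux: float = 10.0,
    h2_exchange: str = "EX_h2_e",
) -> ScenarioResult:
    """Yields with single amino-acid supplements and with all at once.

    "Unlimited" supplement flux is the package's infinity convention
    (lb = −1000) on each amino-acid exchange, with H₂ uptake fixed.
    """
    if aa_exchange_ids is None:
        aa_exchange_ids = tuple(
            f"EX_{aa}_e" for aa in SINGLE_SUPPLEMENT_AA
            if f"EX_{aa}_e" in model.reactions
        )
    missing = [e for e in aa_exchange_ids if e not in model.reactions]
    if missing:
        raise KeyError(f"model lacks amino-acid exchanges: {missing}")
    base = apply_medium(model, medium)
    base.reactions[h2_exchange].lb = -abs(h2_flux)

    rows = []
    _b, mu0, y0 = _solve_row(base, dict_of(base))
    rows.append({"condition": "minimal_medium", "growth_rate": mu0, "yield": y0})
    for ex in aa_exchange_ids:
        arm = base.copy()
        arm.reactions[ex].lb = -DEFAULT_BOUND
        _a, mu, y = _solve_row(arm, dict_of(arm))
        rows.append({"condition": ex, "growth_rate": mu, "yield": y})
    all_arm = base.copy()
    for ex in aa_exchange_ids:
        all_arm.reactions[ex].lb = -DEFAULT_BOUND
    _a, mu, y = _solve_row(all_arm, dict_of(all_arm))
    rows.append({"condition": "all_amino_acids", "growth_rate": mu, "yield": y})
    return ScenarioResult(
        name="amino_acid_supplementation",
        table=pd.DataFrame(rows),
        provenance=_provenance(model, medium, h2_flux=h2_flux,
                               aa_exchange_ids=list(aa_exchange_ids)),
    )


def h2_scaling(
    model: MetabolicModel,
    medium,
    h2_fluxes=(10.0, 20.0),
    h2_exchange: str = "EX_h2_e",
) -> ScenarioResult:
    """Yield per H₂ allowance with the NGAM held fixed.

    With a positive NGAM the maintenance tax is diluted at higher donor
    flux, so the yield rises; with NGAM = 0 the LP is homogeneous and the
    yield is flux-invariant.
    """
    base = apply_medium(model, medium)
    rows = []
    for flux in h2_fluxes:
        if flux <= 0:
            raise ValueError("H2 fluxes must be positive")
        arm = base.copy()
        arm.reactions[h2_exchange].lb = -abs(float(flux))
        _a, mu, y = _solve_row(arm, dict_of(arm))
        rows.append({"h2_flux": float(flux), "growth_rate": mu, "yield": y})
    return ScenarioResult(
        name="h2_flux_scaling",
        table=pd.DataFrame(rows),
        provenance=_provenance(model, medium, h2_fluxes=list(h2_fluxes)),
    )


def _with_efficiency(
    model: MetabolicModel, efficiency: float, config: EnergyConfig
) -> MetabolicModel:
    """Scale the respiratory proton translocation to a target efficiency.

    Efficiency is defined against the thermodynamic maximum ATP/H₂, so the
    translocation stoichiometry becomes ``eff × max_atp_per_h2 ×
    protons_per_atp`` protons per H₂-coupled dechlorination.
    """
    if not (0.0 < efficiency <= 1.0):
        raise ValueError("efficiency must be in (0, 1]")
    rxn_id = model.meta.get("respiration_rxn")
    p_atp = model.meta.get("protons_per_atp")
    if rxn_id is None or p_atp is None:
        raise KeyError(
            "model does not declare its respiration reaction / ATP synthase "
            "proton stoichiometry (meta['respiration_rxn'], meta['protons_per_atp'])"
        )
    new = model.copy()
    rxn = new.reactions[rxn_id]
    protons = efficiency * max_atp_per_h2(config) * p_atp
    rxn.stoich["h_c"] = -protons
    rxn.stoich["h_e"] = protons
    new.meta["protons_per_h2"] = protons
    return new


def energy_yield_grid(
    model: MetabolicModel,
    medium,
    acetate_fluxes,
    efficiencies,
    energy_config: EnergyConfig = EnergyConfig(),
    acetate_exchange: str = "EX_ac_e",
) -> ScenarioResult:
    """Yield over (acetate flux × energy-transfer efficiency).

    Above the stoichiometric acetate minimum the yield is independent of
    the acetate allowance and (for fixed NGAM and donor flux) affine in
    the efficiency — the energy-limited-growth signature.
    """
    acetate_fluxes = np.asarray(acetate_fluxes, dtype=float)
    efficiencies = np.asarray(efficiencies, dtype=float)
    grid = np.zeros((len(acetate_fluxes), len(efficiencies)))
    rows = []
    for j, eff in enumerate(efficiencies):
        scaled = _with_efficiency(model, float(eff), energy_config)
        base = apply_medium(scaled, medium)
        for i, ac in enumerate(acetate_fluxes):
            arm = base.copy()
            arm.reactions[acetate_exchange].lb = -abs(float(ac))
            _a, mu, y = _solve_row(arm, dict_of(arm))
            grid[i, j] = y
            rows.append({"acetate_flux": float(ac), "efficiency": float(eff),
                         "growth_rate": mu, "yield": y})
    return ScenarioResult(
        name="acetate_energy_yield_grid",
        table=pd.DataFrame(rows),
        grid=grid,
        axes={"acetate_flux": acetate_fluxes, "efficiency": efficiencies},
        provenance=_provenance(model, medium,
                               energy_config=vars(energy_config)),
    )


def efficiency_for_yield(
    model: MetabolicModel,
    medium,
    target_yield: float,
    energy_config: EnergyConfig = EnergyConfig(),
    bracket: tuple[float, float] = (0.05, 1.0),
) -> float:
    """Energy-transfer efficiency at which the model reaches a yield.

    Exploits the affine yield-vs-efficiency relation: two solves fix the
    line, a third verifies the interpolated root.
    """
    e1, e2 = bracket
    ys = []
    for eff in (e1, e2):
        arm = _with_efficiency(model, eff, energy_config)
        _s, _mu, y = _solve_row(arm, medium)
        ys.append(y)
    y1, y2 = ys
    if y2 == y1:
        raise ValueError("yield does not respond to efficiency in the bracket")
    eff = e1 + (target_yield - y1) * (e2 - e1) / (y2 - y1)
    if not (min(e1, e2) - 1e-9 <= eff <= max(e1, e2) + 1e-9):
        raise ValueError(
            f"target yield {target_yield} outside the bracket yields [{y1}, {y2}]"
        )
    return float(eff)
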