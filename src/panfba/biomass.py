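"""Biomass composition, maintenance energy and yield accounting.

The biomass demand reaction is assembled from a macromolecular composition
(weight fractions of protein, lipid, carbohydrate, DNA, RNA, soluble pool
and ions, each resolved into monomers) as mmol·gDCW⁻¹ coefficients, plus a
growth-associated maintenance (GAM) term hydrolyzing ATP.  Non-growth-
associated maintenance (NGAM, mmol ATP·gDCW⁻¹·h⁻¹) is imposed as the lower
bound of a dedicated ATP hydrolysis reaction.

Electron-equivalent (eeq) accounting is fixed at 2 eeq per mol H₂ (a
two-electron donor); growth yields are reported as gDCW per eeq of donor.
The default energy stoichiometry — 4 H⁺ translocated per H₂-coupled
dechlorination and 6 H⁺ per ATP, hence ⅔ ATP/H₂ = ⅓ ATP/eeq — makes the
Pirt-style maintenance relation reproduce an NGAM of 1.8 mmol
ATP·gDCW⁻¹·h⁻¹ from the observed pure-culture decay rate (0.09 day⁻¹) and
mean growth yield (0.69 gDCW/eeq).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

from .model import Medium, MetabolicModel, Reaction

#: mol ATP conserved per mol electron equivalent by the default
#: respiratory stoichiometry (4 H+ per H2 / 6 H+ per ATP / 2 eeq per H2)
DEFAULT_ATP_PER_EEQ = 1.0 / 3.0

#: electron equivalents carried by one mmol of H2
EEQ_PER_MMOL_H2 = 2.0


class CompositionError(ValueError):
    """Raised when a biomass composition violates its invariants."""


class BracketingError(ValueError):
    """Raised when a calibration target lies outside the achievable range."""


@dataclass(frozen=True)
class Monomer:
    """One biomass precursor within a macromolecule class."""

    met_id: str
    mole_fraction: float
    molar_mass: float  # g/mol


@dataclass
class BiomassComposition:
    """Macromolecule weight fractions plus per-class monomer tables.

    ``class_weight_fractions`` (g/gDCW) together with
    ``cobalamin_weight_fraction`` must sum to 1; monomer mole fractions are
    normalized within each class.
    """

    class_weight_fractions: dict[str, float]
    monomers: dict[str, list[Monomer]]
    cobalamin_weight_fraction: float = 0.0
    cobalamin_met_id: str = "cbl1_c"
    cobalamin_molar_mass: float = 1354.4

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for cls, frac in self.class_weight_fractions.items():
            if frac < 0:
                raise CompositionError(f"negative weight fraction for {cls!r}")
        if self.cobalamin_weight_fraction < 0:
            raise CompositionError("negative cobalamin weight fraction")
        total = sum(self.class_weight_fractions.values()) + self.cobalamin_weight_fraction
        if abs(total - 1.0) > 1e-6:
            raise CompositionError(f"class weight fractions sum to {total}, not 1")
        for cls in self.class_weight_fractions:
            if cls not in self.monomers or not self.monomers[cls]:
                raise CompositionError(f"class {cls!r} has no monomer table")

    def normalized_monomers(self, cls: str) -> list[Monomer]:
        table = self.monomers[cls]
        total = sum(m.mole_fraction for m in table)
        if total <= 0:
            raise CompositionError(f"class {cls!r} monomer fractions sum to 0")
        return [replace(m, mole_fraction=m.mole_fraction / total) for m in table]

    def copy(self) -> "BiomassComposition":
        return BiomassComposition(
            class_weight_fractions=dict(self.class_weight_fractions),
            monomers={c: list(ms) for c, ms in self.monomers.items()},
            cobalamin_weight_fraction=self.cobalamin_weight_fraction,
            cobalamin_met_id=self.cobalamin_met_id,
            cobalamin_molar_mass=self.cobalamin_molar_mass,
        )


@dataclass(frozen=True)
class MaintenanceParams:
    """GAM (mmol ATP/gDCW), NGAM (mmol ATP/gDCW/h) and ATP-per-eeq."""

    ngam: float
    gam: float
    atp_per_eeq: float = DEFAULT_ATP_PER_EEQ

    def __post_init__(self):
        if min(self.ngam, self.gam, self.atp_per_eeq) < 0:
            raise ValueError("maintenance parameters must be non-negative")


@dataclass(frozen=True)
class EnergyConfig:
    """Thermodynamic normalization constants for energy-transfer efficiency.

    ``delta_g_h2_ox`` is the magnitude of the free energy available per mol
    H₂ oxidized with the chlorinated acceptor (kJ/mol); ``atp_cost`` is the
    in vivo energetic cost of synthesizing one mol ATP (kJ/mol).  The
    defaults (189 and 85 kJ/mol) give a thermodynamic maximum of ≈2.22
    ATP/H₂, against which the default respiratory stoichiometry (⅔ ATP/H₂)
    is ≈30% efficient.
    """

    delta_g_h2_ox: float = 189.0
    atp_cost: float = 85.0


@dataclass(frozen=True)
class YieldResult:
    """Growth rate, donor eeq uptake rate, yield and optional efficiency."""

    growth_rate: float  # h^-1
    eeq_uptake: float  # eeq gDCW^-1 h^-1
    yield_gdcw_per_eeq: float
    efficiency: float | None = None


def mass_per_mmol(comp: BiomassComposition) -> float:
    """Total grams of monomers consumed per gDCW formed (mass closure).

    Equals 1.0 for any valid composition; exposed for the invariant check.
    """
    total = 0.0
    for cls, frac in comp.class_weight_fractions.items():
        table = comp.normalized_monomers(cls)
        mean_mw = sum(m.mole_fraction * m.molar_mass for m in table)
        for m in table:
            coeff = 1000.0 * frac * m.mole_fraction / mean_mw  # mmol/gDCW
            total += coeff * m.molar_mass / 1000.0
    total += comp.cobalamin_weight_fraction
    return total


def assemble_biomass(
    comp: BiomassComposition,
    gam: float,
    rxn_id: str | None = None,
    model: MetabolicModel | None = None,
    currency: dict[str, str] | None = None,
) -> Reaction:
    """Build the biomass demand reaction from a composition and a GAM.

    Each monomer is consumed at ``1000 × class_fraction × mole_fraction /
    mean class molar mass`` mmol/gDCW (so Σ coeffᵢ·MWᵢ = 1000 mg), the
    cobalamin fraction at ``1000 × w / MW``, and the GAM term hydrolyzes
    ``gam`` mmol ATP (+ H₂O → ADP + Pi).  The reaction's flux is the
    specific growth rate.
    """
    if gam < 0:
        raise ValueError("GAM must be non-negative")
    cur = {"atp": "atp_c", "h2o": "h2o_c", "adp": "adp_c", "pi": "pi_c"}
    if currency:
        cur.update(currency)
    stoich: dict[str, float] = {}

    def consume(met_id: str, amount: float) -> None:
        stoich[met_id] = stoich.get(met_id, 0.0) - amount

    for cls, frac in comp.class_weight_fractions.items():
        if frac == 0.0:
            continue
        table = comp.normalized_monomers(cls)
        mean_mw = sum(m.mole_fraction * m.molar_mass for m in table)
        for m in table:
            if m.mole_fraction == 0.0:
                continue
            consume(m.met_id, 1000.0 * frac * m.mole_fraction / mean_mw)
    if comp.cobalamin_weight_fraction > 0:
        consume(
            comp.cobalamin_met_id,
            1000.0 * comp.cobalamin_weight_fraction / comp.cobalamin_molar_mass,
        )
    if gam > 0:
        consume(cur["atp"], gam)
        consume(cur["h2o"], gam)
        stoich[cur["adp"]] = stoich.get(cur["adp"], 0.0) + gam
        stoich[cur["pi"]] = stoich.get(cur["pi"], 0.0) + gam

    if model is not None:
        missing = sorted(m for m in stoich if m not in model.metabolites)
        if missing:
            raise CompositionError(
                f"biomass precursors missing from model: {missing}"
            )
    rid = rxn_id or f"BIO_DM_{gam:g}"
    return Reaction(
        rxn_id=rid, stoich=stoich, lb=0.0, ub=1000.0,
        name="biomass synthesis (demand)", subsystem="biomass", kind="demand",
    )


def rescale_cobalamin(comp: BiomassComposition, factor: float) -> BiomassComposition:
    """Multiply the cobalamin weight fraction; renormalize the rest.

    The remaining class fractions are scaled proportionally so the total
    stays 1.  ``factor`` must be positive and must not push the cobalamin
    fraction to ≥ 1.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    w_old = comp.cobalamin_weight_fraction
    w_new = w_old * factor
    if w_new >= 1.0:
        raise CompositionError(f"cobalamin fraction would become {w_new} >= 1")
    scale = (1.0 - w_new) / (1.0 - w_old)
    new = comp.copy()
    new.cobalamin_weight_fraction = w_new
    new.class_weight_fractions = {
        cls: frac * scale for cls, frac in comp.class_weight_fractions.items()
    }
    new.validate()
    return new


def compute_ngam(
    decay_rate_per_day: float,
    yield_gdcw_per_eeq: float,
    atp_per_eeq: float = DEFAULT_ATP_PER_EEQ,
) -> float:
    """NGAM from decay rate and yield via the Pirt maintenance relation.

    The maintenance donor turnover needed to offset decay is
    ``decay/24 ÷ yield`` eeq·gDCW⁻¹·h⁻¹; converting to ATP with the
    energy-conservation stoichiometry gives mmol ATP·gDCW⁻¹·h⁻¹::

        NGAM = (decay/24 / yield) * 1000 * atp_per_eeq / 1000
             = decay/24 / yield * atp_per_eeq * 1000   [meeq scale]

    With the defaults (0.09 day⁻¹, 0.69 gDCW/eeq, ⅓ ATP/eeq) this is 1.81.
    """
    if yield_gdcw_per_eeq <= 0:
        raise ValueError("yield must be positive")
    if decay_rate_per_day < 0:
        raise ValueError("decay rate must be non-negative")
    eeq_per_gdcw_h = decay_rate_per_day / 24.0 / yield_gdcw_per_eeq
    return eeq_per_gdcw_h * 1000.0 * atp_per_eeq


def max_atp_per_h2(config: EnergyConfig = EnergyConfig()) -> float:
    """Thermodynamic maximum mol ATP per mol H₂: |ΔG_H₂| / ATP cost."""
    if config.delta_g_h2_ox <= 0 or config.atp_cost <= 0:
        raise ValueError("energy quantities must be positive")
    return config.delta_g_h2_ox / config.atp_cost


def max_atp_per_eeq(config: EnergyConfig = EnergyConfig()) -> float:
    """Thermodynamic maximum mol ATP per eeq (2 eeq per H₂)."""
    return max_atp_per_h2(config) / EEQ_PER_MMOL_H2


def growth_yield(
    solution,
    model: MetabolicModel,
    donor_exchange_id: str = "EX_h2_e",
    eeq_per_mmol: float = EEQ_PER_MMOL_H2,
    energy_config: EnergyConfig | None = None,
) -> YieldResult:
    """Yield in gDCW per eeq of electron donor for an FBA solution.

    ``yield = μ / (|donor uptake| × eeq_per_mmol / 1000)``.  Zero growth
    gives yield 0; zero donor uptake is an error.  When the model records
    its ATP synthase reaction (``meta['atp_synthase_rxn']``) and an energy
    config is given, the energy-transfer efficiency — ATP synthase flux
    over (H₂ uptake × thermodynamic max ATP/H₂) — is reported too.
    """
    uptake = -solution.fluxes.get(donor_exchange_id, 0.0)
    if uptake <= 0:
        raise ValueError(
            f"no uptake through donor exchange {donor_exchange_id!r}; yield undefined"
        )
    eeq_uptake = uptake * eeq_per_mmol / 1000.0
    mu = solution.objective
    y = mu / eeq_uptake if mu > 0 else 0.0
    efficiency = None
    if energy_config is not None and "atp_synthase_rxn" in model.meta:
        atp_flux = solution.fluxes.get(model.meta["atp_synthase_rxn"], 0.0)
        efficiency = atp_flux / (uptake * max_atp_per_h2(energy_config))
    return YieldResult(
        growth_rate=mu, eeq_uptake=eeq_uptake, yield_gdcw_per_eeq=y,
        efficiency=efficiency,
    )


# -- GAM handling on an existing model -------------------------------------

def current_gam(model: MetabolicModel) -> float:
    """The GAM currently encoded in the model's biomass reaction.

    Taken from ``model.meta['gam']`` when the model was produced by the
    generator; otherwise parsed from the trailing number of the biomass
    reaction id (the ``BIO_..._61`` naming convention carries the GAM).
    """
    if "gam" in model.meta:
        return float(model.meta["gam"])
    match = re.search(r"(\d+(?:\.\d+)?)$", model.objective.rxn_id)
    if match:
        return float(match.group(1))
    raise ValueError("cannot determine current GAM of model")


def set_gam(model: MetabolicModel, gam: float) -> MetabolicModel:
    """Return a copy of the model with the biomass GAM term set to ``gam``.

    When the model carries its :class:`BiomassComposition` in
    ``meta['biomass_composition']`` the biomass reaction is reassembled;
    otherwise the ATP/H₂O/ADP/Pi coefficients are shifted by the GAM delta.
    """
    new = model.copy()
    bio = new.objective
    cur = new.meta.get(
        "currency", {"atp": "atp_c", "h2o": "h2o_c", "adp": "adp_c", "pi": "pi_c"}
    )
    comp: BiomassComposition | None = new.meta.get("biomass_composition")
    if comp is not None:
        rebuilt = assemble_biomass(comp, gam, rxn_id=bio.rxn_id, model=new, currency=cur)
        bio.stoich = rebuilt.stoich
    else:
        delta = gam - current_gam(new)
        for met, sign in ((cur["atp"], -1), (cur["h2o"], -1), (cur["adp"], 1), (cur["pi"], 1)):
            bio.stoich[met] = bio.stoich.get(met, 0.0) + sign * delta
    new.meta["gam"] = gam
    return new


def set_ngam(model: MetabolicModel, ngam: float) -> MetabolicModel:
    """Return a copy with the NGAM ATP-hydrolysis lower bound set.

    The NGAM reaction is ``meta['ngam_rxn']`` when recorded, else the
    first reaction whose id contains ``ATPM`` or ``NGAM``.
    """
    if ngam < 0:
        raise ValueError("NGAM must be non-negative")
    new = model.copy()
    rxn_id = new.meta.get("ngam_rxn")
    if rxn_id is None:
        for rid in new.reactions:
            if "ATPM" in rid.upper() or "NGAM" in rid.upper():
                rxn_id = rid
                break
    if rxn_id is None:
        raise ValueError("model has no maintenance (ATPM/NGAM) reaction")
    new.reactions[rxn_id].lb = ngam
    new.meta["ngam"] = ngam
    return new


def calibrate_gam(
    model: MetabolicModel,
    medium: Medium | dict,
    target_growth: float,
    ngam: float | None = None,
    gam_bounds: tuple[float, float] = (0.0, 2000.0),
    mu_tol: float = 1e-4,
    gam_tol: float = 0.05,
    max_iter: int = 80,
) -> tuple[float, float]:
    """Find the GAM at which FBA growth matches a target rate.

    Growth is monotone non-increasing in GAM, so a 1-D bisection implements
    the regression: iterate until both ``|μ − target| < mu_tol`` (h⁻¹) and
    the GAM bracket is narrower than ``gam_tol`` (mmol ATP/gDCW).  Returns
    ``(gam, achieved_growth)``.
    """
    from .fba import solve_fba  # local import to avoid a cycle

    if ngam is not None:
        model = set_ngam(model, ngam)
    base = apply = lambda gam: solve_fba(set_gam(model, gam), medium=medium)

    lo, hi = gam_bounds
    sol_lo, sol_hi = base(lo), apply(hi)
    mu_lo = sol_lo.objective if sol_lo.optimal else 0.0
    mu_hi = sol_hi.objective if sol_hi.optimal else 0.0
    if not (mu_lo >= target_growth - mu_tol and mu_hi <= target_growth + mu_tol):
        raise BracketingError(
            f"target growth {target_growth} outside achievable range "
            f"[{mu_hi:.6g}, {mu_lo:.6g}] for GAM in {gam_bounds}"
        )
    gam, mu = lo, mu_lo
    for _ in range(max_iter):
        gam = 0.5 * (lo + hi)
        sol = apply(gam)
        mu = sol.objective if sol.optimal else 0.0
        if mu > target_growth:
            lo = gam
        else:
            hi = gam
        if abs(mu - target_growth) < mu_tol and (hi - lo) < gam_tol:
            break
    if math.isnan(mu):
        raise BracketingError("calibration failed: non-optimal solve")
    return gam, mu
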