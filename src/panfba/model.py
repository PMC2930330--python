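"""Constraint-based model data structures.

A :class:`MetabolicModel` is a set of metabolites and reactions with
stoichiometry, flux bounds, GPR associations and a biomass (demand)
objective.  Units are fixed package-wide: fluxes in mmol·gDCW⁻¹·h⁻¹ and
growth rate in h⁻¹.

Sign conventions follow standard COBRA practice: an exchange reaction is
written as ``met <==>`` (exactly one model metabolite, negative coefficient);
positive exchange flux is secretion, negative is uptake, and medium
availability is a negative lower bound.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .gpr import GPR

#: default magnitude used as the package's "infinite" flux bound
DEFAULT_BOUND = 1000.0

ELEMENTS = ("C", "H", "N", "O", "P", "S", "Cl", "Co", "X")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class ModelConsistencyError(ValueError):
    """Raised when references inside a model do not resolve."""


class FormulaError(ValueError):
    """Raised for unparsable elemental formulas."""


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula string such as ``C2H4O2`` into counts.

    Fractional counts are allowed (lumped species).  ``X`` is accepted as a
    generic placeholder element for lumps.
    """
    if formula is None:
        raise FormulaError("formula is None")
    stripped = formula.strip()
    if not stripped:
        return {}
    counts: dict[str, float] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(stripped):
        if match.start() != pos:
            raise FormulaError(f"unparsable formula {formula!r}")
        pos = match.end()
        elem, num = match.groups()
        n = float(num) if num else 1.0
        counts[elem] = counts.get(elem, 0.0) + n
    if pos != len(stripped):
        raise FormulaError(f"unparsable formula {formula!r}")
    return counts


#: standard atomic masses, g/mol (CIAAW 2021, rounded); X/Xd/Xa are
#: zero-mass placeholder "elements" for lumped carriers (CoA, ferredoxin,
#: adenylate scaffold)
ATOMIC_MASS = {
    "C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Co": 58.933, "Fe": 55.845,
    "X": 0.0, "Xd": 0.0, "Xa": 0.0,
}


def formula_weight(formula: str) -> float:
    """Molar mass in g/mol of a formula string."""
    counts = parse_formula(formula)
    try:
        return sum(ATOMIC_MASS[el] * n for el, n in counts.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise FormulaError(f"no atomic mass for element {exc} in {formula!r}")


@dataclass(frozen=True)
class Metabolite:
    """A model species; ``compartment`` is ``c`` (cytosol) or ``e``."""

    met_id: str
    name: str = ""
    formula: str | None = None
    charge: int | None = None
    compartment: str = "c"

    def __post_init__(self):
        if self.compartment not in ("c", "e"):
            raise ModelConsistencyError(
                f"metabolite {self.met_id!r}: invalid compartment "
                f"{self.compartment!r} (must be 'c' or 'e')"
            )

    def elements(self) -> dict[str, float]:
        if self.formula is None:
            raise FormulaError(f"metabolite {self.met_id!r} has no formula")
        return parse_formula(self.formula)


@dataclass
class Reaction:
    """A stoichiometric reaction with bounds, GPR and classification.

    ``kind`` is one of ``intra-system``, ``exchange`` (single extracellular
    species boundary reaction) or ``demand`` (the biomass reaction).
    """

    rxn_id: str
    stoich: dict[str, float]
    lb: float = -DEFAULT_BOUND
    ub: float = DEFAULT_BOUND
    gpr: GPR = field(default_factory=GPR)
    name: str = ""
    subsystem: str = ""
    kind: str = "intra-system"

    def __post_init__(self):
        if not self.stoich:
            raise ModelConsistencyError(f"reaction {self.rxn_id!r}: empty stoichiometry")
        if self.lb > self.ub:
            raise ModelConsistencyError(
                f"reaction {self.rxn_id!r}: lb {self.lb} > ub {self.ub}"
            )
        if self.kind not in ("intra-system", "exchange", "demand"):
            raise ModelConsistencyError(
                f"reaction {self.rxn_id!r}: invalid kind {self.kind!r}"
            )
        if isinstance(self.gpr, str):
            self.gpr = GPR.from_string(self.gpr)

    @property
    def reversible(self) -> bool:
        return self.lb < 0.0

    def copy(self) -> "Reaction":
        return Reaction(
            rxn_id=self.rxn_id, stoich=dict(self.stoich), lb=self.lb, ub=self.ub,
            gpr=self.gpr, name=self.name, subsystem=self.subsystem, kind=self.kind,
        )


@dataclass
class Gene:
    gene_id: str
    category: str = ""  # core / dispensable / unique, when known
    name: str = ""


class Medium(dict):
    """Map ``exchange rxn_id -> (lb, ub)`` in mmol·gDCW⁻¹·h⁻¹."""

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "Medium":
        med = cls()
        for ex_id, bounds in data.items():
            if isinstance(bounds, (int, float)):
                # shorthand: a bare number is the uptake allowance
                med[ex_id] = (-abs(float(bounds)), DEFAULT_BOUND)
            else:
                lb, ub = bounds  # type: ignore[misc]
                med[ex_id] = (float(lb), float(ub))
        return med


class MetabolicModel:
    """Metabolites + reactions + genes + a biomass objective."""

    def __init__(
        self,
        model_id: str = "model",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        genes: Iterable[Gene] = (),
        objective_rxn_id: str | None = None,
        name: str = "",
    ):
        self.model_id = model_id
        self.name = name or model_id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.genes: dict[str, Gene] = {}
        self.objective_rxn_id = objective_rxn_id
        #: free-form metadata (biomass composition, generator parameters, ...)
        self.meta: dict = {}
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)
        for gene in genes:
            self.add_gene(gene)

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.met_id in self.metabolites:
            raise ModelConsistencyError(f"duplicate metabolite id {met.met_id!r}")
        self.metabolites[met.met_id] = met

    def add_gene(self, gene: Gene) -> None:
        self.genes.setdefault(gene.gene_id, gene)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.rxn_id in self.reactions:
            raise ModelConsistencyError(f"duplicate reaction id {rxn.rxn_id!r}")
        missing = [m for m in rxn.stoich if m not in self.metabolites]
        if missing:
            raise ModelConsistencyError(
                f"reaction {rxn.rxn_id!r} references unknown metabolites: {missing}"
            )
        if rxn.kind == "exchange":
            if len(rxn.stoich) != 1:
                raise ModelConsistencyError(
                    f"exchange reaction {rxn.rxn_id!r} must touch exactly one metabolite"
                )
        self.reactions[rxn.rxn_id] = rxn
        for g in rxn.gpr.genes():
            self.add_gene(Gene(g))

    def remove_reaction(self, rxn_id: str) -> None:
        del self.reactions[rxn_id]

    # -- views -------------------------------------------------------------
    @property
    def objective(self) -> Reaction:
        if self.objective_rxn_id is None:
            raise ModelConsistencyError("model has no objective reaction")
        return self.reactions[self.objective_rxn_id]

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def intra_system(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "intra-system"]

    def stats(self) -> dict[str, int]:
        """Model feature counts (the usual reconstruction summary table)."""
        rxns = list(self.reactions.values())
        intra = [r for r in rxns if r.kind == "intra-system"]
        gene_assoc = [r for r in intra if not r.gpr.empty]
        return {
            "reactions_total": len(rxns),
            "reactions_intra_system": len(intra),
            "reactions_gene_associated": len(gene_assoc),
            "reactions_non_gene_associated": len(intra) - len(gene_assoc),
            "reactions_exchange": sum(1 for r in rxns if r.kind == "exchange"),
            "reactions_demand": sum(1 for r in rxns if r.kind == "demand"),
            "metabolites_total": len(self.metabolites),
            "metabolites_extracellular": sum(
                1 for m in self.metabolites.values() if m.compartment == "e"
            ),
            "genes_total": len(self.genes),
        }

    def copy(self) -> "MetabolicModel":
        new = MetabolicModel(
            model_id=self.model_id,
            metabolites=self.metabolites.values(),
            genes=[replace(g) for g in self.genes.values()],
            objective_rxn_id=self.objective_rxn_id,
            name=self.name,
        )
        for rxn in self.reactions.values():
            new.add_reaction(rxn.copy())
        new.meta = dict(self.meta)
        return new

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        data = {
            "model_id": self.model_id,
            "name": self.name,
            "objective": self.objective_rxn_id,
            "metabolites": [
                {
                    "id": m.met_id, "name": m.name, "formula": m.formula,
                    "charge": m.charge, "compartment": m.compartment,
                }
                for m in self.metabolites.values()
            ],
            "reactions": [
                {
                    "id": r.rxn_id, "name": r.name, "stoich": r.stoich,
                    "lb": r.lb, "ub": r.ub, "gpr": r.gpr.to_string(),
                    "subsystem": r.subsystem, "kind": r.kind,
                }
                for r in self.reactions.values()
            ],
            "genes": [
                {"id": g.gene_id, "category": g.category, "name": g.name}
                for g in self.genes.values()
            ],
        }
        return json.dumps(data, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MetabolicModel":
        data = json.loads(text)
        model = cls(model_id=data["model_id"], name=data.get("name", ""))
        for m in data["metabolites"]:
            model.add_metabolite(
                Metabolite(
                    met_id=m["id"], name=m.get("name", ""), formula=m.get("formula"),
                    charge=m.get("charge"), compartment=m.get("compartment", "c"),
                )
            )
        for r in data["reactions"]:
            model.add_reaction(
                Reaction(
                    rxn_id=r["id"], stoich={k: float(v) for k, v in r["stoich"].items()},
                    lb=r["lb"], ub=r["ub"], gpr=GPR.from_string(r.get("gpr", "")),
                    name=r.get("name", ""), subsystem=r.get("subsystem", ""),
                    kind=r.get("kind", "intra-system"),
                )
            )
        for g in data.get("genes", []):
            model.genes[g["id"]] = Gene(g["id"], g.get("category", ""), g.get("name", ""))
        model.objective_rxn_id = data.get("objective")
        return model


def stoichiometric_matrix(
    model: MetabolicModel,
) -> tuple[np.ndarray, dict[str, int], dict[str, int]]:
    """Assemble S (metabolites × reactions) plus row/column index maps.

    Columns follow reaction insertion order, rows metabolite insertion order.
    """
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    rxn_index = {r: j for j, r in enumerate(model.reactions)}
    S = np.zeros((len(met_index), len(rxn_index)))
    for rxn_id, rxn in model.reactions.items():
        j = rxn_index[rxn_id]
        for met_id, coeff in rxn.stoich.items():
            S[met_index[met_id], j] = coeff
    return S, met_index, rxn_index


def check_balance(
    rxn: Reaction, metabolites: Mapping[str, Metabolite], tol: float = 1e-9
) -> dict[str, float] | None:
    """Per-element (and charge) imbalance of an intra-system reaction.

    Returns a dict of signed imbalances, empty when balanced, or ``None``
    for exchange/demand reactions which are boundary pseudo-reactions and
    exempt by construction.
    """
    if rxn.kind in ("exchange", "demand"):
        return None
    totals: dict[str, float] = {}
    charge_total = 0.0
    any_charge = False
    for met_id, coeff in rxn.stoich.items():
        met = metabolites[met_id]
        if met.formula is None:
            raise FormulaError(
                f"metabolite {met_id!r} in reaction {rxn.rxn_id!r} has no formula"
            )
        for el, n in met.elements().items():
            totals[el] = totals.get(el, 0.0) + coeff * n
        if met.charge is not None:
            any_charge = True
            charge_total += coeff * met.charge
    imbalance = {el: v for el, v in totals.items() if abs(v) > tol}
    if any_charge and abs(charge_total) > tol:
        imbalance["charge"] = charge_total
    return imbalance


def apply_medium(model: MetabolicModel, medium: Medium | Mapping) -> MetabolicModel:
    """Return a copy with exchange bounds set from the medium definition.

    Exchanges listed in the medium get the stated (lb, ub); every unlisted
    exchange is closed to uptake (lb = 0) with secretion left open.
    """
    if not isinstance(medium, Medium):
        medium = Medium.from_dict(medium)
    new = model.copy()
    unknown = [ex for ex in medium if ex not in new.reactions]
    if unknown:
        raise ModelConsistencyError(f"medium references unknown exchanges: {unknown}")
    for ex in (e for e in medium if new.reactions[e].kind != "exchange"):
        raise ModelConsistencyError(f"medium entry {ex!r} is not an exchange reaction")
    for rxn in new.reactions.values():
        if rxn.kind != "exchange":
            continue
        if rxn.rxn_id in medium:
            rxn.lb, rxn.ub = medium[rxn.rxn_id]
        else:
            rxn.lb, rxn.ub = 0.0, DEFAULT_BOUND
    return new
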