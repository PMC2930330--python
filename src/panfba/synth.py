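"""Desk-scale synthetic fixtures with known ground truth.

Two generators:

* :func:`generate_core_network` — a reduced (~35-reaction) metabolic
  network with the structure the analysis assumes for *Dehalococcoides*:
  H₂-driven reductive dechlorination (PCE → TCE) as sole respiration,
  acetate + CO₂ carbon assimilation through pyruvate synthase (POR), an
  incomplete TCA cycle (reductive arm to 2-oxoglutarate, optional citrate
  synthase), cobalamin salvage vs. an optional lumped de novo pathway,
  amino-acid exchanges, and a composition-derived biomass demand reaction.
  All intra-system reactions are elementally balanced over
  {C,H,N,O,P,S,Cl,Co} (lumped carriers use placeholder elements of zero
  mass); lumped monomer formulas are derived from their synthesis
  reactions, so balance holds by construction.

* :func:`generate_pangenome_fixture` — 4-genome gene-family overlap
  fixtures with planted core/dispensable/unique counts.

Randomness affects identifiers (and optional slack-bound jitter) only;
stoichiometry is deterministic given the parameters, so numeric results
are seed-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biomass import (
    BiomassComposition,
    Monomer,
    assemble_biomass,
    compute_ngam,
)
from .model import (
    DEFAULT_BOUND,
    Medium,
    Metabolite,
    MetabolicModel,
    Reaction,
    formula_weight,
    parse_formula,
)

#: GAM (mmol ATP/gDCW) of the default network, calibrated once so that the
#: default parameterization reproduces the mean pure-culture growth rate
#: (0.014 h^-1) at an H2 flux of 10 mmol/gDCW/h with the NGAM below.  The
#: reduced network lumps many pathways, so this value absorbs their ATP
#: costs and is larger than a genome-scale model's GAM.
DEFAULT_GAM = 299.644

#: NGAM from decay 0.09 day^-1, yield 0.69 gDCW/eeq, 1/3 ATP/eeq
DEFAULT_NGAM = compute_ngam(0.09, 0.69)

#: amino-acid synthesis lump table: name -> (pyruvates, NH3, Fd_red, ATP,
#: mole fraction in protein).  Each lump's formula is derived from its
#: synthesis reaction (carbon is conserved from pyruvate by construction);
#: water is balanced automatically.
AA_TABLE: dict[str, tuple[int, int, int, int, float]] = {
    "ala": (1, 1, 1, 2, 0.20),
    "gly": (1, 1, 0, 2, 0.18),
    "thr": (1, 1, 1, 2, 0.12),
    "asp": (1, 1, 0, 2, 0.14),
    "glu": (2, 1, 1, 3, 0.16),
    "gln": (2, 2, 1, 4, 0.08),
    "tyr": (3, 1, 4, 4, 0.12),
}

_PYR = parse_formula("C3H4O3")


class GenerationError(RuntimeError):
    """Raised when a parameter set yields an infeasible network."""


@dataclass
class CoreNetworkParams:
    """Parameters of the reduced core network.

    Energy conservation: ``protons_per_h2`` protons are translocated per
    H₂-coupled dechlorination and ``protons_per_atp`` are consumed per ATP,
    so the operational ATP/H₂ ratio is their quotient (default ⅔).
    """

    protons_per_h2: float = 4.0
    protons_per_atp: float = 6.0
    gam: float = DEFAULT_GAM
    ngam: float = DEFAULT_NGAM
    cobalamin_weight_fraction: float = 1.0e-4
    include_cs: bool = False
    include_denovo_cobalamin: bool = False
    denovo_atp_cost: float = 40.0
    glutamate_via_akg: bool = False
    amino_acids: tuple[str, ...] = tuple(AA_TABLE)
    aa_atp_cost: float | None = None  # override every lump's ATP cost
    chain_depth: int = 1  # 1: PCE->TCE; 2: adds TCE->ethene
    bound_jitter: float = 0.0  # relative jitter on non-binding +-1000 bounds
    seed: int = 0

    def __post_init__(self):
        if self.protons_per_h2 <= 0 or self.protons_per_atp <= 0:
            raise ValueError("proton stoichiometries must be positive")
        if self.chain_depth not in (1, 2):
            raise ValueError("chain_depth must be 1 or 2")
        unknown = set(self.amino_acids) - set(AA_TABLE)
        if unknown:
            raise ValueError(f"unknown amino acids: {sorted(unknown)}")

    @property
    def atp_per_h2(self) -> float:
        return self.protons_per_h2 / self.protons_per_atp


def _fmt_formula(counts: dict[str, float]) -> str:
    order = ["C", "H", "N", "O", "P", "S", "Cl", "Co", "Xd", "X"]
    parts = []
    for el in order:
        n = counts.get(el, 0.0)
        if abs(n) < 1e-9:
            continue
        if n < 0:
            raise GenerationError(f"negative element count {el}={n} in derived formula")
        parts.append(el + (f"{n:g}" if abs(n - 1) > 1e-9 else ""))
    return "".join(parts)


def _combine(*terms: tuple[float, dict[str, float]]) -> dict[str, float]:
    out: dict[str, float] = {}
    for coeff, counts in terms:
        for el, n in counts.items():
            out[el] = out.get(el, 0.0) + coeff * n
    return {el: n for el, n in out.items() if abs(n) > 1e-9}


def _lump_formula(pyr: int, nh3: int, h2: int, water: int) -> str:
    """Formula of a monomer lump: pyr·C3H4O3 + NH3·n + H2·d − H2O·w."""
    return _fmt_formula(
        _combine(
            (pyr, _PYR),
            (nh3, parse_formula("NH3")),
            (h2, parse_formula("H2")),
            (-water, parse_formula("H2O")),
        )
    )


#: (pyruvates, NH3, Fd_red, ATP, waters condensed out) per non-protein lump
_LUMPS = {
    # lipid lump ~ C15 acyl chain equivalent, heavily reduced
    "lipid": dict(pyr=5, nh3=0, fdred=18, atp=8, water=13),
    # carbohydrate lump = hexose via gluconeogenesis
    "carb": dict(pyr=2, nh3=0, fdred=2, atp=2, water=0),
    # RNA / DNA nucleotide-equivalent lumps (3 pyr + 2 N + phosphate)
    "rna": dict(pyr=3, nh3=2, fdred=2, atp=6, water=4, pi=1),
    "dna": dict(pyr=3, nh3=2, fdred=3, atp=6, water=5, pi=1),
}

#: macromolecule weight fractions (g/gDCW); the soluble pool absorbs the
#: cobalamin fraction so the total is exactly 1
_CLASS_FRACTIONS = {
    "protein": 0.630,
    "lipid": 0.091,
    "carbohydrate": 0.062,
    "DNA": 0.049,
    "RNA": 0.059,
    "soluble_pool": 0.079,
    "ions": 0.030,
}

_AA_WATERS = {"ala": 1, "gly": 1, "thr": 0, "asp": 0, "glu": 2, "gln": 2, "tyr": 6}

#: real formulas used for the glutamate family when it is routed through
#: 2-oxoglutarate (the TCA-arm topology) instead of the pyruvate lump
_AKG_AA_FORMULAS = {"glu": "C5H9NO4", "gln": "C5H10N2O3"}


def aa_lump_formula(name: str, via_akg: bool = False) -> str:
    if via_akg and name in _AKG_AA_FORMULAS:
        return _AKG_AA_FORMULAS[name]
    a, n, d, _t, _x = AA_TABLE[name]
    return _lump_formula(a, n, d, _AA_WATERS[name])


def default_biomass_composition(params: CoreNetworkParams) -> BiomassComposition:
    """The default macromolecular composition of the core network.

    Weight fractions follow the archaeal-like split commonly assumed for
    S-layer organisms (protein-dominated, modest lipid); monomers are the
    generator's lumps, so molar masses come from the derived formulas.
    """
    aa_monomers = [
        Monomer(
            met_id=f"{name}_c",
            mole_fraction=AA_TABLE[name][4],
            molar_mass=formula_weight(aa_lump_formula(name, params.glutamate_via_akg)),
        )
        for name in params.amino_acids
    ]
    lump_monomers = {
        cls: [Monomer(met_id=f"{key}_c", mole_fraction=1.0,
                      molar_mass=formula_weight(_lump_formula(
                          _LUMPS[key]["pyr"], _LUMPS[key]["nh3"],
                          _LUMPS[key]["fdred"], _LUMPS[key]["water"])
                          if key != "rna" and key != "dna" else _nucleotide_formula(key)))]
        for cls, key in (("lipid", "lipid"), ("carbohydrate", "carb"),
                         ("RNA", "rna"), ("DNA", "dna"))
    }
    fractions = dict(_CLASS_FRACTIONS)
    fractions["soluble_pool"] -= params.cobalamin_weight_fraction
    return BiomassComposition(
        class_weight_fractions=fractions,
        monomers={
            "protein": aa_monomers,
            **lump_monomers,
            "soluble_pool": [
                Monomer("solute_c", 1.0, formula_weight(_solute_formula()))
            ],
            "ions": [
                Monomer("pi_c", 0.50, formula_weight("H3PO4")),
                Monomer("so4_c", 0.25, formula_weight("H2SO4")),
                Monomer("nh4_c", 0.25, formula_weight("NH3")),
            ],
        },
        cobalamin_weight_fraction=params.cobalamin_weight_fraction,
        cobalamin_met_id="cbl1_c",
        cobalamin_molar_mass=formula_weight(_COBALAMIN_FORMULA),
    )


def _nucleotide_formula(key: str) -> str:
    spec = _LUMPS[key]
    return _fmt_formula(
        _combine(
            (spec["pyr"], _PYR),
            (spec["nh3"], parse_formula("NH3")),
            (spec["fdred"], parse_formula("H2")),
            (spec["pi"], parse_formula("H3PO4")),
            (-spec["water"], parse_formula("H2O")),
        )
    )


def _solute_formula() -> str:
    return _fmt_formula(
        _combine(
            (2, parse_formula("H3PO4")),
            (1, parse_formula("H2SO4")),
            (1, parse_formula("NH3")),
        )
    )


#: lumped corrinoid: 21 pyr + 14 NH3 + Pi + Co + 32 H2 - 53 H2O
_COBALAMIN_FORMULA = _fmt_formula(
    _combine(
        (21, _PYR), (14, parse_formula("NH3")), (1, parse_formula("H3PO4")),
        (1, parse_formula("Co")), (32, parse_formula("H2")),
        (-53, parse_formula("H2O")),
    )
)


class _Builder:
    """Accumulates species/reactions with automatic water/ATP bookkeeping."""

    def __init__(self, params: CoreNetworkParams):
        self.params = params
        rng = np.random.default_rng(params.seed)
        tag = f"{rng.integers(0, 16**6):06x}"
        self.model = MetabolicModel(
            model_id=f"dhc_core_{tag}",
            name="reduced Dehalococcoides-like core network",
        )
        self._rng = rng

    def met(self, met_id: str, formula: str, name: str = "", charge: int | None = None):
        comp = "e" if met_id.endswith("_e") else "c"
        self.model.add_metabolite(
            Metabolite(met_id=met_id, name=name or met_id, formula=formula,
                       charge=charge, compartment=comp)
        )

    def _jitter(self, bound: float) -> float:
        j = self.params.bound_jitter
        if j <= 0 or abs(bound) != DEFAULT_BOUND:
            return bound
        return bound * (1.0 + j * float(self._rng.uniform(0, 1)))

    def rxn(self, rxn_id, stoich, lb=0.0, ub=DEFAULT_BOUND, gpr="", kind="intra-system",
            subsystem="", name="", atp=0.0):
        """Add a reaction; ``atp`` adds an ATP-hydrolysis coupling term."""
        stoich = dict(stoich)
        if atp:
            for met, coeff in (("atp_c", -atp), ("h2o_c", -atp),
                               ("adp_c", atp), ("pi_c", atp)):
                stoich[met] = stoich.get(met, 0.0) + coeff
        stoich = {m: c for m, c in stoich.items() if abs(c) > 1e-12}
        self.model.add_reaction(
            Reaction(rxn_id=rxn_id, stoich=stoich, lb=self._jitter(lb),
                     ub=self._jitter(ub), gpr=gpr, kind=kind,
                     subsystem=subsystem, name=name or rxn_id)
        )


def generate_core_network(params: CoreNetworkParams | None = None) -> MetabolicModel:
    """Build the reduced core network; raises on infeasible parameter sets.

    With the default parameters the network grows on the minimal medium at
    ≈0.014 h⁻¹ for an H₂ flux of 10 mmol·gDCW⁻¹·h⁻¹, and every mole of
    assimilated carbon passes through pyruvate synthase (2 acetate carbons
    per CO₂ carbon), so the CO₂ share of imported carbon is exactly ⅓.
    """
    params = params or CoreNetworkParams()
    b = _Builder(params)
    m = b.met

    # -- species ----------------------------------------------------------
    for base, formula, name in [
        ("ac", "C2H4O2", "acetate"), ("co2", "CO2", "carbon dioxide"),
        ("h2", "H2", "molecular hydrogen"), ("h2o", "H2O", "water"),
        ("nh4", "NH3", "ammonium (neutral convention)"),
        ("pi", "H3PO4", "inorganic phosphate"), ("so4", "H2SO4", "sulphate"),
        ("cl", "HCl", "chloride (neutral convention)"),
        ("pce", "C2Cl4", "tetrachloroethene"), ("tce", "C2HCl3", "trichloroethene"),
        ("cbl1", _COBALAMIN_FORMULA, "cobalamin (lumped corrinoid)"),
    ]:
        m(f"{base}_c", formula, name)
        m(f"{base}_e", formula, name)
    if params.chain_depth >= 2:
        m("etl_c", "C2H4", "ethene")
        m("etl_e", "C2H4", "ethene")
    if params.include_denovo_cobalamin:
        m("cobalt2_c", "Co", "cobalt")
        m("cobalt2_e", "Co", "cobalt")
    m("h_e", "H", "periplasmic proton", charge=1)
    m("h_c", "H", "cytosolic proton", charge=1)
    # the adenylate scaffold is the zero-mass placeholder Xa so currency
    # cycling never carries carbon (atp = adp + pi - h2o elementally)
    for met_id, formula, name in [
        ("atp_c", "XaH2O6P2", "ATP (lumped adenylate)"),
        ("adp_c", "XaHO3P", "ADP (lumped adenylate)"),
        ("coa_c", "X", "coenzyme A (carrier)"),
        ("accoa_c", "C2H2OX", "acetyl-CoA"),
        ("fdox_c", "Xd", "oxidized ferredoxin (carrier)"),
        ("fdred_c", "H2Xd", "reduced ferredoxin (carries 2 e-/2 H)"),
        ("pyr_c", "C3H4O3", "pyruvate"), ("oaa_c", "C4H4O5", "oxaloacetate"),
        ("akg_c", "C5H6O5", "2-oxoglutarate"),
        ("lipid_c", _lump_formula(5, 0, 18, 13), "lipid lump"),
        ("carb_c", _lump_formula(2, 0, 2, 0), "carbohydrate lump"),
        ("rna_c", _nucleotide_formula("rna"), "RNA nucleotide lump"),
        ("dna_c", _nucleotide_formula("dna"), "DNA nucleotide lump"),
        ("solute_c", _solute_formula(), "soluble-pool lump"),
    ]:
        m(met_id, formula, name)
    for aa in params.amino_acids:
        f = aa_lump_formula(aa, params.glutamate_via_akg)
        m(f"{aa}_c", f, f"{aa} (lump)")
        m(f"{aa}_e", f, f"{aa} (lump)")

    # -- exchanges ----------------------------------------------------------
    ex_species = ["ac", "cbl1", "cl", "co2", "h", "h2", "h2o", "pce", "tce",
                  "nh4", "pi", "so4"]
    if params.chain_depth >= 2:
        ex_species.append("etl")
    if params.include_denovo_cobalamin:
        ex_species.append("cobalt2")
    ex_species += list(params.amino_acids)
    for base in ex_species:
        b.rxn(f"EX_{base}_e", {f"{base}_e": -1.0}, lb=-DEFAULT_BOUND,
              ub=DEFAULT_BOUND, kind="exchange", subsystem="exchange",
              name=f"{base} exchange")

    # -- transport ----------------------------------------------------------
    for base in ("ac", "co2", "h2", "h2o"):
        b.rxn(f"{base.upper()}t", {f"{base}_e": -1, f"{base}_c": 1},
              lb=-DEFAULT_BOUND, subsystem="transport")
    b.rxn("PCEt", {"pce_e": -1, "pce_c": 1}, subsystem="transport")
    b.rxn("TCEt", {"tce_c": -1, "tce_e": 1}, subsystem="transport")
    b.rxn("CLt", {"cl_c": -1, "cl_e": 1}, subsystem="transport")
    for base in ("nh4", "pi", "so4"):
        b.rxn(f"{base.upper()}t", {f"{base}_e": -1, f"{base}_c": 1},
              subsystem="transport")
    b.rxn("CBLabc", {"cbl1_e": -1, "cbl1_c": 1}, atp=1.0,
          gpr="btuC and btuD and btuF", subsystem="transport",
          name="cobalamin ABC transport")
    for aa in params.amino_acids:
        b.rxn(f"{aa.upper()}t", {f"{aa}_e": -1, f"{aa}_c": 1}, subsystem="transport")
    if params.include_denovo_cobalamin:
        b.rxn("COBALTt", {"cobalt2_e": -1, "cobalt2_c": 1}, subsystem="transport")

    # -- respiration --------------------------------------------------------
    p_h2 = params.protons_per_h2
    p_atp = params.protons_per_atp
    b.rxn("HYD", {"h2_c": -1, "fdox_c": -1, "fdred_c": 1},
          gpr="hupL and hupS", subsystem="energy metabolism",
          name="hydrogenase (ferredoxin-reducing)")
    b.rxn("RDH", {"pce_c": -1, "fdred_c": -1, "h_c": -p_h2,
                  "tce_c": 1, "cl_c": 1, "fdox_c": 1, "h_e": p_h2},
          gpr="rdhA1 or rdhA2", subsystem="energy metabolism",
          name="reductive dehalogenase (proton-translocating lump)")
    if params.chain_depth >= 2:
        b.rxn("RDH2", {"tce_c": -1, "fdred_c": -3, "h_c": -p_h2,
                       "etl_c": 1, "cl_c": 3, "fdox_c": 3, "h_e": p_h2},
              gpr="vcrA", subsystem="energy metabolism",
              name="TCE-to-ethene dechlorination lump")
    b.rxn("ATPS", {"adp_c": -1, "pi_c": -1, "h_e": -p_atp,
                   "atp_c": 1, "h2o_c": 1, "h_c": p_atp},
          gpr="atpA and atpB and atpC", subsystem="energy metabolism",
          name="ATP synthase")
    b.rxn("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
          lb=params.ngam, subsystem="energy metabolism",
          name="non-growth-associated maintenance (ATP hydrolysis)")

    # -- central carbon ------------------------------------------------------
    b.rxn("ACS", {"ac_c": -1, "coa_c": -1, "accoa_c": 1, "h2o_c": 1}, atp=1.0,
          gpr="acs1 or acs2", subsystem="central carbon",
          name="acetate activation to acetyl-CoA")
    b.rxn("POR", {"accoa_c": -1, "co2_c": -1, "fdred_c": -1,
                  "pyr_c": 1, "coa_c": 1, "fdox_c": 1},
          gpr="porA and porB", subsystem="central carbon",
          name="pyruvate synthase (pyruvate:ferredoxin oxidoreductase)")
    b.rxn("PC", {"pyr_c": -1, "co2_c": -1, "oaa_c": 1}, atp=1.0,
          gpr="pycA", subsystem="central carbon", name="pyruvate carboxylase")
    # reductive TCA arm to 2-oxoglutarate (succinyl-CoA synthetase +
    # 2-oxoglutarate synthase, lumped)
    b.rxn("RTCA", {"oaa_c": -1, "fdred_c": -3, "co2_c": -1,
                   "akg_c": 1, "h2o_c": 2, "fdox_c": 3}, atp=1.0,
          gpr="sucCD and korAB", subsystem="central carbon",
          name="reductive TCA arm (OAA to 2-oxoglutarate, lump)")
    if params.include_cs:
        b.model.add_reaction(citrate_synthase_reaction())

    # -- biosynthesis --------------------------------------------------------
    via_akg = params.glutamate_via_akg
    for aa in params.amino_acids:
        a, n_nh3, d, t, _x = AA_TABLE[aa]
        if params.aa_atp_cost is not None:
            t = params.aa_atp_cost
        if via_akg and aa in _AKG_AA_FORMULAS:
            if aa == "glu":
                stoich = {"akg_c": -1, "nh4_c": -1, "fdred_c": -1,
                          "glu_c": 1, "h2o_c": 1, "fdox_c": 1}
            else:  # gln from glu (condensation water returned)
                stoich = {"glu_c": -1, "nh4_c": -1, "gln_c": 1, "h2o_c": 1}
            b.rxn(f"{aa.upper()}syn", stoich, atp=1.0,
                  subsystem="amino acid metabolism", gpr=f"{aa}S")
            continue
        w = _AA_WATERS[aa]
        stoich = {"pyr_c": -a, "nh4_c": -n_nh3, f"{aa}_c": 1}
        if d:
            stoich.update({"fdred_c": -d, "fdox_c": d})
        if w:
            stoich["h2o_c"] = stoich.get("h2o_c", 0.0) + w
        b.rxn(f"{aa.upper()}syn", stoich, atp=t,
              subsystem="amino acid metabolism", gpr=f"{aa}S")

    for cls, key in (("LIP", "lipid"), ("CARB", "carb")):
        spec = _LUMPS[key]
        stoich = {"pyr_c": -spec["pyr"], f"{key}_c": 1,
                  "fdred_c": -spec["fdred"], "fdox_c": spec["fdred"]}
        if spec["water"]:
            stoich["h2o_c"] = spec["water"]
        b.rxn(f"{cls}syn", stoich, atp=spec["atp"],
              subsystem=f"{key} metabolism", gpr=f"{key}S")
    for key in ("rna", "dna"):
        spec = _LUMPS[key]
        stoich = {"pyr_c": -spec["pyr"], "nh4_c": -spec["nh3"],
                  "pi_c": -spec["pi"], f"{key}_c": 1,
                  "fdred_c": -spec["fdred"], "fdox_c": spec["fdred"],
                  "h2o_c": spec["water"]}
        b.rxn(f"{key.upper()}syn", stoich, atp=spec["atp"],
              subsystem="nucleotide metabolism", gpr=f"{key}S")
    b.rxn("SOLsyn", {"pi_c": -2, "so4_c": -1, "nh4_c": -1, "solute_c": 1},
          atp=2.0, subsystem="soluble pool", gpr="solS")
    if params.include_denovo_cobalamin:
        b.rxn("CBLDN",
              {"pyr_c": -21, "nh4_c": -14, "pi_c": -1, "cobalt2_c": -1,
               "fdred_c": -32, "fdox_c": 32, "cbl1_c": 1, "h2o_c": 53},
              atp=params.denovo_atp_cost,
              subsystem="cofactor biosynthesis", gpr="cbiLump",
              name="de novo cobalamin synthesis (lumped)")

    # -- biomass -------------------------------------------------------------
    comp = default_biomass_composition(params)
    bio = assemble_biomass(comp, params.gam, rxn_id=f"BIO_DHC_DM_{params.gam:g}",
                           model=b.model)
    b.model.add_reaction(bio)
    b.model.objective_rxn_id = bio.rxn_id

    for gene in b.model.genes.values():
        gene.category = gene.category or "core"

    b.model.meta.update(
        biomass_composition=comp,
        gam=params.gam,
        ngam=params.ngam,
        ngam_rxn="ATPM",
        atp_synthase_rxn="ATPS",
        respiration_rxn="RDH",
        protons_per_atp=p_atp,
        protons_per_h2=p_h2,
        currency={"atp": "atp_c", "h2o": "h2o_c", "adp": "adp_c", "pi": "pi_c"},
        params=params,
    )

    _assert_feasible(b.model, params)
    return b.model


def citrate_synthase_reaction() -> Reaction:
    """The optional oxidative route to 2-oxoglutarate (CS + aconitase +
    isocitrate dehydrogenase, lumped)."""
    return Reaction(
        rxn_id="CS",
        stoich={"accoa_c": -1, "oaa_c": -1, "h2o_c": -1, "fdox_c": -1,
                "akg_c": 1, "co2_c": 1, "coa_c": 1, "fdred_c": 1},
        lb=0.0, ub=DEFAULT_BOUND, gpr="csLump",
        subsystem="central carbon",
        name="citrate synthase arm (CS..IDH lump)",
    )


def minimal_medium(params: CoreNetworkParams | None = None,
                   h2_flux: float = 10.0) -> Medium:
    """The in silico minimal medium: H₂ (limiting), acetate, CO₂, PCE,
    cobalamin, N/P/S sources and water."""
    params = params or CoreNetworkParams()
    med = Medium({
        "EX_ac_e": (-10.0, DEFAULT_BOUND),
        "EX_cbl1_e": (-1.0, DEFAULT_BOUND),
        "EX_co2_e": (-10.0, DEFAULT_BOUND),
        "EX_h_e": (0.0, DEFAULT_BOUND),
        "EX_h2_e": (-h2_flux, DEFAULT_BOUND),
        "EX_h2o_e": (-DEFAULT_BOUND, DEFAULT_BOUND),
        "EX_pce_e": (-DEFAULT_BOUND, DEFAULT_BOUND),
        "EX_nh4_e": (-10.0, DEFAULT_BOUND),
        "EX_pi_e": (-10.0, DEFAULT_BOUND),
        "EX_so4_e": (-10.0, DEFAULT_BOUND),
    })
    return med


def _assert_feasible(model: MetabolicModel, params: CoreNetworkParams) -> None:
    from .fba import solve_fba  # deferred to avoid import cycle

    sol = solve_fba(model, medium=minimal_medium(params))
    if sol.optimal and sol.objective > 1e-9:
        return
    # diagnose: which biomass precursor cannot be produced?
    med = minimal_medium(params)
    for met_id in model.objective.stoich:
        if model.objective.stoich[met_id] >= 0:
            continue
        probe = model.copy()
        probe.add_reaction(Reaction(
            rxn_id="_probe_dm", stoich={met_id: -1.0}, lb=0.0, ub=DEFAULT_BOUND,
            kind="demand"))
        probe.objective_rxn_id = "_probe_dm"
        psol = solve_fba(probe, medium=med)
        if not psol.optimal or psol.objective <= 1e-9:
            raise GenerationError(
                f"infeasible parameter set: biomass precursor {met_id!r} "
                "cannot be synthesized on the minimal medium"
            )
    raise GenerationError(
        "infeasible parameter set: growth is zero although every biomass "
        "precursor is individually producible (energy balance blocks growth)"
    )


# -- pan-genome fixtures -----------------------------------------------------

@dataclass
class PanFixtureSpec:
    """Planted gene-family overlap structure for ``n_genomes`` genomes."""

    n_genomes: int = 4
    core: int = 10
    dispensable: int = 5
    unique: int = 8
    seed: int = 0
    multiplicities: dict[int, int] | None = None  # optional {shared-by-k: count}

    def __post_init__(self):
        if self.n_genomes < 2:
            raise ValueError("need at least two genomes")
        if min(self.core, self.dispensable, self.unique) < 0:
            raise ValueError("family counts must be non-negative")
        if self.multiplicities:
            for k, n in self.multiplicities.items():
                if not (2 <= k < self.n_genomes) or n < 0:
                    raise ValueError(f"invalid dispensable multiplicity {k}: {n}")


def generate_pangenome_fixture(spec: PanFixtureSpec | None = None):
    """Genomes + ortholog clusters realizing exactly the planted partition.

    Returns ``(genomes, clusters, expected)`` where ``expected`` is a dict
    with the planted (core, dispensable, unique) family counts.  Gene
    identifiers depend on the seed; the partition does not.
    """
    from .pangenome import GeneRecord, GenomeGeneSet, OrthologClusterSet

    spec = spec or PanFixtureSpec()
    rng = np.random.default_rng(spec.seed)
    genome_ids = [f"G{i+1}" for i in range(spec.n_genomes)]
    records: dict[str, list[GeneRecord]] = {g: [] for g in genome_ids}
    clusters: list[frozenset] = []

    def new_gene(genome: str, family: str) -> str:
        gid = f"{genome.lower()}_{family}_{rng.integers(0, 16**4):04x}"
        records[genome].append(GeneRecord(
            gene_id=gid, locus_tag=gid.upper(),
            annotation=f"planted family {family}"))
        return gid

    for i in range(spec.core):
        fam = f"core{i:04d}"
        members = frozenset((g, new_gene(g, fam)) for g in genome_ids)
        clusters.append(members)

    if spec.multiplicities:
        disp_plan = [k for k, n in sorted(spec.multiplicities.items())
                     for _ in range(n)]
    else:
        disp_plan = [
            int(rng.integers(2, spec.n_genomes)) for _ in range(spec.dispensable)
        ]
    for i, k in enumerate(disp_plan):
        fam = f"disp{i:04d}"
        chosen = rng.choice(spec.n_genomes, size=k, replace=False)
        members = frozenset(
            (genome_ids[j], new_gene(genome_ids[j], fam)) for j in chosen
        )
        clusters.append(members)

    for i in range(spec.unique):
        fam = f"uniq{i:04d}"
        genome = genome_ids[i % spec.n_genomes]
        new_gene(genome, fam)  # unclustered singleton

    genomes = [
        GenomeGeneSet.from_records(g, records[g]) for g in genome_ids
    ]
    expected = {
        "core": spec.core,
        "dispensable": len(disp_plan),
        "unique": spec.unique,
        "total": spec.core + len(disp_plan) + spec.unique,
    }
    return genomes, OrthologClusterSet(clusters), expected
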