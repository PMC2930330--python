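# Methods

This note records the models, parameter choices and numerical conventions
behind `panfba`, and what the synthetic fixtures do and do not establish
about real data.

## Pan-genome construction

The pan-genome is built by iterative augmented-genome merging. Starting
from a reference genome, each subject genome contributes exactly those
genes that share no ortholog cluster with a gene already in the augmented
set; clusters are an *input* (the package does not run BLAST/OrthoMCL,
though a reciprocal-best-hit + single-linkage fallback over a user-supplied
all-vs-all identity table is provided, default cut 30% identity — the
usual moderate-confidence homology threshold).

Gene *families* are connected components of the cluster graph under
transitive linkage, identified by a canonical hash of their member set so
they can be compared across merge orders. Presence over genomes defines
the partition: core (all genomes), unique (exactly one), dispensable
(otherwise). Three facts shape the implementation:

* the family partition is order-invariant (components do not depend on the
  merge order), so the quantity that varies across orders — and that the
  max-over-orders selection acts on — is the pan **gene** count;
* gene counts become order-dependent precisely when a cluster holds
  within-genome paralogs (co-ortholog groups): starting at that genome
  keeps all paralogs, any other start collapses the cluster to one
  representative;
* a gene appearing in two clusters is rejected as corrupt input rather
  than silently merged.

All permutations of the input genomes are tried by default (the historical
analyses used an unspecified subset of orders); ties break to the
lexicographically smallest order so results are deterministic.

## The constraint-based model and FBA

`MetabolicModel` stores metabolites (id, formula, charge, compartment
∈ {c, e}), reactions (stoichiometry, bounds in mmol·gDCW⁻¹·h⁻¹, boolean
GPR, kind ∈ {intra-system, exchange, demand}) and a biomass objective.
Exchanges touch exactly one extracellular species, written `met <==>`;
positive flux is secretion, uptake allowance is a negative lower bound,
and applying a medium closes every unlisted exchange to uptake. Default
bounds are ±1000 (reversible) and [0, 1000] (irreversible) — the package's
infinity convention.

FBA maximizes biomass flux subject to S·v = 0 and the bounds, solved with
scipy's HiGHS interface (primal feasibility 1e-9, dual 1e-7; both
configurable). Only the objective value is contract-stable: alternate
optima are a fact of LP degeneracy, so analyses never depend on individual
fluxes unless `flux_variability` certifies them unique (min = max at fixed
optimum). Infeasibility and unboundedness are reported as statuses, never
as zero fluxes; note that a closed medium with a positive NGAM bound is
*infeasible* (maintenance cannot be covered), not zero-growth.

SBML I/O uses the COBRA Level-2 dialect (bounds as kinetic-law parameters,
GPRs as `GENE_ASSOCIATION` notes) with a reversible `__xHH__` escape map
for exotic identifiers; models without machine-readable GPRs parse as
non-gene-associated rather than guessing.

## Carbon-source attribution

The fraction of biomass carbon contributed by each import exchange is
computed by a linear carbon-flow (well-mixed pool) model: every active
reaction mixes the source composition of the carbon it consumes into the
carbon-bearing species it produces, giving a sparse linear system whose
solution is each pool's source composition; the biomass reaction's
consumed-carbon mix is reported. A gross exchange-flux ratio would be
wrong for this guild because the respiratory electron acceptor itself
carries carbon (tetrachloroethene in, trichloroethene out) that never
enters biomass. Pool mixing is exact whenever each reaction has a single
carbon-bearing product (true throughout the default core network, where
currency adenylates are modelled with a zero-mass scaffold placeholder and
carriers like CoA/ferredoxin are carbon-free lumps); with several carbon
products the attribution is an approximation to positional atom tracing.

## Biomass, maintenance and yield conventions

Biomass coefficients are `1000 × class weight fraction × monomer mole
fraction / mean class molar mass` (mmol/gDCW), so Σ coeffᵢ·MWᵢ = 1000 mg
identically; the cobalamin weight fraction is carried separately and
rescaling it renormalizes the other classes to keep the total at 1. GAM
ATP hydrolysis lives inside the biomass reaction; NGAM is the lower bound
of a dedicated ATP-hydrolysis reaction — the standard separation of the
two maintenance terms.

Electron accounting is fixed at 2 eeq per mol H₂; yields are gDCW per eeq
of donor. NGAM follows the Pirt relation (decay ÷ yield, converted to ATP
with the network's ATP-per-eeq). The energy-conservation defaults are 4 H⁺
translocated per H₂-coupled dechlorination and 6 H⁺ per ATP, i.e. ⅔ ATP/H₂
(⅓ ATP/eeq); with the reported decay rate 0.09 day⁻¹ and mean pure-culture
yield 0.69 gDCW/eeq this reproduces the reference NGAM of 1.8 mmol
ATP·gDCW⁻¹·h⁻¹ (the package computes 1.81). Both integers are config
fields; they are stoichiometric commitments, not measurements.

Energy-transfer efficiency normalizes realized ATP-per-H₂ by a
thermodynamic ceiling |ΔG(H₂ oxidation with the chlorinated acceptor)| /
(ATP synthesis cost). The defaults, ΔG = 189 kJ/mol and 85 kJ/mol per ATP,
are literature-scale round values giving a ceiling of ≈2.22 ATP/H₂, which
places the default respiratory stoichiometry at ≈30% efficiency — the
regime observed for pure cultures. Both are declared config values
(`EnergyConfig`).

GAM calibration is a bisection on the monotone non-increasing μ(GAM)
response; because dμ/dGAM is small (≈4 × 10⁻⁵ h⁻¹ per mmol ATP/gDCW on
the default network), iteration continues until *both* |μ − target| <
1e-4 h⁻¹ and the GAM bracket is narrower than 0.05 mmol ATP/gDCW, which is
what makes ±0.5 parameter recovery possible.

## The synthetic core network

`generate_core_network` builds a ~35-reaction, fully elementally balanced
(C,H,N,O,P,S,Cl,Co + zero-mass carrier placeholders) reduced network:
H₂ase reduces a ferredoxin lump; a proton-translocating reductive
dehalogenase lump respires PCE → TCE (chain depth 2 adds TCE → ethene);
ATP synthase closes the proton loop; acetate is activated to acetyl-CoA
and carboxylated by pyruvate synthase (POR) with CO₂ — the sole carbon
entry into anabolism; pyruvate carboxylase and a reductive arm to
2-oxoglutarate represent the incomplete TCA cycle, with an optional
citrate-synthase lump for the oxidative topology; cobalamin is salvaged by
an ABC transporter (optional lumped de novo pathway from cobalt at a
configurable ATP cost, default 40 mmol ATP per mmol — a literature-scale
placeholder); seven amino-acid lumps, lipid, carbohydrate, nucleotide and
soluble-pool lumps are synthesized from pyruvate, NH₃, phosphate, sulfate
and ferredoxin, with formulas *derived from their synthesis reactions* so
balance holds by construction.

Deliberate idealizations, and what they imply:

* **All assimilated carbon passes through POR by default** (the glutamate
  family is a pyruvate lump unless `glutamate_via_akg=True` routes it
  through 2-oxoglutarate). Consequently the CO₂ : acetate carbon split is
  exactly 1 : 2 — the same number the full reconstruction reports — but
  by construction; the fixture demonstrates the accounting, not genomic
  evidence. The 2-oxoglutarate routing (and the CS toggle) is the
  configuration used for TCA-topology experiments.
* The macromolecular weight fractions (protein 0.63, lipid 0.091,
  carbohydrate 0.062, DNA 0.049, RNA 0.059, soluble pool 0.079, ions
  0.030) follow the protein-dominated, archaeal-S-layer-like split assumed
  for these cell-wall-less organisms; the baseline cobalamin weight
  fraction is 1 × 10⁻⁴ g/gDCW, a stand-in for the maximum reported
  corrinoid content (a required config value, not a measurement).
* **Default GAM = 299.644 mmol ATP/gDCW is calibrated**, by the same
  regression the maintenance analysis prescribes, so that the default
  network grows at the mean pure-culture rate 0.014 h⁻¹ at H₂ = 10 with
  NGAM 1.81. A lumped ~35-reaction network omits most ATP-consuming
  pathway detail, so its calibrated GAM absorbs those costs and is much
  larger than a genome-scale model's (~61); the two numbers are not
  comparable. Parameter-recovery tests plant and re-estimate arbitrary
  GAMs.
* Randomness affects identifiers (and optional jitter on non-binding
  ±1000 bounds) only; stoichiometry is deterministic given the
  parameters, so all numeric results are seed-independent.
* The generator verifies feasibility on the minimal medium and names the
  first unproducible biomass precursor (or the energy balance) when a
  parameter set cannot grow.

Passing tests on these fixtures establish that the algorithms — merging,
partitioning, LP solving, calibration, attribution — are correct against
independent oracles (vertex enumeration, truth tables, fixed-point carbon
propagation, planted ground truths). They do not validate the biology of
any particular genome-scale reconstruction; for that, load the published
SBML and re-run the same operations.

## Scenario conventions

* Citrate-synthase comparison reports *both* arms (reductive arm open vs
  CS open with the reductive lump closed) rather than asserting which is
  "the" organism; on the synthetic network the two growth rates differ by
  under 1%.
* "Unlimited" amino-acid supplementation is lb = −1000 on each exchange,
  H₂ pinned at 10.
* Cobalamin robustness rebuilds the biomass per fraction multiplier; the
  growth breakpoint equals μ_max × biomass cobalamin coefficient, checked
  in closed form.
* Efficiency scaling rewrites the respiratory proton translocation to
  `efficiency × (thermodynamic max ATP/H₂) × protons-per-ATP`. Yield vs
  efficiency is then mildly *concave*, not exactly linear: biosynthetic
  reducing equivalents draw on the same fixed H₂ budget, giving
  μ = (k·H₂ − NGAM)/(A + k·E) with k ∝ efficiency. Over the studied
  window (efficiency 0.2–0.8, bracketing the ~30% pure-culture and ~65%
  mixed-culture marks) the default network's R² against a straight line is
  0.9993; at low GAM parameterizations the concavity is more visible
  (R² ≈ 0.994). Yield is exactly invariant to acetate allowance above the
  stoichiometric minimum — the energy-limited signature.
* Every `ScenarioResult` stores a provenance block (model hash, medium,
  parameters) and the yield convention, and re-running a scenario from the
  same inputs is bitwise reproducible (deterministic LP).

## Problem sizes

Everything is desk-scale by design: the core network has ~35 reactions
(58 including exchanges) and solves in milliseconds; property batteries
use 200 random ≤8-reaction LPs against brute-force vertex enumeration,
exhaustive GPR truth tables to 5 genes, 50–100 random compositions and
pan-genome fixtures, and 20 GAM-recovery parameterizations. The full test
suite runs in well under a minute.

## Known limitations

* Two compartments only; no thermodynamic (loopless) constraints, no
  SBML-L3/FBC authoring, no community modelling.
* Carbon attribution is elemental mixing, not positional atom tracing.
* The reduced network's monomer lumps have derived (partly non-natural)
  formulas; masses and redox demands are realistic in aggregate, not per
  species.
* Reproducing published genome-scale numbers requires the deposited SBML
  and its original constraint set, which are not redistributable here.
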