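"""Expansion of a :class:`~pcmodel.model_schema.ModelSpec` into a
proteome-constrained linear program (PCModel).

For every protein the builder creates a synthesis reaction (amino-acid and
energy demand on the ribosome), a degradation reaction (first-order turnover
returning residues), and a lifecycle balance ``v_syn - v_deg - mu*e = 0`` in
which the growth rate mu enters as a parameter — dilution is implicit in the
lifecycle row rather than a separate pseudo-flux.  On top of the metabolite
mass balances it adds:

* enzyme-capacity *equalities* ``v = s * kcat * e`` (enzymes work at maximal
  rate, so minimal required protein levels are computed),
* ribosome-capacity inequalities for the cytosolic and mitochondrial pools,
* per-compartment proteome pool constraints (occupancy form, rhs = 1),
* the cytosolic density *equality* closed by the unspecified protein (UP),
  with a minimum UP expression level,
* a mitochondrial import capacity row tied to the designated importer.

All rows are linear in (v, e) for fixed mu; mu-dependent coefficients are kept
symbolically as ``coeffs + mu * mu_coeffs`` so the LP can be re-assembled at
any growth rate without rebuilding.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

from .model_schema import (
    ModelSpec, ProteinSpec, ReactionSpec, RibosomeParams, Compartment,
    validate, ValidationError,
)

# ---------------------------------------------------------------------------
# energy accounting constants (mmol ATP equivalents); the cost classes are
# translation initiation (with 5'UTR scanning), peptide-bond formation
# (aminoacylation + translocation collapsed), and proteolysis
# ---------------------------------------------------------------------------
ATP_PER_PEPTIDE_BOND = 2.0
C_INIT = 1.0            # per peptide chain
C_SCAN_PER_NT = 0.05    # per 5'UTR nucleotide, per chain
C_DEG_PER_RESIDUE = 1.0

SYN_PREFIX = "syn__"
DEG_PREFIX = "deg__"


@dataclass
class Variable:
    name: str
    kind: str                    # "flux" | "enzyme" | "complex"
    lb: float = 0.0
    ub: float | None = None      # None = +inf
    lb_mu: float = 0.0           # bound = lb + mu * lb_mu
    ub_mu: float = 0.0
    mass: float = 0.0            # g/mmol (enzymes and synthesis fluxes)


@dataclass
class LinearRow:
    name: str
    kind: str                    # "eq" | "ub"   (ub rows: coeffs . x <= rhs)
    coeffs: dict[int, float]
    rhs: float = 0.0
    mu_coeffs: dict[int, float] = field(default_factory=dict)
    category: str = ""           # mass_balance | lifecycle | degradation |
                                 # coupling | ribosome | pool | density |
                                 # min_up | import | complex
    pool: str | None = None      # compartment id for pool/density rows


@dataclass
class PCModel:
    """The expanded, growth-rate-parametrised linear constraint system."""
    base: ModelSpec
    variables: list[Variable]
    rows: list[LinearRow]
    var_index: dict[str, int]
    pool_capacities: dict[str, float]    # per-gDW units after conversion
    density_pool: str | None             # compartment id of the equality pool
    uptake_vars: list[int]               # flux vars tagged "uptake"
    min_up_fraction: float               # g UP per g total protein floor

    def idx(self, name: str) -> int:
        return self.var_index[name]

    def to_debug_dict(self) -> dict:
        """Full dump of variables, rows and coefficients for inspection and
        for independent re-computation in oracle tests."""
        return {
            "variables": [
                {"name": v.name, "kind": v.kind, "lb": v.lb, "ub": v.ub,
                 "lb_mu": v.lb_mu, "ub_mu": v.ub_mu, "mass": v.mass}
                for v in self.variables
            ],
            "rows": [
                {"name": r.name, "kind": r.kind, "category": r.category,
                 "pool": r.pool, "rhs": r.rhs,
                 "coeffs": {self.variables[i].name: c
                            for i, c in sorted(r.coeffs.items())},
                 "mu_coeffs": {self.variables[i].name: c
                               for i, c in sorted(r.mu_coeffs.items())}}
                for r in self.rows
            ],
            "pool_capacities": self.pool_capacities,
            "density_pool": self.density_pool,
            "min_up_fraction": self.min_up_fraction,
        }

    def to_debug_json(self) -> str:
        return json.dumps(self.to_debug_dict(), indent=1, sort_keys=False)


# ---------------------------------------------------------------------------
# per-protein lifecycle reactions
# ---------------------------------------------------------------------------

def synthesis_energy(protein: ProteinSpec) -> float:
    """Total ATP equivalents to make one peptide chain: elongation energy for
    length-1 bonds plus the initiation cost c_init + c_scan * utr_length."""
    return (ATP_PER_PEPTIDE_BOND * (protein.length - 1)
            + C_INIT + C_SCAN_PER_NT * protein.utr_length)


def make_synthesis(protein: ProteinSpec, ribosome: RibosomeParams,
                   aa_species: str = "aa", energy_species: str = "atp",
                   ) -> ReactionSpec:
    """Translation of one protein: consumes ``length`` precursor residues and
    the chain's energy cost, produces one unit of the protein."""
    if protein.length < 1:
        raise ValueError(f"protein {protein.id}: length must be >= 1")
    stoich = {aa_species: -float(protein.length),
              energy_species: -synthesis_energy(protein),
              protein.id: 1.0}
    return ReactionSpec(id=SYN_PREFIX + protein.id,
                        stoichiometry={k: v for k, v in stoich.items() if v != 0.0},
                        tags={"synthesis"})


def make_degradation(protein: ProteinSpec,
                     aa_species: str = "aa", energy_species: str = "atp",
                     ) -> ReactionSpec:
    """Proteolysis: consumes one unit of protein and c_deg ATP per residue,
    returns all residues to the precursor pool.  In steady state this
    reaction's flux equals k_deg * e_i (enforced by the degradation row)."""
    stoich = {protein.id: -1.0,
              aa_species: float(protein.length),
              energy_species: -C_DEG_PER_RESIDUE * protein.length}
    return ReactionSpec(id=DEG_PREFIX + protein.id,
                        stoichiometry={k: v for k, v in stoich.items() if v != 0.0},
                        tags={"degradation"})


# ---------------------------------------------------------------------------
# the builder
# ---------------------------------------------------------------------------

def build_pc_model(model: ModelSpec, *, density_as_equality: bool = True,
                   enforce_min_up: bool = True) -> PCModel:
    """Expand *model* into the full proteome-constrained constraint system.

    ``density_as_equality=False`` relaxes the cytosolic density row to an
    upper bound (used by ablation studies and the proteome-efficiency
    driver); the structural content is otherwise identical.
    """
    report = validate(model)
    if report:
        raise ValidationError("model invalid: " + "; ".join(map(str, report)))

    aa_species = _species_with_role(model, "amino_acid")
    energy_species = _species_with_role(model, "energy")

    variables: list[Variable] = []
    var_index: dict[str, int] = {}

    def add_var(v: Variable) -> int:
        var_index[v.name] = len(variables)
        variables.append(v)
        return var_index[v.name]

    # --- flux variables: base network, then per-protein lifecycle, then the
    # builder-owned biomass and maintenance demands ------------------------
    for r in model.reactions:
        lb_mu = ub_mu = 0.0
        lb, ub = r.lb, r.ub
        add_var(Variable(name=r.id, kind="flux", lb=lb, ub=ub,
                         lb_mu=lb_mu, ub_mu=ub_mu))

    syn_rxns: dict[str, ReactionSpec] = {}
    deg_rxns: dict[str, ReactionSpec] = {}
    for p in model.proteins:
        if model.proteins and model.ribosome is None:  # pragma: no cover
            raise ValidationError("model has proteins but no ribosome")
        syn = make_synthesis(p, model.ribosome, aa_species, energy_species)
        deg = make_degradation(p, aa_species, energy_species)
        syn_rxns[p.id] = syn
        deg_rxns[p.id] = deg
        add_var(Variable(name=syn.id, kind="flux", mass=p.mass))
        add_var(Variable(name=deg.id, kind="flux"))

    # biomass demand: flux pinned to mu, drawing the non-protein composition
    # plus growth-associated maintenance ATP
    biomass_stoich = {m: -c for m, c in model.biomass.composition.items()}
    if model.biomass.gam > 0:
        biomass_stoich[energy_species] = (biomass_stoich.get(energy_species, 0.0)
                                          - model.biomass.gam)
    add_var(Variable(name="biomass_demand", kind="flux",
                     lb=0.0, ub=0.0, lb_mu=1.0, ub_mu=1.0))
    ngam_total = model.biomass.ngam + model.conditions.carbon_ngam
    add_var(Variable(name="maintenance", kind="flux",
                     lb=ngam_total, ub=ngam_total))

    # --- enzyme and complex level variables -------------------------------
    for p in model.proteins:
        add_var(Variable(name="enz__" + p.id, kind="enzyme", mass=p.mass,
                         lb=p.fixed_level if p.fixed_level is not None else 0.0,
                         ub=p.fixed_level))
    for cx in model.complexes:
        add_var(Variable(name="cplx__" + cx.id, kind="complex"))

    rows: list[LinearRow] = []

    # --- (1) steady-state metabolite mass balances ------------------------
    balance: dict[str, tuple[dict[int, float], dict[int, float]]] = {
        m.id: ({}, {}) for m in model.metabolites if not m.boundary}

    def accumulate(rxn_stoich: dict[str, float], var: int, coeff_scale: float = 1.0):
        for mid, coeff in rxn_stoich.items():
            if mid in balance:
                balance[mid][0][var] = balance[mid][0].get(var, 0.0) + coeff * coeff_scale

    for r in model.reactions:
        accumulate(r.stoichiometry, var_index[r.id])
    for p in model.proteins:
        accumulate({k: v for k, v in syn_rxns[p.id].stoichiometry.items()
                    if k != p.id}, var_index[SYN_PREFIX + p.id])
        accumulate({k: v for k, v in deg_rxns[p.id].stoichiometry.items()
                    if k != p.id}, var_index[DEG_PREFIX + p.id])
    accumulate(biomass_stoich, var_index["biomass_demand"])
    if energy_species in balance:
        balance[energy_species][0][var_index["maintenance"]] = \
            balance[energy_species][0].get(var_index["maintenance"], 0.0) - 1.0

    for m in model.metabolites:
        if m.boundary:
            continue
        coeffs, mu_coeffs = balance[m.id]
        rows.append(LinearRow(name="mass__" + m.id, kind="eq", coeffs=coeffs,
                              mu_coeffs=mu_coeffs, category="mass_balance"))

    # --- protein lifecycle and degradation kinetics -----------------------
    for p in model.proteins:
        e = var_index["enz__" + p.id]
        rows.append(LinearRow(
            name="life__" + p.id, kind="eq",
            coeffs={var_index[SYN_PREFIX + p.id]: 1.0,
                    var_index[DEG_PREFIX + p.id]: -1.0},
            mu_coeffs={e: -1.0},
            category="lifecycle"))
        rows.append(LinearRow(
            name="degk__" + p.id, kind="eq",
            coeffs={var_index[DEG_PREFIX + p.id]: 1.0, e: -p.k_deg},
            category="degradation"))

    # --- complex stoichiometric lumping: e_subunit = n * e_complex --------
    for cx in model.complexes:
        c = var_index["cplx__" + cx.id]
        for pid, n in cx.subunits.items():
            rows.append(LinearRow(
                name=f"cplx__{cx.id}__{pid}", kind="eq",
                coeffs={var_index["enz__" + pid]: 1.0, c: -float(n)},
                category="complex"))

    # --- (3) enzyme capacity equalities v = s * kcat * e ------------------
    prot_ids = {p.id for p in model.proteins}
    for rule in model.catalysis:
        cat_var = ("enz__" + rule.catalyst if rule.catalyst in prot_ids
                   else "cplx__" + rule.catalyst)
        rows.append(LinearRow(
            name="cap__" + rule.reaction, kind="eq",
            coeffs={var_index[rule.reaction]: 1.0,
                    var_index[cat_var]: -rule.saturation * rule.kcat},
            category="coupling"))

    # --- (4) ribosome capacity, cytosolic and mitochondrial ---------------
    cyto_terms: dict[int, float] = {}
    mito_terms: dict[int, float] = {}
    cyto_rib = mito_rib = None
    for p in model.proteins:
        if p.is_ribosome:
            comp = model.compartment(p.compartment)
            if comp.organelle == "mitochondrial":
                mito_rib = p
            else:
                cyto_rib = p
    for p in model.proteins:
        term = (mito_terms if model.translated_by_mito_ribosome(p) else cyto_terms)
        term[var_index[SYN_PREFIX + p.id]] = float(p.length)
    if cyto_terms:
        if cyto_rib is None:
            raise ValidationError("model has cytosolically translated proteins "
                                  "but no cytosolic ribosome")
        coeffs = dict(cyto_terms)
        coeffs[var_index["enz__" + cyto_rib.id]] = -model.ribosome.effective_k_el
        rows.append(LinearRow(name="ribosome__cyto", kind="ub", coeffs=coeffs,
                              rhs=0.0, category="ribosome"))
    if mito_terms:
        if mito_rib is None:
            raise ValidationError("model has mitochondrially translated proteins "
                                  "but no mitochondrial ribosome")
        if model.ribosome.effective_mito_k_el <= 0:
            raise ValidationError("mitochondrial translation requires mito_k_el > 0")
        coeffs = dict(mito_terms)
        coeffs[var_index["enz__" + mito_rib.id]] = -model.ribosome.effective_mito_k_el
        rows.append(LinearRow(name="ribosome__mito", kind="ub", coeffs=coeffs,
                              rhs=0.0, category="ribosome"))

    # --- (5)/(6) compartment proteome pools and the density equality ------
    p_ref = model.biomass.protein_per_gdw
    cells = model.conditions.cells_per_gdw
    pool_capacities: dict[str, float] = {}
    density_pool = None
    up = model.unspecified_protein
    for comp in model.compartments:
        members = [p for p in model.proteins if p.compartment == comp.id]
        cap = (comp.capacity * p_ref if comp.kind == "volumetric"
               else comp.capacity * cells)
        pool_capacities[comp.id] = cap
        coeffs = {var_index["enz__" + p.id]: p.specific_size(comp) / cap
                  for p in members}
        if comp.fill_rule == "equality":
            density_pool = comp.id
            kind = "eq" if density_as_equality else "ub"
            rows.append(LinearRow(name="density__" + comp.id, kind=kind,
                                  coeffs=coeffs, rhs=1.0, category="density",
                                  pool=comp.id))
        else:
            if coeffs:
                rows.append(LinearRow(name="pool__" + comp.id, kind="ub",
                                      coeffs=coeffs, rhs=1.0, category="pool",
                                      pool=comp.id))

    # minimum UP expression relative to the (variable) total protein mass:
    # mass_UP * e_UP >= f * sum_i mass_i * e_i.  Through this coupling every
    # gram of protein anywhere in the cell claims f grams of cytosolic space
    # for unspecified protein.
    min_up_fraction = 0.0
    if up is not None and enforce_min_up and model.conditions.min_up_fraction > 0:
        f = model.conditions.min_up_fraction
        min_up_fraction = f
        coeffs = {var_index["enz__" + p.id]: f * p.mass for p in model.proteins}
        coeffs[var_index["enz__" + up.id]] = (f - 1.0) * up.mass
        rows.append(LinearRow(
            name="min_up", kind="ub", coeffs=coeffs,
            rhs=0.0, category="min_up", pool=density_pool))

    # --- mitochondrial import capacity ------------------------------------
    import_row = make_import_demand(model, var_index)
    if import_row is not None:
        rows.append(import_row)

    uptake_vars = [var_index[r.id] for r in model.reactions if "uptake" in r.tags]

    return PCModel(base=model, variables=variables, rows=rows,
                   var_index=var_index, pool_capacities=pool_capacities,
                   density_pool=density_pool, uptake_vars=uptake_vars,
                   min_up_fraction=min_up_fraction)


def make_import_demand(model: ModelSpec, var_index: dict[str, int],
                       ) -> LinearRow | None:
    """Cap the summed synthesis flux of mitochondrially imported proteins by
    the designated importer: sum v_syn,i <= k_import * e_importer.

    The importer is a membrane-resident protein or complex competing for
    inner-membrane pool space.  Returns ``None`` when the model has no
    imported proteins; raises when imported proteins exist without a
    designated importer.
    """
    imported = [p for p in model.proteins if p.import_route == "mitochondrial"]
    if not imported:
        return None
    if model.import_params is None:
        raise ValidationError("model has mitochondrially imported proteins "
                              "but no designated importer")
    imp = model.import_params
    prot_ids = {p.id for p in model.proteins}
    imp_var = ("enz__" + imp.importer if imp.importer in prot_ids
               else "cplx__" + imp.importer)
    coeffs = {var_index[SYN_PREFIX + p.id]: 1.0 for p in imported}
    coeffs[var_index[imp_var]] = coeffs.get(var_index[imp_var], 0.0) - imp.k_import
    return LinearRow(name="import__mito", kind="ub", coeffs=coeffs,
                     rhs=0.0, category="import")


def _species_with_role(model: ModelSpec, role: str) -> str:
    hits = [m.id for m in model.metabolites if m.role == role]
    if not hits:
        raise ValidationError(f"model must declare a metabolite with role "
                              f"'{role}' to build protein lifecycle reactions")
    return hits[0]
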