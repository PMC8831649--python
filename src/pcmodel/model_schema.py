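"""Domain types, validation and I/O for proteome-constrained metabolic models.

A :class:`ModelSpec` bundles a stoichiometric network with the protein-level
annotations needed to expand it into a proteome-constrained model: per-protein
lengths, compartment assignments, specific sizes (volume or membrane area per
mmol), degradation constants, catalysis rules (kcat assignments) and ribosome
parameters.  Models are stored in a versioned JSON schema (see
``docs/methods.md`` and the packaged ``data/toy_yeast.json`` for a worked
instance); condition overlays are small YAML files that override the three
condition-dependent parameters (transporter capacity, carbon-linked NGAM,
minimal unspecified-protein fraction).

Unit conventions
----------------
* fluxes: mmol/gDW/h; enzyme levels: mmol/gDW
* protein mass: 110 g/mol per residue (``AA_RESIDUE_MASS``)
* volumetric compartment capacities: g protein per g total protein, converted
  to g/gDW with the reference total protein content ``protein_per_gdw``
* membrane compartment capacities: um^2 per cell, converted to um^2/gDW with
  the ``cells_per_gdw`` constant
* uptake fluxes are positive into the cell; exchange reactions are written
  ``substrate_external -> substrate``
"""
from __future__ import annotations

import copy
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

SCHEMA_VERSION = 1

# ---------------------------------------------------------------------------
# package-wide physical constants (single calibration knobs, overridable via
# the model file)
# ---------------------------------------------------------------------------

#: average amino-acid residue mass, g per mmol of residues
AA_RESIDUE_MASS = 0.110

#: cells per gram dry weight (15 pg dry mass per cell); converts per-cell
#: membrane areas into per-gDW capacities
DEFAULT_CELLS_PER_GDW = 6.7e10

#: membrane footprint per residue for integral membrane proteins,
#: um^2 per mmol per residue (~0.022 nm^2 per residue per molecule)
MEMBRANE_AREA_PER_RESIDUE = 1.32e13

#: default reference total protein content, g protein per gDW
DEFAULT_PROTEIN_PER_GDW = 0.46


class SchemaError(ValueError):
    """Raised when a model file does not conform to the JSON schema."""


class ValidationError(ValueError):
    """Raised when cross-references in a model cannot be resolved."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    carbon: int = 0                 # carbon atoms, used for balance checks
    boundary: bool = False          # boundary species are not mass-balanced
    mass: float | None = None       # g/mmol, optional (yields)
    role: str = ""                  # "", "amino_acid" or "energy"


@dataclass
class Compartment:
    """A proteome pool.

    ``kind`` is ``volumetric`` (capacity in g protein / g total protein) or
    ``membrane`` (capacity in um^2 per cell).  At most one compartment may use
    ``fill_rule="equality"`` — the cytosol, whose density constraint is closed
    by the unspecified protein.  ``organelle`` distinguishes mitochondrial
    pools, which determines which ribosome translates resident proteins.
    """
    id: str
    kind: str                       # "volumetric" | "membrane"
    capacity: float
    fill_rule: str = "inequality"   # "inequality" | "equality"
    organelle: str = "cytoplasmic"  # "cytoplasmic" | "mitochondrial"


@dataclass
class ProteinSpec:
    id: str
    length: int                     # amino acids
    compartment: str
    w: float | None = None          # specific size per mmol (g or um^2)
    k_deg: float = 0.0              # 1/h
    utr_length: int = 0             # nt, 5'UTR scanning cost
    is_ribosome: bool = False
    is_unspecified: bool = False
    import_route: str = "none"      # "none" | "mitochondrial"
    fixed_level: float | None = None  # pin e_i (mmol/gDW); gratuitous protein

    @property
    def mass(self) -> float:
        """Molecular mass in g/mmol."""
        return self.length * AA_RESIDUE_MASS

    def specific_size(self, compartment: Compartment) -> float:
        """w_i: g/mmol in volumetric pools, um^2/mmol in membranes."""
        if self.w is not None:
            return self.w
        if compartment.kind == "membrane":
            return self.length * MEMBRANE_AREA_PER_RESIDUE
        return self.mass


@dataclass
class CatalysisRule:
    reaction: str
    catalyst: str                   # protein or complex id
    kcat: float                     # 1/h
    saturation: float = 1.0         # in (0, 1]


@dataclass
class ReactionSpec:
    id: str
    stoichiometry: dict[str, float]
    lb: float = 0.0
    ub: float | None = None         # None = +inf
    tags: set[str] = field(default_factory=set)


@dataclass
class ComplexSpec:
    id: str
    subunits: dict[str, int]
    compartment: str


@dataclass
class RibosomeParams:
    k_el: float                     # aa/h, cytosolic elongation rate
    f_inactive: float = 0.0         # inactive ribosome fraction, [0, 1)
    sigma: float = 1.0              # saturation of translating ribosomes
    mito_k_el: float = 0.0          # aa/h, mitochondrial ribosome pool

    @property
    def effective_k_el(self) -> float:
        return self.sigma * (1.0 - self.f_inactive) * self.k_el

    @property
    def effective_mito_k_el(self) -> float:
        return self.sigma * (1.0 - self.f_inactive) * self.mito_k_el


@dataclass
class ImportParams:
    """Mitochondrial protein import: total import flux is capped by the
    designated importer complex/protein residing in the inner membrane."""
    importer: str
    k_import: float                 # mmol protein imported / h / mmol importer


@dataclass
class ConditionOverlay:
    """Named parameter overrides for a growth condition (sugar-excess runs)."""
    name: str
    transporter_capacity: float     # um^2 per cell
    carbon_ngam: float              # mmol ATP/gDW/h on top of base NGAM
    min_up_fraction: float          # g UP per g protein


@dataclass
class Conditions:
    name: str = "glucose"
    carbon_ngam: float = 0.0
    min_up_fraction: float = 0.0
    cells_per_gdw: float = DEFAULT_CELLS_PER_GDW


@dataclass
class BiomassSpec:
    composition: dict[str, float] = field(default_factory=dict)  # mmol/g biomass
    gam: float = 0.0                # mmol ATP per g biomass
    ngam: float = 0.0               # mmol ATP/gDW/h
    protein_per_gdw: float = DEFAULT_PROTEIN_PER_GDW


@dataclass
class ModelSpec:
    name: str
    metabolites: list[Metabolite]
    reactions: list[ReactionSpec]
    proteins: list[ProteinSpec]
    compartments: list[Compartment]
    catalysis: list[CatalysisRule]
    ribosome: RibosomeParams
    biomass: BiomassSpec
    complexes: list[ComplexSpec] = field(default_factory=list)
    import_params: ImportParams | None = None
    conditions: Conditions = field(default_factory=Conditions)
    amino_acid_model: str = "lumped"   # "lumped" | "per-species"

    # -- lookups ----------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        return _by_id(self.metabolites, mid)

    def protein(self, pid: str) -> ProteinSpec:
        return _by_id(self.proteins, pid)

    def reaction(self, rid: str) -> ReactionSpec:
        return _by_id(self.reactions, rid)

    def compartment(self, cid: str) -> Compartment:
        return _by_id(self.compartments, cid)

    def complex(self, cid: str) -> ComplexSpec:
        return _by_id(self.complexes, cid)

    @property
    def unspecified_protein(self) -> ProteinSpec | None:
        ups = [p for p in self.proteins if p.is_unspecified]
        return ups[0] if len(ups) == 1 else None

    def transporter_pool(self) -> Compartment | None:
        """The membrane compartment hosting the catalyst of the uptake
        reaction — the pool whose capacity the overlay overrides."""
        uptake = [r for r in self.reactions if "uptake" in r.tags]
        for rule in self.catalysis:
            if any(rule.reaction == r.id for r in uptake):
                comp_id = self._catalyst_compartment(rule.catalyst)
                if comp_id is not None:
                    comp = self.compartment(comp_id)
                    if comp.kind == "membrane":
                        return comp
        return None

    def _catalyst_compartment(self, cat_id: str) -> str | None:
        for p in self.proteins:
            if p.id == cat_id:
                return p.compartment
        for c in self.complexes:
            if c.id == cat_id:
                return c.compartment
        return None

    def translated_by_mito_ribosome(self, protein: ProteinSpec) -> bool:
        """Proteins resident in a mitochondrial compartment that were not
        imported must have been translated by the mitochondrial ribosome."""
        comp = self.compartment(protein.compartment)
        return comp.organelle == "mitochondrial" and protein.import_route == "none"


def _by_id(items, item_id):
    for it in items:
        if it.id == item_id:
            return it
    raise KeyError(item_id)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    entity: str
    rule: str
    value: object

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.entity}: {self.rule} (got {self.value!r})"


def validate(model: ModelSpec) -> list[Violation]:
    """Check every type invariant; returns an empty list iff the model is valid."""
    v: list[Violation] = []
    comp_ids = {c.id for c in model.compartments}
    prot_ids = {p.id for p in model.proteins}
    cplx_ids = {c.id for c in model.complexes}
    met_ids = {m.id for m in model.metabolites}
    rxn_ids = {r.id for r in model.reactions}

    equality_comps = [c for c in model.compartments if c.fill_rule == "equality"]
    if len(equality_comps) > 1:
        v.append(Violation("compartments", "at most one equality fill_rule",
                           [c.id for c in equality_comps]))
    for c in model.compartments:
        if not (c.capacity > 0):
            v.append(Violation(c.id, "capacity > 0", c.capacity))
        if c.kind not in ("volumetric", "membrane"):
            v.append(Violation(c.id, "kind in {volumetric, membrane}", c.kind))
        if c.fill_rule not in ("inequality", "equality"):
            v.append(Violation(c.id, "fill_rule in {inequality, equality}", c.fill_rule))

    ups = [p for p in model.proteins if p.is_unspecified]
    if len(ups) != 1:
        v.append(Violation("proteins", "exactly one is_unspecified protein",
                           [p.id for p in ups]))
    for p in model.proteins:
        if p.length < 1:
            v.append(Violation(p.id, "length >= 1", p.length))
        if p.compartment not in comp_ids:
            v.append(Violation(p.id, "compartment exists", p.compartment))
        else:
            if p.specific_size(model.compartment(p.compartment)) <= 0:
                v.append(Violation(p.id, "w > 0", p.w))
        if p.k_deg < 0:
            v.append(Violation(p.id, "k_deg >= 0", p.k_deg))
        if p.utr_length < 0:
            v.append(Violation(p.id, "utr_length >= 0", p.utr_length))
        if p.import_route not in ("none", "mitochondrial"):
            v.append(Violation(p.id, "import_route in {none, mitochondrial}",
                               p.import_route))
        if p.is_unspecified and p.compartment in comp_ids:
            comp = model.compartment(p.compartment)
            if comp.fill_rule != "equality":
                v.append(Violation(p.id, "UP must live in the density-equality "
                                   "compartment", p.compartment))

    seen_rxn = set()
    for rule in model.catalysis:
        if rule.kcat <= 0:
            v.append(Violation(rule.reaction, "kcat > 0", rule.kcat))
        if not (0 < rule.saturation <= 1):
            v.append(Violation(rule.reaction, "0 < saturation <= 1", rule.saturation))
        if rule.reaction not in rxn_ids:
            v.append(Violation(rule.reaction, "catalysed reaction exists", rule.reaction))
        if rule.catalyst not in prot_ids | cplx_ids:
            v.append(Violation(rule.reaction, "catalyst exists", rule.catalyst))
        if rule.reaction in seen_rxn:
            v.append(Violation(rule.reaction, "one rule per catalysed reaction",
                               rule.reaction))
        seen_rxn.add(rule.reaction)

    for r in model.reactions:
        if not r.stoichiometry and "exchange" not in r.tags:
            v.append(Violation(r.id, "nonempty stoichiometry unless exchange", {}))
        if r.ub is not None and r.lb > r.ub:
            v.append(Violation(r.id, "lb <= ub", (r.lb, r.ub)))
        for mid in r.stoichiometry:
            if mid not in met_ids:
                v.append(Violation(r.id, "metabolite exists", mid))

    for cx in model.complexes:
        if cx.compartment not in comp_ids:
            v.append(Violation(cx.id, "compartment exists", cx.compartment))
        for pid, n in cx.subunits.items():
            if pid not in prot_ids:
                v.append(Violation(cx.id, "subunit exists", pid))
            if n < 1:
                v.append(Violation(cx.id, "copies >= 1", n))

    rib = model.ribosome
    if rib.effective_k_el <= 0:
        v.append(Violation("ribosome", "sigma*(1-f_inactive)*k_el > 0",
                           rib.effective_k_el))
    if not (0 <= rib.f_inactive < 1):
        v.append(Violation("ribosome", "0 <= f_inactive < 1", rib.f_inactive))
    if not (0 < rib.sigma <= 1):
        v.append(Violation("ribosome", "0 < sigma <= 1", rib.sigma))

    cond = model.conditions
    if not (0 <= cond.min_up_fraction < 1):
        v.append(Violation("conditions", "0 <= min_up_fraction < 1",
                           cond.min_up_fraction))
    if cond.carbon_ngam < 0 or not math.isfinite(cond.carbon_ngam):
        v.append(Violation("conditions", "carbon_ngam finite and >= 0",
                           cond.carbon_ngam))

    if model.import_params is not None:
        imp = model.import_params
        if imp.importer not in prot_ids | cplx_ids:
            v.append(Violation("import", "importer exists", imp.importer))
        if imp.k_import <= 0:
            v.append(Violation("import", "k_import > 0", imp.k_import))

    for mid, coeff in model.biomass.composition.items():
        if mid not in met_ids:
            v.append(Violation("biomass", "metabolite exists", mid))
    return v


# ---------------------------------------------------------------------------
# condition overlays
# ---------------------------------------------------------------------------

def apply_overlay(model: ModelSpec, overlay: ConditionOverlay) -> ModelSpec:
    """Return a copy of *model* with the three condition parameters replaced.

    The transporter capacity is written through to the membrane pool that
    hosts the uptake catalyst; the original model is left unchanged.
    """
    for f in ("transporter_capacity", "carbon_ngam", "min_up_fraction"):
        val = getattr(overlay, f)
        if not math.isfinite(val):
            raise ValueError(f"overlay field {f} must be finite, got {val}")
    out = copy.deepcopy(model)
    pool = out.transporter_pool()
    if pool is None:
        raise ValidationError(
            "overlay references a transporter but the model has no catalysed "
            "uptake reaction on a membrane compartment")
    pool.capacity = overlay.transporter_capacity
    out.conditions = dataclasses.replace(
        out.conditions,
        name=overlay.name,
        carbon_ngam=overlay.carbon_ngam,
        min_up_fraction=overlay.min_up_fraction,
    )
    return out


def load_overlay(path: str | Path) -> ConditionOverlay:
    """Read a YAML overlay file with the three condition fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"overlay file {path} is not a mapping")
    try:
        return ConditionOverlay(
            name=str(raw.get("name", Path(path).stem)),
            transporter_capacity=float(raw["transporter_capacity"]),
            carbon_ngam=float(raw["carbon_ngam"]),
            min_up_fraction=float(raw["min_up_fraction"]),
        )
    except KeyError as e:
        raise SchemaError(f"overlay file {path} missing field {e.args[0]}") from e


def save_overlay(overlay: ConditionOverlay, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(overlay), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# JSON (de)serialisation
# ---------------------------------------------------------------------------

def _req(raw: Mapping, key: str, ctx: str):
    if key not in raw:
        raise SchemaError(f"{ctx}: missing required field '{key}'")
    return raw[key]


def model_to_dict(model: ModelSpec) -> dict:
    d = {
        "schema_version": SCHEMA_VERSION,
        "name": model.name,
        "amino_acid_model": model.amino_acid_model,
        "metabolites": [dataclasses.asdict(m) for m in model.metabolites],
        "reactions": [
            {"id": r.id, "stoichiometry": r.stoichiometry, "lb": r.lb,
             "ub": r.ub, "tags": sorted(r.tags)}
            for r in model.reactions
        ],
        "proteins": [dataclasses.asdict(p) for p in model.proteins],
        "complexes": [dataclasses.asdict(c) for c in model.complexes],
        "compartments": [dataclasses.asdict(c) for c in model.compartments],
        "catalysis": [dataclasses.asdict(c) for c in model.catalysis],
        "ribosome": dataclasses.asdict(model.ribosome),
        "biomass": dataclasses.asdict(model.biomass),
        "conditions": dataclasses.asdict(model.conditions),
    }
    if model.import_params is not None:
        d["import"] = dataclasses.asdict(model.import_params)
    return d


def model_from_dict(raw: Mapping) -> ModelSpec:
    if not isinstance(raw, Mapping):
        raise SchemaError("model document must be a JSON object")
    version = _req(raw, "schema_version", "model")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {version!r}")
    try:
        metabolites = [Metabolite(**m) for m in raw.get("metabolites", [])]
        reactions = [
            ReactionSpec(
                id=_req(r, "id", "reaction"),
                stoichiometry={str(k): float(v)
                               for k, v in _req(r, "stoichiometry", r.get("id", "reaction")).items()},
                lb=float(r.get("lb", 0.0)),
                ub=None if r.get("ub") is None else float(r["ub"]),
                tags=set(r.get("tags", [])),
            )
            for r in raw.get("reactions", [])
        ]
        proteins = [ProteinSpec(**p) for p in raw.get("proteins", [])]
        complexes = [ComplexSpec(**c) for c in raw.get("complexes", [])]
        compartments = [Compartment(**c) for c in raw.get("compartments", [])]
        catalysis = [CatalysisRule(**c) for c in raw.get("catalysis", [])]
        ribosome = RibosomeParams(**_req(raw, "ribosome", "model"))
        biomass = BiomassSpec(**_req(raw, "biomass", "model"))
        conditions = Conditions(**raw.get("conditions", {}))
        import_params = ImportParams(**raw["import"]) if "import" in raw else None
    except SchemaError:
        raise
    except (TypeError, KeyError, ValueError) as e:
        raise SchemaError(f"model document malformed: {e}") from e
    model = ModelSpec(
        name=str(raw.get("name", "unnamed")),
        metabolites=metabolites,
        reactions=reactions,
        proteins=proteins,
        compartments=compartments,
        catalysis=catalysis,
        ribosome=ribosome,
        biomass=biomass,
        complexes=complexes,
        import_params=import_params,
        conditions=conditions,
        amino_acid_model=str(raw.get("amino_acid_model", "lumped")),
    )
    _check_references(model)
    return model


def _check_references(model: ModelSpec) -> None:
    """Cross-reference resolution; raises listing every dangling reference."""
    dangling = [v for v in validate(model)
                if "exists" in v.rule or "density-equality" in v.rule]
    if dangling:
        raise ValidationError(
            "dangling references: " + "; ".join(str(d) for d in dangling))


def load_model(path: str | Path) -> ModelSpec:
    """Load and validate a model from the documented JSON schema."""
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: not valid JSON ({e})") from e
    return model_from_dict(raw)


def save_model(model: ModelSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# optional SBML import and annotation TSV
# ---------------------------------------------------------------------------

def import_sbml(path: str | Path) -> tuple[list[Metabolite], list[ReactionSpec]]:
    """Import metabolites and reactions from an SBML Level 3 file.

    Protein semantics (FBC gene products etc.) are deliberately ignored —
    annotations are supplied separately via :func:`read_annotations_tsv`.
    """
    import cobra.io  # deferred; optional extra

    cb = cobra.io.read_sbml_model(str(path))
    boundary_met_ids = {m.id for r in cb.boundary for m in r.metabolites}
    mets = [
        Metabolite(id=m.id,
                   carbon=int(m.elements.get("C", 0)) if m.formula else 0,
                   boundary=m.id in boundary_met_ids)
        for m in cb.metabolites
    ]
    rxns = [
        ReactionSpec(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lb=float(r.lower_bound),
            ub=None if r.upper_bound >= 1e6 else float(r.upper_bound),
            tags={"exchange"} if r.boundary else set(),
        )
        for r in cb.reactions
    ]
    return mets, rxns


def read_annotations_tsv(path: str | Path) -> list[ProteinSpec]:
    """Read a protein annotation table.

    Columns: protein_id, length, compartment, w, k_deg, utr_length.  An empty
    ``w`` defers to the length-derived default.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "length", "compartment"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"annotation table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        w = row.get("w")
        out.append(ProteinSpec(
            id=str(row["protein_id"]),
            length=int(row["length"]),
            compartment=str(row["compartment"]),
            w=None if w is None or (isinstance(w, float) and math.isnan(w)) else float(w),
            k_deg=float(row.get("k_deg", 0.0) or 0.0),
            utr_length=int(row.get("utr_length", 0) or 0),
        ))
    return out
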