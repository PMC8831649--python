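"""Fixtures and synthetic-data generators.

* :func:`make_self_replicator` — the one-protein analytic model whose maximal
  growth rate has the closed form ``mu_max = sigma * (1 - f_inactive) * k_el / L_R``,
  used to verify the bisection engine.
* :func:`make_toy_yeast` — a calibrated reduced yeast cell: ~12 lumped
  proteins over four proteome pools (cytosol, plasma membrane, mitochondrial
  matrix, inner mitochondrial membrane) with glycolytic, fermentative and
  respiratory routes, mitochondrial protein import and translation, and an
  unspecified-protein sector.  The default :class:`Calibration` is frozen
  from a scripted search (``scripts/calibrate_toy.py``) against four growth
  anchors: ethanol onset near 0.28 1/h, cytosol-full near 0.35 1/h, glucose
  batch growth in 0.37-0.39 1/h, and galactose batch growth near 0.16 1/h.
* :func:`make_random_model` — seeded random linear-pathway models for
  property tests.
* :func:`make_synthetic_proteomics` — measured-fraction tables emulating
  label-free proteomics with a known per-pathway enzyme saturation.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_schema import (
    ModelSpec, Metabolite, ReactionSpec, ProteinSpec, Compartment,
    CatalysisRule, ComplexSpec, RibosomeParams, ImportParams, BiomassSpec,
    Conditions, ConditionOverlay, DEFAULT_CELLS_PER_GDW,
)

# ---------------------------------------------------------------------------
# condition overlays (sugar-excess parameter sets)
# ---------------------------------------------------------------------------

#: transporter area um^2/cell, carbon-linked NGAM mmol/gDW/h, min UP g/g
OVERLAYS = {
    "glucose": ConditionOverlay("glucose", 7.5, 0.0, 0.245),
    "galactose": ConditionOverlay("galactose", 3.0, 3.0, 0.49),
    "maltose": ConditionOverlay("maltose", 3.5, 0.0, 0.34),
}


# ---------------------------------------------------------------------------
# self-replicator
# ---------------------------------------------------------------------------

def make_self_replicator(k_el: float, L_R: int, sigma: float = 1.0,
                         f_inactive: float = 0.0) -> ModelSpec:
    """One ribosome protein synthesising itself from free precursors.

    Amino acids and ATP are supplied by unbounded uncatalysed exchanges, the
    cytosol is the only pool, and the ribosome does not turn over — so the
    only binding constraint is its own elongation capacity and
    ``mu_max = sigma * (1 - f_inactive) * k_el / L_R`` exactly.
    """
    if min(k_el, L_R, sigma) <= 0 or not (0 <= f_inactive < 1):
        raise ValueError("self-replicator parameters must be positive "
                         "(f_inactive in [0, 1))")
    return ModelSpec(
        name="self_replicator",
        metabolites=[
            Metabolite("aa_ext", boundary=True),
            Metabolite("atp_ext", boundary=True),
            Metabolite("aa", carbon=5, role="amino_acid"),
            Metabolite("atp", role="energy"),
        ],
        reactions=[
            ReactionSpec("t_aa", {"aa_ext": -1.0, "aa": 1.0}),
            ReactionSpec("t_atp", {"atp_ext": -1.0, "atp": 1.0}),
        ],
        proteins=[
            ProteinSpec("R", length=int(L_R), compartment="cytosol",
                        k_deg=0.0, is_ribosome=True),
            ProteinSpec("UP", length=100, compartment="cytosol",
                        k_deg=0.0, is_unspecified=True),
        ],
        compartments=[
            Compartment("cytosol", kind="volumetric", capacity=1.0,
                        fill_rule="equality"),
        ],
        catalysis=[],
        ribosome=RibosomeParams(k_el=k_el, f_inactive=f_inactive, sigma=sigma,
                                mito_k_el=0.0),
        biomass=BiomassSpec(composition={}, gam=0.0, ngam=0.0,
                            protein_per_gdw=0.46),
        conditions=Conditions(name="self_replicator", min_up_fraction=0.0),
    )


# ---------------------------------------------------------------------------
# calibrated reduced yeast cell
# ---------------------------------------------------------------------------

@dataclass
class Calibration:
    """Parameter set of the reduced yeast model.

    kcats are per catalytic lump (1/h); lengths are aa-equivalents per
    catalytic unit chosen so minimal pathway mass fractions fall in the
    physiological range; capacities use the package unit conventions
    (volumetric: g/g protein, membranes: um^2/cell).
    """
    # conversion and global composition
    cells_per_gdw: float = DEFAULT_CELLS_PER_GDW
    protein_per_gdw: float = 0.46          # g protein / gDW reference
    carb_per_gdw: float = 3.33             # mmol non-protein lump / g biomass

    # compartment capacities
    cytosol_capacity: float = 0.3137       # g / g protein, density equality
    mito_matrix_capacity: float = 0.12     # g / g protein
    transporter_area: float = 7.5          # um^2/cell (glucose condition)
    mito_membrane_area: float = 258.0      # um^2/cell

    # catalytic constants, 1/h
    kcat_transport: float = 1.048e5
    kcat_glycolysis: float = 2.4e5
    kcat_fermentation: float = 4.0e5
    kcat_pyruvate_ox: float = 1.0e5
    kcat_respiration: float = 5.0e4
    kcat_aa_synth: float = 3.0e4
    kcat_carb_synth: float = 2.0e5
    k_import: float = 3600.0               # chains/h per importer complex

    # protein lengths, aa-equivalents
    lengths: dict = field(default_factory=lambda: {
        "HXT": 550, "GLY": 5000, "FER": 1500, "PDH": 3000,
        "RESP_N": 4000, "COX_M": 1000, "TOM": 2000, "AAS": 4000,
        "CBS": 2500, "RIB": 12000, "MRIB": 3000, "UP": 400,
    })
    k_deg_enzyme: float = 0.02             # 1/h, metabolic lumps

    # energy parameters
    p_o_ratio: float = 1.0                 # ATP per O
    gam: float = 44.9                      # mmol ATP / g biomass
    ngam: float = 1.0                      # mmol ATP/gDW/h
    carb_atp_cost: float = 1.0             # mmol ATP / mmol carb lump

    # ribosome parameters
    k_el: float = 36000.0                  # aa/h
    f_inactive: float = 0.15
    sigma: float = 0.85
    mito_k_el: float = 22000.0

    # glucose-condition proteome floor
    min_up_fraction: float = 0.245


DEFAULT_CALIBRATION = Calibration()

#: pathway annotation of the reduced model, used by the proteome-fraction
#: analyses and the synthetic-proteomics generator
TOY_PATHWAYS = {
    "HXT": "transport", "GLY": "glycolysis", "FER": "fermentation",
    "PDH": "respiration", "RESP_N": "respiration", "COX_M": "respiration",
    "MRIB": "respiration", "TOM": "respiration",
    "AAS": "amino_acid_synthesis", "CBS": "other_biosynthesis",
    "RIB": "ribosome",
}


def make_toy_yeast(cal: Calibration | None = None) -> ModelSpec:
    """Build the calibrated reduced yeast model.

    Lumped routes: hexose uptake (plasma membrane), glycolysis
    (glc -> 2 pyr + 2 ATP + 2 NADH), fermentation (pyr + NADH -> ethanol +
    CO2), pyruvate oxidation + TCA (pyr -> 3 CO2 + 5 NADH + ATP, matrix),
    oxidative phosphorylation (NADH + 0.5 O2 -> P/O ATP, inner membrane,
    catalysed by a two-subunit complex with one mitochondrially translated
    subunit), amino-acid synthesis, non-protein biomass synthesis, protein
    import and both ribosome pools.  Carbon is balanced exactly (glucose C6,
    residue C5 with 1 CO2 released per residue made, carb lump C6).
    """
    cal = cal or DEFAULT_CALIBRATION
    L = cal.lengths
    po = cal.p_o_ratio

    metabolites = [
        Metabolite("glc_ext", carbon=6, boundary=True, mass=0.180),
        Metabolite("o2_ext", boundary=True),
        Metabolite("etoh_ext", carbon=2, boundary=True),
        Metabolite("co2_ext", carbon=1, boundary=True),
        Metabolite("glc", carbon=6),
        Metabolite("pyr", carbon=3),
        Metabolite("o2"),
        Metabolite("atp", role="energy"),
        Metabolite("nadh"),
        Metabolite("aa", carbon=5, role="amino_acid"),
        Metabolite("carb", carbon=6),
    ]
    reactions = [
        ReactionSpec("t_glc", {"glc_ext": -1.0, "glc": 1.0}, tags={"uptake"}),
        ReactionSpec("t_o2", {"o2_ext": -1.0, "o2": 1.0}),
        ReactionSpec("glycolysis",
                     {"glc": -1.0, "pyr": 2.0, "atp": 2.0, "nadh": 2.0}),
        ReactionSpec("fermentation",
                     {"pyr": -1.0, "nadh": -1.0, "etoh_ext": 1.0,
                      "co2_ext": 1.0}),
        ReactionSpec("pyr_ox",
                     {"pyr": -1.0, "co2_ext": 3.0, "nadh": 5.0, "atp": 1.0}),
        ReactionSpec("respiration",
                     {"nadh": -1.0, "o2": -0.5, "atp": po}),
        # residue C5 from glucose C6: one CO2 per residue keeps carbon closed
        ReactionSpec("aa_synth",
                     {"glc": -1.0, "atp": -2.0, "nadh": -1.0, "aa": 1.0,
                      "co2_ext": 1.0}),
        ReactionSpec("carb_synth",
                     {"glc": -1.0, "atp": -cal.carb_atp_cost, "carb": 1.0}),
    ]
    c = "cytosol"
    proteins = [
        ProteinSpec("HXT", L["HXT"], "plasma_membrane", k_deg=cal.k_deg_enzyme,
                    utr_length=50),
        ProteinSpec("GLY", L["GLY"], c, k_deg=cal.k_deg_enzyme, utr_length=50),
        ProteinSpec("FER", L["FER"], c, k_deg=cal.k_deg_enzyme, utr_length=50),
        ProteinSpec("PDH", L["PDH"], "mito_matrix", k_deg=cal.k_deg_enzyme,
                    utr_length=50, import_route="mitochondrial"),
        ProteinSpec("RESP_N", L["RESP_N"], "mito_inner_membrane",
                    k_deg=cal.k_deg_enzyme, utr_length=50,
                    import_route="mitochondrial"),
        ProteinSpec("COX_M", L["COX_M"], "mito_inner_membrane",
                    k_deg=cal.k_deg_enzyme),           # mito-translated
        ProteinSpec("TOM", L["TOM"], "mito_inner_membrane",
                    k_deg=cal.k_deg_enzyme, utr_length=50,
                    import_route="mitochondrial"),
        ProteinSpec("AAS", L["AAS"], c, k_deg=cal.k_deg_enzyme, utr_length=50),
        ProteinSpec("CBS", L["CBS"], c, k_deg=cal.k_deg_enzyme, utr_length=50),
        ProteinSpec("RIB", L["RIB"], c, k_deg=0.0, utr_length=50,
                    is_ribosome=True),
        ProteinSpec("MRIB", L["MRIB"], "mito_matrix", k_deg=0.0,
                    utr_length=50, import_route="mitochondrial",
                    is_ribosome=True),
        ProteinSpec("UP", L["UP"], c, k_deg=0.0, is_unspecified=True),
    ]
    complexes = [ComplexSpec("RESPC", {"RESP_N": 1, "COX_M": 1},
                             "mito_inner_membrane")]
    compartments = [
        Compartment(c, "volumetric", cal.cytosol_capacity,
                    fill_rule="equality"),
        Compartment("plasma_membrane", "membrane", cal.transporter_area),
        Compartment("mito_matrix", "volumetric", cal.mito_matrix_capacity,
                    organelle="mitochondrial"),
        Compartment("mito_inner_membrane", "membrane", cal.mito_membrane_area,
                    organelle="mitochondrial"),
    ]
    catalysis = [
        CatalysisRule("t_glc", "HXT", cal.kcat_transport),
        CatalysisRule("glycolysis", "GLY", cal.kcat_glycolysis),
        CatalysisRule("fermentation", "FER", cal.kcat_fermentation),
        CatalysisRule("pyr_ox", "PDH", cal.kcat_pyruvate_ox),
        CatalysisRule("respiration", "RESPC", cal.kcat_respiration),
        CatalysisRule("aa_synth", "AAS", cal.kcat_aa_synth),
        CatalysisRule("carb_synth", "CBS", cal.kcat_carb_synth),
    ]
    return ModelSpec(
        name="toy_yeast",
        metabolites=metabolites,
        reactions=reactions,
        proteins=proteins,
        compartments=compartments,
        catalysis=catalysis,
        ribosome=RibosomeParams(k_el=cal.k_el, f_inactive=cal.f_inactive,
                                sigma=cal.sigma, mito_k_el=cal.mito_k_el),
        biomass=BiomassSpec(composition={"carb": cal.carb_per_gdw},
                            gam=cal.gam, ngam=cal.ngam,
                            protein_per_gdw=cal.protein_per_gdw),
        complexes=complexes,
        import_params=ImportParams(importer="TOM", k_import=cal.k_import),
        conditions=Conditions(name="glucose", carbon_ngam=0.0,
                              min_up_fraction=cal.min_up_fraction,
                              cells_per_gdw=cal.cells_per_gdw),
    )


# ---------------------------------------------------------------------------
# random small models for property tests
# ---------------------------------------------------------------------------

def make_random_model(seed: int, size: int = 3) -> ModelSpec:
    """A seeded random linear-pathway model: substrate -> m1 -> ... -> product,
    each step catalysed by its own enzyme, product drained by the biomass
    demand.  Always validates cleanly; identical seed gives an identical
    model."""
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed)
    mets = [Metabolite("s_ext", boundary=True),
            Metabolite("atp_ext", boundary=True),
            Metabolite("aa", carbon=5, role="amino_acid"),
            Metabolite("atp", role="energy")]
    mets += [Metabolite(f"m{i}", carbon=3) for i in range(size)]
    reactions = [
        ReactionSpec("t_s", {"s_ext": -1.0, "m0": 1.0}, tags={"uptake"}),
        ReactionSpec("t_atp", {"atp_ext": -1.0, "atp": 1.0}),
        # the last intermediate is aminated into the residue precursor
        ReactionSpec("aa_synth", {f"m{size - 1}": -1.0, "atp": -1.0,
                                  "aa": 1.0}),
    ]
    catalysis = []
    proteins = []
    for i in range(size):
        if i + 1 < size:
            reactions.append(
                ReactionSpec(f"r{i}", {f"m{i}": -1.0, f"m{i + 1}": 1.0}))
        pid = f"E{i}"
        target = f"r{i}" if i + 1 < size else "aa_synth"
        proteins.append(ProteinSpec(
            pid, int(rng.integers(200, 5000)), "cytosol",
            k_deg=float(rng.uniform(0.0, 0.05)), utr_length=int(rng.integers(0, 200))))
        catalysis.append(CatalysisRule(
            target, pid, float(rng.uniform(1e4, 1e6))))
    L_R = int(rng.integers(5000, 20000))
    proteins.append(ProteinSpec("R", L_R, "cytosol",
                                k_deg=0.0, is_ribosome=True))
    proteins.append(ProteinSpec("UP", int(rng.integers(100, 600)), "cytosol",
                                k_deg=0.0, is_unspecified=True))
    f_inactive = float(rng.uniform(0.0, 0.4))
    sigma = float(rng.uniform(0.5, 1.0))
    # draw the ribosome-limited growth ceiling directly so every generated
    # model has mu_max below 1/h (keeps exhaustive scans over [0, 1] finite)
    mu_rib = float(rng.uniform(0.05, 0.95))
    k_el = mu_rib * L_R / (sigma * (1.0 - f_inactive))
    return ModelSpec(
        name=f"random_{seed}_{size}",
        metabolites=mets,
        reactions=reactions,
        proteins=proteins,
        compartments=[Compartment("cytosol", "volumetric",
                                  float(rng.uniform(0.3, 0.9)),
                                  fill_rule="equality")],
        catalysis=catalysis,
        ribosome=RibosomeParams(k_el=k_el, f_inactive=f_inactive,
                                sigma=sigma, mito_k_el=0.0),
        biomass=BiomassSpec(composition={}, gam=float(rng.uniform(0.0, 30.0)),
                            ngam=float(rng.uniform(0.0, 1.0)),
                            protein_per_gdw=0.46),
        conditions=Conditions(name="random",
                              min_up_fraction=float(rng.uniform(0.0, 0.4))),
    )


# ---------------------------------------------------------------------------
# synthetic proteomics
# ---------------------------------------------------------------------------

def make_synthetic_proteomics(sol, saturation_map: dict[str, float],
                              noise_rel: float, seed: int,
                              annotation: dict[str, str] | None = None,
                              ) -> pd.DataFrame:
    """Emulate a measured proteome-fraction table from a model solution.

    For each pathway the "measured" fraction is the predicted minimal
    fraction divided by the assumed enzyme saturation (undersaturated enzymes
    are expressed above the minimal level), perturbed by multiplicative
    lognormal noise of relative sigma ``noise_rel``.  The unspecified-protein
    fraction absorbs the remainder so fractions still sum to one.
    """
    from .experiments import pathway_fractions

    annotation = annotation or TOY_PATHWAYS
    for pw, s in saturation_map.items():
        if not (0 < s <= 1):
            raise ValueError(f"saturation for {pw} must be in (0, 1]")
    rng = np.random.default_rng(seed)
    pred = pathway_fractions(sol, annotation)
    rows = []
    total = 0.0
    for _, rec in pred.iterrows():
        pw = rec["pathway"]
        if pw == "UP":
            continue
        s = saturation_map.get(pw, 1.0)
        measured = rec["predicted_fraction"] / s
        if noise_rel > 0:
            measured *= float(rng.lognormal(mean=0.0, sigma=noise_rel))
        rows.append((pw, rec["predicted_fraction"], measured))
        total += measured
    if total > 1.0:
        raise ValueError(
            f"saturation map implies total protein fraction {total:.3f} > 1")
    rows.append(("UP", float(pred.loc[pred.pathway == "UP",
                                      "predicted_fraction"].sum()),
                 1.0 - total))
    return pd.DataFrame(rows, columns=["pathway", "predicted_fraction",
                                       "measured_fraction"])


def make_synthetic_mito_series(v_syn_max: float, k_deg: float,
                               mu_values, noise_rel: float, seed: int,
                               ) -> pd.DataFrame:
    """Steady-state mitochondrial protein fraction under a capped biogenesis
    rate: fraction = v_syn_max / (mu + k_deg), with multiplicative noise."""
    rng = np.random.default_rng(seed)
    mu = np.asarray(list(mu_values), dtype=float)
    frac = v_syn_max / (mu + k_deg)
    if noise_rel > 0:
        frac = frac * rng.lognormal(mean=0.0, sigma=noise_rel, size=len(mu))
    return pd.DataFrame({"mu": mu, "mito_fraction": frac})
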