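"""In-silico physiology experiments on proteome-constrained models.

Drivers for the standard perturbations — transporter-saturation sweeps
(glucose availability), gratuitous-protein expression, translation
inhibition, sugar-condition overlays — plus the model-vs-data analyses:
pathway proteome fractions, enzyme-saturation proxies, the capped
mitochondrial-biogenesis fit, and strategy-level proteome efficiency.

Every driver returns tidy tables (one row per swept point) so results can be
dumped straight to TSV.
"""
from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_schema import ModelSpec, ConditionOverlay, apply_overlay
from .pc_builder import PCModel, build_pc_model, SYN_PREFIX
from .lp_engine import GrowthSolution, maximize_growth, solve_at_mu

#: flux threshold for calling a by-product "produced" (regime boundaries)
ETHANOL_FLUX_TOL = 1e-6
#: UP slack below which the cytosol counts as full
UP_SLACK_TOL = 1e-6


@dataclass
class SweepResult:
    control: str
    table: pd.DataFrame
    boundaries: dict = field(default_factory=dict)
    solutions: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def boundary_fluxes(sol: GrowthSolution, model: ModelSpec) -> dict[str, float]:
    """Net production rate of every boundary species (negative = consumed)."""
    out: dict[str, float] = {}
    boundary = {m.id for m in model.metabolites if m.boundary}
    for r in model.reactions:
        v = sol.fluxes.get(r.id, 0.0)
        for mid, coeff in r.stoichiometry.items():
            if mid in boundary:
                out[mid] = out.get(mid, 0.0) + coeff * v
    return out


def carbon_balance(sol: GrowthSolution, model: ModelSpec) -> dict[str, float]:
    """Carbon bookkeeping of a solution, mmol C/gDW/h.

    In steady state carbon consumed from the medium equals carbon secreted
    plus carbon fixed into biomass (protein residues plus the non-protein
    composition drained by the biomass demand).
    """
    carbon_of = {m.id: m.carbon for m in model.metabolites}
    ex = boundary_fluxes(sol, model)
    c_in = -sum(v * carbon_of.get(mid, 0) for mid, v in ex.items() if v < 0)
    c_out = sum(v * carbon_of.get(mid, 0) for mid, v in ex.items() if v > 0)
    aa_c = next((m.carbon for m in model.metabolites if m.role == "amino_acid"), 0)
    protein_c = sol.mu * aa_c * sum(
        p.length * sol.enzyme_levels.get(p.id, 0.0) for p in model.proteins)
    biomass_c = sol.mu * sum(coeff * carbon_of.get(mid, 0)
                             for mid, coeff in model.biomass.composition.items())
    return {"in": c_in, "out": c_out, "biomass": protein_c + biomass_c,
            "residual": c_in - c_out - protein_c - biomass_c}


def _uptake_reaction(model: ModelSpec) -> str:
    for r in model.reactions:
        if "uptake" in r.tags:
            return r.id
    raise ValueError("model has no reaction tagged 'uptake'")


def _uptake_rule(model: ModelSpec):
    rid = _uptake_reaction(model)
    for rule in model.catalysis:
        if rule.reaction == rid:
            return rule
    raise ValueError(f"uptake reaction {rid} is not catalysed")


def _substrate_mass(model: ModelSpec) -> float | None:
    rid = _uptake_reaction(model)
    rxn = model.reaction(rid)
    for mid, coeff in rxn.stoichiometry.items():
        if coeff < 0 and model.metabolite(mid).boundary:
            return model.metabolite(mid).mass
    return None


def up_slack(sol: GrowthSolution, model: ModelSpec) -> float:
    """Unspecified protein expressed above its enforced minimum, g/gDW."""
    up = model.unspecified_protein
    if up is None:
        return math.inf
    total = sum(p.mass * sol.enzyme_levels.get(p.id, 0.0)
                for p in model.proteins)
    up_mass = up.mass * sol.enzyme_levels.get(up.id, 0.0)
    return up_mass - model.conditions.min_up_fraction * total


def _solution_record(model: ModelSpec, sol: GrowthSolution) -> dict:
    ex = boundary_fluxes(sol, model)
    rec = {"mu_max": sol.mu}
    uptake_id = None
    try:
        uptake_id = _uptake_reaction(model)
    except ValueError:
        pass
    if uptake_id is not None:
        rec["uptake"] = sol.fluxes.get(uptake_id, 0.0)
        m = _substrate_mass(model)
        if m and rec["uptake"] > 0:
            rec["yield_gdw_per_g"] = sol.mu / (rec["uptake"] * m)
    for mid, v in ex.items():
        rec[f"ex_{mid}"] = v
    for cid, occ in sol.occupancies.items():
        rec[f"occ_{cid}"] = occ
    rec["up_slack"] = up_slack(sol, model)
    rec["active_constraints"] = ",".join(sol.active)
    rec["n_active"] = len(sol.active)
    return rec


# ---------------------------------------------------------------------------
# transporter saturation sweep (glucose availability)
# ---------------------------------------------------------------------------

def saturation_sweep(pc: PCModel, s_values, tol: float = 1e-4) -> SweepResult:
    """Maximise growth across transporter saturation levels.

    Emulates varying external glucose without kinetics: the saturation s
    multiplies the transporter kcat in its capacity equality, while the
    transporter expression cap (membrane pool) stays fixed.  Reports regime
    boundaries: first s with by-product (ethanol) flux above threshold, and
    first s with the unspecified protein at its minimum (cytosol full).
    """
    s_values = list(s_values)
    if any(not (0 < s <= 1) for s in s_values):
        raise ValueError("saturation values must lie in (0, 1]")
    if sorted(s_values) != s_values:
        raise ValueError("saturation values must be sorted ascending")
    base = pc.base
    rows, sols = [], []
    for s in s_values:
        model = copy.deepcopy(base)
        _uptake_rule(model).saturation = s
        try:
            sol = maximize_growth(build_pc_model(model), tol=tol)
        except RuntimeError:
            rows.append({"s": s, "status": "infeasible"})
            sols.append(None)
            continue
        rec = {"s": s, "status": "optimal"}
        rec.update(_solution_record(model, sol))
        rec["ethanol"] = rec.get("ex_etoh_ext", 0.0)
        rows.append(rec)
        sols.append(sol)
    table = pd.DataFrame(rows)
    boundaries = {}
    ok = table[table.status == "optimal"]
    eth = ok[ok.ethanol > ETHANOL_FLUX_TOL]
    if len(eth):
        boundaries["ethanol_onset_s"] = float(eth.iloc[0]["s"])
        boundaries["ethanol_onset_mu"] = float(eth.iloc[0]["mu_max"])
    full = ok[ok.up_slack < UP_SLACK_TOL]
    if len(full):
        boundaries["cytosol_full_s"] = float(full.iloc[0]["s"])
        boundaries["cytosol_full_mu"] = float(full.iloc[0]["mu_max"])
    return SweepResult(control="saturation", table=table,
                       boundaries=boundaries, solutions=sols)


def locate_regime_boundaries(pc: PCModel, s_lo: float = 0.01,
                             s_hi: float = 1.0, tol: float = 1e-4,
                             s_tol: float = 1e-3) -> dict:
    """Bisection in saturation for the two regime boundaries: the growth rate
    at ethanol onset and at the point where UP reaches its minimum."""
    base = pc.base

    def solve(s):
        model = copy.deepcopy(base)
        _uptake_rule(model).saturation = s
        try:
            sol = maximize_growth(build_pc_model(model), tol=tol)
        except RuntimeError:   # no growth at this saturation
            sol = None
        return model, sol

    def bisect(pred):
        lo, hi = s_lo, s_hi
        _, sol = solve(lo)
        if sol is not None and pred(base, sol):
            return lo, sol
        _, sol_hi = solve(hi)
        if sol_hi is None or not pred(base, sol_hi):
            return None, None
        best = (hi, sol_hi)
        while hi - lo > s_tol:
            mid = 0.5 * (lo + hi)
            _, sol = solve(mid)
            if sol is not None and pred(base, sol):
                hi, best = mid, (mid, sol)
            else:
                lo = mid
        return best

    def has_ethanol(model, sol):
        return boundary_fluxes(sol, model).get("etoh_ext", 0.0) > ETHANOL_FLUX_TOL

    def cytosol_full(model, sol):
        return up_slack(sol, model) < UP_SLACK_TOL

    out = {}
    s_eth, sol_eth = bisect(has_ethanol)
    if s_eth is not None:
        out["ethanol_onset_s"] = s_eth
        out["ethanol_onset_mu"] = sol_eth.mu
    s_full, sol_full = bisect(cytosol_full)
    if s_full is not None:
        out["cytosol_full_s"] = s_full
        out["cytosol_full_mu"] = sol_full.mu
    return out


# ---------------------------------------------------------------------------
# residual substrate back-calculation (inverse Monod)
# ---------------------------------------------------------------------------

def residual_substrate(s: float, Km: float = 1.0) -> float:
    """Residual substrate concentration (mM) implied by transporter
    saturation s with Michaelis constant Km: c = s*Km/(1-s).  Assumes
    negligible intracellular substrate."""
    if not (0 <= s < 1):
        raise ValueError("saturation must lie in [0, 1) for a finite "
                         "residual concentration")
    if Km <= 0:
        raise ValueError("Km must be positive")
    return s * Km / (1.0 - s)


# ---------------------------------------------------------------------------
# gratuitous protein expression
# ---------------------------------------------------------------------------

def gratuitous_curve(pc: PCModel, phi_values, tol: float = 1e-4,
                     protein_length: int = 300) -> SweepResult:
    """Maximal growth rate as a function of the proteome mass fraction pinned
    to an unneeded cytosolic protein; reports relative fitness mu(phi)/mu(0)."""
    base = pc.base
    phi_values = list(phi_values)
    if any(p < 0 or p >= 1 for p in phi_values):
        raise ValueError("gratuitous fractions must lie in [0, 1)")
    rows, sols = [], []
    mu0 = None
    for phi in phi_values:
        model = copy.deepcopy(base)
        if phi > 0:
            model.proteins.append(_gratuitous_protein(model, phi, protein_length))
        try:
            sol = maximize_growth(build_pc_model(model), tol=tol)
        except RuntimeError:
            rows.append({"phi": phi, "status": "infeasible"})
            sols.append(None)
            continue
        if mu0 is None and phi == 0:
            mu0 = sol.mu
        rec = {"phi": phi, "status": "optimal"}
        rec.update(_solution_record(model, sol))
        rows.append(rec)
        sols.append(sol)
    table = pd.DataFrame(rows)
    if mu0:
        table["relative_fitness"] = table["mu_max"] / mu0
    return SweepResult(control="gratuitous_fraction", table=table,
                       solutions=sols)


def _gratuitous_protein(model: ModelSpec, phi: float, length: int) -> "ProteinSpec":
    """A dead-weight cytosolic protein pinned to mass fraction phi of the
    reference total protein content."""
    from .model_schema import ProteinSpec, AA_RESIDUE_MASS

    density = next(c for c in model.compartments if c.fill_rule == "equality")
    mass = length * AA_RESIDUE_MASS
    level = phi * model.biomass.protein_per_gdw / mass
    return ProteinSpec("GRT", length, density.id, k_deg=0.0,
                       fixed_level=level)


# ---------------------------------------------------------------------------
# translation inhibition
# ---------------------------------------------------------------------------

def translation_inhibition(pc: PCModel, eta_values, tol: float = 1e-4,
                           ) -> SweepResult:
    """Scale the cytosolic elongation rate to (1 - eta) * k_el, emulating a
    translation inhibitor, and maximise growth at each inhibition level."""
    base = pc.base
    eta_values = list(eta_values)
    if any(e < 0 or e >= 1 for e in eta_values):
        raise ValueError("inhibition levels must lie in [0, 1)")
    rows, sols = [], []
    for eta in eta_values:
        model = copy.deepcopy(base)
        model.ribosome.k_el = base.ribosome.k_el * (1.0 - eta)
        try:
            sol = maximize_growth(build_pc_model(model), tol=tol)
        except RuntimeError:
            rows.append({"eta": eta, "status": "infeasible"})
            sols.append(None)
            continue
        rec = {"eta": eta, "status": "optimal"}
        rec.update(_solution_record(model, sol))
        rib = next(p for p in model.proteins
                   if p.is_ribosome and
                   model.compartment(p.compartment).organelle != "mitochondrial")
        total = sum(p.mass * sol.enzyme_levels.get(p.id, 0.0)
                    for p in model.proteins)
        rib_mass = rib.mass * sol.enzyme_levels.get(rib.id, 0.0)
        rec["ribosome_fraction"] = rib_mass / total if total else 0.0
        # proteome fraction lost to inhibitor-stalled ribosomes: eta of the
        # pool behaves like gratuitous protein
        rec["equivalent_gratuitous_phi"] = (
            eta * rib_mass / model.biomass.protein_per_gdw)
        rows.append(rec)
        sols.append(sol)
    return SweepResult(control="inhibition", table=pd.DataFrame(rows),
                       solutions=sols)


# ---------------------------------------------------------------------------
# sugar-condition overlays
# ---------------------------------------------------------------------------

def condition_run(pc: PCModel, overlay: ConditionOverlay,
                  tol: float = 1e-4) -> tuple[GrowthSolution, dict]:
    """Maximise growth under a condition overlay; returns the solution and a
    summary record (fluxes, occupancies, active constraints, ethanol flux)."""
    model = apply_overlay(pc.base, overlay)
    sol = maximize_growth(build_pc_model(model), tol=tol)
    rec = {"condition": overlay.name}
    rec.update(_solution_record(model, sol))
    rec["ethanol"] = rec.get("ex_etoh_ext", 0.0)
    return sol, rec


# ---------------------------------------------------------------------------
# proteome fractions, saturation proxy, biogenesis-cap fit
# ---------------------------------------------------------------------------

def pathway_fractions(sol: GrowthSolution, annotation: dict[str, str],
                      model: ModelSpec | None = None) -> pd.DataFrame:
    """Predicted minimal proteome mass fraction per pathway.

    Fractions are relative to total modelled protein mass (so they sum to 1
    including the unspecified-protein remainder).  Flux-carrying proteins
    missing from the annotation are bucketed as "other" with a warning.
    """
    masses: dict[str, float] = {}
    if model is not None:
        prot = {p.id: p.mass for p in model.proteins}
        up_id = model.unspecified_protein.id if model.unspecified_protein else None
    else:
        prot = sol.protein_masses
        up_id = sol.up_id
    total = 0.0
    for pid, e in sol.enzyme_levels.items():
        if pid not in prot:
            continue  # complex level variables
        m = prot[pid] * e
        total += m
        if pid == up_id:
            pw = "UP"
        elif pid in annotation:
            pw = annotation[pid]
        else:
            if e > 1e-12:
                warnings.warn(f"protein {pid} carries flux but has no pathway "
                              "annotation; bucketed as 'other'")
            pw = "other"
        masses[pw] = masses.get(pw, 0.0) + m
    recs = [(pw, m / total if total else 0.0) for pw, m in masses.items()]
    return pd.DataFrame(recs, columns=["pathway", "predicted_fraction"])


class SaturationProxy(float):
    """Ratio predicted/measured; ``exceeds_one`` flags a clipped estimate."""
    exceeds_one: bool
    undefined: bool

    def __new__(cls, value: float, exceeds_one: bool = False,
                undefined: bool = False):
        obj = super().__new__(cls, value)
        obj.exceeds_one = exceeds_one
        obj.undefined = undefined
        return obj


def saturation_proxy(predicted: float, measured: float) -> SaturationProxy:
    """Estimate average in-vivo enzyme saturation as the ratio of the
    predicted minimal proteome fraction to the measured fraction."""
    if measured == 0:
        warnings.warn("measured fraction is zero; saturation proxy undefined")
        return SaturationProxy(math.nan, undefined=True)
    ratio = predicted / measured
    return SaturationProxy(ratio, exceeds_one=ratio > 1.0)


def fit_vsyn_max(series, k_deg: float = 0.0) -> tuple[float, np.ndarray]:
    """Least-squares estimate of a capped biosynthesis rate from the decay of
    a steady-state protein fraction with growth rate.

    Model: fraction = v_syn_max / (mu + k_deg) — dilution-by-growth kinetics
    of a sector whose synthesis flux has saturated.  Closed-form weighted
    least squares in v_syn_max; returns (estimate, residuals).
    """
    df = pd.DataFrame(series)
    if df.shape[1] != 2:
        df = df[["mu", "mito_fraction"]]
    mu = df.iloc[:, 0].to_numpy(dtype=float)
    frac = df.iloc[:, 1].to_numpy(dtype=float)
    mask = mu + k_deg > 0
    if not mask.any():
        raise ValueError("need at least one point with mu + k_deg > 0")
    g = 1.0 / (mu[mask] + k_deg)
    v = float(np.dot(frac[mask], g) / np.dot(g, g))
    residuals = frac - np.where(mu + k_deg > 0, v / (mu + k_deg), np.nan)
    return v, residuals


# ---------------------------------------------------------------------------
# strategy-level proteome efficiency
# ---------------------------------------------------------------------------

def proteome_efficiency(pc: PCModel,
                        strategies: dict[str, list[str]] | None = None,
                        atp_flux: float = 1.0) -> pd.DataFrame:
    """Protein cost and substrate cost of each pure catabolic strategy.

    For each strategy, all reactions listed for the *other* strategies are
    shut off and the minimal total protein mass sustaining a unit maintenance
    ATP flux at zero growth is computed (the density equality and UP floor
    are relaxed: costs refer to metabolically committed protein only).
    Reports ATP per protein mass (mmol ATP/h per g) and ATP per substrate
    (mmol ATP per mmol).
    """
    strategies = strategies or {
        "fermentation": ["fermentation"],
        "respiration": ["pyr_ox", "respiration"],
    }
    base = pc.base
    recs = []
    for name, keep in strategies.items():
        off = [r for other, rxns in strategies.items() if other != name
               for r in rxns]
        model = copy.deepcopy(base)
        model.biomass = copy.deepcopy(model.biomass)
        model.biomass.ngam = atp_flux
        model.conditions = copy.deepcopy(model.conditions)
        model.conditions.carbon_ngam = 0.0
        for rid in off:
            rxn = model.reaction(rid)
            rxn.ub = 0.0
        pcx = build_pc_model(model, density_as_equality=False,
                             enforce_min_up=False)
        sol = _min_protein_at_zero_growth(pcx)
        if sol is None:
            recs.append({"strategy": name, "feasible": False})
            continue
        protein_mass, fluxes = sol
        uptake = fluxes.get(_uptake_reaction(model), 0.0)
        recs.append({
            "strategy": name, "feasible": True,
            "protein_mass": protein_mass,
            "atp_per_protein": atp_flux / protein_mass if protein_mass else math.inf,
            "atp_per_substrate": atp_flux / uptake if uptake else math.inf,
            "substrate_flux": uptake,
        })
    return pd.DataFrame(recs)


def _min_protein_at_zero_growth(pcx: PCModel):
    """Minimise total enzyme mass at mu = 0 subject to all rows."""
    import numpy as np
    from .lp_engine import _assemble, _linprog

    a_eq, b_eq, _, a_ub, b_ub, _, bounds = _assemble(pcx, 0.0)
    c = np.array([v.mass if v.kind == "enzyme" else 0.0
                  for v in pcx.variables])
    res = _linprog(c, a_ub, b_ub, a_eq, b_eq, bounds)
    if res.status != 0:
        return None
    mass = float(c @ res.x)
    fluxes = {v.name: float(x) for v, x in zip(pcx.variables, res.x)
              if v.kind == "flux"}
    return mass, fluxes
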