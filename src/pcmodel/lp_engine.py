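"""Assembly and solution of the growth-rate-parametrised linear program.

The feasibility problem at a fixed growth rate mu is a plain LP; the maximal
growth rate is located by bisection on mu (feasibility is monotone: any
solution at mu can be scaled into one at a lower mu on the models built
here).  At the accepted mu a lexicographic refinement selects a unique
optimum among alternate solutions: first minimise substrate uptake flux
(mirroring chemostat simulation at fixed dilution rate), then minimise total
protein synthesis mass — yielding the minimal-proteome solution that is
compared to proteomics data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .pc_builder import PCModel, SYN_PREFIX

#: primal/dual feasibility tolerance passed to HiGHS
SOLVER_TOL = 1e-9
#: occupancies within this distance of [0, 1] are clamped onto the interval
OCCUPANCY_CLAMP = 1e-6
#: default threshold for calling a pool constraint active
ACTIVE_EPS = 1e-3
#: dual magnitude above which a binding-but-free row is reported active
DUAL_EPS = 1e-8

_HIGHS_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": SOLVER_TOL,
    "dual_feasibility_tolerance": SOLVER_TOL,
}


class UnboundedError(RuntimeError):
    """The LP is unbounded — a capacity row is missing from the model."""


@dataclass
class GrowthSolution:
    mu: float
    status: str                                  # "optimal" | "infeasible"
    fluxes: dict[str, float] = field(default_factory=dict)
    enzyme_levels: dict[str, float] = field(default_factory=dict)
    occupancies: dict[str, float] = field(default_factory=dict)
    duals: dict[str, float] = field(default_factory=dict)
    active: list[str] = field(default_factory=list)
    objective: float = math.nan                  # stage-1 value (uptake flux)
    density_pool: str | None = None
    protein_masses: dict[str, float] = field(default_factory=dict)
    up_id: str | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# numeric assembly
# ---------------------------------------------------------------------------

def _assemble(pc: PCModel, mu: float):
    n = len(pc.variables)
    a_eq, b_eq, eq_names = [], [], []
    a_ub, b_ub, ub_names = [], [], []
    for row in pc.rows:
        dense = np.zeros(n)
        for i, c in row.coeffs.items():
            dense[i] += c
        for i, c in row.mu_coeffs.items():
            dense[i] += mu * c
        if row.kind == "eq":
            a_eq.append(dense); b_eq.append(row.rhs); eq_names.append(row.name)
        else:
            a_ub.append(dense); b_ub.append(row.rhs); ub_names.append(row.name)
    bounds = []
    for v in pc.variables:
        lo = v.lb + mu * v.lb_mu
        hi = None if v.ub is None else v.ub + mu * v.ub_mu
        bounds.append((lo, hi))
    return (np.array(a_eq), np.array(b_eq), eq_names,
            np.array(a_ub) if a_ub else np.zeros((0, n)),
            np.array(b_ub) if b_ub else np.zeros(0), ub_names, bounds)


def _linprog(c, a_ub, b_ub, a_eq, b_eq, bounds):
    res = linprog(c, A_ub=a_ub if len(a_ub) else None,
                  b_ub=b_ub if len(b_ub) else None,
                  A_eq=a_eq if len(a_eq) else None,
                  b_eq=b_eq if len(b_eq) else None,
                  bounds=bounds, method="highs", options=_HIGHS_OPTIONS)
    if res.status == 3:
        raise UnboundedError("LP unbounded: a capacity constraint is missing")
    return res


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def solve_at_mu(pc: PCModel, mu: float, *, refine: bool = True) -> GrowthSolution:
    """Solve the LP at growth rate *mu*.

    Stage 1 minimises substrate uptake flux; with ``refine`` (the default) a
    second stage pins the uptake optimum and minimises total protein
    synthesis mass, making the reported solution unique in practice.
    """
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    n = len(pc.variables)
    a_eq, b_eq, eq_names, a_ub, b_ub, ub_names, bounds = _assemble(pc, mu)

    c1 = np.zeros(n)
    for i in pc.uptake_vars:
        c1[i] = 1.0
    res = _linprog(c1, a_ub, b_ub, a_eq, b_eq, bounds)
    if res.status != 0:
        return GrowthSolution(mu=mu, status="infeasible")
    uptake_opt = float(c1 @ res.x)

    if refine:
        c2 = np.array([v.mass if v.name.startswith(SYN_PREFIX) else 0.0
                       for v in pc.variables])
        slack = 1e-9 * max(1.0, abs(uptake_opt))
        a_ub2 = np.vstack([a_ub, c1[None, :]]) if len(a_ub) else c1[None, :]
        b_ub2 = np.append(b_ub, uptake_opt + slack)
        res2 = _linprog(c2, a_ub2, b_ub2, a_eq, b_eq, bounds)
        if res2.status == 0:
            res, a_ub_used, ub_names_used = res2, a_ub2, ub_names + ["_pin_uptake"]
        else:  # extremely tight pin can fail numerically; keep stage 1
            a_ub_used, ub_names_used = a_ub, ub_names
    else:
        a_ub_used, ub_names_used = a_ub, ub_names

    x = res.x
    sol = GrowthSolution(mu=mu, status="optimal", objective=uptake_opt)
    for v, val in zip(pc.variables, x):
        if v.kind == "flux":
            sol.fluxes[v.name] = float(val)
        elif v.kind == "enzyme":
            sol.enzyme_levels[v.name[len("enz__"):]] = float(val)
        else:
            sol.enzyme_levels[v.name] = float(val)

    duals: dict[str, float] = {}
    if res.eqlin is not None and len(eq_names):
        for name, marg in zip(eq_names, np.atleast_1d(res.eqlin.marginals)):
            duals[name] = float(marg)
    if res.ineqlin is not None and len(ub_names_used):
        for name, marg in zip(ub_names_used, np.atleast_1d(res.ineqlin.marginals)):
            if name != "_pin_uptake":
                duals[name] = float(marg)
    sol.duals = duals
    sol.density_pool = pc.density_pool
    sol.protein_masses = {p.id: p.mass for p in pc.base.proteins}
    up = pc.base.unspecified_protein
    sol.up_id = up.id if up is not None else None

    sol.occupancies = pool_occupancy(sol, pc)
    sol.active = active_constraints(sol, ACTIVE_EPS)
    return sol


def pool_occupancy(sol: GrowthSolution, pc: PCModel) -> dict[str, float]:
    """Occupancy of every proteome pool: sum_i w_i e_i / capacity.

    The density-equality pool excludes unspecified protein expressed above
    its minimum, so occupancy 1 there means "no free UP slack" — the cytosol
    is full of metabolically committed protein.
    """
    model = pc.base
    occ: dict[str, float] = {}
    up = model.unspecified_protein
    for comp in model.compartments:
        cap = pc.pool_capacities[comp.id]
        total = 0.0
        for p in model.proteins:
            if p.compartment != comp.id:
                continue
            total += p.specific_size(comp) * sol.enzyme_levels.get(p.id, 0.0)
        frac = total / cap
        if comp.id == pc.density_pool and up is not None:
            total_protein = sum(p.mass * sol.enzyme_levels.get(p.id, 0.0)
                                for p in model.proteins)
            up_mass = up.mass * sol.enzyme_levels.get(up.id, 0.0)
            slack = max(0.0, up_mass - pc.min_up_fraction * total_protein)
            frac = (total - slack) / cap
        if -OCCUPANCY_CLAMP <= frac <= 1.0 + OCCUPANCY_CLAMP:
            frac = min(1.0, max(0.0, frac))
        occ[comp.id] = frac
    return occ


def active_constraints(sol: GrowthSolution, eps: float = ACTIVE_EPS) -> list[str]:
    """Pool identifiers limiting growth: occupancy >= 1 - eps, or a pool
    capacity row binding through its dual value; ordered by dual magnitude
    (largest first), occupancy-only hits after."""
    if not sol.optimal:
        return []
    dual_of = {}
    for name, d in sol.duals.items():
        if name.startswith("pool__"):
            dual_of[name[len("pool__"):]] = abs(d)
        elif name == "min_up" and sol.density_pool is not None:
            # the UP floor is the operative part of the density pool
            dual_of[sol.density_pool] = abs(d)
    hits: dict[str, float] = {}
    for cid, frac in sol.occupancies.items():
        dual = dual_of.get(cid, 0.0)
        if frac >= 1.0 - eps or dual > DUAL_EPS:
            hits[cid] = dual
    return sorted(hits, key=lambda cid: (-hits[cid], cid))


def maximize_growth(pc: PCModel, lo: float = 0.0, hi: float = 1.0,
                    tol: float = 1e-4, max_iter: int = 40,
                    log: list | None = None) -> GrowthSolution:
    """Binary search for the maximum growth rate at which the LP is feasible.

    The returned mu is feasible while mu + tol is infeasible.  If *hi* turns
    out feasible the bracket is widened once (to 4x) before giving up.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    lo_sol = solve_at_mu(pc, lo, refine=False)
    if not lo_sol.optimal:
        raise RuntimeError(f"no growth: LP infeasible at mu = {lo}")
    hi_sol = solve_at_mu(pc, hi, refine=False)
    if hi_sol.optimal:
        lo = hi
        hi = hi * 4 if hi > 0 else 1.0
        if solve_at_mu(pc, hi, refine=False).optimal:
            raise RuntimeError(
                f"growth rate exceeds widened ceiling {hi}; is a capacity "
                "constraint missing?")
    it = 0
    while hi - lo > tol and it < max_iter:
        mid = 0.5 * (lo + hi)
        feasible = solve_at_mu(pc, mid, refine=False).optimal
        if log is not None:
            log.append((it, lo, hi, mid, feasible))
        if feasible:
            lo = mid
        else:
            hi = mid
        it += 1
    return solve_at_mu(pc, lo, refine=True)


# ---------------------------------------------------------------------------
# residual checks and dumps
# ---------------------------------------------------------------------------

def constraint_residuals(sol: GrowthSolution, pc: PCModel) -> dict[str, float]:
    """Signed residual of every row at the solution (eq: |Ax-b|; ub: max(0, Ax-b))."""
    values = _solution_vector(sol, pc)
    out = {}
    for row in pc.rows:
        acc = sum(c * values[i] for i, c in row.coeffs.items())
        acc += sol.mu * sum(c * values[i] for i, c in row.mu_coeffs.items())
        out[row.name] = (abs(acc - row.rhs) if row.kind == "eq"
                         else max(0.0, acc - row.rhs))
    return out


def _solution_vector(sol: GrowthSolution, pc: PCModel) -> np.ndarray:
    values = np.zeros(len(pc.variables))
    for i, v in enumerate(pc.variables):
        if v.kind == "flux":
            values[i] = sol.fluxes.get(v.name, 0.0)
        elif v.kind == "enzyme":
            values[i] = sol.enzyme_levels.get(v.name[len("enz__"):], 0.0)
        else:
            values[i] = sol.enzyme_levels.get(v.name, 0.0)
    return values


def solution_table(sol: GrowthSolution, pc: PCModel):
    """Tidy dump: one row per entity with columns entity_type/id/value/units."""
    import pandas as pd

    rows = [("growth_rate", "mu", sol.mu, "1/h")]
    rows += [("flux", k, v, "mmol/gDW/h") for k, v in sol.fluxes.items()]
    rows += [("enzyme", k, v, "mmol/gDW") for k, v in sol.enzyme_levels.items()]
    return pd.DataFrame(rows, columns=["entity_type", "id", "value", "units"])


def occupancy_table(sol: GrowthSolution, pc: PCModel):
    import pandas as pd

    dual_of = {name[len("pool__"):]: d for name, d in sol.duals.items()
               if name.startswith("pool__")}
    if "min_up" in sol.duals and pc.density_pool is not None:
        dual_of[pc.density_pool] = sol.duals["min_up"]
    recs = [(cid, occ, dual_of.get(cid, 0.0), cid in sol.active)
            for cid, occ in sol.occupancies.items()]
    return pd.DataFrame(recs, columns=["pool", "occupancy", "dual", "active"])
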