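"""Calibration search for the reduced yeast model.

Tunes four knobs against four growth-rate anchors and prints a frozen
Calibration ready to paste into ``pcmodel.toy_yeast``:

* ``gam``                 -> glucose batch mu_max            (target 0.38 1/h)
* ``cytosol_capacity``    -> UP-at-minimum (cytosol full)    (target 0.35 1/h)
* ``mito_membrane_area``  -> ethanol onset                   (target 0.28 1/h)
* ``kcat_transport``      -> galactose batch mu_max          (target 0.16 1/h)

Each anchor responds monotonically to its knob; a round-robin log-secant
iteration converges in a handful of rounds.  Run from the repository root:

    python scripts/calibrate_toy.py
"""
from __future__ import annotations

import dataclasses
import math
import sys

import pcmodel as pm

TARGETS = {
    "batch": 0.38,
    "cytosol_full": 0.35,
    "ethanol_onset": 0.28,
    "galactose": 0.16,
}


def measure(cal: pm.Calibration) -> dict:
    model = pm.make_toy_yeast(cal)
    pc = pm.build_pc_model(model)
    out = {"batch": pm.maximize_growth(pc).mu}
    gal_sol, gal_rec = pm.condition_run(pc, pm.OVERLAYS["galactose"])
    out["galactose"] = gal_sol.mu
    out["galactose_ethanol"] = gal_rec["ethanol"]
    bounds = pm.locate_regime_boundaries(pc, s_lo=0.01, s_tol=5e-4)
    out["ethanol_onset"] = bounds.get("ethanol_onset_mu", math.nan)
    out["cytosol_full"] = bounds.get("cytosol_full_mu", math.nan)
    return out


def secant_step(cal, knob, anchor, sign, state):
    """One log-secant update of a knob toward its anchor target."""
    x0 = getattr(cal, knob)
    y0 = measure(cal)[anchor]
    t = TARGETS[anchor]
    if math.isfinite(y0) and abs(y0 - t) < 1e-3:
        return cal, y0
    if not math.isfinite(y0) or y0 <= 0:
        x1 = x0 * 1.3
    else:
        # first-order: d log(mu) / d log(knob) ~ sign * elasticity (start 1)
        el = state.setdefault((knob, "el"), 1.0 * sign)
        x1 = x0 * math.exp(max(-0.7, min(0.7, math.log(t / y0) / el)))
    cal1 = dataclasses.replace(cal, **{knob: x1})
    y1 = measure(cal1)[anchor]
    if (math.isfinite(y0) and math.isfinite(y1) and y1 != y0
            and abs(math.log(x1 / x0)) > 1e-6):
        state[(knob, "el")] = max(0.05, min(20.0, abs(
            (math.log(y1) - math.log(y0)) / math.log(x1 / x0)))) * sign
    return (cal1, y1) if abs(y1 - t) < abs(y0 - t) else (cal, y0)


def main():
    cal = pm.Calibration()
    state: dict = {}
    plan = [
        ("gam", "batch", -1),
        ("mito_membrane_area", "ethanol_onset", 1),
        ("cytosol_capacity", "cytosol_full", 1),
        ("kcat_transport", "galactose", 1),
    ]
    for rnd in range(8):
        for knob, anchor, sign in plan:
            cal, y = secant_step(cal, knob, anchor, sign, state)
            print(f"round {rnd} {knob:>20s} -> {getattr(cal, knob):12.5g}   "
                  f"{anchor} = {y:.4f} (target {TARGETS[anchor]})",
                  flush=True)
        res = measure(cal)
        err = max(abs(res[a] - t) / t for a, t in TARGETS.items())
        print(f"round {rnd} summary: {res}  max rel err {err:.3f}", flush=True)
        if err < 0.01:
            break
    print("\nfrozen calibration:")
    for f in dataclasses.fields(cal):
        print(f"  {f.name} = {getattr(cal, f.name)!r}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
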