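"""Regenerate the packaged model fixtures from the frozen calibration.

Writes the reduced yeast model JSON and the condition overlay YAMLs into
``src/pcmodel/data/``.  Run from the repository root after changing the
calibration:

    python scripts/make_fixtures.py
"""
from pathlib import Path

import pcmodel as pm
from pcmodel.model_schema import save_model, save_overlay

DATA = Path(__file__).resolve().parent.parent / "src" / "pcmodel" / "data"


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    save_model(pm.make_toy_yeast(), DATA / "toy_yeast.json")
    for name, overlay in pm.OVERLAYS.items():
        save_overlay(overlay, DATA / f"{name}.yaml")
    print(f"wrote fixtures to {DATA}")


if __name__ == "__main__":
    main()
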