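#!/usr/bin/env python
"""Calibrate the nominal virtual patient and verify the seven criteria.

Back-solves the 44 uncertain parameters from steady-state flux balance at
clinically normal blood counts, finds the homeostatic equilibrium, runs the
7-day induction-chemotherapy protocol, and checks all seven acceptability
criteria.  Writes results/nominal_fixture.json.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from leukosim.fixtures import make_nominal_fixture, save_fixture
from leukosim.states import STATE_NAMES

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

fix = make_nominal_fixture()
save_fixture(fix, OUT / "nominal_fixture.json")

print("Calibrated nominal fixture")
print(f"  equilibrium residual: {fix.criteria['equilibrium_residual']:.2e}")
print(f"  stem-cell equilibrium: {fix.criteria['stem_equilibrium']:.2f} cells/uL")
print("  equilibrium (cells/uL):")
for name, v in zip(STATE_NAMES, fix.equilibrium):
    if v > 0:
        print(f"    {name:6s} {v:12.2f}")
crit = {k: v for k, v in fix.criteria.items() if k.startswith("c")}
print(f"  criteria: {crit} -> accepted={fix.criteria['accepted']}")
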