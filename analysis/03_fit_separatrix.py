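#!/usr/bin/env python
"""Pairwise parameter constraints from the accepted uni-lineage cohorts.

Fits the separatrix constraints (per-parameter accepted ranges + corner-cut
half-planes for the self-renewal/mitosis and neutrophil-feedback pairs) and
reports the inverse log-log relationship between self-renewal fraction and
mitosis rate.  Writes results/constraints.json.
"""
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from leukosim.separatrix import fit_cohort_constraints, save_constraints

OUT = Path(__file__).resolve().parent.parent / "results"
tables = {ln: pd.read_csv(OUT / f"cohort_uni_{ln}.csv") for ln in "NLM"}
cons = fit_cohort_constraints(tables)
save_constraints(cons, OUT / "constraints.json")
print(f"fitted {len(cons)} constraints -> results/constraints.json")

PAIRS = {"N": ("aN2", "mrN2"), "L": ("aL2", "mrL2"), "M": ("aM2", "mrM2")}
print("self-renewal vs mitosis rate among accepted sets (log-log Spearman):")
for ln, (a, mr) in PAIRS.items():
    acc = tables[ln][tables[ln]["accepted"]]
    if len(acc) < 5:
        print(f"  {ln}: too few accepted sets ({len(acc)})")
        continue
    rho, p = stats.spearmanr(np.log(acc[a]), np.log(acc[mr]))
    print(f"  {ln}: rho = {rho:+.3f} (p = {p:.2g}, n = {len(acc)})"
          f"  -> {'inverse' if rho < 0 else 'direct'} relationship")
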