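#!/usr/bin/env python
"""AML progression, survival curves and the cancer-parameter screens.

Seeds one cancer stem cell into every accepted virtual patient (cancer rates
= their own monocyte rates), computes diagnosis/death endpoints and per-cluster
survival curves; then runs the Latin-Hypercube cancer-parameter screen on the
cluster representatives, free and with the mitosis rate fixed, and reports the
pooled survival correlations.  Writes results/aml_*.csv and
results/survival_curves.csv.
"""
import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from leukosim.aml import (cancer_parameter_screen, initiate_aml, score_outcome,
                          survival_curves)
from leukosim.fixtures import load_fixture
from leukosim.parameters import PARAM_NAMES
from leukosim.pipeline import stage_seeds
from leukosim.sampling import params_from_sample
from leukosim.simulate import find_equilibrium

ap = argparse.ArgumentParser()
ap.add_argument("--n-per", type=int, default=100,
                help="cancer samples per representative (study scale: 625)")
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

OUT = Path(__file__).resolve().parent.parent / "results"
fix = load_fixture(OUT / "nominal_fixture.json")
cohort = pd.read_csv(OUT / "cohort_multi.csv").set_index("run_id")
clusters = pd.read_csv(OUT / "clusters.csv")
seeds = stage_seeds(args.seed)


def patient(rid):
    row = cohort.loc[rid]
    p = params_from_sample(fix.params, {c: row[c] for c in cohort.columns
                                        if c in PARAM_NAMES})
    eq = find_equilibrium(p, fix.equilibrium)
    return (p, eq.x) if eq.tag == "nontrivial" else (p, None)


# baseline AML in every accepted patient
outcomes_by_cluster, rows = {}, []
for _, r in clusters.iterrows():
    p, eq = patient(int(r["run_id"]))
    if eq is None:
        continue
    out = score_outcome(initiate_aml(p, eq), run_id=int(r["run_id"]))
    outcomes_by_cluster.setdefault(int(r["cluster"]), []).append(out)
    rows.append({"run_id": int(r["run_id"]), "cluster": int(r["cluster"]),
                 "diagnosis_day": out.diagnosis_day,
                 "death_day": out.death_day, "survival": out.survival})
pd.DataFrame(rows).to_csv(OUT / "aml_baseline_outcomes.csv", index=False)
curves, summaries = survival_curves(outcomes_by_cluster)
pd.DataFrame([{"cluster": lab, "day": float(t), "survival": float(s)}
              for lab, (ts, ss) in curves.items()
              for t, s in zip(ts, ss)]).to_csv(OUT / "survival_curves.csv",
                                               index=False)
print("baseline AML (own monocyte rates):")
for lab, s in sorted(summaries.items()):
    med = s.get("median")
    print(f"  cluster {lab}: n={s['n']} median death day "
          f"{med:.0f}" if med else f"  cluster {lab}: no deaths")

# cancer-parameter screens on the representatives
reps = {int(r["cluster"]): patient(int(r["run_id"]))
        for _, r in clusters[clusters["representative"]].iterrows()}
reps = {k: v for k, v in reps.items() if v[1] is not None}
reference = fix.params.monocyte_cancer_baseline()  # one shared Table of bounds
for fixed, tag, param in ((False, "", "mrMc2"), (True, "_fixed_mr", "aMc2")):
    outc, corr = cancer_parameter_screen(
        reps, n_per=args.n_per, seed=seeds["aml_fixed" if fixed else "aml"],
        fix_mitosis=fixed, reference=reference)
    outc.to_csv(OUT / f"aml_outcomes{tag}.csv", index=False)
    corr.to_csv(OUT / f"aml_correlations{tag}.csv")
    r, p = corr.attrs["pooled_raw"][param]
    n_diag = int(outc["diagnosed"].sum())
    label = "mitosis rate" if param == "mrMc2" else "self-renewal fraction"
    print(f"{'fixed-mitosis ' if fixed else ''}screen: {n_diag} diagnosed; "
          f"pooled correlation of cancer {label} with survival: "
          f"{r:+.4f} (p = {p:.2g})")
mx = pd.read_csv(OUT / "aml_outcomes.csv")
mx = mx[mx["diagnosed"]]
print(f"longest post-diagnosis survival: {mx['survival'].max():.0f} days "
      f"({mx['survival'].max() / 30.44:.1f} months)")
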