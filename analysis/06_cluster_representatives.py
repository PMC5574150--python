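#!/usr/bin/env python
"""Cluster accepted multi-lineage dynamics into representative patients.

Accepted protocol trajectories (re-simulated from the cohort table) are
normalized per state onto the 162-point grid and clustered with k-means
(k = 13, as in the study, capped by cohort size).  Writes results/clusters.csv
with each run's cluster and the representative flag.
"""
import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from leukosim.clustering import cluster, normalize_trajectories
from leukosim.fixtures import load_fixture
from leukosim.parameters import PARAM_NAMES
from leukosim.pipeline import stage_seeds
from leukosim.sampling import params_from_sample
from leukosim.screening import run_chemo_protocol
from leukosim.simulate import find_equilibrium

ap = argparse.ArgumentParser()
ap.add_argument("--k", type=int, default=13)
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

OUT = Path(__file__).resolve().parent.parent / "results"
fix = load_fixture(OUT / "nominal_fixture.json")
cohort = pd.read_csv(OUT / "cohort_multi.csv")
acc = cohort[cohort["accepted"]]

trajs = {}
for _, row in acc.iterrows():
    p = params_from_sample(fix.params, {c: row[c] for c in cohort.columns
                                        if c in PARAM_NAMES})
    eq = find_equilibrium(p, fix.equilibrium)
    if eq.tag != "nontrivial":
        continue
    trajs[int(row["run_id"])] = run_chemo_protocol(p, eq.x)

dyn = normalize_trajectories(trajs)
k = min(args.k, len(dyn.run_ids))
asg = cluster(dyn, k, stage_seeds(args.seed)["cluster"])
rows = [{"run_id": rid, "cluster": lab,
         "representative": asg.representatives[lab] == rid}
        for rid, lab in asg.labels.items()]
pd.DataFrame(rows).to_csv(OUT / "clusters.csv", index=False)
sizes = pd.Series(list(asg.labels.values())).value_counts().sort_index()
print(f"clustered {len(dyn.run_ids)} accepted patients into k={k}")
print("cluster sizes:", sizes.to_dict())
print("representatives (run ids):", asg.representatives)
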