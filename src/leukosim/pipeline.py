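"""End-to-end virtual-cohort pipeline.

Stages, in the order the study runs them: calibrate the nominal fixture ->
uni-lineage acceptability screens -> separatrix constraints -> constrained
multi-lineage screen -> trajectory clustering into representative patients ->
PRCC sensitivity -> AML initiation per patient and the cancer-parameter
screens.  Every artifact is stamped with the configuration hash and seeds;
rerunning with the same configuration reproduces identical artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aml import cancer_parameter_screen, initiate_aml, score_outcome, survival_curves
from .clustering import ClusterAssignment, cluster, normalize_trajectories, select_k
from .config import RunConfig
from .fixtures import NominalFixture, make_nominal_fixture, save_fixture
from .parameters import ChemoSchedule
from .prcc import sensitivity_report
from .sampling import params_from_sample
from .screening import ScreenResult, screen_multilineage, screen_unilineage
from .separatrix import fit_cohort_constraints, save_constraints

log = logging.getLogger("leukosim")

LINEAGES = ("N", "L", "M")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the master seed."""
    ss = np.random.SeedSequence(seed)
    names = ["uni_N", "uni_L", "uni_M", "multi", "cluster", "aml", "aml_fixed",
             "panel"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31))
            for n, c in zip(names, children)}


@dataclass
class PipelineResult:
    config: RunConfig
    fixture: NominalFixture
    uni: dict[str, ScreenResult]
    constraints: list
    multi: ScreenResult
    assignment: ClusterAssignment | None
    representatives: dict[int, tuple]
    prcc_table: pd.DataFrame | None
    baseline_outcomes: pd.DataFrame | None
    survival: tuple | None
    aml_outcomes: pd.DataFrame | None
    aml_correlations: pd.DataFrame | None
    aml_outcomes_fixed: pd.DataFrame | None
    aml_correlations_fixed: pd.DataFrame | None


def build_representatives(multi: ScreenResult, assignment: ClusterAssignment,
                          base_params) -> dict[int, tuple]:
    """Cluster label -> (parameters, healthy equilibrium) for each
    representative patient (the member nearest its centroid)."""
    table = multi.table.set_index("run_id")
    reps = {}
    for label, rid in assignment.representatives.items():
        row = table.loc[rid]
        sampled = {c: row[c] for c in table.columns
                   if c in base_params.named_values()}
        params = params_from_sample(base_params, sampled)
        reps[label] = (params, multi.equilibria[rid])
    return reps


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full pipeline; optionally write the artifact bundle."""
    seeds = stage_seeds(config.seed)
    schedule = ChemoSchedule(start=config.chemo_start, end=config.chemo_end,
                             infusion=config.chemo_infusion)
    thresholds = config.thresholds()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        manifest_path = out / "manifest.json"
        if manifest_path.exists():
            prev = json.loads(manifest_path.read_text())
            if prev.get("config_hash") != config.hash():
                raise RuntimeError(
                    f"output bundle {out} was produced by config "
                    f"{prev.get('config_hash')}; refusing to mix with "
                    f"{config.hash()}")
        manifest_path.write_text(json.dumps(
            {"config_hash": config.hash(), "seeds": seeds,
             "config": config.to_dict()}, indent=1))

    log.info("calibrating nominal fixture")
    fixture = make_nominal_fixture(config.calibration_targets or None,
                                   config.calibration_choices or None,
                                   config.fixed_deaths or None,
                                   thresholds=thresholds)
    if out is not None:
        save_fixture(fixture, out / "nominal_fixture.json")

    uni = {}
    for ln in LINEAGES:
        log.info("uni-lineage screen %s (n=%d)", ln, config.n_unilineage)
        uni[ln] = screen_unilineage(
            ln, config.n_unilineage, seeds[f"uni_{ln}"], fixture.params,
            fixture.equilibrium, thresholds=thresholds, schedule=schedule,
            keep_trajectories=True)
        log.info("  accepted %d / %d", int(uni[ln].table["accepted"].sum())
                 if len(uni[ln].table) else 0, config.n_unilineage)
        if out is not None:
            uni[ln].table.to_csv(out / f"cohort_uni_{ln}.csv", index=False)

    constraints = fit_cohort_constraints(
        {ln: r.table for ln, r in uni.items() if len(r.table)},
        min_accepted=config.separatrix_min_accepted)
    log.info("fitted %d separatrix constraints", len(constraints))
    if out is not None:
        save_constraints(constraints, out / "constraints.json")

    log.info("multi-lineage screen (n=%d, constrained=%s)",
             config.n_multilineage, bool(constraints))
    multi = screen_multilineage(
        config.n_multilineage, seeds["multi"], fixture.params,
        fixture.equilibrium, constraints=constraints or None,
        thresholds=thresholds, schedule=schedule, keep_trajectories=True)
    n_acc = int(multi.table["accepted"].sum()) if len(multi.table) else 0
    log.info("  accepted %d / %d", n_acc, config.n_multilineage)
    if out is not None:
        multi.table.to_csv(out / "cohort_multi.csv", index=False)
    if n_acc == 0:
        raise RuntimeError("no accepted multi-lineage virtual patients; "
                           "increase n_multilineage")

    # clustering into representative patients
    dynamics = normalize_trajectories(multi.trajectories)
    k = min(config.k_clusters, len(dynamics.run_ids))
    if not config.pin_k and len(dynamics.run_ids) >= 6:
        k, _diag = select_k(dynamics, range(*config.k_range), seeds["cluster"],
                            n_init=config.kmeans_n_init)
    assignment = cluster(dynamics, k, seeds["cluster"],
                         n_init=config.kmeans_n_init)
    log.info("clustered %d accepted patients into k=%d", len(dynamics.run_ids), k)
    if out is not None:
        rows = [{"run_id": rid, "cluster": lab,
                 "representative": assignment.representatives[lab] == rid}
                for rid, lab in assignment.labels.items()]
        pd.DataFrame(rows).to_csv(out / "clusters.csv", index=False)

    representatives = build_representatives(multi, assignment, fixture.params)

    # PRCC sensitivity on the accepted cohort
    prcc_table = None
    acc = multi.table[multi.table["accepted"]].set_index("run_id")
    out_cols = {"stem": "final_HSC", "neutrophils_pb": "final_N_pb",
                "lymphocytes_pb": "final_L3_pb", "monocytes_pb": "final_M_pb"}
    if len(acc) >= 50:  # PRCC needs n comfortably above p
        outputs = pd.DataFrame({k: acc[v] for k, v in out_cols.items()})
        prcc_table = sensitivity_report(acc, outputs)
        if out is not None:
            prcc_table.to_csv(out / "prcc.csv", index=False)

    # baseline AML in every accepted patient (cancer = own monocyte rates)
    log.info("baseline AML simulations in %d patients", len(acc))
    outcomes_by_cluster: dict[int, list] = {}
    base_rows = []
    for rid, label in assignment.labels.items():
        row = multi.table.set_index("run_id").loc[rid]
        sampled = {c: row[c] for c in multi.table.columns
                   if c in fixture.params.named_values()}
        params = params_from_sample(fixture.params, sampled)
        traj = initiate_aml(params, multi.equilibria[rid],
                            seed_concentration=config.cancer_seed_concentration,
                            horizon=config.cancer_horizon,
                            death_threshold=config.death_threshold)
        o = score_outcome(traj, run_id=rid,
                          blast_fraction=config.blast_diagnosis_fraction,
                          death_threshold=config.death_threshold,
                          diagnosis_window=config.diagnosis_window)
        outcomes_by_cluster.setdefault(label, []).append(o)
        base_rows.append({"run_id": rid, "cluster": label,
                          "diagnosis_day": o.diagnosis_day,
                          "death_day": o.death_day, "survival": o.survival,
                          "censored": o.censored})
    baseline_outcomes = pd.DataFrame(base_rows)
    curves, summaries = survival_curves(outcomes_by_cluster)
    if out is not None:
        baseline_outcomes.to_csv(out / "aml_baseline_outcomes.csv", index=False)
        curve_rows = [{"cluster": lab, "day": float(t), "survival": float(s)}
                      for lab, (ts, ss) in curves.items()
                      for t, s in zip(ts, ss)]
        pd.DataFrame(curve_rows).to_csv(out / "survival_curves.csv", index=False)
        (out / "survival_summaries.json").write_text(
            json.dumps(summaries, indent=1, default=float))

    # cancer-parameter screens (Table-2 bounds), free and mitosis-fixed
    log.info("cancer-parameter screen: %d reps x %d", len(representatives),
             config.n_cancer_per_rep)
    reference = fixture.params.monocyte_cancer_baseline()
    aml_outcomes, aml_corr = cancer_parameter_screen(
        representatives, config.n_cancer_per_rep, seeds["aml"],
        reference=reference, horizon=config.cancer_horizon,
        method=config.correlation_method,
        diagnosis_window=config.diagnosis_window)
    aml_outcomes_fx, aml_corr_fx = cancer_parameter_screen(
        representatives, config.n_cancer_per_rep, seeds["aml_fixed"],
        fix_mitosis=True, reference=reference,
        horizon=config.cancer_horizon, method=config.correlation_method,
        diagnosis_window=config.diagnosis_window)
    if out is not None:
        aml_outcomes.to_csv(out / "aml_outcomes.csv", index=False)
        aml_corr.to_csv(out / "aml_correlations.csv")
        aml_outcomes_fx.to_csv(out / "aml_outcomes_fixed_mr.csv", index=False)
        aml_corr_fx.to_csv(out / "aml_correlations_fixed_mr.csv")

    return PipelineResult(
        config=config, fixture=fixture, uni=uni, constraints=constraints,
        multi=multi, assignment=assignment, representatives=representatives,
        prcc_table=prcc_table, baseline_outcomes=baseline_outcomes,
        survival=(curves, summaries), aml_outcomes=aml_outcomes,
        aml_correlations=aml_corr, aml_outcomes_fixed=aml_outcomes_fx,
        aml_correlations_fixed=aml_corr_fx)
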