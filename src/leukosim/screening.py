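"""Virtual-patient generation: sample, find equilibria, treat, screen.

Each Latin Hypercube sample is pushed through the same protocol the clinical
recovery data reflect: find the untreated homeostatic equilibrium, apply the
7-day induction course, simulate recovery through day 300, and score the seven
dynamic acceptability criteria.  Uni-lineage screens run the focal lineage plus
stem cells with the other lineages absent; the multi-lineage screen runs the
integrated model, optionally restricted to a separatrix-constrained region of
parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criteria import CriteriaThresholds, evaluate_acceptability
from .parameters import ChemoSchedule, ModelParameters
from .rhs import lineage_active
from .sampling import (SamplingBounds, default_bounds, lhs_sample,
                       params_from_sample, unilineage_names)
from .simulate import Trajectory, find_equilibrium, protocol_grid, simulate


def run_chemo_protocol(params: ModelParameters, equilibrium: np.ndarray,
                       schedule: ChemoSchedule | None = None,
                       active: np.ndarray | None = None,
                       grid: np.ndarray | None = None) -> Trajectory:
    """Simulate the induction protocol from a homeostatic equilibrium:
    chemotherapy from day -7 to day 0, recovery followed through day 300
    (daily through day 150)."""
    schedule = schedule or ChemoSchedule()
    grid = protocol_grid(chemo_start=schedule.start) if grid is None else grid
    return simulate(params, equilibrium, grid, schedule=schedule, active=active)


@dataclass
class ScreenResult:
    """Cohort table plus the protocol trajectories of accepted samples."""

    table: pd.DataFrame
    trajectories: dict[int, Trajectory]
    equilibria: dict[int, np.ndarray]


def _screen(samples: pd.DataFrame, base: ModelParameters, x0_guess: np.ndarray,
            lineages: tuple[str, ...], active, thresholds, schedule, seed,
            scope: str, keep_trajectories: bool) -> ScreenResult:
    rows = []
    trajs: dict[int, Trajectory] = {}
    eqs: dict[int, np.ndarray] = {}
    for i, row in samples.iterrows():
        params = params_from_sample(base, row.to_dict())
        record = dict(row)
        record.update(run_id=int(i), scope=scope, seed=int(seed))
        eq = find_equilibrium(params, x0_guess, active=active)
        record["equilibrium_tag"] = eq.tag
        if eq.tag != "nontrivial":
            record.update({f"c{k}": False for k in range(1, 8)})
            record.update(accepted=False, overshoot_ratio=np.nan,
                          nadir_frac=np.nan, stem_final=np.nan, pb_final=np.nan)
            rows.append(record)
            continue
        traj = run_chemo_protocol(params, eq.x, schedule=schedule, active=active)
        rep = evaluate_acceptability(traj, thresholds, lineages=lineages)
        record.update(rep.as_dict())
        diag = rep.diagnostics
        record.update(
            overshoot_ratio=max(diag["overshoot_ratio"].values(), default=np.nan),
            nadir_frac=min(diag["nadir_frac"].values(), default=np.nan),
            stem_final=diag["stem_final"], pb_final=diag["pb_final"])
        record.update({f"final_{s}": v for s, v in diag["final_values"].items()})
        rows.append(record)
        if rep.overall:
            eqs[int(i)] = eq.x
            if keep_trajectories:
                trajs[int(i)] = traj
    table = pd.DataFrame(rows)
    if len(table):
        table["accepted"] = table["accepted"].astype(bool)
    return ScreenResult(table=table, trajectories=trajs, equilibria=eqs)


def screen_unilineage(lineage: str, n: int, seed: int, base: ModelParameters,
                      x0_guess: np.ndarray, bounds: SamplingBounds | None = None,
                      thresholds: CriteriaThresholds | None = None,
                      schedule: ChemoSchedule | None = None,
                      keep_trajectories: bool = False) -> ScreenResult:
    """Screen ``n`` LHS samples of a uni-lineage sub-model (stem cells + one
    lineage; criteria referencing absent states pass vacuously)."""
    names = unilineage_names(lineage)
    bounds = bounds.subset(names) if bounds is not None else \
        default_bounds(base, names=names)
    if n == 0:
        return ScreenResult(pd.DataFrame(), {}, {})
    samples = lhs_sample(bounds, n, seed)
    return _screen(samples, base, x0_guess, (lineage,),
                   lineage_active(lineage), thresholds, schedule, seed,
                   scope=lineage, keep_trajectories=keep_trajectories)


def overshoot_peak_over_final(result: ScreenResult,
                              lineage: str | None = None) -> pd.Series:
    """Recovery overshoot per accepted run: the largest post-chemotherapy
    peak relative to the final homeostatic value, over the circulating states
    present plus stem cells."""
    from .states import IDX

    states = {"N": ["N_pb"], "L": ["L3_pb"], "M": ["M_pb"]}.get(
        lineage, ["N_pb", "L3_pb", "M_pb"])
    out = {}
    for rid, tr in result.trajectories.items():
        post = tr.t > (tr.schedule.end if tr.schedule else 0.0)
        vals = [1.0]
        for s in states + ["HSC"]:
            y = tr.x[post, IDX[s]]
            if y[-1] > 0:
                vals.append(float(y.max() / y[-1]))
        out[rid] = max(vals)
    return pd.Series(out, name="overshoot_peak_over_final")


def compare_overshoot(uni_values, multi_values, guard: float = 1.02) -> dict:
    """One-sided rank test that multi-lineage recoveries overshoot less.

    Cross-lineage feedback damps recovery overshoot, so among trajectories
    that overshoot at all (peak more than ``guard`` above the final value) the
    multi-lineage accepted cohort should sit below the uni-lineage one.
    Trajectories without overshoot are uninformative and are excluded.
    """
    from scipy import stats

    u = np.asarray(uni_values, dtype=float)
    m = np.asarray(multi_values, dtype=float)
    u, m = u[u > guard], m[m > guard]
    if len(u) < 4 or len(m) < 4:
        return {"n_uni": len(u), "n_multi": len(m), "p_value": np.nan,
                "median_uni": np.nan, "median_multi": np.nan}
    _, p = stats.mannwhitneyu(m, u, alternative="less")
    return {"n_uni": int(len(u)), "n_multi": int(len(m)),
            "median_uni": float(np.median(u)),
            "median_multi": float(np.median(m)), "p_value": float(p)}


def constrained_bounds(bounds: SamplingBounds, constraints) -> SamplingBounds:
    """Tighten sampling bounds to the accepted per-parameter ranges.

    The separatrix method's first stage re-samples inside the range each
    parameter occupied among accepted uni-lineage sets; this applies those
    :class:`~leukosim.separatrix.RangeConstraint` objects to the bounds (the
    pairwise corner cuts stay with the rejection filter)."""
    from .separatrix import RangeConstraint

    new = dict(bounds.bounds)
    for c in constraints:
        if not isinstance(c, RangeConstraint) or c.name not in new:
            continue
        lo, hi, scale = new[c.name]
        lo2, hi2 = max(lo, 10.0 ** c.lo), min(hi, 10.0 ** c.hi)
        if lo2 < hi2:
            new[c.name] = (lo2, hi2, scale)
    return SamplingBounds(new)


def screen_multilineage(n: int, seed: int, base: ModelParameters,
                        x0_guess: np.ndarray,
                        bounds: SamplingBounds | None = None,
                        constraints=None,
                        constraint_filter=None,
                        thresholds: CriteriaThresholds | None = None,
                        schedule: ChemoSchedule | None = None,
                        keep_trajectories: bool = False,
                        max_batches: int = 200) -> ScreenResult:
    """Screen ``n`` samples of the integrated model.

    ``constraints`` (from the separatrix module) re-shape the sampling space:
    per-parameter range constraints tighten the LHS bounds directly, and the
    pairwise corner-cut constraints reject proposals until ``n`` survive.
    A raw ``constraint_filter`` may be given instead; proposal acceptance
    below 0.1% aborts with an infeasibility error either way.
    """
    bounds = bounds or default_bounds(base)
    if n == 0:
        return ScreenResult(pd.DataFrame(), {}, {})
    if constraints is not None:
        from .separatrix import ConstraintFilter, RangeConstraint

        bounds = constrained_bounds(bounds, constraints)
        pair_cons = [c for c in constraints
                     if not isinstance(c, RangeConstraint)]
        constraint_filter = ConstraintFilter(pair_cons) if pair_cons else None
    if constraint_filter is None:
        samples = lhs_sample(bounds, n, seed)
    else:
        kept, proposed = [], 0
        for b in range(max_batches):
            batch = lhs_sample(bounds, n, seed + 7919 * b)
            mask = batch.apply(lambda r: constraint_filter(r.to_dict()), axis=1)
            proposed += len(batch)
            kept.append(batch[mask.values])
            total = sum(len(k) for k in kept)
            if total >= n:
                break
            if proposed >= 1e5 and total < 1e-3 * proposed:
                raise RuntimeError(
                    f"separatrix constraints infeasible: {total}/{proposed} proposals")
        samples = pd.concat(kept, ignore_index=True).head(n)
        if len(samples) < n:
            raise RuntimeError(
                f"could not draw {n} constrained samples in {max_batches} batches")
    return _screen(samples, base, x0_guess, ("N", "L", "M"),
                   lineage_active(None), thresholds, schedule, seed,
                   scope="multi", keep_trajectories=keep_trajectories)
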