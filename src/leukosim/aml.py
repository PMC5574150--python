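"""AML initiation, progression, survival endpoints and cancer-parameter screens.

Leukemia is modelled parallel to the monocyte lineage (AML derives from
granulocyte/macrophage progenitors): cancer progenitors self-renew and divide
like monocyte progenitors but with every homeostatic feedback removed and no
recruitment back into tissue, so a single transformed cell accumulates
clonally.  AML is diagnosed when blasts exceed 20% of the bone marrow or the
peripheral blood while cancer progenitors exceed 1 cell/uL; the patient dies
when the cancer concentration in either compartment exceeds the theoretical
bone-marrow packing density (3e5 cells/uL), at which point growth — and the
simulation — stops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import CancerParameters, ModelParameters
from .rhs import FULL_ACTIVE
from .sampling import SamplingBounds, lhs_sample
from .simulate import Trajectory, simulate
from .states import CANCER_IDX, IDX

#: One cancer stem cell expressed as a concentration: one cell in ~5 L of blood.
DEFAULT_SEED_CONCENTRATION = 2e-4

BLAST_DIAGNOSIS_FRACTION = 0.20
DIAGNOSIS_STEM_MIN = 1.0            # cells/uL
DEATH_THRESHOLD = 3.0e5             # cells/uL, bone-marrow packing density
DIAGNOSIS_WINDOW = 365.0            # days: leukemia accumulates over one year


@dataclass
class CancerOutcome:
    run_id: int
    cancer: CancerParameters
    initiation_day: float
    diagnosis_day: float | None
    death_day: float | None
    censored: bool

    @property
    def survival(self) -> float | None:
        if self.diagnosis_day is None or self.death_day is None:
            return None
        return self.death_day - self.diagnosis_day


def initiate_aml(params: ModelParameters, equilibrium: np.ndarray,
                 seed_concentration: float = DEFAULT_SEED_CONCENTRATION,
                 cancer: CancerParameters | None = None,
                 horizon: float = 550.0, chunk: float = 64.0,
                 death_threshold: float = DEATH_THRESHOLD) -> Trajectory:
    """Seed one cancer stem cell into a healthy equilibrium and grow it.

    Integrates on a daily grid in chunks and stops once the cancer
    concentration in marrow or blood clears the death threshold (the capacity
    at which growth stops), or at ``horizon`` days.
    """
    eq = np.asarray(equilibrium, dtype=float)
    if np.any(eq[CANCER_IDX] != 0):
        raise ValueError("equilibrium already contains cancer cells")
    if cancer is not None:
        params = params.with_updates(cancer=cancer)
    x0 = eq.copy()
    x0[IDX["Mc2"]] = seed_concentration
    ts, xs = [np.array([0.0])], [x0[None, :]]
    t0, x = 0.0, x0
    stop = 1.3 * death_threshold
    while t0 < horizon:
        t_grid = t0 + np.arange(0.0, min(chunk, horizon - t0) + 0.5)
        if len(t_grid) < 2:
            break
        tr = simulate(params, x, t_grid, schedule=None, active=FULL_ACTIVE)
        ts.append(tr.t[1:])
        xs.append(tr.x[1:])
        if not tr.success:
            return Trajectory(np.concatenate(ts), np.vstack(xs), params,
                              None, success=False, message=tr.message)
        x, t0 = tr.x[-1], tr.t[-1]
        cbm = x[IDX["Mc2"]] + x[IDX["Mc_bm"]]
        if max(cbm, x[IDX["Mc_pb"]]) > stop:
            break
    return Trajectory(np.concatenate(ts), np.vstack(xs), params, None)


def _first_crossing(t: np.ndarray, y: np.ndarray, threshold: float) -> float | None:
    """First crossing day of ``y > threshold``, linearly interpolated."""
    above = y > threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))


def score_outcome(traj: Trajectory, run_id: int = 0,
                  blast_fraction: float = BLAST_DIAGNOSIS_FRACTION,
                  stem_min: float = DIAGNOSIS_STEM_MIN,
                  death_threshold: float = DEATH_THRESHOLD,
                  diagnosis_window: float = DIAGNOSIS_WINDOW) -> CancerOutcome:
    """Diagnosis and death endpoints from an AML trajectory.

    Diagnosis: first day blasts exceed ``blast_fraction`` of the bone marrow
    or the peripheral blood AND cancer progenitors exceed ``stem_min``,
    within ``diagnosis_window`` days of initiation (the leukemia is allowed
    one year of clonal accumulation; clones too indolent to present within it
    are never diagnosed).  Death: first day the cancer concentration in
    marrow or blood exceeds ``death_threshold``.  Missing events are censored.
    """
    t, x = traj.t, traj.x
    c_bm = x[:, IDX["Mc2"]] + x[:, IDX["Mc_bm"]]
    c_pb = x[:, IDX["Mc_pb"]]
    bm_tot = x[:, [IDX[s] for s in
                   ("HSC", "N2", "N_bm", "L2", "M2", "M_bm", "MAC", "A")]].sum(axis=1)
    pb_tot = x[:, [IDX[s] for s in ("N_pb", "L3_pb", "M_pb")]].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_bm = c_bm / (c_bm + bm_tot)
        frac_pb = np.where(c_pb + pb_tot > 0, c_pb / (c_pb + pb_tot), 0.0)
    blast_ok = np.maximum(np.nan_to_num(frac_bm), np.nan_to_num(frac_pb))
    stem_ok = x[:, IDX["Mc2"]] > stem_min

    diag_day = None
    crossing = (blast_ok > blast_fraction) & stem_ok
    if crossing.any():
        i = int(np.argmax(crossing))
        # interpolate the blast-fraction crossing within the flagged interval
        if i > 0 and blast_ok[i - 1] <= blast_fraction and stem_ok[i - 1]:
            diag_day = _first_crossing(t[i - 1:i + 1], blast_ok[i - 1:i + 1],
                                       blast_fraction)
        else:
            diag_day = float(t[i])
        if diag_day is not None and diag_day - t[0] > diagnosis_window:
            diag_day = None

    death_day = _first_crossing(t, np.maximum(c_bm, c_pb), death_threshold)
    if diag_day is None:
        death_day = None
    if diag_day is not None and death_day is not None:
        death_day = max(death_day, diag_day)
    censored = diag_day is None or death_day is None
    return CancerOutcome(run_id=run_id, cancer=traj.params.cancer,
                         initiation_day=float(t[0]), diagnosis_day=diag_day,
                         death_day=death_day, censored=censored)


def survival_curves(outcomes_by_cluster: dict[int, list[CancerOutcome]]):
    """Empirical survival S(t) per cluster plus box summaries of time to death.

    All events are observed (censored outcomes are excluded with a flag in the
    summary); S(t) = fraction of patients with death day > t.
    """
    curves, summaries = {}, {}
    for label, outs in outcomes_by_cluster.items():
        deaths = np.sort([o.death_day for o in outs if o.death_day is not None])
        n_cens = sum(o.death_day is None for o in outs)
        if len(deaths) == 0:
            curves[label] = (np.array([0.0]), np.array([1.0]))
            summaries[label] = {"n": 0, "censored": n_cens}
            continue
        tgrid = np.concatenate([[0.0], deaths])
        surv = 1.0 - np.searchsorted(deaths, tgrid, side="right") / len(deaths)
        surv[0] = 1.0
        curves[label] = (tgrid, surv)
        q1, med, q3 = np.percentile(deaths, [25, 50, 75])
        iqr = q3 - q1
        outliers = deaths[(deaths < q1 - 1.5 * iqr) | (deaths > q3 + 1.5 * iqr)]
        summaries[label] = {"n": len(deaths), "censored": n_cens,
                            "median": float(med), "q1": float(q1),
                            "q3": float(q3), "outliers": outliers.tolist()}
    return curves, summaries


def cancer_bounds(reference: CancerParameters,
                  mr_upper_mult: float = 30.0,
                  mr_upper_absolute: float | None = None) -> SamplingBounds:
    """Screen bounds relative to the healthy reference lineage rates:
    death and mobilization slower than normal (1e-4x .. 1x), self-renewal from
    0.01x up to 1, and mitosis 0.5x up to ``mr_upper_mult`` times normal (the
    printed upper bound '30' is read as a multiple of the monocyte mitosis
    rate for dimensional consistency; an absolute override is available)."""
    mr_hi = mr_upper_absolute if mr_upper_absolute is not None \
        else mr_upper_mult * reference.mrMc2
    return SamplingBounds({
        "dMc": (1e-4 * reference.dMc, reference.dMc, "log"),
        "aMc2": (0.01 * reference.aMc2, 1.0, "linear"),
        "mrMc2": (0.5 * reference.mrMc2, mr_hi, "log"),
        "mbMc": (1e-4 * reference.mbMc, reference.mbMc, "log"),
    })


def _corr(values: np.ndarray, survival: np.ndarray, log: bool,
          method: str = "spearman") -> tuple[float, float]:
    v = np.log10(values) if log else values
    if len(v) < 3 or np.ptp(v) == 0 or np.ptp(survival) == 0:
        return np.nan, np.nan
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    r, p = fn(v, survival)
    return float(r), float(p)


LOG_PARAMS = {"dMc": True, "aMc2": False, "mrMc2": True, "mbMc": True}


def cancer_parameter_screen(representatives: dict[int, tuple[ModelParameters, np.ndarray]],
                            n_per: int, seed: int,
                            fix_mitosis: bool = False,
                            variant: str = "monocyte",
                            reference: CancerParameters | None = None,
                            horizon: float = 550.0,
                            diagnosis_window: float = DIAGNOSIS_WINDOW,
                            method: str = "spearman",
                            alpha: float = 0.05):
    """Latin Hypercube screen of the four cancer parameters per representative.

    ``representatives`` maps cluster label -> (parameters, healthy equilibrium).
    The sampling bounds (and the pinned rate under ``fix_mitosis``) come from
    ``reference`` — one shared table of healthy-lineage rates, normally the
    nominal fixture's — or, if ``reference`` is None, from each
    representative's own lineage rates.  With ``fix_mitosis`` the mitosis rate
    stays at its reference and only death, self-renewal and mobilization are
    sampled (the constrained screen).  Returns ``(outcomes,
    correlation_table)`` where the correlation table has one row per cancer
    parameter, one column per cluster plus ``pooled``, with insignificant
    (p >= alpha) cells masked to NaN.
    """
    rows = []
    rng = np.random.SeedSequence(seed)
    for label, (params, eq) in sorted(representatives.items()):
        ref = reference
        if ref is None:
            ref = (params.monocyte_cancer_baseline() if variant == "monocyte"
                   else params.neutrophil_cancer_baseline())
        bounds = cancer_bounds(ref)
        if fix_mitosis:
            bounds = bounds.subset(["dMc", "aMc2", "mbMc"])
        sub_seed = int(rng.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        samples = lhs_sample(bounds, n_per, sub_seed)
        for i, row in samples.iterrows():
            cp = CancerParameters(
                dMc=float(row["dMc"]), aMc2=float(row["aMc2"]),
                mrMc2=ref.mrMc2 if fix_mitosis else float(row["mrMc2"]),
                mbMc=float(row["mbMc"]), sMc=ref.sMc)
            traj = initiate_aml(params, eq, cancer=cp, horizon=horizon)
            out = score_outcome(traj, run_id=int(i),
                                diagnosis_window=diagnosis_window)
            rows.append({
                "cluster": label, "run": int(i),
                "dMc": cp.dMc, "aMc2": cp.aMc2, "mrMc2": cp.mrMc2,
                "mbMc": cp.mbMc,
                "diagnosed": out.diagnosis_day is not None,
                "diagnosis_day": out.diagnosis_day,
                "death_day": out.death_day,
                "survival": out.survival,
            })
    outcomes = pd.DataFrame(rows)
    diagnosed = outcomes[outcomes["diagnosed"] & outcomes["survival"].notna()]

    params_list = ["dMc", "aMc2", "mbMc"] if fix_mitosis \
        else ["dMc", "aMc2", "mrMc2", "mbMc"]
    cols = {}
    for label in sorted(representatives):
        sub = diagnosed[diagnosed["cluster"] == label]
        col = {}
        for p in params_list:
            r, pv = _corr(sub[p].to_numpy(dtype=float),
                          sub["survival"].to_numpy(dtype=float),
                          LOG_PARAMS[p], method)
            col[p] = r if (np.isfinite(pv) and pv < alpha) else np.nan
        cols[label] = col
    pooled = {}
    pooled_raw = {}
    for p in params_list:
        r, pv = _corr(diagnosed[p].to_numpy(dtype=float),
                      diagnosed["survival"].to_numpy(dtype=float),
                      LOG_PARAMS[p], method)
        pooled_raw[p] = (r, pv)
        pooled[p] = r if (np.isfinite(pv) and pv < alpha) else np.nan
    cols["pooled"] = pooled
    corr_table = pd.DataFrame(cols)
    corr_table.attrs["pooled_raw"] = pooled_raw
    return outcomes, corr_table
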