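"""The seven dynamic acceptability criteria for healthy chemotherapy response.

A virtual patient is accepted when, over the day -7..300 induction-chemotherapy
protocol, the simulation

1. recovers total circulating white cells above 80 cells/uL,
2. recovers stem cells into the 1-100 cells/uL band (and shows recovery off
   the nadir),
3. returns every circulating lineage to its clinically normal range,
4. keeps each marginal pool within one order of magnitude of the circulating
   pool (neutrophils and monocytes; lymphocytes carry no marginal pool),
5. is depleted below 20% of baseline at the end of the 7-day course,
6. overshoots during recovery by less than 12x the value five days after the
   overshoot peak, and
7. damps its post-chemotherapy oscillations: the second recovery peak must sit
   at least 18% below the first (sustained or growing oscillations fail).

Criteria 5-7 are applied to each circulating lineage state and to stem cells;
a failure in any evaluated state fails the criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import Trajectory
from .states import IDX

#: Acceptable final circulating values (cells/uL): the upper limits of the
#: clinically normal ranges.  The bound is one-sided because low counts
#: (post-chemotherapy neutropenia/lymphopenia) are a normal recovery state,
#: whereas counts above normal (e.g. neutrophilia) indicate a response the
#: healthy model should not produce; total-blood recovery is enforced
#: separately.  Two-sided ranges can be configured.
DEFAULT_CLINICAL_RANGES = {
    "N_pb": (0.0, 8000.0),
    "L3_pb": (0.0, 4800.0),
    "M_pb": (0.0, 1000.0),
}

MARGINAL_PAIRS = {"N": ("N_mp", "N_pb"), "M": ("M_mp", "M_pb")}
LINEAGE_PB = {"N": "N_pb", "L": "L3_pb", "M": "M_pb"}


@dataclass
class CriteriaThresholds:
    pb_recovery_min: float = 80.0         # c1, cells/uL
    stem_band: tuple[float, float] = (1.0, 100.0)   # c2, cells/uL
    stem_recovery_factor: float = 1.05    # c2: final > nadir * factor
    clinical_ranges: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_RANGES))
    marginal_log_tol: float = 1.0         # c4, orders of magnitude
    depletion_frac: float = 0.20          # c5
    overshoot_max: float = 12.0           # c6
    osc_tol: float = 0.18                 # c7
    osc_form: str = "damped"              # "damped" | "symmetric"
    peak_guard: float = 0.01              # ignore peaks < 1% above final value


@dataclass
class AcceptabilityReport:
    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool
    c6: bool
    c7: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return all((self.c1, self.c2, self.c3, self.c4, self.c5, self.c6, self.c7))

    def as_dict(self) -> dict:
        d = {f"c{i}": bool(getattr(self, f"c{i}")) for i in range(1, 8)}
        d["accepted"] = self.overall
        return d


def _post_chemo_peaks(t: np.ndarray, y: np.ndarray, final: float,
                      guard: float) -> list[tuple[float, float]]:
    """(time, amplitude-about-final) of local maxima after chemotherapy that
    clear the noise guard.  Endpoints are not peaks."""
    peaks = []
    thr = final * (1.0 + guard)
    for i in range(1, len(y) - 1):
        if y[i] > y[i - 1] and y[i] >= y[i + 1] and y[i] > thr:
            peaks.append((float(t[i]), float(y[i] - final)))
    return peaks


def _overshoot_ratio(t: np.ndarray, y: np.ndarray) -> float:
    """Max post-chemo value over the value five days later (or the final value
    if the grid ends sooner)."""
    imax = int(np.argmax(y))
    peak = y[imax]
    if peak <= 0:
        return 1.0
    t_ref = t[imax] + 5.0
    ref = y[-1] if t_ref >= t[-1] else float(np.interp(t_ref, t, y))
    if ref <= 0 or peak > ref * 1e12:
        return np.inf
    return float(peak / ref)


def evaluate_acceptability(traj: Trajectory,
                           thresholds: CriteriaThresholds | None = None,
                           lineages: tuple[str, ...] = ("N", "L", "M"),
                           chemo_end: float | None = None) -> AcceptabilityReport:
    """Score one protocol trajectory against the seven criteria.

    ``lineages`` names the lineages present in the simulation; criteria that
    reference absent states pass vacuously (e.g. the marginal-pool criterion
    for a lymphocyte uni-lineage run).
    """
    th = thresholds or CriteriaThresholds()
    t = traj.t
    if chemo_end is None:
        chemo_end = traj.schedule.end if traj.schedule is not None else 0.0
    if t[0] > (traj.schedule.start if traj.schedule else -7.0) or t[-1] < chemo_end + 100:
        raise ValueError("trajectory does not cover the protocol window")

    x_final = traj.x[-1]
    x_base = traj.x[0]
    i_end = int(np.argmin(np.abs(t - chemo_end)))
    post = t > chemo_end

    eval_states = ["HSC"] + [LINEAGE_PB[ln] for ln in lineages]

    # c1: total circulating leukocytes recover
    pb_states = [LINEAGE_PB[ln] for ln in lineages]
    pb_final = float(sum(x_final[IDX[s]] for s in pb_states))
    c1 = pb_final > th.pb_recovery_min

    # c2: stem band + recovery off the nadir (recovery is only demanded when
    # chemotherapy actually depleted the pool; an undisturbed trajectory at a
    # healthy level has nothing to recover from)
    stem = traj.state("HSC")
    stem_final = float(stem[-1])
    stem_nadir = float(stem.min())
    depleted = stem_nadir < 0.5 * float(stem[0]) if stem[0] > 0 else False
    c2 = (th.stem_band[0] <= stem_final <= th.stem_band[1]
          and (not depleted or stem_final > stem_nadir * th.stem_recovery_factor))

    # c3: clinically normal final circulating values per present lineage
    c3 = True
    for ln in lineages:
        s = LINEAGE_PB[ln]
        lo, hi = th.clinical_ranges[s]
        if not (lo <= x_final[IDX[s]] <= hi):
            c3 = False

    # c4: marginal pool within one order of magnitude of circulating pool
    c4 = True
    log_ratios = {}
    for ln, (mp, pb) in MARGINAL_PAIRS.items():
        if ln not in lineages:
            continue
        vm, vp = x_final[IDX[mp]], x_final[IDX[pb]]
        if vm <= 0 or vp <= 0:
            c4 = False
            log_ratios[ln] = np.inf
            continue
        r = abs(np.log10(vm) - np.log10(vp))
        log_ratios[ln] = float(r)
        if r > th.marginal_log_tol:
            c4 = False

    # c5-c7 per evaluated state
    c5 = c6 = c7 = True
    nadir_fracs, overshoots, peak_amps = {}, {}, {}
    for s in eval_states:
        y = traj.x[:, IDX[s]]
        base = x_base[IDX[s]]
        if base < 1e-12:  # absent or denormal state: nothing to evaluate
            continue
        nadir_fracs[s] = float(y.min() / base)
        if y[i_end] >= th.depletion_frac * base:
            c5 = False
        ratio = _overshoot_ratio(t[post], y[post])
        overshoots[s] = ratio
        if not ratio < th.overshoot_max:
            c6 = False
        peaks = _post_chemo_peaks(t[post], y[post], float(y[-1]), th.peak_guard)
        peak_amps[s] = [a for _, a in peaks[:2]]
        if len(peaks) >= 2:
            a1, a2 = peaks[0][1], peaks[1][1]
            if th.osc_form == "symmetric":
                ok = abs(a2 - a1) / a1 < th.osc_tol
            else:  # damped: second peak must have decayed by >= osc_tol
                ok = a2 <= (1.0 - th.osc_tol) * a1
            if not ok:
                c7 = False

    diagnostics = {
        "pb_final": pb_final,
        "stem_final": stem_final,
        "stem_nadir": stem_nadir,
        "final_values": {s: float(x_final[IDX[s]]) for s in eval_states},
        "marginal_log_ratio": log_ratios,
        "nadir_frac": nadir_fracs,
        "overshoot_ratio": overshoots,
        "peak_amplitudes": peak_amps,
        "solver_success": traj.success,
    }
    if not traj.success:
        return AcceptabilityReport(False, False, False, False, False, False, False,
                                   diagnostics)
    return AcceptabilityReport(c1, c2, c3, c4, c5, c6, c7, diagnostics)
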