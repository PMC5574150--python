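"""Stiff integration of the leukopoiesis model and equilibrium finding."""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
import pandas as pd
from scipy.integrate import odeint
from scipy.integrate._odepack_py import ODEintWarning

from .parameters import ChemoSchedule, ModelParameters
from .rhs import FULL_ACTIVE, pack_chemo, pack_killmask, rhs
from .states import N_STATES, STATE_NAMES

RTOL = 1e-6
ATOL = 1e-9            # cells/uL
NEG_FLOOR = -1e-6      # below this a trajectory is rejected, above it floored


@dataclass
class Trajectory:
    """Time grid (days) x 17-state matrix from one simulation."""

    t: np.ndarray
    x: np.ndarray                     # shape (len(t), 17)
    params: ModelParameters
    schedule: ChemoSchedule | None = None
    success: bool = True
    message: str = ""

    def state(self, name: str) -> np.ndarray:
        return self.x[:, STATE_NAMES.index(name)]

    def at(self, day: float) -> np.ndarray:
        """State vector at a grid day (nearest grid point)."""
        return self.x[int(np.argmin(np.abs(self.t - day)))]

    def to_frame(self, run_id: str = "run0") -> pd.DataFrame:
        """Tidy CSV-ready table: time, state, value, run_id."""
        n = len(self.t)
        return pd.DataFrame({
            "time": np.repeat(self.t, N_STATES),
            "state": np.tile(STATE_NAMES, n),
            "value": self.x.ravel(),
            "run_id": run_id,
        })


class SolverError(RuntimeError):
    pass


def _integrate(x0: np.ndarray, t_grid: np.ndarray, pvec: np.ndarray,
               chemo: np.ndarray, killmask: np.ndarray,
               active: np.ndarray) -> tuple[np.ndarray, bool, str]:
    """LSODA integration on an output grid; floors sub-tolerance negatives."""
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ODEintWarning)
            out, info = odeint(rhs, x0, t_grid,
                               args=(pvec, chemo, killmask, active),
                               rtol=RTOL, atol=ATOL, mxstep=30000,
                               full_output=True, tfirst=False)
    except (ZeroDivisionError, FloatingPointError, OverflowError) as exc:
        # runaway states can push a feedback denominator to zero; treat it as
        # the stiffness-induced solver failure it is
        out = np.full((len(t_grid), len(x0)), np.nan)
        return out, False, f"right-hand side failure: {exc}"
    ok = info["message"] == "Integration successful."
    msg = "" if ok else str(info["message"])
    if not np.all(np.isfinite(out)):
        return out, False, "non-finite state values"
    if out.min() < NEG_FLOOR:
        return out, False, f"negative excursion {out.min():.3g} below solver floor"
    np.clip(out, 0.0, None, out=out)
    return out, ok, msg


def simulate(params: ModelParameters, x0: np.ndarray, t_grid: np.ndarray,
             schedule: ChemoSchedule | None = None,
             active: np.ndarray | None = None) -> Trajectory:
    """Integrate the model over ``t_grid`` (strictly increasing days).

    Deterministic for identical inputs and tolerances.  Solver failures are
    returned as flagged trajectories (``success=False``) rather than raised, so
    cohort screens can log and skip stiffness casualties.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (N_STATES,) or np.any(x0 < 0) or np.any(~np.isfinite(x0)):
        raise ValueError("x0 must be 17 finite non-negative concentrations")
    act = FULL_ACTIVE if active is None else np.asarray(active, dtype=float)
    x0 = x0 * np.concatenate([
        [1.0], np.repeat(act[0], 4), np.repeat(act[1], 3),
        np.repeat(act[2], 4), [1.0, 1.0], np.repeat(act[3], 3)])
    out, ok, msg = _integrate(x0, t_grid, params.to_vector(),
                              pack_chemo(schedule, params),
                              pack_killmask(schedule), act)
    return Trajectory(t=t_grid, x=out, params=params, schedule=schedule,
                      success=ok, message=msg)


@dataclass
class EquilibriumResult:
    tag: str                      # "nontrivial" | "trivial" | "none"
    x: np.ndarray | None
    residual: float = np.nan
    horizon: float = np.nan


def find_equilibrium(params: ModelParameters, x0: np.ndarray,
                     active: np.ndarray | None = None,
                     max_horizon: float = 2000.0, window: float = 100.0,
                     reltol: float = 1e-7, eps: float = 1e-2) -> EquilibriumResult:
    """Integrate without chemotherapy until the state stops moving.

    Convergence: the relative change of every state over a trailing ``window``
    (days) falls below ``reltol``.  Classification: all states below ``eps``
    cells/uL -> ``trivial``; converged with some state above -> ``nontrivial``;
    no convergence within ``max_horizon`` or solver failure -> ``none``.
    """
    act = FULL_ACTIVE if active is None else np.asarray(active, dtype=float)
    x = np.asarray(x0, dtype=float).copy()
    x = x * np.concatenate([
        [1.0], np.repeat(act[0], 4), np.repeat(act[1], 3),
        np.repeat(act[2], 4), [1.0, 1.0], np.repeat(act[3], 3)])
    pvec = params.to_vector()
    chemo = pack_chemo(ChemoSchedule.none(), params)
    killmask = pack_killmask(None)
    t_done = 0.0
    chunk = 200.0
    while t_done < max_horizon:
        t_grid = np.array([0.0, chunk - window, chunk])
        out, ok, _ = _integrate(x, t_grid, pvec, chemo, killmask, act)
        if not ok:
            return EquilibriumResult(tag="none", x=None, horizon=t_done)
        t_done += chunk
        prev, cur = out[1], out[2]
        x = cur
        scale = np.maximum(np.abs(cur), eps)
        if np.max(np.abs(cur - prev) / scale) < reltol:
            dx = rhs(cur, t_done, pvec, chemo, killmask, act)
            resid = float(np.max(np.abs(dx)))
            if np.all(cur < eps):
                return EquilibriumResult("trivial", cur, resid, t_done)
            return EquilibriumResult("nontrivial", cur, resid, t_done)
        chunk = min(chunk * 2.0, max_horizon - t_done + window)
        if chunk <= window:
            break
    return EquilibriumResult(tag="none", x=None, horizon=t_done)


def protocol_grid(chemo_start: float = -7.0, dense_until: float = 150.0,
                  end: float = 300.0, coarse_step: float = 30.0) -> np.ndarray:
    """Daily sampling from chemo start through ``dense_until``, then every
    ``coarse_step`` days up to ``end``."""
    dense = np.arange(chemo_start, dense_until + 0.5)
    coarse = np.arange(dense_until + coarse_step, end + 0.5, coarse_step)
    return np.concatenate([dense, coarse])
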