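"""Assembled 17-state right-hand side of the leukopoiesis/AML model.

The derivative of each state is the sum of production (asymmetric self-renewal
plus differentiation influx), movement (mobilization, margination,
demargination, recruitment; each inhibited by crowding of the destination
compartment), and loss (natural death plus the chemotherapy log-kill term,
whose casualties are routed into the apoptotic-debris state).

Feedback wiring:

* progenitor self-renewal is inhibited by the same-lineage mature concentration
  in the circulating blood (``kN``, ``kL``, ``kM``); the same constant inhibits
  movement of that lineage's mature cells into the blood, and each movement is
  inhibited by the same-lineage concentration already in its destination pool;
* stem-cell self-renewal is inhibited jointly by the stem-cell concentration
  (``kHSC``) and the total bone-marrow concentration (``kBM``), keeping the
  marrow below its packing capacity;
* apoptotic debris drives macrophage activation and proliferation (positive
  feedback via ``kA``); macrophages enhance recruitment of mature cells back
  into tissue and accelerate debris clearance (positive feedback via ``kMAC``);
* the cancer states obey the monocyte-lineage equations with every homeostatic
  feedback removed and no recruitment back into tissue.

The function is written in scalar form so `numba` can compile it; without
numba the pure-Python version is used unchanged.
"""

from __future__ import annotations

import numpy as np

from .parameters import ChemoSchedule, ModelParameters


def chemo_concentration(t, schedule: ChemoSchedule, elimination: float | None = None):
    """Drug level of a one-compartment PK model at time ``t`` (days).

    Constant-rate infusion over ``[start, end]`` with first-order elimination;
    zero before the infusion starts, exponential washout after it ends.
    Vectorized over ``t``.
    """
    schedule.validate()
    e = schedule.elimination if schedule.elimination is not None else elimination
    if e is None:
        raise ValueError("no elimination rate available (schedule or parameters)")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    on = (t >= schedule.start) & (t <= schedule.end)
    after = t > schedule.end
    if e > 0:
        peak = schedule.infusion / e
        out[on] = peak * (1.0 - np.exp(-e * (t[on] - schedule.start)))
        d_end = peak * (1.0 - np.exp(-e * (schedule.end - schedule.start)))
        out[after] = d_end * np.exp(-e * (t[after] - schedule.end))
    else:
        out[on] = schedule.infusion * (t[on] - schedule.start)
        out[after] = schedule.infusion * (schedule.end - schedule.start)
    return float(out) if out.ndim == 0 else out


def _rhs(x, t, p, chemo, killmask, active):
    """dx/dt for the 17-state model.  ``p`` is ModelParameters.to_vector(),
    ``chemo = [start, end, infusion, elim]``, ``killmask`` a 0/1 vector,
    ``active = [N, L, M, cancer]`` lineage gates (uni-lineage sub-models)."""
    # unpack parameters (order fixed by parameters.PARAM_NAMES)
    dP2 = p[0]; dNm = p[1]; dL3 = p[2]; dL3pb = p[3]
    dMbm = p[4]; dMpb = p[5]; dMAC = p[6]
    aHSC = p[7]; mrHSC = p[8]; sHSC = p[9]; dHSC = p[10]
    fN = p[11]; fL = p[12]; fM = p[13]; kHSC = p[14]; kBM = p[15]
    aN2 = p[16]; mrN2 = p[17]; sN2 = p[18]; kN = p[19]; mbN = p[20]
    mgN = p[21]; dmN = p[22]; kNmp = p[23]; rN = p[24]; kNbm = p[25]
    aL2 = p[26]; mrL2 = p[27]; sL2 = p[28]; kL = p[29]; mbL = p[30]
    rL = p[31]; kLt = p[32]
    aM2 = p[33]; mrM2 = p[34]; sM2 = p[35]; kM = p[36]; mbM = p[37]
    mgM = p[38]; dmM = p[39]; kMmp = p[40]; rM = p[41]; kMbm = p[42]
    actM = p[43]; kA = p[44]; mrMAC = p[45]; clA = p[46]; clAM = p[47]
    kMAC = p[48]
    chKill = p[49]
    dMc = p[52]; aMc2 = p[53]; mrMc2 = p[54]; mbMc = p[55]; sMc = p[56]

    nON = active[0]; lON = active[1]; mON = active[2]; cON = active[3]

    HSC = x[0]
    N2 = x[1]; Nbm = x[2]; Npb = x[3]; Nmp = x[4]
    L2 = x[5]; L3 = x[6]; L3pb = x[7]
    M2 = x[8]; Mbm = x[9]; Mpb = x[10]; Mmp = x[11]
    MAC = x[12]; A = x[13]
    Mc2 = x[14]; Mcbm = x[15]; Mcpb = x[16]

    # compartment totals (only active lineages contribute)
    PBtot = Npb * nON + L3pb * lON + Mpb * mON + Mcpb * cON
    BMtot = (HSC + (N2 + Nbm) * nON + L2 * lON + (M2 + Mbm) * mON
             + MAC + A + (Mc2 + Mcbm) * cON)

    # chemotherapy drug level (closed-form one-compartment PK)
    start = chemo[0]; end = chemo[1]; infusion = chemo[2]; elim = chemo[3]
    if t < start or infusion == 0.0:
        D = 0.0
    elif elim > 0.0:
        peak = infusion / elim
        if t <= end:
            D = peak * (1.0 - np.exp(-elim * (t - start)))
        else:
            Dend = peak * (1.0 - np.exp(-elim * (end - start)))
            D = Dend * np.exp(-elim * (t - end))
    else:
        D = infusion * (min(t, end) - start)
    kill = chKill * D

    # feedback factors; each lineage's constant k regulates both progenitor
    # self-renewal and movement of its mature cells into the blood, driven by
    # that lineage's circulating concentration
    inhH = (kHSC / (kHSC + HSC)) * (kBM / (kBM + BMtot))
    inhN = kN / (kN + Npb)
    inhL = kL / (kL + L3pb)
    inhM = kM / (kM + Mpb)
    nfPB_N = inhN
    nfPB_L = inhL
    nfPB_M = inhM
    pfMAC = MAC / (kMAC + MAC)
    pfA = A / (kA + A)

    dx = np.zeros(17)

    # --- stem cells -----------------------------------------------------
    aH = aHSC * inhH
    dx[0] = ((2.0 * aH - 1.0) * mrHSC - sHSC - dHSC - kill * killmask[0]) * HSC
    phi = (2.0 * (1.0 - aH) * mrHSC + sHSC) * HSC   # differentiation outflux

    # --- neutrophil lineage ---------------------------------------------
    if nON > 0.0:
        aN = aN2 * inhN
        jN2 = fN * phi
        dx[1] = (jN2 + ((2.0 * aN - 1.0) * mrN2 - sN2 - dP2
                        - kill * killmask[1]) * N2)
        prodN = (2.0 * (1.0 - aN) * mrN2 + sN2) * N2
        recN = rN * pfMAC * (kNbm / (kNbm + Nbm)) * Npb
        mobN = mbN * nfPB_N * Nbm
        margN = mgN * (kNmp / (kNmp + Nmp)) * Npb
        demargN = dmN * nfPB_N * Nmp
        dx[2] = prodN + recN - mobN - (dNm + kill * killmask[2]) * Nbm
        dx[3] = mobN + demargN - margN - recN - (dNm + kill * killmask[3]) * Npb
        dx[4] = margN - demargN - (dNm + kill * killmask[4]) * Nmp

    # --- lymphocyte lineage ----------------------------------------------
    if lON > 0.0:
        aL = aL2 * inhL
        jL2 = fL * phi
        dx[5] = (jL2 + ((2.0 * aL - 1.0) * mrL2 - sL2 - dP2
                        - kill * killmask[5]) * L2)
        prodL = (2.0 * (1.0 - aL) * mrL2 + sL2) * L2
        recL = rL * pfMAC * (kLt / (kLt + L3)) * L3pb
        mobL = mbL * nfPB_L * L3
        dx[6] = prodL + recL - mobL - (dL3 + kill * killmask[6]) * L3
        dx[7] = mobL - recL - (dL3pb + kill * killmask[7]) * L3pb

    # --- monocyte lineage -------------------------------------------------
    actFlux = 0.0
    if mON > 0.0:
        aM = aM2 * inhM
        jM2 = fM * phi
        dx[8] = (jM2 + ((2.0 * aM - 1.0) * mrM2 - sM2 - dP2
                        - kill * killmask[8]) * M2)
        prodM = (2.0 * (1.0 - aM) * mrM2 + sM2) * M2
        recM = rM * pfMAC * (kMbm / (kMbm + Mbm)) * Mpb
        mobM = mbM * nfPB_M * Mbm
        margM = mgM * (kMmp / (kMmp + Mmp)) * Mpb
        demargM = dmM * nfPB_M * Mmp
        actFlux = actM * pfA * Mpb
        dx[9] = prodM + recM - mobM - (dMbm + kill * killmask[9]) * Mbm
        dx[10] = (mobM + demargM - margM - recM - actFlux
                  - (dMpb + kill * killmask[10]) * Mpb)
        dx[11] = margM - demargM - (dMpb + kill * killmask[11]) * Mmp

    # --- macrophages and apoptotic debris ---------------------------------
    dx[12] = actFlux + mrMAC * pfA * MAC - dMAC * MAC
    killed = 0.0
    for i in range(17):
        killed += kill * killmask[i] * x[i]
    dx[13] = killed - clA * A - clAM * pfMAC * A

    # --- cancer states (feedback-free monocyte analog) --------------------
    if cON > 0.0:
        dx[14] = ((2.0 * aMc2 - 1.0) * mrMc2 - sMc - dMc
                  - kill * killmask[14]) * Mc2
        prodC = (2.0 * (1.0 - aMc2) * mrMc2 + sMc) * Mc2
        mobC = mbMc * Mcbm
        dx[15] = prodC - mobC - (dMc + kill * killmask[15]) * Mcbm
        dx[16] = mobC - (dMc + kill * killmask[16]) * Mcpb

    return dx


try:  # compiled fast path; the Python fallback is the same function
    import numba

    rhs = numba.njit(_rhs, cache=False, fastmath=False)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    rhs = _rhs
    HAVE_NUMBA = False


def pack_chemo(schedule: ChemoSchedule | None, params: ModelParameters) -> np.ndarray:
    """[start, end, infusion, elimination] for the compiled RHS."""
    if schedule is None:
        schedule = ChemoSchedule.none()
    schedule.validate()
    elim = schedule.elimination if schedule.elimination is not None else params.chElim
    return np.array([schedule.start, schedule.end, schedule.infusion, elim])


def pack_killmask(schedule: ChemoSchedule | None) -> np.ndarray:
    from .states import IDX, N_STATES, default_kill_mask

    if schedule is None or schedule.kill_states is None:
        return default_kill_mask()
    mask = np.zeros(N_STATES)
    for s in schedule.kill_states:
        mask[IDX[s]] = 1.0
    return mask


FULL_ACTIVE = np.array([1.0, 1.0, 1.0, 1.0])
HEALTHY_ACTIVE = np.array([1.0, 1.0, 1.0, 0.0])

_LINEAGE_SLOT = {"N": 0, "L": 1, "M": 2}


def lineage_active(lineage: str | None, cancer: bool = False) -> np.ndarray:
    """Activity gates for uni-lineage sub-models.

    ``lineage`` in {"N", "L", "M"} keeps only that lineage (plus stem cells,
    macrophages and debris); ``None`` keeps all three.  Inactive states are
    pinned at zero and their stem influx is discarded (those cells differentiate
    into lineages outside the sub-model).
    """
    act = np.zeros(4)
    if lineage is None:
        act[:3] = 1.0
    else:
        act[_LINEAGE_SLOT[lineage]] = 1.0
    act[3] = 1.0 if cancer else 0.0
    return act


def derivatives(t: float, x: np.ndarray, params: ModelParameters,
                schedule: ChemoSchedule | None = None,
                active: np.ndarray | None = None) -> np.ndarray:
    """Convenience wrapper evaluating the packed RHS at one point."""
    x = np.asarray(x, dtype=float)
    if x.shape != (17,):
        raise ValueError(f"state vector must have 17 entries, got {x.shape}")
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise ValueError("state vector must be finite and non-negative")
    act = FULL_ACTIVE if active is None else active
    return rhs(x, float(t), params.to_vector(), pack_chemo(schedule, params),
               pack_killmask(schedule), act)
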