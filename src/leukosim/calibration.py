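"""Steady-state calibration of nominal parameters.

The nominal parameter set is not hand-entered: it is back-solved from flux
balance at a clinically normal homeostatic operating point.  Literature death
rates are fixed first; target concentrations for every compartment and a small
set of design choices (mitosis rates, raw self-renewal fractions, effective
traffic rates, Michaelis-constant multipliers) then determine every remaining
rate and feedback constant analytically:

* marginal-pool balance fixes margination from demargination and death;
* circulating-blood balance fixes mobilization out of the marrow;
* marrow balance fixes the progenitor output flux, hence the progenitor pool
  size given its mitosis and differentiation rates;
* each progenitor's effective self-renewal is pinned just below
  self-sufficiency, the deficit being covered by the stem-cell differentiation
  flux split across lineages;
* Michaelis constants are solved from the ratio of effective to raw
  self-renewal at the operating point.

The stem-cell block and the progenitor pools are mutually coupled through the
total bone-marrow concentration, so the solve iterates a few fixed-point
passes (it converges in 2-3 because the coupling is weak).
"""

from __future__ import annotations

import copy

import numpy as np

from .parameters import ModelParameters
from .states import IDX, zeros

#: Fixed death rates (1/day) from the literature ranges recorded in config:
#: progenitors ~10 day lifespan; circulating neutrophils half-life ~8 h;
#: thymic selection loss of maturing lymphocytes; long-lived circulating
#: lymphocytes; marrow monocytes ~10 days; circulating monocytes ~1 day;
#: tissue macrophages ~1-2 months.
DEFAULT_FIXED_DEATHS = {
    "dP2": 0.10,
    "dNm": 2.0,
    "dL3": 0.30,
    "dL3pb": 0.02,
    "dMbm": 0.10,
    "dMpb": 0.60,
    "dMAC": 0.02,
}

#: Homeostatic operating point (cells/uL): normal adult differential counts
#: with marrow reserves a few-fold above blood and marginal pools equal to the
#: circulating pools.
DEFAULT_TARGETS = {
    "HSC": 10.0,
    "N_bm": 8000.0, "N_pb": 4000.0, "N_mp": 4000.0,
    "L3": 2000.0, "L3_pb": 2000.0,
    "M_bm": 800.0, "M_pb": 400.0, "M_mp": 400.0,
}

#: Calibration design choices (see docs/methods.md for rationale).
DEFAULT_CHOICES = {
    "stem": {"aHSC": 0.95, "sHSC": 0.4, "dHSC": 0.05,
             "kHSC_mult": 19.0, "kBM_mult": 9.0},
    "splits": {"fN": 0.55, "fL": 0.25, "fM": 0.20},
    "N": {"mr": 2.0, "s": 0.5, "a": 0.70, "dm_eff": 1.0, "kmp_mult": 4.0},
    "L": {"mr": 1.0, "s": 0.2, "a": 0.70},
    "M": {"mr": 1.5, "s": 0.3, "a": 0.65, "dm_eff": 1.0, "kmp_mult": 4.0},
    "recruitment": {"rN": 0.5, "rL": 0.5, "rM": 0.5,
                    "kbm_mult": 2.0, "kLt_mult": 2.0},
    "macrophage": {"actM": 0.2, "kA": 1000.0, "mrMAC": 0.4,
                   "clA": 0.05, "clAM": 1.0, "kMAC": 30.0},
    "chemo": {"chKill": 1.2, "chElim": 1.0},
    "capacity": 3.0e5,
}


class CalibrationError(RuntimeError):
    pass


def _solve_marginal_lineage(tg, d_bm, d_pb, ch):
    """Mobilization/margination algebra for a lineage with a marginal pool.
    Returns (mg_eff, mb_eff, J) effective rates and progenitor output flux."""
    x_pb, x_mp, x_bm = tg["pb"], tg["mp"], tg["bm"]
    mg_eff = (ch["dm_eff"] + d_pb) * x_mp / x_pb
    mb_eff = ((mg_eff + d_pb) * x_pb - ch["dm_eff"] * x_mp) / x_bm
    if mb_eff <= 0:
        raise CalibrationError("targets imply non-positive mobilization")
    J = (mb_eff + d_bm) * x_bm
    return mg_eff, mb_eff, J


def _progenitor(mr, s, dP2, eps):
    """Effective self-renewal and output coefficient for a progenitor whose
    net loss rate (self-sufficiency deficit) is ``eps``."""
    a_eff = 0.5 * ((s + dP2 - eps) / mr + 1.0)
    if not 0.0 < a_eff < 1.0:
        raise CalibrationError(f"effective self-renewal {a_eff} out of range")
    coeff = 2.0 * (1.0 - a_eff) * mr + s
    return a_eff, coeff


def _michaelis(a_raw, a_eff, C):
    rho = a_eff / a_raw
    if not 0.0 < rho < 1.0:
        raise CalibrationError(
            f"raw self-renewal {a_raw} incompatible with effective {a_eff}")
    return C * rho / (1.0 - rho)


def calibrate_nominal(targets: dict | None = None, choices: dict | None = None,
                      fixed_deaths: dict | None = None,
                      n_iter: int = 4) -> tuple[ModelParameters, np.ndarray]:
    """Back-solve nominal parameters; returns (parameters, steady-state guess).

    The returned state vector is the analytic flux-balance point; it is exact
    up to the fixed-point iteration tolerance and is refined numerically by
    :func:`leukosim.simulate.find_equilibrium` downstream.
    """
    tg = dict(DEFAULT_TARGETS, **(targets or {}))
    ch = copy.deepcopy(DEFAULT_CHOICES)
    for key, val in (choices or {}).items():
        if isinstance(val, dict):
            ch[key].update(val)
        else:
            ch[key] = val
    fd = dict(DEFAULT_FIXED_DEATHS, **(fixed_deaths or {}))

    # mature-compartment balances (independent of the stem block)
    mgN_eff, mbN_eff, J_N = _solve_marginal_lineage(
        {"pb": tg["N_pb"], "mp": tg["N_mp"], "bm": tg["N_bm"]},
        fd["dNm"], fd["dNm"], ch["N"])
    mgM_eff, mbM_eff, J_M = _solve_marginal_lineage(
        {"pb": tg["M_pb"], "mp": tg["M_mp"], "bm": tg["M_bm"]},
        fd["dMbm"], fd["dMpb"], ch["M"])
    mbL_eff = fd["dL3pb"] * tg["L3_pb"] / tg["L3"]
    J_L = (mbL_eff + fd["dL3"]) * tg["L3"]

    st = ch["stem"]
    spl = ch["splits"]
    f = np.array([spl["fN"], spl["fL"], spl["fM"]])
    f = f / f.sum()

    # fixed-point iteration over (progenitor pools <-> marrow total <-> stem flux)
    eps = np.zeros(3)
    x2 = np.zeros(3)
    lineages = (("N", J_N), ("L", J_L), ("M", J_M))
    a_eff = np.zeros(3)
    for _ in range(n_iter):
        for i, (name, J) in enumerate(lineages):
            a_eff[i], coeff = _progenitor(ch[name]["mr"], ch[name]["s"],
                                          fd["dP2"], eps[i])
            x2[i] = J / coeff
        bm_tot = (tg["HSC"] + x2.sum() + tg["N_bm"] + tg["L3"] * 0.0
                  + tg["M_bm"])
        kHSC = st["kHSC_mult"] * tg["HSC"]
        kBM = st["kBM_mult"] * bm_tot
        nfH = (kHSC / (kHSC + tg["HSC"])) * (kBM / (kBM + bm_tot))
        aH_eff = st["aHSC"] * nfH
        if aH_eff <= 0.5 + 1e-3:
            raise CalibrationError(
                f"stem effective self-renewal {aH_eff} cannot balance losses")
        mrHSC = (st["sHSC"] + st["dHSC"]) / (2.0 * aH_eff - 1.0)
        phi = (2.0 * (1.0 - aH_eff) * mrHSC + st["sHSC"]) * tg["HSC"]
        eps = f * phi / np.maximum(x2, 1e-12)

    kN = _michaelis(ch["N"]["a"], a_eff[0], tg["N_pb"])
    kL = _michaelis(ch["L"]["a"], a_eff[1], tg["L3_pb"])
    kM = _michaelis(ch["M"]["a"], a_eff[2], tg["M_pb"])

    # effective -> raw traffic rates (divide out crowding factors at the
    # operating point; movement into the blood is inhibited by the lineage's
    # own circulating concentration)
    nfPB_N = kN / (kN + tg["N_pb"])
    nfPB_L = kL / (kL + tg["L3_pb"])
    nfPB_M = kM / (kM + tg["M_pb"])
    kNmp = ch["N"]["kmp_mult"] * tg["N_mp"]
    kMmp = ch["M"]["kmp_mult"] * tg["M_mp"]
    rec = ch["recruitment"]
    mac = ch["macrophage"]

    params = ModelParameters(
        **fd,
        aHSC=st["aHSC"], mrHSC=mrHSC, sHSC=st["sHSC"], dHSC=st["dHSC"],
        fN=f[0], fL=f[1], fM=f[2], kHSC=kHSC, kBM=kBM,
        aN2=ch["N"]["a"], mrN2=ch["N"]["mr"], sN2=ch["N"]["s"], kN=kN,
        mbN=mbN_eff / nfPB_N, mgN=mgN_eff / (kNmp / (kNmp + tg["N_mp"])),
        dmN=ch["N"]["dm_eff"] / nfPB_N, kNmp=kNmp,
        rN=rec["rN"], kNbm=rec["kbm_mult"] * tg["N_bm"],
        aL2=ch["L"]["a"], mrL2=ch["L"]["mr"], sL2=ch["L"]["s"], kL=kL,
        mbL=mbL_eff / nfPB_L, rL=rec["rL"], kLt=rec["kLt_mult"] * tg["L3"],
        aM2=ch["M"]["a"], mrM2=ch["M"]["mr"], sM2=ch["M"]["s"], kM=kM,
        mbM=mbM_eff / nfPB_M, mgM=mgM_eff / (kMmp / (kMmp + tg["M_mp"])),
        dmM=ch["M"]["dm_eff"] / nfPB_M, kMmp=kMmp,
        rM=rec["rM"], kMbm=rec["kbm_mult"] * tg["M_bm"],
        actM=mac["actM"], kA=mac["kA"], mrMAC=mac["mrMAC"],
        clA=mac["clA"], clAM=mac["clAM"], kMAC=mac["kMAC"],
        chKill=ch["chemo"]["chKill"], chElim=ch["chemo"]["chElim"],
        capacity=ch["capacity"],
    )
    params.validate()

    x0 = zeros()
    x0[IDX["HSC"]] = tg["HSC"]
    x0[IDX["N2"]], x0[IDX["L2"]], x0[IDX["M2"]] = x2
    for name in ("N_bm", "N_pb", "N_mp", "L3", "L3_pb", "M_bm", "M_pb", "M_mp"):
        x0[IDX[name]] = tg[name]
    return params, x0
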