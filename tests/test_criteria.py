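"""Threshold logic of the seven acceptability criteria on constructed curves."""

import numpy as np
import pytest

from leukosim.criteria import CriteriaThresholds, evaluate_acceptability
from leukosim.parameters import ChemoSchedule
from leukosim.simulate import Trajectory, protocol_grid
from leukosim.states import IDX, N_STATES

HEALTHY = {"HSC": 10.0, "N2": 100.0, "N_bm": 8000.0, "N_pb": 4000.0,
           "N_mp": 4000.0, "L2": 100.0, "L3": 2000.0, "L3_pb": 2000.0,
           "M2": 100.0, "M_bm": 800.0, "M_pb": 400.0, "M_mp": 400.0}


def make_traj(series: dict | None = None, params=None) -> Trajectory:
    """Constant healthy trajectory with selected state series overridden."""
    t = protocol_grid()
    x = np.zeros((len(t), N_STATES))
    for name, v in HEALTHY.items():
        x[:, IDX[name]] = v
    for name, arr in (series or {}).items():
        x[:, IDX[name]] = arr
    return Trajectory(t=t, x=x, params=params, schedule=ChemoSchedule())


def dip_recover(t, base, nadir_frac=0.01, tau=10.0):
    """Chemo-like curve: baseline, crash during treatment, smooth recovery."""
    y = np.full_like(t, base, dtype=float)
    during = (t >= -7) & (t <= 0)
    y[during] = base * (nadir_frac + (1 - nadir_frac) * np.exp(-(t[during] + 7)))
    post = t > 0
    y[post] = base * (nadir_frac + (1 - nadir_frac) * (1 - np.exp(-t[post] / tau)))
    return y


def recovering_traj():
    t = protocol_grid()
    series = {name: dip_recover(t, HEALTHY[name])
              for name in ("HSC", "N_bm", "N_pb", "N_mp", "L3", "L3_pb",
                           "M_bm", "M_pb", "M_mp", "N2", "L2", "M2")}
    return make_traj(series)


def test_constant_trajectory_fails_only_depletion():
    rep = evaluate_acceptability(make_traj())
    assert rep.as_dict() == {"c1": True, "c2": True, "c3": True, "c4": True,
                             "c5": False, "c6": True, "c7": True,
                             "accepted": False}


def test_recovering_trajectory_accepted():
    rep = evaluate_acceptability(recovering_traj())
    assert rep.overall, rep.as_dict()


def test_overshoot_thirteen_fold_fails_c6():
    t = protocol_grid()
    y = dip_recover(t, HEALTHY["N_pb"])
    # a sharp spike at day 20 that is 13x the value five days later
    spike = (t >= 18) & (t <= 20)
    y[spike] = 13.0 * HEALTHY["N_pb"]
    base = {name: dip_recover(t, HEALTHY[name])
            for name in ("HSC", "L3_pb", "M_pb", "N_mp", "M_mp")}
    rep = evaluate_acceptability(make_traj({**base, "N_pb": y}))
    assert not rep.c6


def two_peak_wave(t, base, a1, a2):
    """Fast recovery to baseline plus two Gaussian peaks of relative
    amplitude ``a1`` (day 40) and ``a2`` (day 90)."""
    y = dip_recover(t, base, tau=3.0)
    for amp, day in ((a1, 40.0), (a2, 90.0)):
        y += base * amp * np.exp(-0.5 * ((t - day) / 5.0) ** 2) * (t > 0)
    return y


@pytest.mark.parametrize("a2_over_a1,ok_damped,ok_symmetric", [
    (0.25, True, False),   # second peak 25% of first: damped enough
    (0.95, False, True),   # sustained oscillation: ~95% amplitude retained
])
def test_oscillation_criterion_forms(a2_over_a1, ok_damped, ok_symmetric):
    t = protocol_grid()
    base = {name: dip_recover(t, HEALTHY[name])
            for name in ("HSC", "N_pb", "M_pb", "N_mp", "M_mp")}
    traj = make_traj({**base,
                      "L3_pb": two_peak_wave(t, HEALTHY["L3_pb"], 0.5,
                                             0.5 * a2_over_a1)})
    rep = evaluate_acceptability(traj)
    assert rep.c7 == ok_damped
    rep_sym = evaluate_acceptability(
        traj, CriteriaThresholds(osc_form="symmetric"))
    assert rep_sym.c7 == ok_symmetric


def test_single_peak_passes_vacuously():
    rep = evaluate_acceptability(recovering_traj())
    assert rep.c7


def test_marginal_pool_order_of_magnitude():
    t = protocol_grid()
    base = {name: dip_recover(t, HEALTHY[name])
            for name in ("HSC", "N_pb", "L3_pb", "M_pb", "M_mp")}
    # marginal neutrophils land 30x below circulating: > one order of magnitude
    bad = dip_recover(t, HEALTHY["N_pb"] / 30.0)
    rep = evaluate_acceptability(make_traj({**base, "N_mp": bad}))
    assert not rep.c4


def test_lymphocyte_unilineage_c4_vacuous():
    t = protocol_grid()
    traj = make_traj({"HSC": dip_recover(t, HEALTHY["HSC"]),
                      "L3_pb": dip_recover(t, HEALTHY["L3_pb"]),
                      "N_pb": np.zeros_like(t), "N_mp": np.zeros_like(t),
                      "M_pb": np.zeros_like(t), "M_mp": np.zeros_like(t)})
    rep = evaluate_acceptability(traj, lineages=("L",))
    assert rep.c4
    assert rep.overall, rep.as_dict()


def test_short_trajectory_rejected(nominal_params):
    t = np.arange(-7.0, 20.0)
    x = np.ones((len(t), N_STATES))
    traj = Trajectory(t=t, x=x, params=nominal_params,
                      schedule=ChemoSchedule())
    with pytest.raises(ValueError):
        evaluate_acceptability(traj)


def test_overall_is_conjunction():
    rep = evaluate_acceptability(make_traj())
    d = rep.as_dict()
    assert d["accepted"] == all(d[f"c{i}"] for i in range(1, 8))
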