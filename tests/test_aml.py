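"""AML initiation, endpoint scoring, survival curves and screen mechanics."""

import numpy as np
import pytest

from leukosim.aml import (CancerOutcome, DEATH_THRESHOLD, cancer_bounds,
                          cancer_parameter_screen, initiate_aml, score_outcome,
                          survival_curves)
from leukosim.parameters import CancerParameters
from leukosim.simulate import Trajectory
from leukosim.states import IDX, N_STATES


def test_zero_seed_stays_extinct(nominal_params, nominal_equilibrium):
    tr = initiate_aml(nominal_params, nominal_equilibrium,
                      seed_concentration=0.0, horizon=120.0)
    for s in ("Mc2", "Mc_bm", "Mc_pb"):
        assert np.all(tr.state(s) == 0.0)


def test_nonzero_cancer_equilibrium_rejected(nominal_params,
                                             nominal_equilibrium):
    bad = nominal_equilibrium.copy()
    bad[IDX["Mc2"]] = 1.0
    with pytest.raises(ValueError):
        initiate_aml(nominal_params, bad)


def test_symmetric_division_with_death_goes_extinct(nominal_params,
                                                    nominal_equilibrium):
    """aMc2 = 0.5 gives zero net self-renewal; death wins and the clone dies."""
    cp = CancerParameters(dMc=0.2, aMc2=0.5, mrMc2=2.0, mbMc=0.1, sMc=0.3)
    tr = initiate_aml(nominal_params, nominal_equilibrium, cancer=cp,
                      horizon=200.0)
    assert tr.state("Mc2")[-1] < 1e-6
    out = score_outcome(tr)
    assert out.censored and out.diagnosis_day is None


def test_growing_cancer_monotone_until_capacity(nominal_params,
                                                nominal_equilibrium):
    cp = CancerParameters(dMc=0.02, aMc2=0.9, mrMc2=2.0, mbMc=0.3, sMc=0.3)
    tr = initiate_aml(nominal_params, nominal_equilibrium, cancer=cp)
    y = tr.state("Mc2") + tr.state("Mc_bm")
    assert np.all(np.diff(y) > -1e-6 * y[:-1].max())
    assert y[-1] > DEATH_THRESHOLD


def test_score_outcome_threshold_arithmetic(nominal_params):
    """Constructed trajectory: blasts cross 20% at day 100, the death
    threshold at day 160 -> survival 60 days."""
    t = np.arange(0.0, 201.0)
    x = np.zeros((len(t), N_STATES))
    x[:, IDX["N_bm"]] = 10000.0      # healthy marrow background
    # cancer marrow burden: linear through 20% blasts (=2500) at day 100
    # and 3e5 at day 160
    c = np.where(t <= 100, 25.0 * t,
                 2500.0 + (DEATH_THRESHOLD - 2500.0) * (t - 100) / 60.0)
    x[:, IDX["Mc2"]] = c
    traj = Trajectory(t=t, x=x, params=nominal_params)
    out = score_outcome(traj)
    assert out.diagnosis_day == pytest.approx(100.0, abs=1.0)
    assert out.death_day == pytest.approx(160.0, abs=1.0)
    assert out.survival == pytest.approx(60.0, abs=2.0)
    assert not out.censored


def test_undiagnosed_when_below_stem_minimum(nominal_params):
    t = np.arange(0.0, 50.0)
    x = np.zeros((len(t), N_STATES))
    x[:, IDX["N_bm"]] = 1.0
    x[:, IDX["Mc2"]] = 0.9           # blasts are >20% but below 1 cell/uL
    out = score_outcome(Trajectory(t=t, x=x, params=nominal_params))
    assert out.diagnosis_day is None and out.censored


def test_faster_mitosis_dies_earlier(nominal_params, nominal_equilibrium):
    base = CancerParameters(dMc=0.05, aMc2=0.85, mrMc2=1.5, mbMc=0.2, sMc=0.3)
    fast = CancerParameters(dMc=0.05, aMc2=0.85, mrMc2=3.0, mbMc=0.2, sMc=0.3)
    d1 = score_outcome(initiate_aml(nominal_params, nominal_equilibrium,
                                    cancer=base)).death_day
    d2 = score_outcome(initiate_aml(nominal_params, nominal_equilibrium,
                                    cancer=fast)).death_day
    assert d2 < d1


def test_death_never_precedes_diagnosis(nominal_params, nominal_equilibrium):
    cp = CancerParameters(dMc=0.05, aMc2=0.95, mrMc2=4.0, mbMc=0.5, sMc=0.3)
    out = score_outcome(initiate_aml(nominal_params, nominal_equilibrium,
                                     cancer=cp))
    assert out.diagnosis_day <= out.death_day
    assert out.survival >= 0.0


def _outcome(death, diag=0.0):
    return CancerOutcome(run_id=0, cancer=None, initiation_day=0.0,
                         diagnosis_day=diag, death_day=death,
                         censored=death is None)


def test_survival_curve_step_and_box_summary():
    outs = {1: [_outcome(200.0) for _ in range(5)],
            2: [_outcome(d) for d in (50.0, 100.0, 150.0, 400.0)]}
    curves, summaries = survival_curves(outs)
    t1, s1 = curves[1]
    assert s1[0] == 1.0
    assert s1[np.searchsorted(t1, 200.0)] == 0.0       # all die at day 200
    assert summaries[2]["median"] == pytest.approx(125.0)
    assert summaries[1]["n"] == 5 and summaries[1]["censored"] == 0


def test_cancer_bounds_follow_reference():
    ref = CancerParameters(dMc=0.1, aMc2=0.65, mrMc2=1.5, mbMc=2.0, sMc=0.3)
    b = cancer_bounds(ref)
    assert b.bounds["dMc"] == (pytest.approx(1e-5), pytest.approx(0.1), "log")
    assert b.bounds["aMc2"][1] == 1.0
    assert b.bounds["mrMc2"][1] == pytest.approx(45.0)   # 30x reference
    b_abs = cancer_bounds(ref, mr_upper_absolute=30.0)
    assert b_abs.bounds["mrMc2"][1] == 30.0


def test_screen_variants_share_structure(nominal_params, nominal_equilibrium):
    reps = {1: (nominal_params, nominal_equilibrium)}
    out_m, corr_m = cancer_parameter_screen(reps, n_per=12, seed=3,
                                            variant="monocyte")
    out_n, corr_n = cancer_parameter_screen(reps, n_per=12, seed=3,
                                            variant="neutrophil")
    # identical layout; only the reference lineage rates differ
    assert list(out_m.columns) == list(out_n.columns)
    assert set(corr_m.columns) == set(corr_n.columns)
    assert not np.allclose(out_m["mrMc2"], out_n["mrMc2"])


def test_screen_shuffled_survival_insignificant(nominal_params,
                                                nominal_equilibrium):
    rng = np.random.default_rng(0)
    reps = {1: (nominal_params, nominal_equilibrium)}
    out, _ = cancer_parameter_screen(reps, n_per=60, seed=5)
    d = out[out["diagnosed"] & out["survival"].notna()].copy()
    from leukosim.aml import _corr
    shuffled = rng.permutation(d["survival"].to_numpy())
    for p, lg in (("mrMc2", True), ("aMc2", False)):
        r, pv = _corr(d[p].to_numpy(), shuffled, lg)
        assert not pv < 0.01
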