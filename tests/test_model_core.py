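"""The assembled 17-state system: fixed points, chemo PK, cancer closed form,
uni-lineage decoupling and solver behaviour."""

import numpy as np
import pytest

from leukosim import (CancerParameters, ChemoSchedule, find_equilibrium,
                      protocol_grid, simulate)
from leukosim.rhs import chemo_concentration, derivatives, lineage_active
from leukosim.simulate import EquilibriumResult
from leukosim.states import IDX, STATE_NAMES, zeros


def test_state_vector_layout():
    assert len(STATE_NAMES) == 17
    assert "L_mp" not in STATE_NAMES  # no lymphocyte marginal pool


def test_extinction_is_a_fixed_point(nominal_params):
    dx = derivatives(0.0, zeros(), nominal_params)
    assert np.all(dx == 0.0)


def test_equilibrium_residual(nominal_params, nominal_equilibrium):
    dx = derivatives(0.0, nominal_equilibrium, nominal_params)
    assert np.max(np.abs(dx)) <= 1e-6 * np.max(nominal_equilibrium)


def test_derivatives_rejects_bad_states(nominal_params):
    bad = zeros()
    bad[0] = -1.0
    with pytest.raises(ValueError):
        derivatives(0.0, bad, nominal_params)
    nan = zeros()
    nan[3] = np.nan
    with pytest.raises(ValueError):
        derivatives(0.0, nan, nominal_params)


def test_isolated_cancer_symbolic_reduction(nominal_params):
    """With every other state empty the cancer progenitor equation reduces to
    dMc2/dt = ((2 a - 1) mr - s - d) Mc2."""
    cp = CancerParameters(dMc=0.07, aMc2=0.85, mrMc2=2.5, mbMc=0.2, sMc=0.4)
    p = nominal_params.with_updates(cancer=cp)
    x = zeros()
    x[IDX["Mc2"]] = 123.0
    dx = derivatives(0.0, x, p)
    expected = ((2 * 0.85 - 1) * 2.5 - 0.4 - 0.07) * 123.0
    assert dx[IDX["Mc2"]] == pytest.approx(expected, rel=1e-12)


def test_isolated_cancer_exponential_growth(nominal_params):
    """Feedback-free growth matches the analytic exponential to <1% over 30 d."""
    cp = CancerParameters(dMc=0.05, aMc2=0.9, mrMc2=2.0, mbMc=0.1, sMc=0.3)
    p = nominal_params.with_updates(cancer=cp)
    x = zeros()
    x[IDX["Mc2"]] = 1.0
    t = np.arange(0.0, 31.0)
    tr = simulate(p, x, t)
    g = (2 * 0.9 - 1) * 2.0 - 0.3 - 0.05
    rel = np.abs(tr.state("Mc2") - np.exp(g * t)) / np.exp(g * t)
    assert rel.max() < 0.01


class TestChemoConcentration:
    sched = ChemoSchedule(start=-7.0, end=0.0, infusion=1.0, elimination=1.0)

    def test_zero_before_start(self):
        assert chemo_concentration(-8.0, self.sched) == 0.0

    def test_washout_to_zero(self):
        assert chemo_concentration(200.0, self.sched) < 1e-12

    def test_plateau_closed_form(self):
        # infusion 1/day, elimination 1/day, five days in: 1 - e^-5
        val = chemo_concentration(-2.0, self.sched)
        assert val == pytest.approx(1.0 - np.exp(-5.0), rel=1e-12)

    def test_continuity_at_infusion_end(self):
        before = chemo_concentration(-1e-9, self.sched)
        after = chemo_concentration(1e-9, self.sched)
        assert before == pytest.approx(after, rel=1e-6)

    def test_invalid_schedule(self):
        with pytest.raises(ValueError):
            ChemoSchedule(start=0.0, end=-1.0).validate()


def test_zero_initial_condition_stays_zero(nominal_params):
    tr = simulate(nominal_params, zeros(), np.linspace(0, 50, 26),
                  schedule=ChemoSchedule())
    assert np.all(tr.x == 0.0)


def test_simulation_deterministic(nominal_params, nominal_equilibrium):
    grid = protocol_grid()
    a = simulate(nominal_params, nominal_equilibrium, grid, ChemoSchedule())
    b = simulate(nominal_params, nominal_equilibrium, grid, ChemoSchedule())
    assert np.array_equal(a.x, b.x)


def test_trajectory_nonnegative(nominal_params, nominal_equilibrium):
    tr = simulate(nominal_params, nominal_equilibrium, protocol_grid(),
                  ChemoSchedule())
    assert tr.success
    assert tr.x.min() >= 0.0


def test_decoupling_equivalence(nominal_params, nominal_equilibrium):
    """The uni-lineage sub-model equals the full model with the other lineages
    empty and their stem influx shut off, bitwise on the same solver."""
    p = nominal_params.with_updates(fN=1.0, fL=0.0, fM=0.0)
    x0 = nominal_equilibrium.copy()
    for s in ("L2", "L3", "L3_pb", "M2", "M_bm", "M_pb", "M_mp"):
        x0[IDX[s]] = 0.0
    grid = np.arange(-7.0, 60.0)
    full = simulate(p, x0, grid, ChemoSchedule())
    sub = simulate(p, x0, grid, ChemoSchedule(), active=lineage_active("N"))
    assert np.array_equal(full.x, sub.x)


class TestFindEquilibrium:
    def test_zero_start_is_trivial(self, nominal_params):
        res = find_equilibrium(nominal_params, zeros())
        assert res.tag == "trivial"

    def test_nominal_is_nontrivial_with_stem_band(self, nominal_params,
                                                  nominal_equilibrium):
        res = find_equilibrium(nominal_params, nominal_equilibrium)
        assert res.tag == "nontrivial"
        assert 1.0 <= res.x[IDX["HSC"]] <= 100.0
        assert res.residual <= 1e-6 * np.max(res.x)

    def test_pure_self_renewal_diverges(self, nominal_params,
                                        nominal_equilibrium):
        """Self-renewal pinned at 1 with feedback effectively disabled grows
        without bound: no equilibrium is found."""
        p = nominal_params.with_updates(
            aHSC=1.0, aN2=1.0, aL2=1.0, aM2=1.0,
            kHSC=1e12, kBM=1e12, kN=1e12, kL=1e12, kM=1e12)
        res = p and find_equilibrium(p, nominal_equilibrium)
        assert isinstance(res, EquilibriumResult)
        assert res.tag == "none"
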