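"""Synthetic fixtures: calibration acceptance, pseudo-patient panels, oracles."""

import numpy as np
import pytest

from leukosim.calibration import CalibrationError, calibrate_nominal
from leukosim.fixtures import (load_fixture, make_nominal_fixture,
                               make_planted_clusters, make_pseudo_hsct_panel,
                               panel_overshoot_ratio, save_fixture)


def test_nominal_fixture_passes_all_criteria():
    fix = make_nominal_fixture()
    assert fix.criteria["accepted"]
    assert all(fix.criteria[f"c{i}"] for i in range(1, 8))
    assert 1.0 <= fix.criteria["stem_equilibrium"] <= 100.0


def test_shipped_fixture_matches_regeneration(tmp_path):
    """The versioned fixture regenerates bit-identically from the config."""
    fix = make_nominal_fixture()
    shipped = load_fixture()
    assert fix.params.named_values() == shipped.params.named_values()
    assert np.allclose(fix.equilibrium, shipped.equilibrium, rtol=1e-12)
    path = tmp_path / "fix.json"
    save_fixture(fix, path)
    assert load_fixture(path).params.named_values() == fix.params.named_values()


def test_unstable_calibration_choices_fail_loudly():
    """Self-renewal forced to the 0.99 ceiling everywhere cannot be balanced
    by feedback and is reported as a calibration/acceptance failure."""
    choices = {"N": {"a": 0.99}, "L": {"a": 0.99}, "M": {"a": 0.99},
               "stem": {"aHSC": 0.99, "kHSC_mult": 1e6, "kBM_mult": 1e6}}
    with pytest.raises(CalibrationError):
        make_nominal_fixture(choices=choices)


def test_calibration_hits_targets():
    params, x0 = calibrate_nominal()
    from leukosim.simulate import find_equilibrium
    eq = find_equilibrium(params, x0)
    assert eq.tag == "nontrivial"
    assert np.allclose(eq.x[:13], x0[:13], rtol=1e-3, atol=1e-6)


class TestPseudoPanel:
    def test_noiseless_panel_equals_simulation(self, nominal):
        panel = make_pseudo_hsct_panel(2, overshoot_fraction=0.0, noise_cv=0.0,
                                       seed=1,
                                       cohort=[(nominal.params,
                                                nominal.equilibrium)])
        from leukosim.screening import run_chemo_protocol
        from leukosim.states import IDX
        traj = run_chemo_protocol(nominal.params, nominal.equilibrium)
        neut = panel[(panel.patient == 0) & (panel.lineage == "neutrophils")]
        expected = np.interp(neut["day"], traj.t, traj.x[:, IDX["N_pb"]])
        assert np.allclose(neut["count"].to_numpy(), expected)

    def test_same_seed_identical(self, nominal):
        kw = dict(n_patients=3, overshoot_fraction=0.3, noise_cv=0.25,
                  cohort=[(nominal.params, nominal.equilibrium)])
        a = make_pseudo_hsct_panel(seed=7, **kw)
        b = make_pseudo_hsct_panel(seed=7, **kw)
        assert a.equals(b)

    def test_overshoot_fraction_binomial(self, nominal):
        """47 patients at 15% overshoot: about 40 without overshoot."""
        panel = make_pseudo_hsct_panel(47, overshoot_fraction=0.15,
                                       noise_cv=0.0, seed=11,
                                       cohort=[(nominal.params,
                                                nominal.equilibrium)])
        flags = panel.groupby("patient")["overshoot"].first()
        n_without = int((~flags).sum())
        # 3-sigma binomial band around 40/47
        assert abs(n_without - 47 * 0.85) <= 3 * np.sqrt(47 * 0.15 * 0.85)

    def test_overshoot_ratio_bounded_by_twelve(self, nominal):
        panel = make_pseudo_hsct_panel(20, overshoot_fraction=1.0,
                                       noise_cv=0.1, seed=13,
                                       cohort=[(nominal.params,
                                                nominal.equilibrium)])
        ratios = panel_overshoot_ratio(panel)
        assert (ratios <= 12.0).all()
        assert panel["count"].min() >= 0.0


def test_planted_clusters_reproducible():
    a, la = make_planted_clusters(3, 5, separation=1.0, seed=2)
    b, lb = make_planted_clusters(3, 5, separation=1.0, seed=2)
    assert np.array_equal(a.matrices, b.matrices)
    assert np.array_equal(la, lb)
    assert a.matrices.min() >= 0.0 and a.matrices.max() <= 1.0


def test_planted_separation_zero_is_degenerate():
    dyn, labels = make_planted_clusters(2, 10, separation=0.0, seed=3)
    centers = [dyn.flat[labels == k].mean(axis=0) for k in (0, 1)]
    assert np.allclose(centers[0], centers[1], atol=0.05)
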