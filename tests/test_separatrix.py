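"""Separatrix fitting against synthetic oracles with known boundaries."""

import numpy as np
import pytest

from leukosim.fixtures import make_separatrix_oracle
from leukosim.separatrix import (ConstraintFilter, RangeConstraint,
                                 SeparatrixConstraint, fit_separatrix,
                                 load_constraints, satisfies, save_constraints)


def fit_oracle(slope, intercept, seed, n=10_000, flip=False):
    df, truth = make_separatrix_oracle(slope, intercept, n=n, seed=seed,
                                       flip=flip)
    acc = df[df["accepted"]]
    con = fit_separatrix(acc["x"].to_numpy(), acc["y"].to_numpy(), ("x", "y"))
    return df, truth, con


@pytest.mark.parametrize("slope,intercept,seed", [
    (-1.0, 2.5, 0), (-0.5, 2.0, 1), (-2.0, 3.5, 2),
])
def test_oracle_boundary_recovered(slope, intercept, seed):
    """The corner cut lies within one bin width of the true line and
    classification agrees >= 95% outside the one-bin boundary band."""
    df, truth, con = fit_oracle(slope, intercept, seed)
    binw = (con.box[0][1] - con.box[0][0]) / 10
    binh = (con.box[1][1] - con.box[1][0]) / 10
    assert len(con.inequalities) >= 1
    # the cut that excludes the upper region should match the true line
    cuts = [(a, b, c) for a, b, c in con.inequalities if b < 0]
    assert cuts, con.inequalities
    a, b, c = max(cuts, key=lambda q: abs(q[0]))
    fit_slope, fit_icept = -a / b, c / b   # ly <= fit_slope*lx + fit_icept
    assert abs(fit_slope - slope) < 0.25 * max(1.0, abs(slope))
    # the corner-ward translation biases the intercept conservatively; on
    # steep boundaries that bias approaches the bin quantization itself
    assert abs(fit_icept - intercept) < binh * max(1.0, abs(slope) / 1.3)

    lx, ly = np.log10(df["x"]), np.log10(df["y"])
    truth_lab = df["accepted"].to_numpy()
    pred = np.array([satisfies(con, {"x": x, "y": y})
                     for x, y in zip(df["x"], df["y"])])
    dist = np.abs(ly - slope * lx - intercept) / np.hypot(slope, 1.0)
    inbox = ((lx >= con.box[0][0]) & (lx <= con.box[0][1])
             & (ly >= con.box[1][0]) & (ly <= con.box[1][1]))
    sel = (dist > max(binw, binh)) & inbox
    assert (pred[sel] == truth_lab[sel]).mean() >= 0.95


def test_all_acceptable_cloud_gives_box_only():
    """Uniform accepted density has no corner staircase to cut: every point
    inside the box is retained (the degenerate box-only constraint)."""
    rng = np.random.default_rng(5)
    x = 10.0 ** rng.uniform(0, 2, 2000)
    y = 10.0 ** rng.uniform(0, 2, 2000)
    con = fit_separatrix(x, y, ("x", "y"))
    assert con.inequalities == []
    assert all(satisfies(con, {"x": a, "y": b}) for a, b in zip(x, y))


def test_flipped_labels_cut_complementary_corner():
    _, _, con = fit_oracle(-1.0, 2.0, seed=3)
    _, _, con_f = fit_oracle(-1.0, 2.0, seed=3, flip=True)
    # original: acceptable below the anti-diagonal -> upper-right corner cut
    # (b < 0); flipped: lower-left corner cut (b > 0)
    assert any(b < 0 for _, b, _ in con.inequalities)
    assert any(b > 0 for _, b, _ in con_f.inequalities)


def test_conservativeness_on_training_points():
    """>= 96% of training accepted points remain inside the fitted region."""
    df, _, con = fit_oracle(-1.0, 2.5, seed=7)
    acc = df[df["accepted"]]
    kept = np.mean([satisfies(con, {"x": x, "y": y})
                    for x, y in zip(acc["x"], acc["y"])])
    assert kept >= 1.0 - 4 * 0.01


def test_box_refit_idempotent():
    df, _, con = fit_oracle(-1.0, 2.5, seed=8)
    acc = df[df["accepted"]]
    keep = [satisfies(con, {"x": x, "y": y})
            for x, y in zip(acc["x"], acc["y"])]
    refit = fit_separatrix(acc["x"][keep].to_numpy(), acc["y"][keep].to_numpy(),
                           ("x", "y"))
    for axis in (0, 1):
        assert refit.box[axis][0] >= con.box[axis][0] - 1e-9
        assert refit.box[axis][1] <= con.box[axis][1] + 1e-9


def test_satisfies_examples():
    _, _, con = fit_oracle(-1.0, 2.5, seed=9)
    assert not satisfies(con, {"x": 10 ** 3.0, "y": 10 ** 1.0})  # outside box
    assert satisfies(con, {"x": 10 ** 0.5, "y": 10 ** 0.5})      # deep inside
    with pytest.raises(KeyError):
        satisfies(con, {"x": 1.0})


def test_degenerate_points_rejected():
    with pytest.raises(ValueError):
        fit_separatrix(np.ones(5), np.arange(1, 6), ("x", "y"))


def test_constraint_filter_rates():
    empty = ConstraintFilter([])
    rng = np.random.default_rng(0)
    for _ in range(100):
        assert empty({"x": rng.uniform(1, 100)})
    assert empty.acceptance_rate == 1.0

    # box covering 25% of the proposal area -> acceptance ~ 0.25
    box = SeparatrixConstraint(pair=("x", "y"), box=((0.0, 1.0), (0.0, 1.0)),
                               grid=np.ones((10, 10), dtype=bool),
                               inequalities=[], cutoff=0.0)
    filt = ConstraintFilter([box])
    pts = 10.0 ** rng.uniform(0, 2, size=(10_000, 2))
    hits = sum(filt({"x": p, "y": q}) for p, q in pts)
    assert abs(hits / 10_000 - 0.25) < 0.02


def test_range_constraint_and_serialization(tmp_path):
    rc = RangeConstraint(name="mrN2", lo=0.0, hi=1.0)
    assert rc.satisfies({"mrN2": 5.0})
    assert not rc.satisfies({"mrN2": 20.0})
    _, _, con = fit_oracle(-1.0, 2.5, seed=11)
    path = tmp_path / "cons.json"
    save_constraints([rc, con], path)
    loaded = load_constraints(path)
    assert isinstance(loaded[0], RangeConstraint)
    assert isinstance(loaded[1], SeparatrixConstraint)
    assert loaded[1].inequalities == [tuple(q) for q in con.inequalities]
    assert np.array_equal(loaded[1].grid, con.grid)
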