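"""Trajectory normalization and k-means stratification."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from leukosim.clustering import (cluster, clustering_grid,
                                 normalize_trajectories, select_k)
from leukosim.fixtures import make_planted_clusters
from leukosim.parameters import ChemoSchedule
from leukosim.simulate import Trajectory, protocol_grid
from leukosim.states import IDX, N_STATES


def test_grid_has_162_points():
    assert len(clustering_grid()) == 162


def make_traj(params, fill):
    t = protocol_grid()
    x = np.zeros((len(t), N_STATES))
    for name, series in fill.items():
        x[:, IDX[name]] = series
    return Trajectory(t=t, x=x, params=params, schedule=ChemoSchedule())


def test_normalization_properties(nominal_params):
    t = protocol_grid()
    rising = 1.0 - np.exp(-np.clip(t, 0, None) / 20.0)
    trajs = {
        0: make_traj(nominal_params, {"N_pb": np.full(len(t), 7.0),
                                      "L3_pb": rising}),
        1: make_traj(nominal_params, {"N_pb": np.full(len(t), 70.0),
                                      "L3_pb": 10.0 * rising}),
    }
    dyn = normalize_trajectories(trajs)
    # constant positive series -> all ones; scaling leaves the row unchanged
    assert np.allclose(dyn.matrices[0, IDX["N_pb"]], 1.0)
    assert np.allclose(dyn.matrices[0, IDX["N_pb"]],
                       dyn.matrices[1, IDX["N_pb"]])
    assert np.allclose(dyn.matrices[0, IDX["L3_pb"]],
                       dyn.matrices[1, IDX["L3_pb"]])
    # absent states stay identically zero without division errors
    assert np.all(dyn.matrices[:, IDX["Mc2"]] == 0.0)
    # entries bounded in [0, 1] and each present state attains its max of 1
    assert dyn.matrices.min() >= 0.0 and dyn.matrices.max() <= 1.0
    assert dyn.matrices[0, IDX["L3_pb"]].max() == pytest.approx(1.0)


def test_normalization_idempotent(nominal_params):
    t = protocol_grid()
    trajs = {0: make_traj(nominal_params,
                          {"N_pb": 5 + np.sin(t / 30.0) ** 2})}
    once = normalize_trajectories(trajs)
    again = [Trajectory(t=once.grid, x=once.matrices[0].T,
                        params=nominal_params, schedule=ChemoSchedule())]
    twice = normalize_trajectories({0: again[0]})
    assert np.allclose(once.matrices, twice.matrices)


def test_uncovered_grid_rejected(nominal_params):
    t = np.arange(0.0, 100.0)
    traj = Trajectory(t=t, x=np.ones((len(t), N_STATES)),
                      params=nominal_params, schedule=ChemoSchedule())
    with pytest.raises(ValueError):
        normalize_trajectories({0: traj})


def test_planted_two_clusters_recovered():
    dyn, labels = make_planted_clusters(k_true=2, n_per=20, separation=1.0,
                                        seed=0)
    asg = cluster(dyn, k=2, seed=0)
    pred = [asg.labels[r] for r in dyn.run_ids]
    assert adjusted_rand_score(labels, pred) == 1.0
    # representatives are actual members and clusters are non-empty
    assert set(asg.representatives.values()) <= set(dyn.run_ids)
    assert set(asg.labels.values()) == {1, 2}


def test_k_equals_set_size_zero_wcss():
    dyn, _ = make_planted_clusters(k_true=3, n_per=2, separation=2.0, seed=1)
    asg = cluster(dyn, k=6, seed=0)
    assert asg.inertia == pytest.approx(0.0, abs=1e-9)


def test_clustering_deterministic():
    dyn, _ = make_planted_clusters(k_true=3, n_per=10, separation=0.8, seed=2)
    a = cluster(dyn, k=3, seed=42)
    b = cluster(dyn, k=3, seed=42)
    assert a.labels == b.labels
    assert np.array_equal(a.centroids, b.centroids)


def test_label_recovery_invariant_to_seed():
    dyn, labels = make_planted_clusters(k_true=3, n_per=15, separation=1.2,
                                        seed=3)
    for seed in (0, 7, 99):
        pred = [cluster(dyn, k=3, seed=seed).labels[r] for r in dyn.run_ids]
        assert adjusted_rand_score(labels, pred) == 1.0


def test_select_k_finds_planted_structure():
    dyn, _ = make_planted_clusters(k_true=3, n_per=15, separation=1.2, seed=4)
    k, diag = select_k(dyn, range(2, 7), seed=0)
    assert k == 3
    assert set(diag) == {2, 3, 4, 5, 6}
    assert all(d["wcss"] > 0 for d in diag.values())


def test_select_k_pin_overrides():
    dyn, _ = make_planted_clusters(k_true=2, n_per=10, separation=1.0, seed=5)
    k, _ = select_k(dyn, range(2, 5), seed=0, pin=13)
    assert k == 13


def test_single_blob_low_silhouette():
    dyn, _ = make_planted_clusters(k_true=1, n_per=40, separation=0.0, seed=6)
    _, diag = select_k(dyn, range(2, 5), seed=0)
    assert max(d["silhouette"] for d in diag.values()) < 0.6


def test_too_few_members_rejected():
    dyn, _ = make_planted_clusters(k_true=2, n_per=2, separation=1.0, seed=7)
    with pytest.raises(ValueError):
        cluster(dyn, k=10, seed=0)
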