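"""Trajectory normalization and k-means stratification into representative
virtual patients.

Accepted protocol simulations are resampled onto a fixed 162-point grid (daily
from day -7 through day 150, then days 180, 210, 240, 270), each state scaled
by its own per-simulation maximum, and the flattened 17 x 162 matrices
clustered with k-means.  The cohort member nearest each centroid is that
cluster's representative patient: unlike the centroid itself it carries a
parameter set, so it can be re-simulated (e.g. for the AML screens).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .simulate import Trajectory
from .states import N_STATES


def clustering_grid(chemo_start: float = -7.0, dense_until: float = 150.0,
                    coarse_step: float = 30.0, n_coarse: int = 4) -> np.ndarray:
    """The 162-point normalization grid."""
    dense = np.arange(chemo_start, dense_until + 0.5)
    coarse = dense_until + coarse_step * np.arange(1, n_coarse + 1)
    return np.concatenate([dense, coarse])


@dataclass
class NormalizedDynamics:
    """Per-simulation 17 x T matrices, each state scaled to its own max."""

    run_ids: list[int]
    matrices: np.ndarray       # (n_runs, 17, T)
    grid: np.ndarray

    @property
    def flat(self) -> np.ndarray:
        return self.matrices.reshape(len(self.run_ids), -1)


def normalize_trajectories(trajs: dict[int, Trajectory],
                           grid: np.ndarray | None = None) -> NormalizedDynamics:
    """Resample each trajectory onto the clustering grid and normalize each
    state by its own maximum (identically-zero states stay zero)."""
    grid = clustering_grid() if grid is None else np.asarray(grid, dtype=float)
    run_ids = sorted(trajs)
    mats = np.zeros((len(run_ids), N_STATES, len(grid)))
    for r, rid in enumerate(run_ids):
        tr = trajs[rid]
        if grid[0] < tr.t[0] - 1e-9 or grid[-1] > tr.t[-1] + 1e-9:
            raise ValueError(f"trajectory {rid} does not cover the grid")
        for s in range(N_STATES):
            y = np.interp(grid, tr.t, tr.x[:, s])
            m = y.max()
            mats[r, s] = y / m if m > 0 else 0.0
    return NormalizedDynamics(run_ids=run_ids, matrices=mats, grid=grid)


@dataclass
class ClusterAssignment:
    labels: dict[int, int]            # run id -> 1-based cluster label
    centroids: np.ndarray             # (k, 17*T) in normalized space
    representatives: dict[int, int]   # cluster label -> run id nearest centroid
    k: int
    inertia: float


def cluster(dynamics: NormalizedDynamics, k: int, seed: int,
            n_init: int = 10) -> ClusterAssignment:
    """k-means (k-means++ seeding, best of ``n_init`` restarts) on the
    flattened normalized dynamics; deterministic under a fixed seed."""
    X = dynamics.flat
    if len(X) < k:
        raise ValueError(f"cannot form {k} clusters from {len(X)} runs")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed))
    lab0 = km.fit_predict(X)
    labels = {rid: int(l) + 1 for rid, l in zip(dynamics.run_ids, lab0)}
    reps = {}
    for c in range(k):
        members = np.where(lab0 == c)[0]
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        reps[c + 1] = dynamics.run_ids[members[int(np.argmin(d))]]
    return ClusterAssignment(labels=labels, centroids=km.cluster_centers_,
                             representatives=reps, k=k,
                             inertia=float(km.inertia_))


def select_k(dynamics: NormalizedDynamics, k_range, seed: int,
             n_init: int = 10, pin: int | None = None):
    """Scan ``k_range``, report WCSS and mean silhouette per k, and choose the
    silhouette-maximizing k (or honour a pinned k, e.g. 13).

    Returns ``(chosen_k, diagnostics)`` where diagnostics maps k -> dict with
    ``wcss`` and ``silhouette``.
    """
    X = dynamics.flat
    diagnostics = {}
    best_k, best_sil = None, -np.inf
    for k in k_range:
        if not 2 <= k <= len(X) - 1:
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed))
        lab = km.fit_predict(X)
        sil = float(silhouette_score(X, lab)) if len(set(lab)) > 1 else -1.0
        diagnostics[k] = {"wcss": float(km.inertia_), "silhouette": sil}
        if sil > best_sil:
            best_k, best_sil = k, sil
    if pin is not None:
        return pin, diagnostics
    if best_k is None:
        raise ValueError("no feasible k in range")
    return best_k, diagnostics
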