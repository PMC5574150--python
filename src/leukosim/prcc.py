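"""Partial rank correlation coefficient (PRCC) global sensitivity analysis.

PRCC measures the monotone association between one sampled parameter and a
model output while controlling for the (rank-transformed) influence of all
other sampled parameters: both the parameter and the output are rank
transformed, each is regressed linearly on the ranks of the remaining
parameters, and the Pearson correlation of the two residual series is the
PRCC.  Significance uses the t statistic with n - 2 - (p - 1) degrees of
freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)  # midranks for ties


def prcc(X: np.ndarray, y: np.ndarray,
         names: list[str] | None = None) -> pd.DataFrame:
    """PRCC of each column of ``X`` (n x p) against ``y`` (n).

    Returns a DataFrame with columns prcc, p_value, p_adjusted (Benjamini-
    Hochberg across parameters), n.  Constant columns are flagged undefined
    (NaN) rather than silently computed; duplicated columns make the partial
    regression singular and are likewise flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on sample count")
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 (got n={n}, p={p})")
    names = names or [f"x{j}" for j in range(p)]

    constant = np.array([np.ptp(X[:, j]) == 0 for j in range(p)])
    if np.ptp(y) == 0:
        raise ValueError("output is constant")
    # duplicated columns (identical ranks) are undefined as well
    R = _rank(X)
    ry = _rank(y)
    dup = np.zeros(p, dtype=bool)
    _, first_idx, inv = np.unique(R.T, axis=0, return_index=True, return_inverse=True)
    for g in range(len(first_idx)):
        members = np.where(inv == g)[0]
        if len(members) > 1:
            dup[members] = True

    dof = n - 2 - (p - 1)
    vals = np.full(p, np.nan)
    pvals = np.full(p, np.nan)
    ones = np.ones((n, 1))
    for j in range(p):
        if constant[j] or dup[j]:
            continue
        others = np.c_[ones, np.delete(R, j, axis=1)]
        beta_x, *_ = np.linalg.lstsq(others, R[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, ry, rcond=None)
        res_x = R[:, j] - others @ beta_x
        res_y = ry - others @ beta_y
        denom = np.sqrt((res_x ** 2).sum() * (res_y ** 2).sum())
        if denom == 0:
            continue
        r = float((res_x * res_y).sum() / denom)
        r = min(1.0, max(-1.0, r))
        if abs(r) >= 1.0:
            pv = 0.0
        else:
            tstat = r * np.sqrt(dof / (1.0 - r ** 2))
            pv = float(2.0 * stats.t.sf(abs(tstat), dof))
        vals[j], pvals[j] = r, pv

    finite = np.isfinite(pvals)
    p_adj = np.full(p, np.nan)
    if finite.any():
        p_adj[finite] = stats.false_discovery_control(pvals[finite], method="bh")
    return pd.DataFrame({"parameter": names, "prcc": vals, "p_value": pvals,
                         "p_adjusted": p_adj, "n": n}).set_index("parameter")


def sensitivity_report(cohort: pd.DataFrame, outputs: pd.DataFrame,
                       parameters: list[str] | None = None) -> pd.DataFrame:
    """Ranked PRCC table of sampled parameters against named model outputs.

    ``cohort`` holds one row per simulation with parameter columns; ``outputs``
    holds the output summaries (same index), by default the final homeostatic
    concentrations of stem cells and the three circulating lineages.  Returns a
    long table sorted by |PRCC| within each output.
    """
    if parameters is None:
        from .parameters import SAMPLED_NAMES
        parameters = [c for c in cohort.columns if c in SAMPLED_NAMES]
    X = cohort[parameters].to_numpy()
    frames = []
    for out_name in outputs.columns:
        res = prcc(X, outputs[out_name].to_numpy(), names=list(parameters))
        res = res.assign(output=out_name,
                         rank=(-res["prcc"].abs()).rank(method="first"))
        frames.append(res.reset_index())
    report = pd.concat(frames, ignore_index=True)
    return report.sort_values(["output", "rank"]).reset_index(drop=True)
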