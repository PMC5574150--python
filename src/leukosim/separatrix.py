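"""Separatrix constraints: pairwise log-space boundaries of acceptability.

Accepted parameter sets occupy a wedge of log parameter space (e.g. high
self-renewal demands low mitosis rate, and vice versa).  The separatrix method
captures that wedge cheaply: bound the accepted range of each parameter pair
with a rectangle, grid it 10x10, flag bins holding more accepted sets than a
uniform-density cutoff, and cut away rectangle corners whose bins fall below
the cutoff with one half-plane inequality per corner.  The resulting box +
inequalities filter subsequent Latin Hypercube proposals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

NBINS = 10


@dataclass
class SeparatrixConstraint:
    """Box + corner-cut half-planes for one parameter pair, in log10 space.

    ``inequalities`` are (a, b, c) triples retaining points with
    ``a*log10(x) + b*log10(y) >= c``.
    """

    pair: tuple[str, str]
    box: tuple[tuple[float, float], tuple[float, float]]   # (x_lo,x_hi),(y_lo,y_hi)
    grid: np.ndarray                                       # bool, NBINS x NBINS
    inequalities: list[tuple[float, float, float]]
    cutoff: float

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "box": [list(self.box[0]), list(self.box[1])],
            "grid": self.grid.astype(int).tolist(),
            "inequalities": [list(q) for q in self.inequalities],
            "cutoff": self.cutoff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SeparatrixConstraint":
        return cls(pair=tuple(d["pair"]),
                   box=(tuple(d["box"][0]), tuple(d["box"][1])),
                   grid=np.asarray(d["grid"], dtype=bool),
                   inequalities=[tuple(q) for q in d["inequalities"]],
                   cutoff=float(d["cutoff"]))


def _staircase(unacceptable: np.ndarray) -> np.ndarray:
    """Heights of the maximal corner-anchored staircase of unacceptable bins
    (lower-left convention: ``unacceptable[ix, iy]``, corner at ix=iy=0)."""
    n = unacceptable.shape[0]
    heights = np.zeros(n, dtype=int)
    prev = n
    for ix in range(n):
        col = unacceptable[ix]
        h = 0
        while h < n and col[h]:
            h += 1
        h = min(h, prev)
        if h == 0:
            break
        heights[ix] = h
        prev = h
    return heights


def _corner_inequality(acc_grid: np.ndarray, xedges: np.ndarray,
                       yedges: np.ndarray, corner: tuple[int, int]):
    """One half-plane cutting the given corner (0/1 per axis), or None.

    The staircase's inner step vertices are fit with a least-squares line;
    the line is then translated toward the corner until every vertex lies on
    the retained side, so the removed region never exceeds the staircase bins.
    """
    cx, cy = corner
    sx = 1.0 if cx == 0 else -1.0
    sy = 1.0 if cy == 0 else -1.0
    grid = acc_grid
    ue, ve = xedges.copy(), yedges.copy()
    if cx == 1:
        grid = grid[::-1, :]
        ue = -xedges[::-1]
    if cy == 1:
        grid = grid[:, ::-1]
        ve = -yedges[::-1]
    heights = _staircase(~grid)
    if heights[0] == 0:
        return None
    pts_u, pts_v = [], []
    for ix, h in enumerate(heights):
        if h == 0:
            break
        pts_u.extend([ue[ix], ue[ix + 1]])
        pts_v.extend([ve[h], ve[h]])
    pts_u, pts_v = np.array(pts_u), np.array(pts_v)
    if np.ptp(pts_u) < 1e-12:  # one-column staircase -> vertical cut
        u0 = float(pts_u.max())
        return (sx * 1.0, 0.0, u0) if cy == 0 else (sx * 1.0, 0.0, u0)
    m, _ = np.polyfit(pts_u, pts_v, 1)
    q = float(np.min(pts_v - m * pts_u))
    # retained side: v - m*u >= q  (in corner-local coordinates)
    return (-m * sx, sy, q)


def fit_separatrix(accepted_x: np.ndarray, accepted_y: np.ndarray,
                   pair: tuple[str, str],
                   cutoff_divisor: float = 100.0,
                   min_points_for_cuts: float | None = None) -> SeparatrixConstraint:
    """Fit the box/grid/corner-cut constraint for one parameter pair.

    ``accepted_x``/``accepted_y`` are the raw (linear-scale, positive) values
    of the pair over all accepted parameter sets.
    """
    x = np.log10(np.asarray(accepted_x, dtype=float))
    y = np.log10(np.asarray(accepted_y, dtype=float))
    if len(x) < 2 or len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("need >= 2 distinct accepted points to fit a separatrix")
    box = ((float(x.min()), float(x.max())), (float(y.min()), float(y.max())))
    xedges = np.linspace(*box[0], NBINS + 1)
    yedges = np.linspace(*box[1], NBINS + 1)
    counts, _, _ = np.histogram2d(x, y, bins=[xedges, yedges])
    cutoff = len(x) / cutoff_divisor
    acc_grid = counts > cutoff
    inequalities = []
    gate = cutoff_divisor if min_points_for_cuts is None else min_points_for_cuts
    if len(x) >= gate:  # below this the grid is all-noise: box only
        for corner in ((0, 0), (0, 1), (1, 0), (1, 1)):
            ineq = _corner_inequality(acc_grid, xedges, yedges, corner)
            if ineq is not None:
                inequalities.append(ineq)
    return SeparatrixConstraint(pair=pair, box=box, grid=acc_grid,
                                inequalities=inequalities, cutoff=cutoff)


@dataclass
class RangeConstraint:
    """Accepted range of a single parameter, in log10 space.

    The first stage of the separatrix method: before any corner is cut, every
    sampled parameter is constrained to the range the accepted uni-lineage
    sets actually occupied.
    """

    name: str
    lo: float
    hi: float

    def satisfies(self, point: dict) -> bool:
        if self.name not in point:
            raise KeyError(f"point is missing parameter {self.name!r}")
        lv = np.log10(float(point[self.name]))
        return self.lo - 1e-12 <= lv <= self.hi + 1e-12

    def to_dict(self) -> dict:
        return {"kind": "range", "name": self.name, "lo": self.lo, "hi": self.hi}

    @classmethod
    def from_dict(cls, d: dict) -> "RangeConstraint":
        return cls(name=d["name"], lo=float(d["lo"]), hi=float(d["hi"]))


def fit_ranges(accepted: "pd.DataFrame", names) -> list[RangeConstraint]:
    """Per-parameter accepted ranges (log10) from a cohort's accepted rows."""
    out = []
    for name in names:
        v = np.log10(accepted[name].to_numpy(dtype=float))
        out.append(RangeConstraint(name=name, lo=float(v.min()), hi=float(v.max())))
    return out


def satisfies(constraint: SeparatrixConstraint, point: dict) -> bool:
    """True iff the point lies inside the bounding box and on the retained
    side of every corner-cut inequality (evaluated in log10 space)."""
    px, py = constraint.pair
    if px not in point or py not in point:
        raise KeyError(f"point is missing parameter {px!r} or {py!r}")
    lx, ly = np.log10(float(point[px])), np.log10(float(point[py]))
    (x_lo, x_hi), (y_lo, y_hi) = constraint.box
    tol = 1e-12
    if not (x_lo - tol <= lx <= x_hi + tol and y_lo - tol <= ly <= y_hi + tol):
        return False
    for a, b, c in constraint.inequalities:
        if a * lx + b * ly < c - tol:
            return False
    return True


class ConstraintFilter:
    """Conjunction of separatrix constraints, usable as a proposal filter.

    Tracks its empirical acceptance rate; raises once the rate proves the
    constrained space infeasible (< 0.1% over >= 1e5 proposals).
    """

    def __init__(self, constraints: list[SeparatrixConstraint]):
        self.constraints = list(constraints)
        self.n_seen = 0
        self.n_passed = 0

    def __call__(self, point: dict) -> bool:
        self.n_seen += 1
        ok = all(c.satisfies(point) if isinstance(c, RangeConstraint)
                 else satisfies(c, point) for c in self.constraints)
        self.n_passed += ok
        if self.n_seen >= 100000 and self.acceptance_rate < 1e-3:
            raise RuntimeError(
                f"constraint filter infeasible: rate {self.acceptance_rate:.2e}")
        return ok

    @property
    def acceptance_rate(self) -> float:
        return self.n_passed / self.n_seen if self.n_seen else 1.0


#: The pairwise relationships fitted by default: self-renewal vs mitosis rate
#: for each progenitor type and the stem cells, plus neutrophil self-renewal
#: vs the neutrophil blood feedback constant.
DEFAULT_PAIRS = {
    "N": [("aN2", "mrN2"), ("aHSC", "mrHSC"), ("aN2", "kN")],
    "L": [("aL2", "mrL2"), ("aHSC", "mrHSC")],
    "M": [("aM2", "mrM2"), ("aHSC", "mrHSC")],
}


def fit_cohort_constraints(tables: dict[str, "pd.DataFrame"],
                           pairs: dict[str, list[tuple[str, str]]] | None = None,
                           min_accepted: int = 5,
                           min_pair_accepted: int = 10,
                           all_pairs: bool = False) -> list:
    """Fit constraints from uni-lineage cohort tables (keyed by lineage).

    Two stages per lineage: the accepted range of every sampled parameter
    (the bounding-box stage), then pairwise corner cuts for the configured
    relationships.  Lineages with fewer than ``min_accepted`` accepted rows
    contribute nothing; pairwise fits additionally need
    ``min_pair_accepted`` points.  Stem-cell parameters appear in several
    screens; the conjunction of their per-lineage ranges is their
    intersection.
    """
    from .sampling import unilineage_names

    constraints, seen = [], set()
    pairs = pairs or DEFAULT_PAIRS
    for lineage, table in tables.items():
        acc = table[table["accepted"]]
        if len(acc) < min_accepted:
            continue
        names = [n for n in unilineage_names(lineage) if n in acc.columns]
        constraints.extend(fit_ranges(acc, names))
        if len(acc) < min_pair_accepted:
            continue
        if all_pairs:
            lineage_pairs = [(a, b) for i, a in enumerate(names)
                             for b in names[i + 1:]]
        else:
            lineage_pairs = pairs.get(lineage, [])
        for pair in lineage_pairs:
            if pair in seen:
                continue
            seen.add(pair)
            try:
                constraints.append(fit_separatrix(
                    acc[pair[0]].to_numpy(), acc[pair[1]].to_numpy(), pair,
                    min_points_for_cuts=min_pair_accepted if all_pairs else None))
            except ValueError:
                continue  # degenerate pair (too few distinct values)
    return constraints


def save_constraints(constraints, path) -> None:
    payload = []
    for c in constraints:
        d = c.to_dict()
        if isinstance(c, SeparatrixConstraint):
            d["kind"] = "separatrix"
        payload.append(d)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_constraints(path) -> list:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for d in payload:
        if d.get("kind") == "range":
            out.append(RangeConstraint.from_dict(d))
        else:
            out.append(SeparatrixConstraint.from_dict(d))
    return out
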