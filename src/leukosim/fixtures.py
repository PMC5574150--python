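"""Synthetic inputs: every input the pipeline needs is generated in-repo.

* the calibrated nominal fixture (parameters + equilibrium) that anchors
  sampling bounds and smoke tests;
* pseudo transplant-recovery panels emulating per-patient daily blood counts
  over ~60 days post-chemotherapy (nadir, recovery, occasional bounded
  overshoot, multiplicative lognormal measurement noise) — the clinical data
  the acceptability thresholds were derived from are IRB-protected and are
  emulated, never reproduced;
* labelled point clouds with a known linear log-space boundary (separatrix
  test oracle);
* planted-cluster normalized dynamics (clustering test oracle).

All fixtures regenerate bit-identically from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .calibration import calibrate_nominal
from .clustering import NormalizedDynamics, clustering_grid
from .criteria import CriteriaThresholds, evaluate_acceptability
from .parameters import ModelParameters
from .screening import run_chemo_protocol
from .simulate import find_equilibrium
from .states import IDX, N_STATES


@dataclass
class NominalFixture:
    params: ModelParameters
    equilibrium: np.ndarray
    criteria: dict

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(),
                "equilibrium": self.equilibrium.tolist(),
                "criteria": self.criteria}

    @classmethod
    def from_dict(cls, d: dict) -> "NominalFixture":
        return cls(params=ModelParameters.from_dict(d["params"]),
                   equilibrium=np.asarray(d["equilibrium"], dtype=float),
                   criteria=d["criteria"])


from .calibration import CalibrationError


class CalibrationFailure(CalibrationError):
    pass


def make_nominal_fixture(targets: dict | None = None, choices: dict | None = None,
                         fixed_deaths: dict | None = None,
                         thresholds: CriteriaThresholds | None = None,
                         verify: bool = True) -> NominalFixture:
    """Calibrate the nominal parameter set and verify it against the seven
    acceptability criteria under the default 7-day chemotherapy protocol."""
    params, x0 = calibrate_nominal(targets, choices, fixed_deaths)
    eq = find_equilibrium(params, x0)
    if eq.tag != "nontrivial":
        raise CalibrationFailure(
            f"calibrated parameters yield a {eq.tag} equilibrium "
            f"(residual={eq.residual!r})")
    report = {"equilibrium_residual": eq.residual}
    if verify:
        traj = run_chemo_protocol(params, eq.x)
        rep = evaluate_acceptability(traj, thresholds)
        report.update(rep.as_dict())
        report["stem_equilibrium"] = float(eq.x[IDX["HSC"]])
        if not rep.overall:
            failed = [k for k, v in rep.as_dict().items() if not v]
            raise CalibrationFailure(
                f"nominal fixture fails criteria {failed}; "
                f"diagnostics: {rep.diagnostics}")
    return NominalFixture(params=params, equilibrium=eq.x, criteria=report)


def save_fixture(fix: NominalFixture, path) -> None:
    with open(path, "w") as fh:
        json.dump(fix.to_dict(), fh, indent=1)


def load_fixture(path=None) -> NominalFixture:
    """Load a fixture JSON; with no path, the versioned fixture shipped with
    the package."""
    if path is None:
        ref = resources.files("leukosim").joinpath("data/nominal_fixture.json")
        with ref.open() as fh:
            return NominalFixture.from_dict(json.load(fh))
    with open(path) as fh:
        return NominalFixture.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# pseudo transplant-recovery panel
# ---------------------------------------------------------------------------

PANEL_STATES = {"neutrophils": "N_pb", "lymphocytes": "L3_pb",
                "monocytes": "M_pb"}


def make_pseudo_hsct_panel(n_patients: int, overshoot_fraction: float,
                           noise_cv: float, seed: int,
                           cohort: list[tuple[ModelParameters, np.ndarray]] | None = None,
                           days: int = 60,
                           overshoot_cap: float = 12.0) -> pd.DataFrame:
    """Per-patient daily absolute counts for ~``days`` days post-chemotherapy.

    Patients are simulated through the standard protocol (accepted parameter
    sets if provided, else the nominal fixture), subsampled daily, and given
    multiplicative lognormal noise with coefficient of variation ``noise_cv``.
    A Bernoulli(``overshoot_fraction``) subset receives a transient neutrophil
    recovery overshoot, always bounded so that the peak stays below
    ``overshoot_cap`` times the value five days later.
    """
    if not 0.0 <= overshoot_fraction <= 1.0:
        raise ValueError("overshoot_fraction must be in [0, 1]")
    if cohort is None:
        fix = make_nominal_fixture(verify=False)
        cohort = [(fix.params, fix.equilibrium)]
    rng = np.random.default_rng(seed)
    t_days = np.arange(0.0, days + 0.5)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    rows = []
    for pat in range(n_patients):
        params, eq = cohort[pat % len(cohort)]
        traj = run_chemo_protocol(params, eq)
        overshoot = bool(rng.random() < overshoot_fraction)
        bump_peak = rng.uniform(15.0, 35.0)      # day of the synthetic peak
        bump_amp = rng.uniform(1.5, overshoot_cap * 0.5)
        for label, state in PANEL_STATES.items():
            y = np.interp(t_days, traj.t, traj.x[:, IDX[state]])
            if overshoot and label == "neutrophils":
                bump = 1.0 + (bump_amp - 1.0) * np.exp(
                    -0.5 * ((t_days - bump_peak) / 4.0) ** 2)
                y = y * bump
            if noise_cv > 0:
                y = y * rng.lognormal(-0.5 * sigma ** 2, sigma, size=len(y))
            for d, v in zip(t_days, y):
                rows.append({"patient": pat, "day": float(d), "lineage": label,
                             "count": float(v), "overshoot": overshoot,
                             "noise_cv": noise_cv})
    return pd.DataFrame(rows)


def panel_overshoot_ratio(panel: pd.DataFrame, lineage: str = "neutrophils") -> pd.Series:
    """Peak post-recovery count over the count five days later, per patient."""
    out = {}
    for pat, g in panel[panel["lineage"] == lineage].groupby("patient"):
        g = g.sort_values("day")
        y = g["count"].to_numpy()
        d = g["day"].to_numpy()
        i = int(np.argmax(y))
        ref_day = d[i] + 5.0
        ref = y[-1] if ref_day >= d[-1] else float(np.interp(ref_day, d, y))
        out[pat] = y[i] / ref if ref > 0 else np.inf
    return pd.Series(out, name="overshoot_ratio")


# ---------------------------------------------------------------------------
# separatrix oracle
# ---------------------------------------------------------------------------

def make_separatrix_oracle(slope: float, intercept: float, n: int, seed: int,
                           box=((0.0, 2.0), (0.0, 2.0)),
                           flip: bool = False):
    """Uniform points in a log10 box labelled by a known linear boundary.

    Acceptable iff ``log10(y) < slope * log10(x) + intercept`` (reversed with
    ``flip``).  Returns ``(DataFrame[x, y, accepted], truth)`` with the raw
    (linear-scale) coordinates and the ground-truth boundary.
    """
    (x_lo, x_hi), (y_lo, y_hi) = box
    rng = np.random.default_rng(seed)
    lx = rng.uniform(x_lo, x_hi, n)
    ly = rng.uniform(y_lo, y_hi, n)
    acc = ly < slope * lx + intercept
    if flip:
        acc = ~acc
    df = pd.DataFrame({"x": 10.0 ** lx, "y": 10.0 ** ly, "accepted": acc})
    truth = {"slope": slope, "intercept": intercept, "box": box, "flip": flip}
    return df, truth


# ---------------------------------------------------------------------------
# planted clusters
# ---------------------------------------------------------------------------

def make_planted_clusters(k_true: int, n_per: int, separation: float,
                          seed: int, noise: float = 0.05):
    """Normalized-dynamics set with ``k_true`` planted families.

    Each family is a smooth random recovery-like template; members are the
    template plus bounded noise.  ``separation`` scales how far the templates
    sit from their common mean, so 0 makes all families identical (chance-level
    recovery) and large values make them trivially separable.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    grid = clustering_grid()
    T = len(grid)
    base = 1.0 / (1.0 + np.exp(-(grid[None, :] - 20.0) / 10.0)) * np.ones((N_STATES, 1))
    templates = []
    for _ in range(k_true):
        shift = rng.uniform(-30, 30, size=(N_STATES, 1))
        scale = rng.uniform(5, 20, size=(N_STATES, 1))
        tpl = 1.0 / (1.0 + np.exp(-(grid[None, :] - 20.0 - shift) / scale))
        templates.append(base + separation * (tpl - base))
    mats = np.zeros((k_true * n_per, N_STATES, T))
    labels = np.zeros(k_true * n_per, dtype=int)
    for k, tpl in enumerate(templates):
        for j in range(n_per):
            i = k * n_per + j
            mats[i] = np.clip(tpl + rng.uniform(-noise, noise, tpl.shape), 0, 1)
            labels[i] = k
    dyn = NormalizedDynamics(run_ids=list(range(len(mats))), matrices=mats,
                             grid=grid)
    return dyn, labels
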