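"""Latin Hypercube sampling of the uncertain parameter space.

Rates are sampled in log space between 1/5 and 5 times their nominal values;
self-renewal fractions are sampled linearly on [0.5, 1] and the stem-cell
lineage split fractions linearly around their nominals (renormalized to sum to
one when a parameter set is assembled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .parameters import (FRACTION_NAMES, ModelParameters, SAMPLED_NAMES,
                         SELF_RENEWAL_NAMES)

STEM_CORE = ("aHSC", "mrHSC", "sHSC", "dHSC", "kHSC", "kBM")
SPLITS = ("fN", "fL", "fM")
LINEAGE_BLOCKS = {
    "N": ("aN2", "mrN2", "sN2", "kN", "mbN", "mgN", "dmN", "kNmp", "rN", "kNbm"),
    "L": ("aL2", "mrL2", "sL2", "kL", "mbL", "rL", "kLt"),
    "M": ("aM2", "mrM2", "sM2", "kM", "mbM", "mgM", "dmM", "kMmp", "rM", "kMbm"),
}
MACRO_BLOCK = ("actM", "kA", "mrMAC", "clA", "clAM", "kMAC")
CHEMO_BLOCK = ("chKill", "chElim")


@dataclass
class SamplingBounds:
    """Per-parameter (lower, upper, scale) with scale in {"log", "linear"}."""

    bounds: dict[str, tuple[float, float, str]]

    def __post_init__(self) -> None:
        for name, (lo, hi, scale) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name}: lower {lo} !< upper {hi}")
            if scale == "log" and lo <= 0:
                raise ValueError(f"log-scale bounds for {name} need lower > 0")
            if scale not in ("log", "linear"):
                raise ValueError(f"unknown scale {scale!r} for {name}")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def subset(self, names) -> "SamplingBounds":
        return SamplingBounds({n: self.bounds[n] for n in names})


def default_bounds(nominal: ModelParameters, factor: float = 5.0,
                   names=SAMPLED_NAMES) -> SamplingBounds:
    """Nominal/factor .. nominal*factor in log space for rates; [0.5, 1] for
    self-renewal fractions; clipped linear bands for split fractions."""
    bounds = {}
    for name in names:
        nom = getattr(nominal, name)
        if name in SELF_RENEWAL_NAMES:
            bounds[name] = (0.5, 1.0, "linear")
        elif name in FRACTION_NAMES:  # split fractions
            bounds[name] = (max(nom / factor, 1e-3),
                            min(nom * factor, 1.0), "linear")
        else:
            bounds[name] = (nom / factor, nom * factor, "log")
    return SamplingBounds(bounds)


def unilineage_names(lineage: str) -> tuple[str, ...]:
    """Parameters sampled in a uni-lineage screen: the focal lineage block,
    the stem-cell core, and the chemotherapy pharmacodynamics."""
    if lineage not in LINEAGE_BLOCKS:
        raise ValueError(f"unknown lineage {lineage!r}")
    return STEM_CORE + LINEAGE_BLOCKS[lineage] + CHEMO_BLOCK


def lhs_sample(bounds: SamplingBounds, n: int, seed: int) -> pd.DataFrame:
    """``n`` Latin Hypercube parameter vectors, one column per bounded name.

    Each marginal is stratified: exactly one point per equal-probability
    stratum, on the declared scale.  Reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = bounds.names
    sampler = qmc.LatinHypercube(d=len(names), seed=int(seed))
    u = sampler.random(n)
    cols = {}
    for j, name in enumerate(names):
        lo, hi, scale = bounds.bounds[name]
        if scale == "log":
            cols[name] = np.exp(np.log(lo) + u[:, j] * (np.log(hi) - np.log(lo)))
        else:
            cols[name] = lo + u[:, j] * (hi - lo)
    return pd.DataFrame(cols)


def params_from_sample(base: ModelParameters, row: dict) -> ModelParameters:
    """Assemble a full parameter set from a sampled row over the nominal base.

    Split fractions are renormalized to sum to one; the cancer baseline is
    re-derived from the (possibly sampled) monocyte values.
    """
    updates = {k: float(v) for k, v in row.items()}
    fs = {k: updates.get(k, getattr(base, k)) for k in SPLITS}
    tot = sum(fs.values())
    for k in SPLITS:
        updates[k] = fs[k] / tot
    return base.with_updates(**updates)
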