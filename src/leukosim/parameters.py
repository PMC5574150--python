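"""Named parameters of the leukopoiesis model.

51 named scalar parameters govern healthy hematopoiesis: 7 death rates fixed
from literature and 44 uncertain parameters that are sampled when building
virtual cohorts.  The bone-marrow capacity constant (a structural geometric
ceiling) and the four cancer parameters (equal to their monocyte counterparts
in the healthy baseline) sit alongside them in :class:`ModelParameters` but are
not part of the 51-parameter count.

Naming convention: ``a*`` self-renewal fractions (dimensionless), ``mr*``
mitosis rates (1/day), ``s*`` differentiation rates (1/day), ``mb*``
mobilization bone-marrow->blood (1/day), ``mg*``/``dm*`` margination and
demargination (1/day), ``r*`` recruitment blood->tissue (1/day), ``d*`` death
rates (1/day), ``k*`` Michaelis-Menten feedback constants (cells/uL), ``f*``
stem-cell lineage split fractions (dimensionless, sum to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

# --- literature-fixed death rates (1/day) -----------------------------------
FIXED_NAMES: tuple[str, ...] = (
    "dP2",    # progenitor death (N2, L2, M2)
    "dNm",    # mature neutrophil death (all compartments)
    "dL3",    # maturing lymphocyte loss (thymic selection)
    "dL3pb",  # circulating lymphocyte death
    "dMbm",   # mature monocyte death, bone marrow
    "dMpb",   # mature monocyte death, blood + marginal pool
    "dMAC",   # activated macrophage death
)

# --- 44 sampled parameters ---------------------------------------------------
SAMPLED_NAMES: tuple[str, ...] = (
    # stem-cell block
    "aHSC", "mrHSC", "sHSC", "dHSC", "fN", "fL", "fM", "kHSC", "kBM",
    # neutrophil lineage
    "aN2", "mrN2", "sN2", "kN", "mbN", "mgN", "dmN", "kNmp", "rN", "kNbm",
    # lymphocyte lineage
    "aL2", "mrL2", "sL2", "kL", "mbL", "rL", "kLt",
    # monocyte lineage
    "aM2", "mrM2", "sM2", "kM", "mbM", "mgM", "dmM", "kMmp", "rM", "kMbm",
    # macrophage / debris block
    "actM", "kA", "mrMAC", "clA", "clAM", "kMAC",
    # chemotherapy pharmacodynamics
    "chKill", "chElim",
)

PARAM_NAMES: tuple[str, ...] = FIXED_NAMES + SAMPLED_NAMES
N_PARAMS = len(PARAM_NAMES)          # 51
N_FIXED = len(FIXED_NAMES)           # 7
N_SAMPLED = len(SAMPLED_NAMES)       # 44

# Parameters sampled on a linear scale (fractions); all rates sample in log space.
FRACTION_NAMES: tuple[str, ...] = ("aHSC", "aN2", "aL2", "aM2", "fN", "fL", "fM")
SELF_RENEWAL_NAMES: tuple[str, ...] = ("aHSC", "aN2", "aL2", "aM2")


@dataclass
class CancerParameters:
    """The four parameters that mediate AML; baseline equals monocyte values.

    ``sMc`` (cancer progenitor differentiation) is carried along for the model
    equations but is not one of the four screened parameters: it stays pinned
    to the monocyte value ``sM2``.
    """

    dMc: float     # death rate of all cancer states (1/day)
    aMc2: float    # self-renewal fraction of cancer progenitors
    mrMc2: float   # mitosis rate of cancer progenitors (1/day)
    mbMc: float    # mobilization of mature cancer into blood (1/day)
    sMc: float     # differentiation rate, pinned to sM2 (1/day)

    SCREENED: tuple[str, ...] = ("dMc", "aMc2", "mrMc2", "mbMc")

    def validate(self) -> None:
        for name in self.SCREENED + ("sMc",):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"cancer parameter {name}={v} must be >= 0")
        if self.aMc2 > 1:
            raise ValueError(f"aMc2={self.aMc2} exceeds 1")

    def to_array(self) -> np.ndarray:
        return np.array([self.dMc, self.aMc2, self.mrMc2, self.mbMc, self.sMc])


@dataclass
class ChemoSchedule:
    """One-compartment chemotherapy pharmacokinetics.

    Constant-rate infusion over ``[start, end]`` (default day -7 to day 0, the
    7-day induction course) with first-order elimination.  ``kill_states``
    lists the states subject to the log-kill term; ``None`` selects the default
    mask (everything except macrophages and debris).
    """

    start: float = -7.0
    end: float = 0.0
    infusion: float = 1.0          # drug units/day
    elimination: float | None = None   # 1/day; None -> ModelParameters.chElim
    kill_states: tuple[str, ...] | None = None

    def validate(self) -> None:
        if not self.end > self.start:
            raise ValueError("chemo schedule requires end > start")

    @classmethod
    def none(cls) -> "ChemoSchedule":
        """A schedule that delivers no drug."""
        return cls(start=0.0, end=1.0, infusion=0.0)


def _params_dataclass():
    # Build the dataclass fields programmatically so the name list stays the
    # single source of truth.
    return [(name, float) for name in PARAM_NAMES]


@dataclass
class ModelParameters:
    """All 51 named parameters plus capacity and cancer blocks."""

    # 7 literature-fixed death rates
    dP2: float
    dNm: float
    dL3: float
    dL3pb: float
    dMbm: float
    dMpb: float
    dMAC: float
    # stem block
    aHSC: float
    mrHSC: float
    sHSC: float
    dHSC: float
    fN: float
    fL: float
    fM: float
    kHSC: float
    kBM: float
    # neutrophil lineage
    aN2: float
    mrN2: float
    sN2: float
    kN: float
    mbN: float
    mgN: float
    dmN: float
    kNmp: float
    rN: float
    kNbm: float
    # lymphocyte lineage
    aL2: float
    mrL2: float
    sL2: float
    kL: float
    mbL: float
    rL: float
    kLt: float
    # monocyte lineage
    aM2: float
    mrM2: float
    sM2: float
    kM: float
    mbM: float
    mgM: float
    dmM: float
    kMmp: float
    rM: float
    kMbm: float
    # macrophage / debris
    actM: float
    kA: float
    mrMAC: float
    clA: float
    clAM: float
    kMAC: float
    # chemotherapy pharmacodynamics
    chKill: float
    chElim: float
    # structural constant: theoretical maximal bone-marrow density (cells/uL)
    capacity: float = 3.0e5
    cancer: CancerParameters | None = None

    def __post_init__(self) -> None:
        if self.cancer is None:
            self.cancer = self.monocyte_cancer_baseline()

    def monocyte_cancer_baseline(self) -> CancerParameters:
        """Cancer parameters assumed equal to healthy monocyte values."""
        return CancerParameters(dMc=self.dMbm, aMc2=self.aM2,
                                mrMc2=self.mrM2, mbMc=self.mbM, sMc=self.sM2)

    def neutrophil_cancer_baseline(self) -> CancerParameters:
        """Cancer analog mirrored off the neutrophil progenitor lineage."""
        return CancerParameters(dMc=self.dNm, aMc2=self.aN2,
                                mrMc2=self.mrN2, mbMc=self.mbN, sMc=self.sN2)

    # -- serialization ---------------------------------------------------
    def named_values(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def to_dict(self) -> dict:
        d = self.named_values()
        d["capacity"] = float(self.capacity)
        d["cancer"] = {k: float(getattr(self.cancer, k))
                       for k in ("dMc", "aMc2", "mrMc2", "mbMc", "sMc")}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        kwargs = {name: float(d[name]) for name in PARAM_NAMES}
        kwargs["capacity"] = float(d.get("capacity", 3.0e5))
        cancer = d.get("cancer")
        if cancer is not None:
            cancer = CancerParameters(**{k: float(v) for k, v in cancer.items()})
        return cls(cancer=cancer, **kwargs)

    def with_updates(self, **updates) -> "ModelParameters":
        """A copy with named parameters replaced; cancer baseline re-derived
        from the (possibly updated) monocyte values unless explicitly given."""
        cancer = updates.pop("cancer", None)
        out = replace(self, **updates)
        out.cancer = cancer if cancer is not None else out.monocyte_cancer_baseline()
        return out

    def validate(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name}={v} must be finite and >= 0")
        for name in SELF_RENEWAL_NAMES:
            v = getattr(self, name)
            if not (0.5 <= v <= 1.0):
                raise ValueError(f"self-renewal fraction {name}={v} outside [0.5, 1]")
        for name in PARAM_NAMES:
            if name.startswith("k") and getattr(self, name) <= 0:
                raise ValueError(f"Michaelis constant {name} must be > 0")
        splits = self.fN + self.fL + self.fM
        if abs(splits - 1.0) > 1e-9:
            raise ValueError(f"lineage split fractions sum to {splits}, expected 1")
        if self.capacity <= 0:
            raise ValueError("bone-marrow capacity must be > 0")
        self.cancer.validate()

    # -- packed vector for the compiled RHS ------------------------------
    def to_vector(self) -> np.ndarray:
        """51 named parameters + capacity + 5 cancer values, in a fixed order."""
        vec = np.empty(N_PARAMS + 1 + 5)
        for i, name in enumerate(PARAM_NAMES):
            vec[i] = getattr(self, name)
        vec[N_PARAMS] = self.capacity
        vec[N_PARAMS + 1:] = self.cancer.to_array()
        return vec


PVEC_CAPACITY = N_PARAMS          # index of capacity in the packed vector
PVEC_CANCER = N_PARAMS + 1        # start of [dMc, aMc2, mrMc2, mbMc, sMc]
PVEC_LEN = N_PARAMS + 6

PARAM_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}
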