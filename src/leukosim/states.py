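"""State-vector layout of the multi-lineage multi-compartment leukopoiesis model.

The model tracks 17 cell concentrations (cells/uL).  Three maturation stages
(stem -> progenitor -> mature) for each of the neutrophil (N), lymphocyte (L)
and monocyte (M) lineages, with mature myeloid cells split over bone marrow,
circulating peripheral blood, and a non-circulating marginal pool.  Lymphocytes
mature in tissue/thymus and carry no marginal pool.  Two inflammation states
(activated macrophages, apoptotic debris) close the post-chemotherapy clearance
loop, and three cancer states mirror the monocyte lineage with all homeostatic
feedback removed.
"""

from __future__ import annotations

import numpy as np

STATE_NAMES: tuple[str, ...] = (
    "HSC",     # 0  hematopoietic stem cells (bone marrow)
    "N2",      # 1  neutrophil progenitors (bone marrow)
    "N_bm",    # 2  mature neutrophils, bone marrow reserve
    "N_pb",    # 3  circulating neutrophils
    "N_mp",    # 4  marginal-pool neutrophils
    "L2",      # 5  lymphoid progenitors (bone marrow)
    "L3",      # 6  maturing lymphocytes, tissue/thymus
    "L3_pb",   # 7  circulating lymphocytes
    "M2",      # 8  monocyte progenitors (bone marrow)
    "M_bm",    # 9  mature monocytes, bone marrow
    "M_pb",    # 10 circulating monocytes
    "M_mp",    # 11 marginal-pool monocytes
    "MAC",     # 12 activated macrophages (tissue/bone marrow)
    "A",       # 13 apoptotic debris awaiting clearance
    "Mc2",     # 14 cancer progenitors (bone marrow)
    "Mc_bm",   # 15 mature cancer cells, bone marrow
    "Mc_pb",   # 16 circulating cancer cells
)

N_STATES = len(STATE_NAMES)

IDX = {name: i for i, name in enumerate(STATE_NAMES)}

# Compartment membership (used for crowding feedback and criteria).
PB_STATES = ("N_pb", "L3_pb", "M_pb", "Mc_pb")          # circulating blood
MARGINAL_STATES = ("N_mp", "M_mp")                      # marginal pool
BM_STATES = ("HSC", "N2", "N_bm", "L2", "M2", "M_bm",
             "MAC", "A", "Mc2", "Mc_bm")                # bone marrow
CANCER_STATES = ("Mc2", "Mc_bm", "Mc_pb")
HEALTHY_PB_STATES = ("N_pb", "L3_pb", "M_pb")

PB_IDX = np.array([IDX[s] for s in PB_STATES])
BM_IDX = np.array([IDX[s] for s in BM_STATES])
CANCER_IDX = np.array([IDX[s] for s in CANCER_STATES])
HEALTHY_PB_IDX = np.array([IDX[s] for s in HEALTHY_PB_STATES])

# Chemotherapy kill mask: every stem, progenitor and mature cell in all
# compartments; macrophages and debris are exempt (they are the clearance
# machinery, not a proliferating target).  Configurable at run time.
DEFAULT_KILL_STATES = tuple(s for s in STATE_NAMES if s not in ("MAC", "A"))


def default_kill_mask() -> np.ndarray:
    """Boolean mask (as float64, for the compiled RHS) of chemo-sensitive states."""
    mask = np.zeros(N_STATES)
    for s in DEFAULT_KILL_STATES:
        mask[IDX[s]] = 1.0
    return mask


def zeros() -> np.ndarray:
    return np.zeros(N_STATES)


def as_series(x: np.ndarray) -> dict[str, float]:
    return {name: float(x[i]) for i, name in enumerate(STATE_NAMES)}
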