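"""Run configuration: every threshold, bound, size and seed in one place.

The configuration round-trips losslessly through YAML/JSON, and its canonical
hash stamps every artifact a pipeline run writes, so a results bundle can be
traced back to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .criteria import CriteriaThresholds


@dataclass
class RunConfig:
    # calibration (None -> package defaults in calibration.py)
    calibration_targets: dict = field(default_factory=dict)
    calibration_choices: dict = field(default_factory=dict)
    fixed_deaths: dict = field(default_factory=dict)

    # sampling
    bounds_factor: float = 5.0
    n_unilineage: int = 1000
    n_multilineage: int = 1000

    # chemotherapy protocol
    chemo_start: float = -7.0
    chemo_end: float = 0.0
    chemo_infusion: float = 1.0

    # acceptability thresholds (Table-1 values)
    pb_recovery_min: float = 80.0
    stem_band: tuple = (1.0, 100.0)
    depletion_frac: float = 0.20
    overshoot_max: float = 12.0
    osc_tol: float = 0.18
    osc_form: str = "damped"
    marginal_log_tol: float = 1.0
    clinical_ranges: dict = field(default_factory=dict)

    # clustering
    k_clusters: int = 13
    k_range: tuple = (2, 16)
    pin_k: bool = True
    kmeans_n_init: int = 10

    # cancer screen (Table-2 settings)
    n_cancer_per_rep: int = 625
    cancer_mr_upper_mult: float = 30.0
    cancer_seed_concentration: float = 2e-4
    blast_diagnosis_fraction: float = 0.20
    death_threshold: float = 3.0e5
    cancer_horizon: float = 550.0
    diagnosis_window: float = 365.0
    correlation_method: str = "spearman"

    # separatrix
    separatrix_min_accepted: int = 5

    seed: int = 0

    def thresholds(self) -> CriteriaThresholds:
        kw = {}
        if self.clinical_ranges:
            kw["clinical_ranges"] = {k: tuple(v)
                                     for k, v in self.clinical_ranges.items()}
        return CriteriaThresholds(
            pb_recovery_min=self.pb_recovery_min,
            stem_band=tuple(self.stem_band),
            depletion_frac=self.depletion_frac,
            overshoot_max=self.overshoot_max,
            osc_tol=self.osc_tol, osc_form=self.osc_form,
            marginal_log_tol=self.marginal_log_tol, **kw)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        # canonical JSON-compatible form (tuples become lists) so that a
        # config and its serialized round-trip hash identically
        return json.loads(json.dumps(asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("stem_band", "k_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
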