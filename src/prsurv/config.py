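"""Pipeline configuration.

All analysis thresholds live here with their canonical defaults: the
fine-mapping prior (W=0.04, 99% credible level, 5e-8 significance, ±500 kb
windows), QC cutoffs (GQ 20, missingness 0.1, allele balance [0.3, 0.7],
HWE 5e-8), the TSH abnormality rule (>5 mU/L, 7-day precedence window), the
150-day landmark, and the cross-validation shapes (3 folds x 100 repeats
for the lasso penalty, 4 folds for predictor evaluation). A run writes its
resolved configuration next to its outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig"]

_ALL_STAGES = ["simulate", "gwas", "ld", "finemap", "score",
               "survival", "lasso", "evaluate"]

_DEPENDS = {
    "gwas": ["simulate"],
    "ld": ["simulate"],
    "finemap": ["gwas", "ld"],
    "score": ["finemap"],
    "survival": ["score", "simulate"],
    "lasso": ["survival"],
    "evaluate": ["survival"],
}


@dataclass
class PipelineConfig:
    seed: int = 1
    stages: list[str] = field(default_factory=lambda: list(_ALL_STAGES))

    # fine-mapping
    prior_W: float = 0.04
    credible_level: float = 0.99
    significance: float = 5e-8
    window_bp: int = 500_000

    # QC
    gq_min: int = 20
    missingness_max: float = 0.1
    balance_low: float = 0.3
    balance_high: float = 0.7
    hwe_p_min: float = 5e-8

    # lab events
    tsh_threshold: float = 5.0
    precedence_window_days: int = 7
    ordering_prob: float = 0.857

    # survival
    landmark_days: float = 150.0

    # cross validation
    lasso_folds: int = 3
    lasso_repeats: int = 100
    eval_folds: int = 4

    # synthetic problem sizes
    n_cases: int = 2000
    n_controls: int = 2000
    n_haplotypes: int = 4000
    n_trial_patients: int = 1200
    n_trial_arms: int = 6
    prs_hr: float = 1.52
    irae_os_hr: float = 0.57

    def validate(self) -> None:
        order = {s: i for i, s in enumerate(_ALL_STAGES)}
        enabled = set(self.stages)
        unknown = enabled - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in enabled:
            for dep in _DEPENDS.get(s, []):
                if dep not in enabled:
                    raise ValueError(
                        f"stage {s!r} requires artifact of disabled stage {dep!r}"
                    )
        self.stages = sorted(enabled, key=order.get)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
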