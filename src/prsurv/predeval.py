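"""Evaluating the PRS as a pre-treatment predictor.

Precision/recall (PPV/sensitivity) over score thresholds, cross-validated
standardized effect size between cases and controls, analytic power for a
two-sample mean difference under the normal approximation, and hazard-ratio
contrasts between composite risk subgroups (e.g. female, above-median PRS
and above-median baseline TSH vs male, below-median both).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .coxph import CoxData, CoxFit, cox_fit
from .rng import substream

__all__ = [
    "PrecisionRecallCurve",
    "ppv_sensitivity_curve",
    "cv_effect_size",
    "power_two_sample",
    "combined_subgroup_hr",
]


@dataclass
class PrecisionRecallCurve:
    """PPV and sensitivity across score thresholds.

    ``ppv`` is NaN where no sample is predicted positive (an explicit
    undefined marker, not 0 or 1).
    """

    thresholds: np.ndarray
    ppv: np.ndarray
    sensitivity: np.ndarray
    prevalence: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "ppv": self.ppv,
            "sensitivity": self.sensitivity,
        })


def ppv_sensitivity_curve(
    scores: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> PrecisionRecallCurve:
    """Threshold sweep of PPV (precision) and sensitivity (recall).

    Predicted-positive means score >= threshold (closed rule). Default
    thresholds are the sorted unique scores plus one below the minimum
    (all-positive: sensitivity 1, PPV = prevalence) and one above the
    maximum (empty-positive: sensitivity 0, PPV undefined).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    classes = set(np.unique(labels))
    if classes != {0, 1}:
        raise ValueError("labels must contain both classes")
    if thresholds is None:
        u = np.unique(scores)
        thresholds = np.r_[u[0] - 1.0, u, u[-1] + 1.0]
    thresholds = np.asarray(thresholds, float)
    n_pos = labels.sum()
    ppv = np.full(len(thresholds), np.nan)
    sens = np.zeros(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        if pred.sum() > 0:
            ppv[i] = tp / pred.sum()
        sens[i] = tp / n_pos
    return PrecisionRecallCurve(thresholds=thresholds, ppv=ppv,
                                sensitivity=sens,
                                prevalence=float(labels.mean()))


def cv_effect_size(
    scores: np.ndarray,
    labels: np.ndarray,
    k: int = 4,
    seed: int = 0,
    trainer: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> float:
    """Cross-validated standardized case/control difference in the score.

    Per test fold: |mean(cases) - mean(controls)| / SD(all scores in the
    fold); the estimate is the average over folds. Folds are stratified by
    label so every test fold contains both classes. When ``trainer`` is
    supplied it re-derives test-fold scores from the training fold
    (signature: (train_idx, test_idx) -> test scores).
    """
    labels = np.asarray(labels, int)
    rng = substream(seed, "cv-effect")
    folds = np.empty(len(labels), int)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    effects = []
    for f in range(k):
        test = folds == f
        if trainer is not None:
            s = np.asarray(trainer(np.flatnonzero(~test), np.flatnonzero(test)), float)
        else:
            s = np.asarray(scores, float)[test]
        y = labels[test]
        sd = s.std(ddof=1)
        if sd == 0:
            effects.append(0.0)
            continue
        effects.append(abs(s[y == 1].mean() - s[y == 0].mean()) / sd)
    return float(np.mean(effects))


def power_two_sample(
    d: float,
    n1: int,
    n2: int,
    alpha: float,
    two_sided: bool = True,
) -> float:
    """Normal-approximation power for a standardized mean difference ``d``.

    power = Phi(d/s - z) + Phi(-d/s - z) with s = sqrt(1/n1 + 1/n2) and
    z the (1 - alpha/2) normal quantile (or 1 - alpha when one-sided).
    At d = 0 this reduces to alpha.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0,1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 per group")
    if d < 0:
        raise ValueError("d must be non-negative")
    s = np.sqrt(1.0 / n1 + 1.0 / n2)
    zcrit = norm.ppf(1.0 - alpha / 2.0) if two_sided else norm.ppf(1.0 - alpha)
    power = norm.cdf(d / s - zcrit)
    if two_sided:
        power += norm.cdf(-d / s - zcrit)
    return float(power)


def combined_subgroup_hr(
    df: pd.DataFrame,
    time: str = "hypo_time",
    status: str = "hypo_event",
    score: str = "prs",
    tsh: str = "tsh",
    gender: str = "gender",
    arm: str | None = "arm",
) -> CoxFit:
    """Hazard ratio of the all-high vs all-low composite risk subgroup.

    Factors: above/below-median score, above/below-median baseline TSH
    (medians over the full supplied cohort) and gender (1 = female). The
    Cox fit is restricted to the two composite subgroups with an all-high
    indicator; other patients do not contribute.
    """
    med_s = df[score].median()
    med_t = df[tsh].median()
    hi = (df[score] > med_s) & (df[tsh] > med_t) & (df[gender] == 1)
    lo = (df[score] <= med_s) & (df[tsh] <= med_t) & (df[gender] == 0)
    for mask, label in ((hi, "all-high (female, PRS>median, TSH>median)"),
                        (lo, "all-low (male, PRS<=median, TSH<=median)")):
        if mask.sum() == 0:
            raise ValueError(f"empty composite subgroup: {label}")
    sub = df[hi | lo].copy()
    sub["all_high"] = hi[hi | lo].astype(int)
    sub = sub.assign(tstart=0.0)
    data = CoxData.from_frame(sub, ["all_high"], stop=time, status=status,
                              strata=arm if arm is not None else None)
    return cox_fit(data)
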