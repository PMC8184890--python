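"""Survival machinery for irAE analyses.

Covers the time-dependent-covariate construction that guards against
immortal-time bias (the covariate is 0 before irAE onset and 1 after, so a
patient contributes unexposed person-time until the event), stratified Cox
fits with one baseline hazard per trial arm, across-arm meta-analysis
(stratified fixed-effect plus DerSimonian-Laird random-effects pooling of
per-arm estimates), landmark analysis, Kaplan-Meier curves, the baseline
hormone model, and derivation of thyroid events from longitudinal TSH labs
(abnormal = TSH strictly above 5 mU/L).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from statsmodels.stats.meta_analysis import combine_effects

from .coxph import CoxData, CoxFit, cox_fit
from .prscore import normal_scores
from .synthpop import LabSeries, TrialPatient

log = logging.getLogger(__name__)

__all__ = [
    "build_intervals",
    "interval_frame",
    "patients_to_frame",
    "cox_fit",
    "MetaResult",
    "meta_hr",
    "landmark_analysis",
    "km_cuminc",
    "plot_km",
    "hormone_model",
    "ThyroidEvents",
    "derive_thyroid_events",
]

EV_NAMES = [f"ev{i + 1}" for i in range(5)]


def patients_to_frame(patients: list[TrialPatient]) -> pd.DataFrame:
    """Flatten trial patients into the analysis phenotype table."""
    rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id, "arm": p.arm, "active": p.active,
            "gender": p.gender, "prs_raw": p.prs_raw, "prs": p.prs,
            "tsh": p.tsh, "ft4": p.ft4, "ft3": p.ft3,
            "hypo_time": p.hypo_time, "hypo_event": p.hypo_event,
            "hyper_time": p.hyper_time, "hyper_event": p.hyper_event,
            "os_time": p.os_time, "os_event": p.os_event,
        }
        for k, name in enumerate(EV_NAMES):
            row[name] = float(p.eigenvectors[k]) if k < len(p.eigenvectors) else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def build_intervals(
    followup: float,
    event: int,
    irae_time: float | None,
) -> list[tuple[float, float, int, int]]:
    """Split one patient's follow-up at irAE onset.

    Returns (tstart, tstop, status, covariate) tuples. The covariate is 0
    before onset and 1 after; patients without an irAE — or with onset at or
    beyond the end of follow-up — contribute a single unexposed interval.
    """
    if followup <= 0:
        raise ValueError("follow-up must be positive")
    if irae_time is not None and irae_time <= 0:
        raise ValueError("irAE time must be positive")
    if irae_time is None or irae_time >= followup:
        return [(0.0, followup, int(event), 0)]
    return [(0.0, float(irae_time), 0, 0), (float(irae_time), followup, int(event), 1)]


def interval_frame(
    df: pd.DataFrame,
    time: str = "os_time",
    status: str = "os_event",
    irae_time: str = "hypo_time",
    irae_event: str = "hypo_event",
    carry: tuple[str, ...] = ("arm",),
) -> pd.DataFrame:
    """Counting-process intervals for a cohort, one block per patient."""
    rows = []
    for _, r in df.iterrows():
        onset = float(r[irae_time]) if r[irae_event] == 1 else None
        for t0, t1, st, cov in build_intervals(float(r[time]), int(r[status]), onset):
            row = {"patient_id": r["patient_id"], "tstart": t0, "tstop": t1,
                   "status": st, "irae": cov}
            for c in carry:
                row[c] = r[c]
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MetaResult:
    """Pooled estimate for one covariate across trial arms.

    ``stratified`` is the primary fixed-effect estimator (one baseline
    hazard per arm, eigenvector adjustment); ``dl_*`` fields pool per-arm
    univariable log-HRs with DerSimonian-Laird random effects.
    """

    covariate: str
    stratified: CoxFit
    per_arm: dict[str, CoxFit]
    dl_log_hr: float
    dl_se: float
    dl_tau2: float
    dropped_arms: list[str] = field(default_factory=list)

    @property
    def hr(self) -> float:
        return float(np.exp(self.stratified.coef[0]))

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = self.stratified.ci[0]
        return float(lo), float(hi)

    @property
    def p(self) -> float:
        return float(self.stratified.p[0])

    @property
    def dl_hr(self) -> float:
        return float(np.exp(self.dl_log_hr))


def meta_hr(
    intervals: pd.DataFrame,
    covariate: str,
    ev_covariates: list[str] | None = None,
    arm: str = "arm",
    start: str = "tstart",
    stop: str = "tstop",
    status: str = "status",
    ties: str = "efron",
) -> MetaResult:
    """Across-arm meta-analysis of one covariate's hazard ratio.

    Primary estimator: Cox model stratified by arm with the covariate first
    and optional eigenvector columns as fixed adjustments. Alternative:
    per-arm univariable fits pooled by DerSimonian-Laird; arms with no
    events (or failed fits) are dropped from the pooling but remain in the
    stratified fit.
    """
    arms = intervals[arm].unique()
    if len(arms) < 2:
        raise ValueError("meta-analysis requires at least 2 arms")
    covs = [covariate] + list(ev_covariates or [])
    data = CoxData.from_frame(intervals, covs, start=start, stop=stop,
                              status=status, strata=arm)
    stratified = cox_fit(data, ties=ties)

    per_arm: dict[str, CoxFit] = {}
    dropped: list[str] = []
    for a in arms:
        sub = intervals[intervals[arm] == a]
        if sub[status].sum() == 0:
            log.warning("arm %s has no events; dropped from per-arm pooling", a)
            dropped.append(str(a))
            continue
        try:
            fit = cox_fit(CoxData.from_frame(sub, [covariate], start=start,
                                             stop=stop, status=status), ties=ties)
        except ValueError as err:
            log.warning("arm %s univariable fit failed (%s); dropped", a, err)
            dropped.append(str(a))
            continue
        per_arm[str(a)] = fit

    if len(per_arm) >= 2:
        eff = np.array([f.coef[0] for f in per_arm.values()])
        var = np.array([f.se[0] ** 2 for f in per_arm.values()])
        if np.allclose(eff, eff[0]):
            dl_log_hr, dl_se, tau2 = float(eff[0]), float(np.sqrt(1.0 / (1.0 / var).sum())), 0.0
        else:
            res = combine_effects(eff, var, method_re="dl")
            frame = res.summary_frame()
            row = frame.loc["random effect"]
            dl_log_hr, dl_se = float(row["eff"]), float(row["sd_eff"])
            tau2 = float(res.tau2)
    elif per_arm:
        only = next(iter(per_arm.values()))
        dl_log_hr, dl_se, tau2 = float(only.coef[0]), float(only.se[0]), 0.0
    else:
        dl_log_hr = dl_se = tau2 = float("nan")

    return MetaResult(
        covariate=covariate, stratified=stratified, per_arm=per_arm,
        dl_log_hr=dl_log_hr, dl_se=dl_se, dl_tau2=tau2, dropped_arms=dropped,
    )


def landmark_analysis(
    df: pd.DataFrame,
    window_days: float = 150.0,
    time: str = "os_time",
    status: str = "os_event",
    irae_time: str = "hypo_time",
    irae_event: str = "hypo_event",
    arm: str | None = "arm",
) -> CoxFit:
    """Landmark analysis: condition on surviving to the landmark and
    classify exposure by irAE occurrence within the window.

    Survival is measured from the landmark; irAE occurring after the
    landmark do not change exposure (the landmark convention).
    """
    alive = df[df[time] > window_days].copy()
    if alive.empty:
        raise ValueError("no patients alive at the landmark")
    exposure = ((alive[irae_event] == 1) & (alive[irae_time] <= window_days)).astype(int)
    alive = alive.assign(
        tstart=0.0,
        tstop=alive[time] - window_days,
        _status=alive[status],
        irae_landmark=exposure,
    )
    data = CoxData.from_frame(alive, ["irae_landmark"], stop="tstop",
                              status="_status",
                              strata=arm if arm is not None else None)
    return cox_fit(data)


def km_cuminc(
    times: np.ndarray,
    status: np.ndarray,
    groups: np.ndarray | None = None,
    cumulative_incidence: bool = False,
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier curves with Greenwood 95% CIs and median survival.

    Returns per group a step table (time, estimate, ci_low, ci_high) with
    the median stored in ``df.attrs["median"]`` (NaN when undefined).
    ``cumulative_incidence`` reports 1 - KM for single-event settings.
    """
    times = np.asarray(times, float)
    status = np.asarray(status, int)
    groups = np.zeros(len(times), int) if groups is None else np.asarray(groups)
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        m = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], status[m])
        surv = kmf.survival_function_.iloc[:, 0]
        ci = kmf.confidence_interval_
        tab = pd.DataFrame({
            "time": surv.index.to_numpy(float),
            "estimate": surv.to_numpy(),
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
        })
        if cumulative_incidence:
            tab["estimate"] = 1.0 - tab["estimate"]
            tab[["ci_low", "ci_high"]] = 1.0 - tab[["ci_high", "ci_low"]].to_numpy()
        med = kmf.median_survival_time_
        tab.attrs["median"] = float(med) if np.isfinite(med) else float("nan")
        out[str(g)] = tab
    return out


def hormone_model(
    df: pd.DataFrame,
    time: str = "hypo_time",
    status: str = "hypo_event",
    arm: str | None = "arm",
) -> CoxFit:
    """Multivariable stratified Cox of irAE risk on baseline labs + gender.

    TSH/fT4/fT3 are quantile-normalised to the standard normal before the
    fit, so hazard ratios are per SD. Patients missing any lab are excluded
    (count logged).
    """
    labs = ["tsh", "ft4", "ft3"]
    ok = df[labs].notna().all(axis=1)
    if (~ok).any():
        log.info("hormone_model: excluding %d patients with missing labs", int((~ok).sum()))
    sub = df[ok].copy()
    for lab in labs:
        sub[f"{lab}_norm"] = normal_scores(sub[lab].to_numpy())
    covs = [f"{lab}_norm" for lab in labs] + ["gender"]
    sub = sub.assign(tstart=0.0)
    data = CoxData.from_frame(sub, covs, stop=time, status=status,
                              strata=arm if arm is not None else None)
    return cox_fit(data)


def plot_km(curves: dict[str, pd.DataFrame], path, title: str = "") -> None:
    """Step plot of km_cuminc output with shaded 95% CIs and dashed median
    lines, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, tab in curves.items():
        ax.step(tab["time"], tab["estimate"], where="post", label=label)
        ax.fill_between(tab["time"], tab["ci_low"], tab["ci_high"],
                        step="post", alpha=0.2)
        med = tab.attrs.get("median", float("nan"))
        if np.isfinite(med):
            ax.axvline(med, linestyle="--", linewidth=0.8, color="grey")
    ax.set_xlabel("days")
    ax.set_ylabel("probability")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class ThyroidEvents:
    """Per-patient thyroid events derived from a TSH lab series."""

    patient_id: str
    first_abnormal_day: float | None
    hyper_onset_day: float | None
    symptomatic_concordant: dict[str, bool]
    ordering: str | None  # "hyper-first" | "hypo-first" | None


def derive_thyroid_events(
    series: list[LabSeries],
    threshold: float = 5.0,
    precede_window_days: float = 7.0,
    hyper_threshold: float = 0.4,
) -> list[ThyroidEvents]:
    """Derive thyroid-event days from longitudinal TSH series.

    Hypothyroid onset is the first day with TSH strictly above ``threshold``
    (mU/L); hyperthyroid onset the first day with TSH below
    ``hyper_threshold`` (suppressed TSH). A symptomatic event is concordant
    iff some abnormal measurement falls in [event - window, event] (window
    closed on both ends). The ordering label compares the two onset days.
    An empty series yields a no-event record.
    """
    out = []
    for s in series:
        s.validate()
        if len(s.days) == 0:
            out.append(ThyroidEvents(s.patient_id, None, None, {}, None))
            continue
        abnormal_days = s.days[s.tsh > threshold]
        hypo = float(abnormal_days[0]) if len(abnormal_days) else None
        low = s.days[s.tsh < hyper_threshold]
        hyper = float(low[0]) if len(low) else None

        concord = {}
        for cls, day in s.symptomatic_days.items():
            window = abnormal_days[(abnormal_days >= day - precede_window_days)
                                   & (abnormal_days <= day)]
            concord[cls] = bool(len(window))

        ordering = None
        if hypo is not None and hyper is not None:
            ordering = "hyper-first" if hyper < hypo else "hypo-first"
        out.append(ThyroidEvents(s.patient_id, hypo, hyper, concord, ordering))
    return out
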