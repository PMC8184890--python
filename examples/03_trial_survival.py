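"""Trial-cohort survival analyses: PRS -> irAE risk and irAE -> survival.

Simulates a multi-arm trial (7 treated arms totalling 1584 patients plus
1302 controls) with a planted per-unit-PRS hazard ratio of 1.52 for the
thyroid adverse event and a planted post-event overall-survival hazard
ratio of 0.57, then recovers both with the stratified meta-analysis and
the time-dependent-covariate Cox model, plus a 150-day landmark analysis
and cumulative-incidence curves by median PRS split.
"""

import numpy as np

from prsurv import survkit, synthpop

sizes = [227, 227, 226, 226, 226, 226, 226]
arms = [synthpop.ArmSpec(f"atezo{k}", n, True) for k, n in enumerate(sizes)]
arms += [synthpop.ArmSpec("soc1", 651, False), synthpop.ArmSpec("soc2", 651, False)]
patients = synthpop.simulate_trial_cohort(
    sum(a.n for a in arms), arms, prs_log_hr=float(np.log(1.52)),
    covariate_effects=synthpop.CovariateEffects(
        gender_log_hr=0.3, tsh_log_hr=0.35,
        irae_os_log_hr=float(np.log(0.57))),
    seed=7)
df = survkit.patients_to_frame(patients)
active = df[df["active"]]

simple = active.assign(tstart=0.0).rename(
    columns={"hypo_time": "tstop", "hypo_event": "status"})
meta = survkit.meta_hr(simple, "prs", ev_covariates=survkit.EV_NAMES)
print(f"PRS -> irAE (stratified over {len(meta.per_arm)} arms): "
      f"HR {meta.hr:.2f} (95% CI {meta.ci[0]:.2f}-{meta.ci[1]:.2f}), "
      f"p = {meta.p:.2e}  [planted 1.52]")
print(f"  random-effects pooling: HR {meta.dl_hr:.2f}, tau^2 {meta.dl_tau2:.4f}")

iv = survkit.interval_frame(active)
meta_os = survkit.meta_hr(iv, "irae")
print(f"irAE -> OS (time-dependent covariate): HR {meta_os.hr:.2f} "
      f"(95% CI {meta_os.ci[0]:.2f}-{meta_os.ci[1]:.2f})  [planted 0.57]")

lm = survkit.landmark_analysis(active, window_days=150.0)
print(f"150-day landmark: HR {lm.hr[0]:.2f} "
      f"(95% CI {lm.ci[0, 0]:.2f}-{lm.ci[0, 1]:.2f})")

split = np.where(active["prs"] > df["prs"].median(), "above-median PRS",
                 "below-median PRS")
curves = survkit.km_cuminc(active["hypo_time"].to_numpy(),
                           active["hypo_event"].to_numpy(), split,
                           cumulative_incidence=True)
survkit.plot_km(curves, "trial_cuminc.png",
                title="Cumulative incidence of thyroid irAE")
print("wrote trial_cuminc.png — higher-PRS patients accumulate events faster")
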