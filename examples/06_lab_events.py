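"""Derive thyroid events from longitudinal TSH lab series.

Simulates TSH series for patients with both thyroid adverse events and
derives per-patient onsets: the first abnormal measurement (TSH strictly
above 5 mU/L), suppressed-TSH hyperthyroidism onsets, symptomatic-event
precedence within 7 days, and the hyperthyroidism-before-hypothyroidism
ordering (generator default 85.7%).
"""

import numpy as np

from prsurv import survkit, synthpop

arms = [synthpop.ArmSpec("a", 500, True, irae_hazard=1 / 150.0)]
patients = synthpop.simulate_trial_cohort(500, arms, prs_log_hr=0.0, seed=3)
for p in patients:  # force dual thyroid events to study the ordering
    p.hypo_event = p.hyper_event = 1
    p.hypo_time = min(p.hypo_time, p.os_time)
    p.hyper_time = min(p.hyper_time, p.os_time)

labs = synthpop.simulate_lab_series(patients, seed=3)
events = survkit.derive_thyroid_events(labs)

one = next(e for e in events if e.ordering == "hyper-first")
print(f"patient {one.patient_id}: hyperthyroid onset day "
      f"{one.hyper_onset_day:.0f}, first abnormal TSH day "
      f"{one.first_abnormal_day:.0f} -> ordering {one.ordering}")

orderings = [e.ordering for e in events if e.ordering is not None]
frac = np.mean([o == "hyper-first" for o in orderings])
concord = [all(e.symptomatic_concordant.values())
           for e in events if e.symptomatic_concordant]
print(f"\n{len(orderings)} dual-event patients; hyper-before-hypo fraction "
      f"{frac:.3f} (generator default 0.857)")
print(f"symptomatic events preceded within 7 days by an abnormal TSH: "
      f"{np.mean(concord):.1%}")
print("The early-suppression-then-elevation pattern reflects thyroid "
      "inflammation appearing first as hyperthyroidism before the gland "
      "fails into hypothyroidism.")
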