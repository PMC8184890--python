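"""Time-dependent intervals, meta-analysis, landmark, KM, hormone model and
lab-event derivation."""

import numpy as np
import pandas as pd
import pytest

from prsurv import survkit, synthpop
from prsurv.synthpop import LabSeries


class TestBuildIntervals:
    def test_split_at_irae_onset(self):
        iv = survkit.build_intervals(100.0, 1, 30.0)
        assert iv == [(0.0, 30.0, 0, 0), (30.0, 100.0, 1, 1)]

    def test_no_irae_single_unexposed_interval(self):
        assert survkit.build_intervals(200.0, 0, None) == [(0.0, 200.0, 0, 0)]

    def test_irae_after_followup_ignored(self):
        assert survkit.build_intervals(100.0, 1, 120.0) == [(0.0, 100.0, 1, 0)]

    def test_nonpositive_irae_time_rejected(self):
        with pytest.raises(ValueError):
            survkit.build_intervals(100.0, 1, 0.0)

    def test_cohort_intervals_contiguous_from_zero(self, trial_frame):
        iv = survkit.interval_frame(trial_frame.head(100))
        for _, grp in iv.groupby("patient_id"):
            grp = grp.sort_values("tstart")
            assert grp["tstart"].iloc[0] == 0.0
            assert np.allclose(grp["tstart"].iloc[1:].to_numpy(),
                               grp["tstop"].iloc[:-1].to_numpy())
            assert grp["status"].iloc[:-1].sum() == 0


class TestMetaHr:
    def _two_arm_frame(self, seed=0, log_hr=0.5, n=300):
        from tests.conftest import exponential_survival_frame

        a = exponential_survival_frame(n, log_hr, seed=seed).assign(arm="A")
        b = exponential_survival_frame(n, log_hr, seed=seed + 1).assign(arm="B")
        return pd.concat([a, b], ignore_index=True)

    def test_identical_arms_have_zero_heterogeneity(self):
        from tests.conftest import exponential_survival_frame

        a = exponential_survival_frame(200, 0.5, seed=2)
        df = pd.concat([a.assign(arm="A"), a.assign(arm="B")],
                       ignore_index=True)
        res = survkit.meta_hr(df, "x")
        assert res.dl_tau2 == pytest.approx(0.0, abs=1e-12)
        assert res.dl_log_hr == pytest.approx(
            res.per_arm["A"].coef[0], abs=1e-10)

    def test_stratified_estimate_invariant_to_arm_relabeling(self):
        df = self._two_arm_frame(seed=4)
        res1 = survkit.meta_hr(df, "x")
        relabeled = df.assign(arm=df["arm"].map({"A": "Z9", "B": "Q1"}))
        res2 = survkit.meta_hr(relabeled, "x")
        assert res1.stratified.coef[0] == pytest.approx(
            res2.stratified.coef[0], abs=1e-10)

    def test_zero_event_arm_dropped_from_pooling_kept_in_stratified(self):
        df = self._two_arm_frame(seed=5)
        dead = df[df["arm"] == "B"].copy()
        dead["status"] = 0
        dead["arm"] = "C"
        full = pd.concat([df, dead], ignore_index=True)
        res = survkit.meta_hr(full, "x")
        assert "C" in res.dropped_arms
        assert "C" not in res.per_arm

    def test_requires_two_arms(self):
        df = self._two_arm_frame()
        with pytest.raises(ValueError):
            survkit.meta_hr(df[df["arm"] == "A"], "x")


class TestLandmark:
    def test_immortal_time_bias_removed_by_time_dependent_model(self):
        """irAE assigned to long survivors with no causal effect: the naive
        from-randomisation model is biased away from 1, the time-dependent
        model is not."""
        rng = np.random.default_rng(11)
        n = 4000
        t = rng.exponential(300.0, size=n)
        c = rng.uniform(600, 1200, size=n)
        os_time = np.minimum(t, c)
        os_event = (t <= c).astype(int)
        # irAE at day 200 for half the patients surviving past 200: the
        # exposure is pure immortal time, with no causal effect
        irae = (os_time > 200.0) & (rng.random(n) < 0.5)
        df = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "os_time": os_time, "os_event": os_event,
            "hypo_time": np.where(irae, 200.0, os_time),
            "hypo_event": irae.astype(int),
            "arm": "A",
        })
        # naive: exposure as a baseline covariate from randomisation
        from prsurv.coxph import CoxData, cox_fit

        naive = cox_fit(CoxData(
            tstart=np.zeros(n), tstop=df["os_time"], status=df["os_event"],
            X=df["hypo_event"].to_numpy(float).reshape(-1, 1)))
        lo, hi = naive.ci[0]
        assert hi < 1.0  # spurious protective association

        iv = survkit.interval_frame(df, carry=())
        td = cox_fit(CoxData.from_frame(iv, ["irae"]))
        lo, hi = td.ci[0]
        assert lo <= 1.0 <= hi

    def test_empty_landmark_risk_set_errors(self, trial_frame):
        with pytest.raises(ValueError):
            survkit.landmark_analysis(trial_frame, window_days=1e9)

    def test_zero_window_gives_degenerate_covariate(self, trial_frame):
        with pytest.raises(ValueError, match="constant"):
            survkit.landmark_analysis(trial_frame, window_days=0.0)

    def test_landmark_recovers_protective_effect(self, trial_frame):
        fit = survkit.landmark_analysis(trial_frame[trial_frame["active"]], 150.0)
        assert fit.hr[0] < 1.1


class TestKm:
    def test_all_censored_survival_stays_one(self):
        curves = survkit.km_cuminc(np.array([5.0, 7.0, 9.0]), np.zeros(3, int))
        tab = curves["0"]
        assert np.allclose(tab["estimate"], 1.0)
        assert np.isnan(tab.attrs["median"])

    def test_two_subjects_one_event(self):
        curves = survkit.km_cuminc(np.array([1.0, 2.0]), np.array([1, 0]))
        tab = curves["0"]
        assert tab.set_index("time").loc[1.0, "estimate"] == pytest.approx(0.5)

    def test_hand_worked_product_limit_with_censoring(self):
        # events at 1 and 2, censored at 1.5 and 3
        times = np.array([1.0, 1.5, 2.0, 3.0])
        status = np.array([1, 0, 1, 0])
        tab = survkit.km_cuminc(times, status)["0"].set_index("time")
        assert tab.loc[1.0, "estimate"] == pytest.approx(0.75)
        assert tab.loc[2.0, "estimate"] == pytest.approx(0.75 * 0.5)
        # Greenwood variance at t=2: S^2 * (1/(4*3) + 1/(2*1))
        s = 0.375
        var = s**2 * (1.0 / 12.0 + 1.0 / 2.0)
        half = tab.loc[2.0, "ci_high"] - tab.loc[2.0, "ci_low"]
        # lifelines uses the log(-log) transform; the width should be of the
        # same scale as the plain Greenwood interval
        assert half == pytest.approx(2 * 1.96 * np.sqrt(var), rel=0.6)

    def test_cumulative_incidence_is_complement(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        s = np.array([1, 1, 0, 1])
        km = survkit.km_cuminc(t, s)["0"]
        ci = survkit.km_cuminc(t, s, cumulative_incidence=True)["0"]
        assert np.allclose(ci["estimate"], 1.0 - km["estimate"])


class TestHormoneModel:
    def test_recovers_planted_lab_and_gender_effects(self):
        arms = [synthpop.ArmSpec("a", 1500, True), synthpop.ArmSpec("b", 1500, True)]
        pats = synthpop.simulate_trial_cohort(
            3000, arms, prs_log_hr=0.0,
            covariate_effects=synthpop.CovariateEffects(
                gender_log_hr=0.3, tsh_log_hr=0.5),
            seed=31)
        fit = survkit.hormone_model(survkit.patients_to_frame(pats))
        s = fit.summary()
        assert abs(s.loc["tsh_norm", "coef"] - 0.5) <= 2 * s.loc["tsh_norm", "se"]
        assert abs(s.loc["gender", "coef"] - 0.3) <= 2 * s.loc["gender", "se"]
        assert abs(s.loc["ft4_norm", "coef"]) <= 2.5 * s.loc["ft4_norm", "se"]

    def test_missing_labs_excluded(self, trial_frame):
        df = trial_frame.copy()
        df.loc[df.index[:10], "tsh"] = np.nan
        fit = survkit.hormone_model(df)
        assert fit.n_events <= trial_frame["hypo_event"].sum()

    def test_constant_lab_rejected(self, trial_frame):
        df = trial_frame.copy()
        df["ft4"] = 1.0
        with pytest.raises(ValueError):
            survkit.hormone_model(df)


class TestDeriveThyroidEvents:
    def test_first_abnormal_day_strict_threshold(self):
        s = LabSeries("p", days=np.array([0.0, 21.0, 42.0]),
                      tsh=np.array([2.0, 6.1, 7.0]))
        (ev,) = survkit.derive_thyroid_events([s])
        assert ev.first_abnormal_day == 21.0

    def test_threshold_is_strict(self):
        s = LabSeries("p", days=np.array([0.0, 21.0]), tsh=np.array([5.0, 5.1]))
        (ev,) = survkit.derive_thyroid_events([s])
        assert ev.first_abnormal_day == 21.0

    def test_symptomatic_concordance_window(self):
        s = LabSeries("p", days=np.array([0.0, 21.0]), tsh=np.array([2.0, 6.0]),
                      symptomatic_days={"hypothyroidism": 25.0})
        (ev,) = survkit.derive_thyroid_events([s])
        assert ev.symptomatic_concordant["hypothyroidism"]
        s2 = LabSeries("p", days=np.array([0.0, 21.0]), tsh=np.array([2.0, 6.0]),
                       symptomatic_days={"hypothyroidism": 29.0})
        (ev2,) = survkit.derive_thyroid_events([s2])
        assert not ev2.symptomatic_concordant["hypothyroidism"]

    def test_ordering_label(self):
        s = LabSeries("p", days=np.array([0.0, 30.0, 60.0]),
                      tsh=np.array([2.0, 0.1, 7.0]))
        (ev,) = survkit.derive_thyroid_events([s])
        assert ev.ordering == "hyper-first"
        assert ev.hyper_onset_day == 30.0

    def test_empty_series_is_no_event(self):
        s = LabSeries("p", days=np.array([]), tsh=np.array([]))
        (ev,) = survkit.derive_thyroid_events([s])
        assert ev.first_abnormal_day is None and ev.ordering is None
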