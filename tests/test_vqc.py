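"""QC filter rulebook: GQ masking, missingness, allele balance, HWE,
heterozygosity F and PCA outliers, tiered INFO/MAF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from prsurv import vqc
from prsurv.vqc import MISSING, GenotypeCallMatrix


def make_calls(gt, gq=None):
    gt = np.asarray(gt, dtype=np.int8)
    n, m = gt.shape
    gq = np.full((n, m), 99) if gq is None else np.asarray(gq)
    ad_ref = np.where(gt == 1, 15, np.where(gt == 0, 30, 0))
    ad_alt = np.where(gt == 1, 15, np.where(gt == 2, 30, 0))
    return GenotypeCallMatrix(gt=gt, ad_ref=ad_ref, ad_alt=ad_alt, gq=gq,
                              variant_ids=[f"v{j}" for j in range(m)],
                              sample_ids=[f"s{i}" for i in range(n)])


class TestMaskAndMissingness:
    def test_low_gq_calls_push_variant_over_missingness_threshold(self):
        gq = np.full((20, 2), 99)
        gq[:3, 0] = 15  # 3/20 = 0.15 > 0.1 after masking
        calls = make_calls(np.zeros((20, 2)), gq)
        out, rep = vqc.mask_and_missingness_filter(calls)
        assert out.variant_ids == ["v1"]
        assert "v0" in rep.variant_fail

    def test_clean_input_is_untouched(self):
        calls = make_calls(np.ones((10, 4)))
        out, rep = vqc.mask_and_missingness_filter(calls)
        assert out.variant_ids == calls.variant_ids
        assert out.sample_ids == calls.sample_ids
        assert not rep.variant_fail and not rep.sample_fail

    def test_sample_with_high_missingness_removed(self):
        gt = np.zeros((5, 20), dtype=np.int8)
        gt[0, :3] = MISSING  # 3/20 = 0.15 > 0.1, variants each 1/5 > 0.1?
        # keep variant missingness below threshold: 1 of 20 samples missing
        gt = np.zeros((20, 20), dtype=np.int8)
        gt[0, :3] = MISSING
        calls = make_calls(gt)
        out, rep = vqc.mask_and_missingness_filter(calls)
        assert "s0" in rep.sample_fail
        assert "s0" not in out.sample_ids

    def test_variant_filter_runs_before_sample_filter(self):
        # sample s0 misses calls only at doomed variants (2/10 = 0.2 before
        # any removal); once those variants are dropped the sample is clean
        # and must be retained — the variant filter runs first
        gt = np.zeros((10, 10), dtype=np.int8)
        gt[:3, 0] = MISSING   # v0: 30% missing -> removed
        gt[:3, 1] = MISSING   # v1: 30% missing -> removed
        calls = make_calls(gt)
        out, _ = vqc.mask_and_missingness_filter(calls)
        assert "v0" not in out.variant_ids and "v1" not in out.variant_ids
        assert "s0" in out.sample_ids

    def test_all_variants_removed_is_warning_not_error(self):
        gq = np.full((10, 2), 10)
        calls = make_calls(np.zeros((10, 2)), gq)
        out, _ = vqc.mask_and_missingness_filter(calls)
        assert out.n_variants == 0

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(0)
        gt = rng.integers(0, 3, size=(30, 15)).astype(np.int8)
        gq = rng.integers(10, 100, size=(30, 15))
        out1, _ = vqc.mask_and_missingness_filter(make_calls(gt, gq))
        out2, _ = vqc.mask_and_missingness_filter(
            GenotypeCallMatrix(out1.gt, out1.ad_ref, out1.ad_alt,
                               np.full(out1.gt.shape, 99), out1.variant_ids,
                               out1.sample_ids))
        assert out2.variant_ids == out1.variant_ids
        assert out2.sample_ids == out1.sample_ids
        assert np.array_equal(out2.gt, out1.gt)


class TestAlleleBalance:
    def run(self, ref, alt):
        df = pd.DataFrame({"variant": ["v"], "ref_reads": [ref], "alt_reads": [alt]})
        return vqc.allele_balance_filter(df).iloc[0]

    def test_perfect_balance_passes(self):
        row = self.run(10, 10)
        assert row["pass"] and row["balance"] == 0.5 and row["p"] == 1.0

    def test_total_imbalance_fails(self):
        assert not self.run(100, 0)["pass"]

    def test_borderline_balance_passes_with_binomial_p(self):
        row = self.run(60, 40)
        # exact two-sided minlike p: sum of outcome probabilities <= P(40)
        pmf = binom.pmf(np.arange(101), 100, 0.5)
        expected = pmf[pmf <= pmf[40] * (1 + 1e-12)].sum()
        assert row["pass"]
        assert row["p"] == pytest.approx(expected, rel=1e-10)
        assert 0.05 < row["p"] < 0.06

    def test_zero_depth_flagged_unevaluable(self):
        row = self.run(0, 0)
        assert not row["pass"] and row["reason"] == "unevaluable"


def hwe_bruteforce(n_aa, n_ab, n_bb):
    """Independent enumeration of the conditional het-count distribution."""
    from math import lgamma

    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def logprob(h):
        ha = (n_a - h) // 2
        hb = n - h - ha
        return (lgamma(n + 1) - lgamma(ha + 1) - lgamma(h + 1) - lgamma(hb + 1)
                + h * np.log(2))

    hets = [h for h in range(min(n_a, 2 * n - n_a) + 1) if (n_a - h) % 2 == 0]
    lp = np.array([logprob(h) for h in hets])
    pr = np.exp(lp - lp.max())
    pr /= pr.sum()
    obs = pr[hets.index(n_ab)]
    return pr[pr <= obs * (1 + 1e-12)].sum()


class TestHWE:
    def test_modal_configuration_has_p_one(self):
        assert vqc.hwe_exact_test(25, 50, 25) == 1.0

    def test_total_heterozygote_deficit_is_extreme(self):
        p = vqc.hwe_exact_test(50, 0, 50)
        assert p < 1e-20
        assert p == pytest.approx(hwe_bruteforce(50, 0, 50), rel=1e-9)

    def test_monomorphic_returns_one(self):
        assert vqc.hwe_exact_test(0, 0, 100) == 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 70), st.integers(0, 70), st.integers(0, 70))
    def test_agrees_with_bruteforce_enumeration(self, a, b, c):
        if a + b + c == 0:
            return
        p = vqc.hwe_exact_test(a, b, c)
        n_rare = 2 * min(a, c) + b
        if n_rare == 0 or n_rare == 2 * (a + b + c):
            assert p == 1.0
            return
        assert p == pytest.approx(hwe_bruteforce(a, b, c), abs=1e-12)


class TestHeterozygosityOutliers:
    def test_identical_samples_all_kept(self):
        gt = np.tile(np.array([0, 1, 2, 1, 0], dtype=np.int8), (10, 1))
        keep, F = vqc.heterozygosity_outlier_filter(gt)
        assert keep.all()

    def test_planted_homozygous_sample_removed(self):
        rng = np.random.default_rng(1)
        gt = rng.binomial(2, 0.4, size=(101, 400)).astype(np.int8)
        gt[0] = np.where(gt[0] == 1, 2, gt[0])  # erase all heterozygosity
        keep, F = vqc.heterozygosity_outlier_filter(gt)
        assert not keep[0]
        assert keep[1:].sum() >= 98

    def test_infinite_multiplier_keeps_everyone(self):
        rng = np.random.default_rng(2)
        gt = rng.binomial(2, 0.3, size=(20, 50)).astype(np.int8)
        keep, _ = vqc.heterozygosity_outlier_filter(gt, sd_mult=np.inf)
        assert keep.all()


class TestPCAOutliers:
    def test_homogeneous_cohort_loses_nobody(self):
        removed = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            gt = rng.binomial(2, 0.3, size=(150, 60)).astype(np.int8)
            keep, evs = vqc.iterative_pca_outlier_removal(gt)
            removed.append(int((~keep).sum()))
            assert evs.shape == (keep.sum(), 5)
        assert sum(r == 0 for r in removed) >= 2

    def test_divergent_population_samples_removed(self):
        rng = np.random.default_rng(3)
        main = rng.binomial(2, np.full(120, 0.3), size=(195, 120))
        drifted = rng.binomial(2, np.full(120, 0.7), size=(5, 120))
        gt = np.vstack([main, drifted]).astype(np.int8)
        keep, _ = vqc.iterative_pca_outlier_removal(gt)
        assert not keep[195:].any()

    def test_zero_rounds_keeps_everyone(self):
        rng = np.random.default_rng(4)
        gt = rng.binomial(2, 0.3, size=(60, 30)).astype(np.int8)
        keep, evs = vqc.iterative_pca_outlier_removal(gt, rounds=0)
        assert keep.all()
        assert evs.shape == (60, 5)

    def test_too_few_samples_error(self):
        gt = np.zeros((8, 30), dtype=np.int8)
        with pytest.raises(ValueError):
            vqc.iterative_pca_outlier_removal(gt, n_ev_screen=10)


class TestInfoMafTiers:
    @pytest.mark.parametrize("maf,info,kept", [
        (0.05, 0.4, True),     # common tier: INFO > 0.3 suffices
        (0.002, 0.85, False),  # rare tier needs INFO > 0.9
        (0.0005, 1.0, False),  # below the absolute MAF floor
        (0.02, 0.61, True),
        (0.02, 0.6, False),    # tier bound exclusive on INFO
        (0.03, 0.65, True),    # 0.03 belongs to the (0.01, 0.03] tier
        (0.007, 0.85, True),
        (0.001, 0.95, True),   # floor value allowed at the strictest tier
    ])
    def test_tier_rules(self, maf, info, kept):
        df = pd.DataFrame({"variant": ["v"], "maf": [maf], "info": [info]})
        out = vqc.ld_panel_info_maf_filter(df)
        assert (len(out) == 1) == kept

    def test_missing_info_removed(self):
        df = pd.DataFrame({"variant": ["v"], "maf": [0.2], "info": [np.nan]})
        assert len(vqc.ld_panel_info_maf_filter(df)) == 0

    def test_invalid_maf_rejected(self):
        df = pd.DataFrame({"variant": ["v"], "maf": [0.7], "info": [1.0]})
        with pytest.raises(ValueError):
            vqc.ld_panel_info_maf_filter(df)


def test_ancestry_relatedness_stub_is_pass_through():
    keep = vqc.ancestry_relatedness_stub(["a", "b", "c"])
    assert keep.all()
    keep = vqc.ancestry_relatedness_stub(
        ["a", "b", "c"], ancestry_pass={"b": False}, related_remove={"c"})
    assert list(keep) == [True, False, False]
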