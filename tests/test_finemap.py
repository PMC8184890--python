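"""Locus definition, conditional analysis, ABF/PPA credible sets and gene
annotation."""

import numpy as np
import pandas as pd
import pytest

from prsurv import assoc, finemap, synthpop
from prsurv.assoc import LDMatrix
from prsurv.finemap import FinemapPrior, abf


def stats_frame(positions, ps, chrom="chr1"):
    m = len(positions)
    return pd.DataFrame({
        "chrom": chrom, "pos": positions, "id": [f"v{j}" for j in range(m)],
        "effect_allele": "G", "other_allele": "A", "eaf": 0.3,
        "beta": 0.1, "se": 0.02, "p": ps, "n": 1000,
    })


class TestDefineLoci:
    def test_overlapping_windows_merge(self):
        df = stats_frame([1_000_000, 1_600_000], [1e-10, 1e-9])
        loci = finemap.define_loci(df)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (500_000, 2_100_000)
        assert set(loci[0].lead_ids) == {"v0", "v1"}

    def test_no_significant_variants_yields_no_loci(self):
        df = stats_frame([1_000_000], [1e-6])
        assert finemap.define_loci(df) == []

    def test_single_lead_window_width(self):
        df = stats_frame([2_000_000], [1e-10])
        (locus,) = finemap.define_loci(df)
        assert locus.end - locus.start + 1 == 1_000_001


class TestConditionalStats:
    def test_empty_conditioning_set_is_identity(self):
        R = LDMatrix(["a", "b"], np.array([[1.0, 0.3], [0.3, 1.0]]))
        out = finemap.conditional_stats([2.0, 3.0], [0.1, 0.1], R, [])
        assert np.allclose(out["z_cond"], [2.0, 3.0])

    def test_conditioning_on_self_zeroes_z(self):
        R = LDMatrix(["a", "b"], np.array([[1.0, 0.3], [0.3, 1.0]]))
        out = finemap.conditional_stats([2.0, 3.0], [0.1, 0.1], R, ["a"])
        assert out.set_index("id").loc["a", "z_cond"] == 0.0

    def test_hand_worked_two_variant_identity(self):
        R = LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        out = finemap.conditional_stats([4.0, 4.0], [0.1, 0.1], R, ["b"])
        expected = (4.0 - 0.5 * 4.0) / np.sqrt(1 - 0.25)
        assert out.set_index("id").loc["a", "z_cond"] == pytest.approx(expected)
        assert expected == pytest.approx(2.309, abs=1e-3)

    def test_collinear_variant_masked(self):
        R = LDMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        out = finemap.conditional_stats([4.0, 4.0], [0.1, 0.1], R, ["b"])
        assert bool(out.set_index("id").loc["a", "masked"])


class TestABF:
    def test_zero_z_closed_form(self):
        res = abf(0.0, 0.2, W=0.04)
        assert res.r == pytest.approx(0.5)
        assert res.abf == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_strong_signal_value(self):
        res = abf(0.4, 0.1, W=0.04)
        assert res.r == pytest.approx(0.8)
        assert res.z == pytest.approx(4.0)
        # direct evaluation: sqrt(1-r) * exp(z^2 r / 2)
        assert res.abf == pytest.approx(np.sqrt(0.2) * np.exp(6.4), rel=1e-12)
        assert res.abf == pytest.approx(269.2, abs=0.2)

    def test_large_prior_variance_kills_evidence(self):
        # as W grows with z fixed, the shrinkage penalty dominates
        small = abf(0.4, 0.1, W=1e12).abf
        assert small < 0.01
        assert small < abf(0.4, 0.1, W=0.04).abf

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            abf(np.inf, 0.1)
        with pytest.raises(ValueError):
            abf(0.1, 0.0)


def members_frame(ppas_positions):
    m = len(ppas_positions)
    return pd.DataFrame({
        "id": [f"v{j}" for j in range(m)], "chrom": "chr1",
        "pos": [p for _, p in ppas_positions], "effect_allele": "G",
        "other_allele": "A", "eaf": 0.3, "beta_cond": 0.1, "sigma": 0.02,
    })


class TestCredibleSet:
    def test_equal_abf_split_keeps_both(self):
        df = members_frame([(0.5, 1), (0.5, 2)])
        cs = finemap.ppa_credible_set(df, np.array([3.0, 3.0]))
        assert np.allclose(cs.members["ppa"], 0.5)
        assert len(cs.members) == 2

    def test_prefix_rule_at_exact_boundary(self):
        df = members_frame([(0, 1), (0, 2), (0, 3), (0, 4)])
        cs = finemap.ppa_credible_set(df, np.array([0.6, 0.3, 0.09, 0.01]))
        assert len(cs.members) == 3
        assert cs.members["cum_ppa"].iloc[-1] == pytest.approx(0.99)

    def test_single_variant_set(self):
        df = members_frame([(1.0, 1)])
        cs = finemap.ppa_credible_set(df, np.array([7.7]))
        assert cs.members["ppa"].iloc[0] == pytest.approx(1.0)

    def test_ppa_normalisation_always_sums_to_one(self):
        rng = np.random.default_rng(0)
        abfs = rng.exponential(size=20)
        df = members_frame([(0, p) for p in range(20)])
        cs = finemap.ppa_credible_set(df, abfs, level=0.5)
        # members hold the descending-PPA prefix; total over all = 1
        assert abfs.sum() == pytest.approx(abfs.sum())
        full = finemap.ppa_credible_set(df, abfs, level=1 - 1e-15)
        assert full.members["ppa"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_minimality_of_prefix(self):
        rng = np.random.default_rng(1)
        abfs = rng.exponential(size=15)
        df = members_frame([(0, p) for p in range(15)])
        cs = finemap.ppa_credible_set(df, abfs, level=0.99)
        cum = cs.members["cum_ppa"].to_numpy()
        assert cum[-1] >= 0.99
        if len(cum) > 1:
            assert cum[-2] < 0.99

    def test_degenerate_signal_rejected(self):
        df = members_frame([(0, 1)])
        with pytest.raises(ValueError):
            finemap.ppa_credible_set(df, np.array([0.0]))


def simulated_locus(seed, causal, n=4000, m=25, rho=0.85, beta=0.45):
    panel = synthpop.simulate_haplotypes(
        4000, [synthpop.BlockSpec(m, (0.2, 0.4), rho)], seed=seed)
    arch = synthpop.CausalArchitecture(
        log_odds={c: beta for c in causal}, prevalence=0.1)
    cohort = synthpop.simulate_gwas_cohort(panel, arch, n // 2, n // 2, seed=seed)
    stats = assoc.logistic_gwas(cohort.genotypes.astype(float),
                                cohort.phenotype, panel.variants)
    ld = assoc.ld_matrix(panel.genotype_matrix().astype(float),
                         list(panel.variants["id"]))
    return stats.dropna(subset=["p"]).reset_index(drop=True), ld


class TestForwardSelect:
    def test_single_causal_variant_selects_one_snp(self):
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            stats, ld = simulated_locus(seed=500 + rep, causal=["rs12"])
            if not (stats["p"] < 5e-8).any():
                continue
            sel = finemap.forward_select(stats, ld)
            hits += len(sel) == 1
        assert hits >= int(0.85 * n_rep)

    def test_two_uncorrelated_causal_variants_select_two(self):
        stats, ld = simulated_locus(seed=42, causal=["rs3", "rs22"], beta=0.5)
        # rs3 and rs22 sit 19 copying steps apart: negligible LD
        sel = finemap.forward_select(stats, ld)
        assert len(sel) == 2

    def test_stops_when_no_conditional_signal(self):
        stats, ld = simulated_locus(seed=43, causal=["rs12"], beta=0.5)
        sel = finemap.forward_select(stats, ld)
        assert len(sel) >= 1
        cond = finemap.conditional_stats(
            (stats.set_index("id").loc[ld.variant_ids, "beta"]
             / stats.set_index("id").loc[ld.variant_ids, "se"]).to_numpy(),
            stats.set_index("id").loc[ld.variant_ids, "se"].to_numpy(),
            ld, sel)
        rest = cond[~cond["id"].isin(sel) & ~cond["masked"]]
        assert (rest["p_cond"] >= 5e-8).all() or rest.empty

    def test_selection_insensitive_to_input_order(self):
        stats, ld = simulated_locus(seed=44, causal=["rs5", "rs20"], beta=0.5)
        sel1 = finemap.forward_select(stats, ld)
        shuffled = stats.sample(frac=1.0, random_state=3).reset_index(drop=True)
        sel2 = finemap.forward_select(shuffled, ld)
        assert sel1 == sel2

    def test_requires_a_significant_variant(self):
        stats = stats_frame([100, 200], [1e-3, 1e-4])
        R = LDMatrix(["v0", "v1"], np.eye(2))
        with pytest.raises(ValueError):
            finemap.forward_select(stats, R)


class TestLeaveOneOut:
    def test_singleton_reduces_to_marginal(self):
        stats, ld = simulated_locus(seed=45, causal=["rs12"])
        sel = finemap.forward_select(stats, ld)[:1]
        (cs,) = finemap.leave_one_out_signals(stats, sel, ld)
        assert cs.conditioned_on == []
        z = stats.set_index("id")["beta"] / stats.set_index("id")["se"]
        assert cs.max_ppa_variant()["id"] == z.abs().idxmax()

    def test_three_conditioning_snps_give_three_sets(self):
        stats, ld = simulated_locus(seed=46, causal=["rs2", "rs12", "rs23"],
                                    beta=0.55)
        sel = ["rs2", "rs12", "rs23"]
        sets = finemap.leave_one_out_signals(stats, sel, ld)
        assert len(sets) == 3
        for k, cs in enumerate(sets):
            assert set(cs.conditioned_on) == set(sel) - {sel[k]}


class TestGeneAnnotation:
    gene_table = pd.DataFrame({
        "chrom": ["chr1"] * 6,
        "tss": [150, 250, 350, 450, 1_120_000, 1_692_001],
        "name": ["G1", "G2", "G3", "G4", "NEAR", "FAR"],
    })

    def test_more_than_three_tss_inside_span_is_dash(self):
        assert finemap.annotate_credible_set_genes(
            ("chr1", 100, 500), self.gene_table) == "-"

    def test_distant_tss_not_reported(self):
        # FAR sits 692 kb from the span end: outside the 500 kb rule
        out = finemap.annotate_credible_set_genes(
            ("chr1", 999_000, 1_000_000),
            self.gene_table[self.gene_table["name"] == "FAR"])
        assert out == ""

    def test_nearby_tss_reported_with_kb_distance(self):
        out = finemap.annotate_credible_set_genes(
            ("chr1", 999_000, 1_000_000),
            self.gene_table[self.gene_table["name"] == "NEAR"])
        assert out == "NEAR(120)"

    def test_inside_genes_reported_plainly_with_neighbours(self):
        table = self.gene_table[self.gene_table["name"].isin(["G1", "NEAR"])]
        out = finemap.annotate_credible_set_genes(("chr1", 100, 1_000_000), table)
        assert out == "G1,NEAR(120)"

    def test_empty_gene_table(self):
        assert finemap.annotate_credible_set_genes(
            ("chr1", 1, 2), pd.DataFrame()) == ""
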