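"""Variant- and sample-level quality control.

Implements the WGS-cohort filter rulebook — genotype-quality masking,
call-rate filters, heterozygous allele-balance testing, the Hardy-Weinberg
exact test, inbreeding-coefficient (F) outlier removal and iterative PCA
outlier removal — plus the tiered INFO/MAF filter used to build an LD
reference panel from imputed data. Filters compose in a fixed order
(mask -> variant missingness -> sample missingness -> remaining variant
filters) and are idempotent on their own output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeCallMatrix",
    "QCReport",
    "mask_and_missingness_filter",
    "allele_balance_filter",
    "hwe_exact_test",
    "heterozygosity_outlier_filter",
    "iterative_pca_outlier_removal",
    "ld_panel_info_maf_filter",
    "ancestry_relatedness_stub",
]

MISSING = -1


@dataclass
class GenotypeCallMatrix:
    """Per-call genotypes with read depths and qualities.

    ``gt``: (n_samples, n_variants) dosage matrix, -1 = missing.
    ``ad_ref``/``ad_alt``: per-call read depths; ``gq``: genotype quality.
    """

    gt: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    gq: np.ndarray
    variant_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        shapes = {self.gt.shape, self.ad_ref.shape, self.ad_alt.shape, self.gq.shape}
        if len(shapes) != 1:
            raise ValueError("call-matrix fields must share one shape")
        if np.any(self.ad_ref < 0) or np.any(self.ad_alt < 0):
            raise ValueError("read depths must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.gt.shape[0]

    @property
    def n_variants(self) -> int:
        return self.gt.shape[1]

    def subset(self, sample_mask=None, variant_mask=None) -> "GenotypeCallMatrix":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else sample_mask
        vm = np.ones(self.n_variants, bool) if variant_mask is None else variant_mask
        return GenotypeCallMatrix(
            gt=self.gt[np.ix_(sm, vm)],
            ad_ref=self.ad_ref[np.ix_(sm, vm)],
            ad_alt=self.ad_alt[np.ix_(sm, vm)],
            gq=self.gq[np.ix_(sm, vm)],
            variant_ids=[v for v, k in zip(self.variant_ids, vm) if k],
            sample_ids=[s for s, k in zip(self.sample_ids, sm) if k],
        )


@dataclass
class QCReport:
    """Filter provenance: per-record failure reasons and stage counts."""

    variant_fail: dict[str, list[str]] = field(default_factory=dict)
    sample_fail: dict[str, list[str]] = field(default_factory=dict)
    stage_counts: list[tuple[str, int, int]] = field(default_factory=list)

    def fail_variant(self, vid: str, reason: str) -> None:
        self.variant_fail.setdefault(vid, []).append(reason)

    def fail_sample(self, sid: str, reason: str) -> None:
        self.sample_fail.setdefault(sid, []).append(reason)

    def record_stage(self, stage: str, n_variants: int, n_samples: int) -> None:
        if self.stage_counts:
            _, pv, ps = self.stage_counts[-1]
            if n_variants > pv or n_samples > ps:
                raise ValueError("stage counts must be non-increasing")
        self.stage_counts.append((stage, n_variants, n_samples))

    def summary(self) -> dict:
        return {
            "stages": [
                {"stage": s, "n_variants": nv, "n_samples": ns}
                for s, nv, ns in self.stage_counts
            ],
            "n_failed_variants": len(self.variant_fail),
            "n_failed_samples": len(self.sample_fail),
        }


def mask_and_missingness_filter(
    calls: GenotypeCallMatrix,
    gq_min: int = 20,
    variant_missing_max: float = 0.1,
    sample_missing_max: float = 0.1,
    report: QCReport | None = None,
) -> tuple[GenotypeCallMatrix, QCReport]:
    """Mask low-GQ calls, then drop high-missingness variants, then samples.

    Calls with GQ <= ``gq_min`` are set missing before any rate is computed;
    the variant filter (call missing rate > ``variant_missing_max``) runs
    before the sample filter (within-sample missing rate >
    ``sample_missing_max``). An empty output is a warning, not an error.
    """
    if calls.n_samples == 0 or calls.n_variants == 0:
        raise ValueError("empty call matrix")
    rep = report or QCReport()
    rep.record_stage("input", calls.n_variants, calls.n_samples)

    gt = calls.gt.copy()
    gt[calls.gq <= gq_min] = MISSING
    masked = GenotypeCallMatrix(gt, calls.ad_ref, calls.ad_alt, calls.gq,
                                calls.variant_ids, calls.sample_ids)

    vmiss = (masked.gt == MISSING).mean(axis=0)
    vkeep = vmiss <= variant_missing_max
    for vid, m, k in zip(masked.variant_ids, vmiss, vkeep):
        if not k:
            rep.fail_variant(vid, f"missing_rate={m:.3f}>{variant_missing_max}")
    masked = masked.subset(variant_mask=vkeep)
    rep.record_stage("variant_missingness", masked.n_variants, masked.n_samples)

    if masked.n_variants == 0:
        log.warning("all variants removed by missingness filter")
        rep.record_stage("sample_missingness", 0, masked.n_samples)
        return masked, rep

    smiss = (masked.gt == MISSING).mean(axis=1)
    skeep = smiss <= sample_missing_max
    for sid, m, k in zip(masked.sample_ids, smiss, skeep):
        if not k:
            rep.fail_sample(sid, f"missing_rate={m:.3f}>{sample_missing_max}")
    masked = masked.subset(sample_mask=skeep)
    rep.record_stage("sample_missingness", masked.n_variants, masked.n_samples)
    return masked, rep


def allele_balance_filter(
    het_depths: pd.DataFrame,
    low: float = 0.3,
    high: float = 0.7,
    p_min: float = 5e-8,
) -> pd.DataFrame:
    """Allele-balance filter on summed heterozygous read depths per variant.

    ``het_depths`` columns: variant, ref_reads, alt_reads (sums over het
    calls). Balance = alt/(ref+alt); fail when outside [low, high] or when
    the exact two-sided binomial test against 0.5 gives p < ``p_min``.
    Zero total depth is unevaluable and treated as fail.
    """
    rows = []
    for _, r in het_depths.iterrows():
        ref, alt = int(r["ref_reads"]), int(r["alt_reads"])
        total = ref + alt
        if total == 0:
            log.warning("variant %s: no het read depth; flagged unevaluable", r["variant"])
            rows.append((r["variant"], np.nan, np.nan, False, "unevaluable"))
            continue
        balance = alt / total
        p = binomtest(alt, total, 0.5).pvalue
        ok = (low <= balance <= high) and (p >= p_min)
        reason = "" if ok else ("balance_out_of_range" if not (low <= balance <= high)
                                else "binomial_p")
        rows.append((r["variant"], balance, p, ok, reason))
    return pd.DataFrame(rows, columns=["variant", "balance", "p", "pass", "reason"])


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test conditioning on allele counts.

    Enumerates the conditional distribution of the heterozygote count given
    the minor-allele count by the standard recurrence and sums the
    probabilities of all tables no more likely than the observed one.
    Monomorphic input returns p = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:
        log.debug("monomorphic variant: HWE p set to 1")
        return 1.0

    # conditional probabilities over het counts with the parity of n_rare
    het_obs = n_Aa
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logp = np.zeros(len(hets))
    for k in range(1, len(hets)):
        # recurrence: P(h+2)/P(h) = 4*hom_rare*hom_common / ((h+2)*(h+1))
        h = hets[k - 1]
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        logp[k] = logp[k - 1] + np.log(4.0 * hom_r * hom_c) - np.log((h + 2) * (h + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[list(hets).index(het_obs)]
    pval = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(1.0, pval)


def heterozygosity_outlier_filter(
    gt: np.ndarray,
    sample_ids: list[str] | None = None,
    sd_mult: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove samples whose inbreeding coefficient F is extreme.

    F = 1 - observed_het / expected_het per sample, with expected
    heterozygosity from within-cohort allele frequencies at that sample's
    non-missing variants. Samples with |F - mean| > ``sd_mult`` * SD are
    removed; a zero SD removes nobody.
    """
    n, m = gt.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    obs = np.ma.masked_equal(gt, MISSING)
    freq = obs.mean(axis=0).filled(np.nan) / 2.0
    exp_het_v = 2.0 * freq * (1.0 - freq)
    called = gt != MISSING
    exp_het = (called * np.nan_to_num(exp_het_v)).sum(axis=1)
    obs_het = ((gt == 1) & called).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(exp_het > 0, 1.0 - obs_het / exp_het, 0.0)
    sd = F.std()
    if sd == 0 or not np.isfinite(sd_mult):
        keep = np.ones(n, bool)
    else:
        keep = np.abs(F - F.mean()) <= sd_mult * sd
    return keep, F


def _standardize(gt: np.ndarray) -> np.ndarray:
    g = gt.astype(float)
    g[g == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    denom[denom == 0] = 1.0
    z = (g - 2.0 * p) / denom
    return np.nan_to_num(z)


def iterative_pca_outlier_removal(
    gt: np.ndarray,
    rounds: int = 5,
    sd_mult: float = 6.0,
    n_ev_screen: int = 10,
    n_ev_out: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative PCA outlier removal for population stratification.

    Runs exactly ``rounds`` remove-and-recompute iterations: each round
    standardises the genotypes of the surviving samples, computes the top
    ``n_ev_screen`` eigenvectors, and removes samples more than ``sd_mult``
    standard deviations from the mean on any of them. A final PCA returns
    ``n_ev_out`` eigenvectors for the kept samples.

    Returns (keep mask over input samples, (n_kept, n_ev_out) eigenvectors).
    """
    n = gt.shape[0]
    keep = np.ones(n, bool)
    for _ in range(rounds):
        if keep.sum() <= n_ev_screen:
            raise ValueError("fewer samples than screening eigenvectors remain")
        z = _standardize(gt[keep])
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        scores = u[:, :n_ev_screen] * s[:n_ev_screen]
        mu, sd = scores.mean(axis=0), scores.std(axis=0)
        sd[sd == 0] = 1.0
        bad = (np.abs(scores - mu) > sd_mult * sd).any(axis=1)
        idx = np.flatnonzero(keep)
        keep[idx[bad]] = False
    if keep.sum() <= n_ev_out:
        raise ValueError("fewer samples than output eigenvectors remain")
    z = _standardize(gt[keep])
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    evs = u[:, :n_ev_out] * s[:n_ev_out]
    return keep, evs


_INFO_TIERS = [(0.03, 0.3), (0.01, 0.6), (0.005, 0.8), (0.001, 0.9)]


def ld_panel_info_maf_filter(variants: pd.DataFrame) -> pd.DataFrame:
    """Tiered INFO/MAF filter for an imputed LD reference panel.

    MAF < 0.001 is always removed; otherwise the required INFO rises as MAF
    falls: INFO > 0.3 for MAF > 0.03, > 0.6 for MAF in (0.01, 0.03],
    > 0.8 for (0.005, 0.01], > 0.9 for [0.001, 0.005]. Tier bounds are
    lower-exclusive / upper-inclusive. Missing INFO removes the variant.
    """
    maf = variants["maf"].to_numpy(float)
    info = variants["info"].to_numpy(float)
    if np.any((maf < 0) | (maf > 0.5)):
        raise ValueError("MAF must lie in [0, 0.5]")
    keep = np.zeros(len(variants), bool)
    for i, (m, f) in enumerate(zip(maf, info)):
        if np.isnan(f):
            log.warning("variant %s: missing INFO; removed", variants.iloc[i].get("variant", i))
            continue
        if m < 0.001:
            continue
        for maf_floor, info_min in _INFO_TIERS:
            if m > maf_floor or maf_floor == 0.001:
                keep[i] = f > info_min
                break
    return variants[keep].reset_index(drop=True)


def ancestry_relatedness_stub(
    sample_ids: list[str],
    ancestry_pass: dict[str, bool] | None = None,
    related_remove: set[str] | None = None,
) -> np.ndarray:
    """Pass-through stand-in for supervised-ancestry and relatedness pruning.

    Accepts precomputed per-sample ancestry flags and a set of samples to
    drop from related pairs; with neither supplied everything passes. Keeps
    the pipeline position of the ancestry/relatedness stages without
    re-deriving them.
    """
    keep = np.ones(len(sample_ids), bool)
    for i, sid in enumerate(sample_ids):
        if ancestry_pass is not None and not ancestry_pass.get(sid, True):
            keep[i] = False
        if related_remove is not None and sid in related_remove:
            keep[i] = False
    return keep
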