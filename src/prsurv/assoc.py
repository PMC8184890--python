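"""Per-variant association statistics, LD matrices and harmonization.

The GWAS here is a plain per-variant logistic regression (Wald beta, SE and
p-value, optionally adjusted for covariates such as genotype eigenvectors);
LD is the Pearson correlation of dosages within a region; harmonization
aligns external summary statistics to a reference panel's allele
orientation, dropping strand-ambiguous variants and the MHC region.

Summary-statistic tables use one row per variant with columns
``chrom, pos, id, effect_allele, other_allele, eaf, beta, se, p, n``.
The harmonized orientation sets the effect allele to the panel's
dosage-counted (alt) allele; a swapped allele match flips the sign of beta
and replaces the frequency with its complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

log = logging.getLogger(__name__)

__all__ = ["SUMSTAT_COLUMNS", "LDMatrix", "logistic_gwas", "ld_matrix", "harmonize"]

SUMSTAT_COLUMNS = ["chrom", "pos", "id", "effect_allele", "other_allele",
                   "eaf", "beta", "se", "p", "n"]

_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}

MHC_HG38 = ("chr6", 28510120, 33480577)


@dataclass
class LDMatrix:
    """Symmetric dosage-correlation matrix over an ordered variant list."""

    variant_ids: list[str]
    R: np.ndarray

    def __post_init__(self) -> None:
        if self.R.shape != (len(self.variant_ids), len(self.variant_ids)):
            raise ValueError("R shape does not match variant list")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("R must be symmetric")

    def submatrix(self, ids: list[str]) -> "LDMatrix":
        pos = {v: i for i, v in enumerate(self.variant_ids)}
        idx = [pos[v] for v in ids]
        return LDMatrix(ids, self.R[np.ix_(idx, idx)])


def _mean_impute(g: np.ndarray) -> np.ndarray:
    g = g.astype(float)
    if np.isnan(g).any():
        means = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g[idx] = np.take(means, idx[1])
    return g


def logistic_gwas(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    variants: pd.DataFrame,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant logistic regression GWAS.

    ``genotypes``: (n, m) dosages (NaN = missing, mean-imputed);
    ``variants``: m rows with chrom/pos/id/ref/alt. The effect allele of the
    output is the alt (dosage-counted) allele. Perfect separation or
    non-convergence flags the record and leaves p missing.
    """
    y = np.asarray(phenotype)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("phenotype must be binary with both classes present")
    g = _mean_impute(np.asarray(genotypes))
    n, m = g.shape
    if len(variants) != m:
        raise ValueError("variant table does not match genotype columns")

    base = np.ones((n, 1))
    if covariates is not None:
        base = np.column_stack([base, covariates])

    rows = []
    for j in range(m):
        x = np.column_stack([base, g[:, j]])
        beta = se = p = np.nan
        eaf = g[:, j].mean() / 2.0
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
            beta = float(fit.params[-1])
            se = float(fit.bse[-1])
            if not np.isfinite(se) or se > 50 or not fit.mle_retvals.get("converged", True):
                raise ValueError("separation or non-convergence")
            p = float(2.0 * norm.sf(abs(beta / se)))
            p = max(p, np.finfo(float).tiny)
        except Exception:  # noqa: BLE001 - any fit failure flags the record
            log.warning("variant %s: logistic fit failed (separation?)", variants.iloc[j]["id"])
            beta, se, p = np.nan, np.nan, np.nan
        v = variants.iloc[j]
        rows.append((v["chrom"], int(v["pos"]), v["id"], v["alt"], v["ref"],
                     eaf, beta, se, p, n))
    return pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)


def ld_matrix(genotypes: np.ndarray, variant_ids: list[str]) -> LDMatrix:
    """Pearson dosage correlation after mean-imputing missing calls.

    Zero-variance variants get a zeroed off-diagonal row/column (flagged in
    the log) with a unit diagonal retained.
    """
    g = _mean_impute(np.asarray(genotypes))
    if g.shape[1] < 2:
        raise ValueError("need at least 2 variants for an LD matrix")
    sd = g.std(axis=0)
    degenerate = sd == 0
    safe = np.where(degenerate, 1.0, sd)
    z = (g - g.mean(axis=0)) / safe
    R = (z.T @ z) / g.shape[0]
    R[degenerate, :] = 0.0
    R[:, degenerate] = 0.0
    np.fill_diagonal(R, 1.0)
    if degenerate.any():
        bad = [v for v, d in zip(variant_ids, degenerate) if d]
        log.warning("zero-variance variants in LD region: %s", bad)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return LDMatrix(list(variant_ids), R)


def harmonize(
    sumstats: pd.DataFrame,
    panel_variants: pd.DataFrame,
    mhc: tuple[str, int, int] = MHC_HG38,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align summary statistics to a panel's allele orientation.

    Matching is by (chrom, pos). The harmonized effect allele is the panel's
    alt allele: a direct (alt, ref) match is kept as is; a swapped match
    flips the sign of beta and complements the frequency; any other allele
    pair is dropped. Strand-ambiguous variants (A/T, C/G) and variants in the
    MHC interval (ends inclusive) are removed. Returns (harmonized stats,
    exclusion log with one reason per dropped variant).

    Duplicate (chrom, pos) keys on either side raise.
    """
    for df, name in ((sumstats, "sumstats"), (panel_variants, "panel")):
        dup = df.loc[df.duplicated(subset=["chrom", "pos"], keep=False)]
        if len(dup):
            offenders = sorted(set(zip(dup["chrom"], dup["pos"])))
            raise ValueError(f"duplicate positions in {name}: {offenders[:10]}")

    panel_idx = {
        (r["chrom"], int(r["pos"])): (r["ref"], r["alt"], r["id"])
        for _, r in panel_variants.iterrows()
    }

    kept, dropped = [], []
    chrom_mhc, lo, hi = mhc
    for _, r in sumstats.iterrows():
        key = (r["chrom"], int(r["pos"]))
        ea, oa = r["effect_allele"], r["other_allele"]
        if frozenset({ea, oa}) in _AMBIGUOUS:
            dropped.append((r["id"], "strand_ambiguous"))
            continue
        if r["chrom"] == chrom_mhc and lo <= int(r["pos"]) <= hi:
            dropped.append((r["id"], "mhc"))
            continue
        if key not in panel_idx:
            dropped.append((r["id"], "unmatched_position"))
            continue
        ref, alt, pid = panel_idx[key]
        rec = r.copy()
        rec["id"] = pid
        if (ea, oa) == (alt, ref):
            pass
        elif (ea, oa) == (ref, alt):
            rec["effect_allele"], rec["other_allele"] = alt, ref
            rec["beta"] = -float(r["beta"])
            rec["eaf"] = 1.0 - float(r["eaf"])
        else:
            dropped.append((r["id"], "allele_mismatch"))
            continue
        kept.append(rec)

    harmonized = pd.DataFrame(kept, columns=sumstats.columns).reset_index(drop=True)
    exclusions = pd.DataFrame(dropped, columns=["id", "reason"])
    return harmonized, exclusions
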