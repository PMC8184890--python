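"""Fine-mapping by forward-selection conditional analysis and Wakefield
credible sets.

Loci are +-500 kb windows around genome-wide-significant lead variants,
merged to a fixpoint. Within a locus, conditionally independent signals are
found by forward selection on approximate conditional statistics computed
from summary z-scores and an LD reference:

    z_{i|S} = (z_i - R_iS R_SS^-1 z_S) / sqrt(1 - R_iS R_SS^-1 R_Si)

which is exact for standardized genotypes with a common sample size.
Selection stops when no conditional p-value passes 5e-8.

For each selected SNP, all *other* selected SNPs are conditioned out and a
per-variant approximate Bayes factor is computed from the conditional
effect beta and its standard error sigma:

    r = W / (W + sigma^2),   z = beta / sigma,
    ABF_H0 = (1 / sqrt(1 - r)) * exp(-z^2 r / 2),   ABF = 1 / ABF_H0,

with prior variance W = 0.04 on the log odds ratio (97.5% prior point at an
odds ratio of 1.48). Posterior probabilities of association are the ABFs
normalised over the signal's variants, and the 99% credible set is the
minimal descending-PPA prefix whose cumulative PPA reaches 0.99.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assoc import LDMatrix

log = logging.getLogger(__name__)

__all__ = [
    "FinemapPrior",
    "ABFResult",
    "Locus",
    "CredibleSet",
    "define_loci",
    "conditional_stats",
    "forward_select",
    "abf",
    "ppa_credible_set",
    "leave_one_out_signals",
    "finemap_locus",
    "annotate_credible_set_genes",
]


@dataclass(frozen=True)
class FinemapPrior:
    """Prior and algorithm settings for fine-mapping."""

    W: float = 0.04
    level: float = 0.99
    threshold: float = 5e-8
    half_width: int = 500_000
    collinear_r: float = 0.9

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError("prior variance W must be positive")
        if not (0.0 < self.level < 1.0):
            raise ValueError("credible level must be in (0,1)")


@dataclass
class ABFResult:
    """Shrinkage ratio, Wald statistic and approximate Bayes factor."""

    r: np.ndarray
    z: np.ndarray
    abf_h0: np.ndarray
    abf: np.ndarray


@dataclass
class Locus:
    locus_id: str
    chrom: str
    start: int
    end: int
    lead_ids: list[str] = field(default_factory=list)


@dataclass
class CredibleSet:
    """One conditionally independent signal's 99% credible set.

    ``members`` rows are ordered by descending PPA and carry per-variant
    PPA, cumulative PPA, conditional beta/sigma and the max-PPA flag.
    """

    locus_id: str
    signal_index: int
    conditioned_on: list[str]
    members: pd.DataFrame
    level: float = 0.99

    def max_ppa_variant(self) -> pd.Series:
        return self.members.iloc[0]

    def span(self) -> tuple[str, int, int]:
        chrom = self.members.iloc[0]["chrom"]
        return chrom, int(self.members["pos"].min()), int(self.members["pos"].max())


def _tie_key(df: pd.DataFrame) -> list:
    """Deterministic tie-break: smaller position, then allele order."""
    return [df["pos"].to_numpy(), df["effect_allele"].to_numpy(),
            df["other_allele"].to_numpy()]


def define_loci(
    sumstats: pd.DataFrame,
    threshold: float = 5e-8,
    half_width: int = 500_000,
) -> list[Locus]:
    """Greedy lead selection by ascending p, +-half_width windows, merged
    to a fixpoint per chromosome. Merged loci accumulate their leads."""
    sig = sumstats[sumstats["p"] < threshold].copy()
    if sig.empty:
        return []
    sig = sig.sort_values(
        ["p", "pos", "effect_allele", "other_allele"], kind="mergesort"
    )
    loci: list[Locus] = []
    for _, lead in sig.iterrows():
        pos = int(lead["pos"])
        covered = any(
            loc.chrom == lead["chrom"] and loc.start <= pos <= loc.end for loc in loci
        )
        if covered:
            continue
        loci.append(Locus(
            locus_id="", chrom=lead["chrom"],
            start=max(1, pos - half_width), end=pos + half_width,
            lead_ids=[lead["id"]],
        ))
        # merge to fixpoint
        merged = True
        while merged:
            merged = False
            for i in range(len(loci)):
                for j in range(i + 1, len(loci)):
                    a, b = loci[i], loci[j]
                    if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                        loci[i] = Locus("", a.chrom, min(a.start, b.start),
                                        max(a.end, b.end), a.lead_ids + b.lead_ids)
                        del loci[j]
                        merged = True
                        break
                if merged:
                    break
    loci.sort(key=lambda l: (l.chrom, l.start))
    for k, loc in enumerate(loci):
        loc.locus_id = f"{loc.chrom}:{loc.start}-{loc.end}"
        log.debug("locus %d: %s leads=%s", k, loc.locus_id, loc.lead_ids)
    return loci


def conditional_stats(
    z: np.ndarray,
    sigma: np.ndarray,
    R: LDMatrix,
    conditioning: list[str],
) -> pd.DataFrame:
    """Approximate conditional z, beta and sigma given a conditioning set.

    Variants in the conditioning set get conditional z = 0; variants whose
    conditional variance term falls below 1e-8 are masked (collinear with
    the set). Conditional beta = z_cond * sigma with sigma unchanged. An
    empty set returns the marginal statistics.
    """
    ids = R.variant_ids
    z = np.asarray(z, float)
    sigma = np.asarray(sigma, float)
    m = len(ids)
    out = pd.DataFrame({"id": ids, "z_cond": z.copy(), "sigma": sigma,
                        "masked": np.zeros(m, bool)})
    if not conditioning:
        out["beta_cond"] = out["z_cond"] * sigma
        out["p_cond"] = 2.0 * norm.sf(np.abs(out["z_cond"]))
        return out

    pos = {v: i for i, v in enumerate(ids)}
    S = [pos[v] for v in conditioning]
    if len(set(S)) != len(S):
        raise ValueError("duplicate conditioning variants")
    # collinearity pruning inside S: drop later members nearly determined
    keepS: list[int] = []
    for si in S:
        if keepS:
            sub = R.R[np.ix_(keepS + [si], keepS + [si])]
            if np.linalg.matrix_rank(sub, tol=1e-6) <= len(keepS):
                log.warning("conditioning variant %s collinear; pruned", ids[si])
                continue
        keepS.append(si)
    S = keepS
    Rss = R.R[np.ix_(S, S)]
    Ris = R.R[:, S]
    zs = z[S]
    adj = Ris @ np.linalg.solve(Rss, zs)
    var = 1.0 - np.einsum("ij,ij->i", Ris, np.linalg.solve(Rss, Ris.T).T)

    z_cond = np.zeros(m)
    masked = np.zeros(m, bool)
    ok = var > 1e-8
    z_cond[ok] = (z[ok] - adj[ok]) / np.sqrt(var[ok])
    masked[~ok] = True
    z_cond[S] = 0.0
    masked[S] = False
    out["z_cond"] = z_cond
    out["masked"] = masked
    out["beta_cond"] = z_cond * sigma
    out["p_cond"] = np.where(masked, np.nan, 2.0 * norm.sf(np.abs(z_cond)))
    return out


def forward_select(
    locus_stats: pd.DataFrame,
    R: LDMatrix,
    prior: FinemapPrior = FinemapPrior(),
) -> list[str]:
    """Forward selection of conditionally independent signals in a locus.

    Starts from the smallest-p variant, conditions on everything selected so
    far, and adds the best conditional signal while it passes the
    genome-wide threshold. Candidates with |r| above the collinearity guard
    to any selected SNP are excluded from conditional testing.
    """
    df = locus_stats.reset_index(drop=True)
    if not (df["p"] < prior.threshold).any():
        raise ValueError("locus has no genome-wide-significant variant")
    order = df.sort_values(["p", "pos", "effect_allele", "other_allele"],
                           kind="mergesort")
    selected = [order.iloc[0]["id"]]

    ids = R.variant_ids
    pos = {v: i for i, v in enumerate(ids)}
    z = (df.set_index("id").loc[ids, "beta"] / df.set_index("id").loc[ids, "se"]).to_numpy()
    sigma = df.set_index("id").loc[ids, "se"].to_numpy()
    posdf = df.set_index("id").loc[ids]

    while True:
        cond = conditional_stats(z, sigma, R, selected)
        sel_idx = [pos[v] for v in selected]
        collinear = (np.abs(R.R[:, sel_idx]) > prior.collinear_r).any(axis=1)
        eligible = (~cond["masked"].to_numpy() & ~collinear
                    & ~np.isin(ids, selected))
        if not eligible.any():
            log.warning("all candidates collinear with conditioning set; stopping")
            break
        cand = cond[eligible].copy()
        cand["pos"] = posdf.loc[cand["id"], "pos"].to_numpy()
        cand["effect_allele"] = posdf.loc[cand["id"], "effect_allele"].to_numpy()
        cand["other_allele"] = posdf.loc[cand["id"], "other_allele"].to_numpy()
        cand = cand.sort_values(["p_cond", "pos", "effect_allele", "other_allele"],
                                kind="mergesort")
        best = cand.iloc[0]
        if best["p_cond"] >= prior.threshold or not np.isfinite(best["p_cond"]):
            break
        selected.append(best["id"])
    return selected


def abf(beta, sigma, W: float = 0.04) -> ABFResult:
    """Per-variant approximate Bayes factor for association vs null."""
    beta = np.asarray(beta, float)
    sigma = np.asarray(sigma, float)
    if np.any(~np.isfinite(beta)) or np.any(~np.isfinite(sigma)):
        raise ValueError("non-finite inputs to abf")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    r = W / (W + sigma**2)
    z = beta / sigma
    log_abf_h0 = -0.5 * np.log1p(-r) - 0.5 * z**2 * r
    return ABFResult(r=r, z=z, abf_h0=np.exp(log_abf_h0), abf=np.exp(-log_abf_h0))


def ppa_credible_set(
    variants: pd.DataFrame,
    abfs: np.ndarray,
    level: float = 0.99,
    locus_id: str = "locus",
    signal_index: int = 0,
    conditioned_on: list[str] | None = None,
) -> CredibleSet:
    """Normalise ABFs to PPAs and take the minimal descending-PPA prefix
    reaching ``level``. Ties break by position then allele order."""
    abfs = np.asarray(abfs, float)
    if len(variants) == 0:
        raise ValueError("empty signal")
    total = abfs.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("degenerate signal: ABFs sum to zero or non-finite")
    df = variants.copy().reset_index(drop=True)
    df["ppa"] = abfs / total
    df = df.sort_values(["ppa", "pos", "effect_allele", "other_allele"],
                        ascending=[False, True, True, True], kind="mergesort")
    df["cum_ppa"] = df["ppa"].cumsum()
    n_keep = int(np.searchsorted(df["cum_ppa"].to_numpy(), level - 1e-12) + 1)
    n_keep = min(n_keep, len(df))
    members = df.iloc[:n_keep].reset_index(drop=True)
    members["is_max_ppa"] = [i == 0 for i in range(len(members))]
    return CredibleSet(
        locus_id=locus_id, signal_index=signal_index,
        conditioned_on=list(conditioned_on or []), members=members, level=level,
    )


def leave_one_out_signals(
    locus_stats: pd.DataFrame,
    selected: list[str],
    R: LDMatrix,
    prior: FinemapPrior = FinemapPrior(),
    locus_id: str = "locus",
) -> list[CredibleSet]:
    """One credible set per selected SNP, conditioning out all the others.

    A singleton selection reduces to credible sets on the marginal
    statistics. PPAs are computed over all unmasked variants of the locus.
    """
    df = locus_stats.set_index("id").loc[R.variant_ids].reset_index()
    z = (df["beta"] / df["se"]).to_numpy()
    sigma = df["se"].to_numpy()

    sets = []
    for k, snp in enumerate(selected):
        others = [s for s in selected if s != snp]
        cond = conditional_stats(z, sigma, R, others)
        keep = ~cond["masked"].to_numpy()
        res = abf(cond.loc[keep, "beta_cond"], cond.loc[keep, "sigma"], prior.W)
        sub = df.loc[keep, ["id", "chrom", "pos", "effect_allele",
                            "other_allele", "eaf"]].copy()
        sub["beta_cond"] = cond.loc[keep, "beta_cond"].to_numpy()
        sub["sigma"] = cond.loc[keep, "sigma"].to_numpy()
        sets.append(ppa_credible_set(
            sub, res.abf, level=prior.level, locus_id=locus_id,
            signal_index=k, conditioned_on=others,
        ))
    return sets


def finemap_locus(
    locus_stats: pd.DataFrame,
    R: LDMatrix,
    prior: FinemapPrior = FinemapPrior(),
    locus_id: str = "locus",
) -> list[CredibleSet]:
    """Forward selection followed by leave-one-out credible sets."""
    selected = forward_select(locus_stats, R, prior)
    return leave_one_out_signals(locus_stats, selected, R, prior, locus_id)


def annotate_credible_set_genes(
    span: tuple[str, int, int],
    gene_table: pd.DataFrame,
    max_dist: int = 500_000,
) -> str:
    """Gene annotation for a credible-set span.

    Genes whose TSS falls inside the span are reported plainly; if more than
    3 TSS fall inside, the annotation is "-". Otherwise the two closest TSS
    within ``max_dist`` of the span ends are appended as NAME(kb), with the
    distance rounded to the nearest kb.
    """
    chrom, start, end = span
    if gene_table.empty:
        return ""
    genes = gene_table[gene_table["chrom"] == chrom]
    inside = genes[(genes["tss"] >= start) & (genes["tss"] <= end)]
    if len(inside) > 3:
        return "-"
    parts = list(inside.sort_values("tss")["name"])
    outside = genes[(genes["tss"] < start) | (genes["tss"] > end)].copy()
    if len(outside):
        outside["dist"] = np.where(outside["tss"] < start,
                                   start - outside["tss"], outside["tss"] - end)
        near = outside[outside["dist"] <= max_dist].sort_values(["dist", "name"])
        for _, g in near.head(2).iterrows():
            parts.append(f"{g['name']}({int(round(g['dist'] / 1000.0))})")
    return ",".join(parts)
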