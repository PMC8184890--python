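"""Polygenic risk score construction and scoring.

The score is a weighted sum of risk-allele dosages,

    S_hat = sum_i beta_i * G_i,        G_i in {0, 1, 2},

with one term per conditionally independent fine-mapping signal: the variant
with the highest posterior probability of association in that signal's 99%
credible set, weighted by its conditional effect size. Raw scores are
quantile-normalised to the standard normal so effect sizes are on a per-SD
scale and comparable across score definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = ["ScoreWeights", "build_score", "apply_score", "normal_scores"]

SCORING_COLUMNS = [
    "rsID", "chr_name", "chr_position", "effect_allele", "other_allele",
    "effect_weight",
]


@dataclass
class ScoreWeights:
    """The score: one (variant, effect allele, weight) entry per signal.

    ``table`` columns: rsID, chr_name, chr_position, effect_allele,
    other_allele, effect_weight, signal, and optionally effect_allele_freq
    (used to impute missing dosages).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SCORING_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"score table missing columns: {missing}")
        if not np.all(np.isfinite(self.table["effect_weight"].to_numpy(float))):
            raise ValueError("score weights must be finite")

    def __len__(self) -> int:
        return len(self.table)


def build_score(credible_sets) -> ScoreWeights:
    """Assemble score weights from fine-mapping credible sets.

    One entry per independent signal: the signal's max-PPA variant with its
    conditional effect size as the weight. Signals sharing a max-PPA variant
    indicate non-independent signals and raise.
    """
    sets = list(credible_sets)
    if not sets:
        raise ValueError("no credible sets supplied")
    rows = []
    for cs in sets:
        top = cs.max_ppa_variant()
        rows.append(
            {
                "rsID": top["id"],
                "chr_name": top["chrom"],
                "chr_position": int(top["pos"]),
                "effect_allele": top["effect_allele"],
                "other_allele": top["other_allele"],
                "effect_weight": float(top["beta_cond"]),
                "signal": f"{cs.locus_id}.{cs.signal_index}",
                "effect_allele_freq": float(top.get("eaf", np.nan)),
            }
        )
    table = pd.DataFrame(rows)
    dup = table["rsID"][table["rsID"].duplicated()]
    if len(dup):
        raise ValueError(
            f"variant(s) {sorted(set(dup))} appear in more than one signal; "
            "signals are not independent"
        )
    return ScoreWeights(table=table)


def apply_score(genotypes: pd.DataFrame, weights: ScoreWeights) -> np.ndarray:
    """Compute raw scores for a cohort.

    ``genotypes``: individuals x variants dosage frame (columns = rsID),
    NaN for missing calls. Missing dosages are imputed as twice the effect
    allele frequency — taken from the weights table when present, else from
    the cohort mean dosage. A variant entirely absent from the cohort with no
    frequency available raises.
    """
    total = np.zeros(len(genotypes))
    freqs = {}
    if "effect_allele_freq" in weights.table.columns:
        freqs = dict(
            zip(weights.table["rsID"], weights.table["effect_allele_freq"])
        )
    for _, row in weights.table.iterrows():
        vid, w = row["rsID"], float(row["effect_weight"])
        if vid in genotypes.columns:
            g = genotypes[vid].to_numpy(float)
            if np.isnan(g).any():
                fill = 2.0 * freqs.get(vid, np.nan)
                if np.isnan(fill):
                    obs = g[~np.isnan(g)]
                    if len(obs) == 0:
                        raise ValueError(
                            f"variant {vid}: all dosages missing and no "
                            "effect allele frequency available"
                        )
                    fill = float(obs.mean())
                g = np.where(np.isnan(g), fill, g)
        else:
            f = freqs.get(vid, np.nan)
            if np.isnan(f):
                raise ValueError(
                    f"variant {vid} absent from genotypes and no effect "
                    "allele frequency available"
                )
            g = np.full(len(genotypes), 2.0 * f)
        total += w * g
    return total


def normal_scores(values) -> np.ndarray:
    """Quantile-normalise to standard normal via Phi^-1((rank - 0.5) / n).

    Ties receive the average rank. Invariant under monotone transforms of
    the input; empirical mean is ~0 by symmetry of the rank grid.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("normal_scores expects a 1-D array")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values to normalise")
    if np.ptp(x) == 0.0:
        warnings.warn("constant input to normal_scores; returning zeros")
        return np.zeros(n)
    ranks = rankdata(x, method="average")
    return norm.ppf((ranks - 0.5) / n)
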