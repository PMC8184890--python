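"""Synthetic cohorts with the statistical structure the pipeline assumes.

Everything downstream of this module (GWAS, fine-mapping, scoring, survival
modelling) is exercised on data produced here: LD-blocked biallelic
haplotypes, a sparse-architecture case-control phenotype, a multi-arm trial
cohort whose adverse-event hazards depend on a polygenic score, and
longitudinal TSH lab series reproducing the hyperthyroidism-before-
hypothyroidism clinical course.

Haplotypes use a first-order copying process within LD blocks: variant *j*
copies variant *j−1*'s allele with probability ``rho`` and otherwise draws a
fresh Bernoulli allele whose rate is chosen so the marginal frequency hits
its target. For equal-frequency neighbours the adjacent-variant correlation
is exactly ``rho`` and decays geometrically with distance; across blocks the
expected correlation is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .rng import substream

__all__ = [
    "BlockSpec",
    "HaplotypePanel",
    "CausalArchitecture",
    "GwasCohort",
    "ArmSpec",
    "CovariateEffects",
    "CensoringSpec",
    "TrialPatient",
    "LabSeries",
    "simulate_haplotypes",
    "simulate_gwas_cohort",
    "simulate_trial_cohort",
    "simulate_lab_series",
]

# ref/alt pairs that survive strand-ambiguity filtering (no A/T, no C/G)
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class BlockSpec:
    """One LD block: ``n_variants`` with target frequencies drawn uniformly
    from ``freq_range`` and adjacent-variant copying probability ``rho``."""

    n_variants: int
    freq_range: tuple[float, float] = (0.05, 0.5)
    rho: float = 0.8

    def validate(self) -> None:
        if self.n_variants < 1:
            raise ValueError("block must contain at least one variant")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"invalid frequency range {self.freq_range}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"within-block correlation must be in [0,1), got {self.rho}")


@dataclass
class HaplotypePanel:
    """A panel of phased haplotypes with block-structured LD.

    Attributes
    ----------
    variants
        One row per variant: ``chrom, pos, id, ref, alt, freq, block``.
    haplotypes
        ``(n_haplotypes, n_variants)`` 0/1 matrix of alt-allele carriage.
    """

    variants: pd.DataFrame
    haplotypes: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def realized_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def genotype_matrix(self) -> np.ndarray:
        """Pair consecutive haplotypes into diploid dosages (0/1/2)."""
        n = (self.n_haplotypes // 2) * 2
        return (self.haplotypes[0:n:2] + self.haplotypes[1:n:2]).astype(np.int8)

    def sample_genotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` diploid genotypes by random union of two haplotypes."""
        i = rng.integers(0, self.n_haplotypes, size=n)
        j = rng.integers(0, self.n_haplotypes, size=n)
        return (self.haplotypes[i] + self.haplotypes[j]).astype(np.int8)


def simulate_haplotypes(
    n_haplotypes: int,
    block_spec: list[BlockSpec],
    seed: int,
    chrom: str = "chr1",
    start_pos: int = 1_000_000,
    variant_spacing: int = 1_000,
    block_gap: int = 200_000,
) -> HaplotypePanel:
    """Simulate LD-blocked biallelic haplotypes.

    Deterministic given ``seed``. Within each block the copying process
    yields geometric decay of pairwise correlation; blocks are mutually
    independent and separated by ``block_gap`` bp.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if not block_spec:
        raise ValueError("block_spec must contain at least one block")
    for b in block_spec:
        b.validate()

    rng = substream(seed, "haplotypes")
    cols: list[np.ndarray] = []
    rows = []
    pos = start_pos
    k = 0
    for bi, spec in enumerate(block_spec):
        lo, hi = spec.freq_range
        # one base frequency per block with small per-variant jitter: keeps
        # the copying process's marginal on target without clipping the
        # fresh-draw rate
        base = rng.uniform(lo, hi)
        freqs = np.clip(base + rng.uniform(-0.02, 0.02, size=spec.n_variants),
                        0.01, 0.99)
        marginal = 0.0
        for v in range(spec.n_variants):
            f = freqs[v]
            if v == 0:
                col = (rng.random(n_haplotypes) < f).astype(np.uint8)
                marginal = f
            else:
                # fresh-draw rate chosen so the marginal frequency stays on
                # target despite copying from the previous variant
                q = (f - spec.rho * marginal) / (1.0 - spec.rho)
                q = float(np.clip(q, 1e-3, 1 - 1e-3))
                copy = rng.random(n_haplotypes) < spec.rho
                fresh = (rng.random(n_haplotypes) < q).astype(np.uint8)
                col = np.where(copy, cols[-1], fresh).astype(np.uint8)
                marginal = spec.rho * marginal + (1.0 - spec.rho) * q
            ref, alt = _ALLELE_PAIRS[rng.integers(0, len(_ALLELE_PAIRS))]
            rows.append((chrom, pos, f"rs{k + 1}", ref, alt, f, bi))
            cols.append(col)
            pos += variant_spacing
            k += 1
        pos += block_gap

    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "ref", "alt", "freq", "block"]
    )
    return HaplotypePanel(variants=variants, haplotypes=np.column_stack(cols))


@dataclass
class CausalArchitecture:
    """Sparse causal architecture for a liability/logistic phenotype.

    ``log_odds`` maps variant id -> per-allele log odds ratio; all other
    variants have log OR exactly 0. The intercept is solved to hit
    ``prevalence`` in the source population.
    """

    log_odds: dict[str, float]
    prevalence: float = 0.05

    def effect_vector(self, variant_ids: pd.Series) -> np.ndarray:
        beta = np.zeros(len(variant_ids))
        idx = {vid: i for i, vid in enumerate(variant_ids)}
        for vid, b in self.log_odds.items():
            if vid not in idx:
                raise ValueError(f"causal variant {vid} not in panel")
            beta[idx[vid]] = float(b)
        return beta


@dataclass
class GwasCohort:
    """Case-control genotypes with the generating truth attached."""

    genotypes: np.ndarray  # (n, m) dosages 0/1/2
    phenotype: np.ndarray  # (n,) 0/1
    variants: pd.DataFrame
    architecture: CausalArchitecture
    intercept: float


def _solve_intercept(lp: np.ndarray, prevalence: float) -> float:
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence must be in (0,1), got {prevalence}")

    def gap(alpha: float) -> float:
        return float(expit(alpha + lp).mean() - prevalence)

    return brentq(gap, -40.0, 40.0)


def simulate_gwas_cohort(
    panel: HaplotypePanel,
    architecture: CausalArchitecture,
    n_cases: int,
    n_controls: int,
    seed: int,
    max_batches: int = 4000,
) -> GwasCohort:
    """Quota-sample a case-control cohort from the logistic liability model.

    Genotypes are drawn from the panel, case status from
    ``P(case) = expit(alpha + sum beta_j g_j)``, and sampling continues until
    both quotas are exactly filled — mirroring case-control ascertainment
    rather than population sampling.
    """
    beta = architecture.effect_vector(panel.variants["id"])
    rng = substream(seed, "gwas-cohort")
    calib = panel.sample_genotypes(20_000, rng)
    alpha = _solve_intercept(calib @ beta, architecture.prevalence)

    n = n_cases + n_controls
    batch = max(2048, n)
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    got_cases = got_controls = 0
    for _ in range(max_batches):
        g = panel.sample_genotypes(batch, rng)
        p = expit(alpha + g @ beta)
        y = rng.random(batch) < p
        if got_cases < n_cases:
            take = g[y][: n_cases - got_cases]
            cases.append(take)
            got_cases += len(take)
        if got_controls < n_controls:
            take = g[~y][: n_controls - got_controls]
            controls.append(take)
            got_controls += len(take)
        if got_cases >= n_cases and got_controls >= n_controls:
            break
    else:
        raise RuntimeError(
            "case/control quotas not met; prevalence "
            f"{architecture.prevalence} unattainable at requested sizes"
        )

    genotypes = np.vstack([np.vstack(cases), np.vstack(controls)])
    phenotype = np.r_[np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    perm = substream(seed, "gwas-shuffle").permutation(n)
    return GwasCohort(
        genotypes=genotypes[perm],
        phenotype=phenotype[perm],
        variants=panel.variants,
        architecture=architecture,
        intercept=alpha,
    )


# ---------------------------------------------------------------------------
# trial cohort


# baseline daily hazards of thyroid irAE chosen so that over a typical
# follow-up roughly 30% of checkpoint-inhibitor-treated patients and ~3% of
# chemotherapy controls develop hypothyroidism — the event proportions the
# trial analysis is designed around
ACTIVE_IRAE_HAZARD = 1.0 / 2000.0
CONTROL_IRAE_HAZARD = 5.5e-5


@dataclass(frozen=True)
class ArmSpec:
    """One trial arm: size, treatment flag, and baseline hazards (per day).

    ``irae_hazard`` defaults by treatment flag: active arms use
    ``ACTIVE_IRAE_HAZARD``, control arms ``CONTROL_IRAE_HAZARD``.
    """

    name: str
    n: int
    active: bool
    irae_hazard: float | None = None
    os_hazard: float = 1.0 / 900.0

    @property
    def irae_hazard_(self) -> float:
        if self.irae_hazard is not None:
            return self.irae_hazard
        return ACTIVE_IRAE_HAZARD if self.active else CONTROL_IRAE_HAZARD

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"arm {self.name}: size must be positive")
        if self.irae_hazard_ < 0 or self.os_hazard < 0:
            raise ValueError(f"arm {self.name}: negative baseline hazard")


@dataclass(frozen=True)
class CovariateEffects:
    """Log hazard ratios of the generating model.

    ``prs_log_hr`` acts on the quantile-normalised score (per-SD scale);
    ``irae_os_log_hr`` switches on at hypothyroidism onset in the OS hazard
    (a genuine time-dependent effect). Lab effects are per-SD of the
    normalised baseline values. Hyperthyroidism shares the PRS effect at a
    reduced strength.
    """

    gender_log_hr: float = 0.0
    tsh_log_hr: float = 0.0
    ft4_log_hr: float = 0.0
    ft3_log_hr: float = 0.0
    irae_os_log_hr: float = 0.0
    prs_active_only: bool = True
    hyper_hazard_frac: float = 0.4
    hyper_prs_frac: float = 0.5
    weibull_shape: float = 1.0  # 1.0 = exponential
    # when set, the irAE hazard acts through the normalised sub-score of
    # these variant indices only — the "subset of lifetime-risk variants
    # drives treatment-emergent risk" architecture
    driver_variants: tuple[int, ...] | None = None


@dataclass(frozen=True)
class CensoringSpec:
    """Administrative censoring uniform on [low, high] days plus optional
    exponential dropout."""

    admin_low: float = 400.0
    admin_high: float = 1200.0
    dropout_hazard: float = 0.0


@dataclass
class TrialPatient:
    """One trial participant with genotype, labs and outcome data.

    Gender is encoded 1 = female, 0 = male.
    """

    patient_id: str
    arm: str
    active: bool
    gender: int
    dosages: np.ndarray
    prs_raw: float
    prs: float
    tsh: float
    ft4: float
    ft3: float
    hypo_time: float
    hypo_event: int
    hyper_time: float
    hyper_event: int
    os_time: float
    os_event: int
    eigenvectors: np.ndarray = field(default_factory=lambda: np.zeros(5))


def default_score_table(m: int = 20, seed: int = 7) -> pd.DataFrame:
    """A desk-scale stand-in score: ``m`` independent variants with
    frequencies U(0.1, 0.5) and weights N(0, 0.15)."""
    rng = substream(seed, "default-score")
    return pd.DataFrame(
        {
            "variant": [f"rs{i + 1}" for i in range(m)],
            "freq": rng.uniform(0.1, 0.5, size=m),
            "effect_weight": rng.normal(0.0, 0.15, size=m),
        }
    )


def _weibull_time(u: np.ndarray, hazard: np.ndarray, shape: float) -> np.ndarray:
    # inverse-CDF: S(t) = exp(-(h t)^k) with scale folded into h
    e = -np.log(u)
    return np.power(e, 1.0 / shape) / hazard


def simulate_trial_cohort(
    n_patients: int,
    arm_spec: list[ArmSpec],
    prs_log_hr: float,
    covariate_effects: CovariateEffects | None = None,
    censoring_spec: CensoringSpec | None = None,
    seed: int = 0,
    score_table: pd.DataFrame | None = None,
) -> list[TrialPatient]:
    """Simulate a multi-arm trial cohort with PRS-dependent irAE hazards.

    The hypothyroidism-irAE hazard is
    ``h0(arm) * exp(prs_log_hr * PRS + covariate terms)`` with the PRS effect
    restricted to active arms when ``prs_active_only``; overall survival is
    piecewise-exponential with the hazard multiplied by
    ``exp(irae_os_log_hr)`` after hypothyroidism onset. Observed times are
    latent times truncated by censoring and death.
    """
    eff = covariate_effects or CovariateEffects()
    cens = censoring_spec or CensoringSpec()
    if not arm_spec:
        raise ValueError("arm_spec must be non-empty")
    for a in arm_spec:
        a.validate()
    if sum(a.n for a in arm_spec) != n_patients:
        raise ValueError("arm sizes must partition n_patients")
    if not np.isfinite(prs_log_hr):
        raise ValueError("prs_log_hr must be finite")

    from .prscore import normal_scores  # local import: avoids cycle at import time

    score = score_table if score_table is not None else default_score_table()
    rng = substream(seed, "trial")
    n = n_patients
    m = len(score)

    dosages = rng.binomial(2, score["freq"].to_numpy(), size=(n, m)).astype(np.int8)
    prs_raw = dosages @ score["effect_weight"].to_numpy()
    prs = normal_scores(prs_raw)

    gender = rng.integers(0, 2, size=n)
    tsh = np.exp(rng.normal(np.log(1.8), 0.45, size=n))
    ft4 = rng.normal(15.0, 2.0, size=n)
    ft3 = rng.normal(4.5, 0.6, size=n)
    evs = rng.normal(0.0, 1.0, size=(n, 5))

    arm_names = np.concatenate([[a.name] * a.n for a in arm_spec])
    active = np.concatenate([[a.active] * a.n for a in arm_spec]).astype(bool)
    h0_irae = np.concatenate([[a.irae_hazard_] * a.n for a in arm_spec])
    h0_os = np.concatenate([[a.os_hazard] * a.n for a in arm_spec])

    lab_lp = (
        eff.gender_log_hr * gender
        + eff.tsh_log_hr * normal_scores(tsh)
        + eff.ft4_log_hr * normal_scores(ft4)
        + eff.ft3_log_hr * normal_scores(ft3)
    )
    if eff.driver_variants is not None:
        idx = list(eff.driver_variants)
        hazard_score = normal_scores(
            dosages[:, idx] @ score["effect_weight"].to_numpy()[idx])
    else:
        hazard_score = prs
    prs_term = prs_log_hr * hazard_score
    if eff.prs_active_only:
        prs_term = np.where(active, prs_term, 0.0)

    h_hypo = h0_irae * np.exp(prs_term + lab_lp)
    h_hyper = h0_irae * eff.hyper_hazard_frac * np.exp(eff.hyper_prs_frac * prs_term)
    t_hypo = _weibull_time(rng.random(n), h_hypo, eff.weibull_shape)
    t_hyper = _weibull_time(rng.random(n), h_hyper, eff.weibull_shape)

    # piecewise-exponential OS: hazard jumps by exp(irae_os_log_hr) at hypo onset
    e = rng.exponential(size=n)
    pre = h0_os * t_hypo
    post_h = h0_os * np.exp(eff.irae_os_log_hr)
    t_os = np.where(e <= pre, e / h0_os, t_hypo + (e - pre) / post_h)

    censor = rng.uniform(cens.admin_low, cens.admin_high, size=n)
    if cens.dropout_hazard > 0:
        censor = np.minimum(censor, rng.exponential(1.0 / cens.dropout_hazard, size=n))

    followup = np.minimum(t_os, censor)
    os_event = (t_os <= censor).astype(int)
    hypo_event = (t_hypo <= followup).astype(int)
    hyper_event = (t_hyper <= followup).astype(int)

    patients = []
    for i in range(n):
        patients.append(
            TrialPatient(
                patient_id=f"P{i + 1:05d}",
                arm=str(arm_names[i]),
                active=bool(active[i]),
                gender=int(gender[i]),
                dosages=dosages[i],
                prs_raw=float(prs_raw[i]),
                prs=float(prs[i]),
                tsh=float(tsh[i]),
                ft4=float(ft4[i]),
                ft3=float(ft3[i]),
                hypo_time=float(min(t_hypo[i], followup[i])),
                hypo_event=int(hypo_event[i]),
                hyper_time=float(min(t_hyper[i], followup[i])),
                hyper_event=int(hyper_event[i]),
                os_time=float(followup[i]),
                os_event=int(os_event[i]),
                eigenvectors=evs[i],
            )
        )
    return patients


# ---------------------------------------------------------------------------
# lab series


@dataclass
class LabSeries:
    """Longitudinal TSH measurements for one patient (days strictly
    increasing, TSH in mU/L), plus optional symptomatic-event days."""

    patient_id: str
    days: np.ndarray
    tsh: np.ndarray
    symptomatic_days: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("lab days must be strictly increasing")
        if np.any(self.tsh < 0):
            raise ValueError("TSH must be non-negative")


def simulate_lab_series(
    patients: list[TrialPatient],
    abnormal_threshold: float = 5.0,
    ordering_prob: float = 0.857,
    symptomatic_lag_days: int = 7,
    seed: int = 0,
    visit_interval: int = 21,
    suppressed_value: float = 0.2,
    elevated_value: float = 7.5,
) -> list[LabSeries]:
    """Generate TSH series consistent with each patient's thyroid events.

    For patients carrying both thyroid irAE, hyperthyroidism (suppressed TSH)
    precedes hypothyroidism (TSH above ``abnormal_threshold``) with
    probability ``ordering_prob`` — the inflammation-then-failure clinical
    course. Symptomatic hypothyroidism events are placed at most
    ``symptomatic_lag_days`` after the first abnormal TSH measurement.
    """
    if not (0.0 <= ordering_prob <= 1.0):
        raise ValueError("ordering_prob must be in [0,1]")
    if symptomatic_lag_days < 0:
        raise ValueError("symptomatic_lag_days must be non-negative")

    rng = substream(seed, "labs")
    out = []
    for p in patients:
        has_hypo = bool(p.hypo_event)
        has_hyper = bool(p.hyper_event)
        d_hypo = p.hypo_time if has_hypo else None
        d_hyper = p.hyper_time if has_hyper else None
        if has_hypo and has_hyper:
            lo, hi = sorted([p.hypo_time, p.hyper_time])
            # keep at least two visits between the phases so both onsets are
            # observable on the visit grid
            hi = max(hi, lo + 2 * visit_interval)
            if rng.random() < ordering_prob:
                d_hyper, d_hypo = lo, hi
            else:
                d_hypo, d_hyper = lo, hi

        end = max(p.os_time, visit_interval)
        for d in (d_hypo, d_hyper):
            if d is not None:
                end = max(end, d + visit_interval)
        days = np.arange(0.0, end + visit_interval, visit_interval)
        base = np.clip(np.exp(rng.normal(np.log(1.8), 0.3, size=len(days))), 0.6, 4.0)
        tsh = base.copy()

        if has_hyper:
            hyper_end = d_hypo if (has_hypo and d_hypo > d_hyper) else days[-1] + 1
            mask = (days >= d_hyper) & (days < hyper_end)
            tsh[mask] = suppressed_value
        if has_hypo:
            if has_hyper and d_hyper > d_hypo:
                mask = (days >= d_hypo) & (days < d_hyper)
            else:
                mask = days >= d_hypo
            tsh[mask] = elevated_value * np.exp(rng.normal(0, 0.05, size=int(mask.sum())))

        symptomatic: dict[str, float] = {}
        if has_hypo:
            abnormal = days[tsh > abnormal_threshold]
            if len(abnormal):
                symptomatic["hypothyroidism"] = float(
                    abnormal[0] + rng.integers(0, symptomatic_lag_days + 1)
                )
        series = LabSeries(patient_id=p.patient_id, days=days, tsh=tsh,
                           symptomatic_days=symptomatic)
        series.validate()
        out.append(series)
    return out
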