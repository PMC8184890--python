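"""Non-negative L1-penalized Cox regression for PRS variant importance.

The design matrix has one column per score variant with entry
``risk-allele dosage x conditional effect size`` (non-negative by
construction once weights are oriented to risk alleles), plus unpenalized,
unconstrained genotype-eigenvector columns. The solver is cyclic coordinate
descent inside an iteratively reweighted least-squares approximation of the
Breslow partial likelihood; variant coefficients are clipped at zero.

The penalty is chosen by k-fold cross-validation on out-of-fold partial-
likelihood deviance over a fixed logarithmic grid, repeated with fresh fold
splits; the per-repeat optima are combined by geometric mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prscore import ScoreWeights
from .rng import substream

log = logging.getLogger(__name__)

__all__ = [
    "LassoDesign",
    "LassoFit",
    "ImportanceTable",
    "build_lasso_design",
    "breslow_derivatives",
    "breslow_loglik",
    "fit_nonneg_cox_lasso",
    "lambda_max",
    "lambda_grid",
    "cv_select_lambda",
    "importance",
]


@dataclass
class LassoDesign:
    """Design for the penalized Cox fit (simple survival, no delayed entry).

    ``penalized`` marks the L1-penalized, non-negativity-constrained variant
    columns; the remaining (eigenvector) columns are free.
    """

    X: np.ndarray
    time: np.ndarray
    status: np.ndarray
    penalized: np.ndarray
    names: list[str]
    effect_sizes: np.ndarray  # conditional effect size per penalized column

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.time = np.asarray(self.time, float)
        self.status = np.asarray(self.status, int)
        self.penalized = np.asarray(self.penalized, bool)
        if np.any(self.X[:, self.penalized] < 0):
            raise ValueError("penalized design entries must be non-negative")
        if np.any(self.time <= 0):
            raise ValueError("event/censoring times must be positive")

    def subset(self, idx: np.ndarray) -> "LassoDesign":
        return LassoDesign(self.X[idx], self.time[idx], self.status[idx],
                           self.penalized, self.names, self.effect_sizes)


@dataclass
class LassoFit:
    coef: np.ndarray
    lam: float
    converged: bool
    n_iter: int


@dataclass
class ImportanceTable:
    """Retained variants with normalised re-weighted importances."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def retained(self) -> pd.DataFrame:
        if self.table.empty:
            return self.table
        return self.table[self.table["retained"]]


def build_lasso_design(
    dosages: pd.DataFrame,
    weights: ScoreWeights,
    time: np.ndarray,
    status: np.ndarray,
    eigenvectors: np.ndarray | None = None,
) -> LassoDesign:
    """Assemble the N x P variant design plus eigenvector columns.

    Weights with negative effect sizes are re-oriented to the risk allele
    (dosage -> 2 - dosage, weight -> |weight|) so all penalized entries are
    non-negative.
    """
    cols, names, effs = [], [], []
    for _, row in weights.table.iterrows():
        vid, w = row["rsID"], float(row["effect_weight"])
        g = dosages[vid].to_numpy(float)
        if w < 0:
            g, w = 2.0 - g, -w
        cols.append(g * w)
        names.append(vid)
        effs.append(w)
    X = np.column_stack(cols)
    pen = np.ones(X.shape[1], bool)
    if eigenvectors is not None:
        ev = np.atleast_2d(np.asarray(eigenvectors, float))
        X = np.column_stack([X, ev])
        names += [f"ev{k + 1}" for k in range(ev.shape[1])]
        pen = np.r_[pen, np.zeros(ev.shape[1], bool)]
    return LassoDesign(X=X, time=np.asarray(time, float),
                       status=np.asarray(status, int), penalized=pen,
                       names=names, effect_sizes=np.array(effs))


def _risk_structure(time: np.ndarray, status: np.ndarray):
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    d = status[order]
    # group rows by unique time; risk set at time s = rows with t >= s
    uniq, first = np.unique(t, return_index=True)
    return order, t, d, uniq, first


def breslow_derivatives(eta: np.ndarray, time: np.ndarray, status: np.ndarray):
    """Breslow partial-likelihood value, eta-gradient and diagonal weights.

    Returns (loglik, u, w) with u_i = dl/deta_i the exact score and w_i the
    exact diagonal curvature -d2l/deta_i^2 = e^eta Lambda_i - e^(2 eta)
    Psi_i, floored at a small positive value so the working weights stay
    usable. The IRLS fixed point satisfies the exact stationarity
    conditions because the score u is exact.
    """
    n = len(eta)
    order, t, d, uniq, first = _risk_structure(time, status)
    eta_s = np.clip(eta[order], -500, 500)
    ex = np.exp(eta_s)
    # S0 at each unique time = sum of e^eta over rows with t >= that time
    suffix = np.cumsum(ex[::-1])[::-1]
    s0 = suffix[first]
    d_per_time = np.add.reduceat(d, first)
    is_event_time = d_per_time > 0
    with np.errstate(divide="ignore"):
        inc_l = np.where(is_event_time, d_per_time / s0, 0.0)
        inc_p = np.where(is_event_time, d_per_time / s0**2, 0.0)
    cum_l = np.cumsum(inc_l)
    cum_p = np.cumsum(inc_p)
    # map each row to its time's index among unique times
    time_idx = np.searchsorted(uniq, t)
    lam = cum_l[time_idx]
    psi = cum_p[time_idx]
    ll = float(np.sum(d * eta_s) -
               np.sum(d_per_time[is_event_time] * np.log(s0[is_event_time])))
    u_s = d - ex * lam
    w_s = np.maximum(ex * lam - ex**2 * psi, 1e-5)
    u = np.empty(n)
    w = np.empty(n)
    u[order] = u_s
    w[order] = np.clip(w_s, 0.0, None)
    return ll, u, w


def breslow_loglik(eta: np.ndarray, time: np.ndarray, status: np.ndarray) -> float:
    return breslow_derivatives(eta, time, status)[0]


def _grad_beta(design: LassoDesign, beta: np.ndarray) -> np.ndarray:
    _, u, _ = breslow_derivatives(design.X @ beta, design.time, design.status)
    return design.X.T @ u


def fit_nonneg_cox_lasso(
    design: LassoDesign,
    lam: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-7,
    max_outer: int = 1000,
    max_sweeps: int = 200,
) -> LassoFit:
    """Penalized fit at one lambda.

    Outer loop: quadratic (IRLS) approximation of the Breslow partial
    likelihood at the current linear predictor. Inner loop: cyclic
    coordinate descent with soft-thresholding; penalized coordinates are
    projected onto [0, inf). Converges when the largest coefficient change
    across an outer iteration is below ``tol``.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    n, p = design.X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    X = design.X
    converged = False
    ll_prev = -np.inf
    it = 0

    def sweep(w, r, wx2, coords) -> float:
        delta = 0.0
        for j in coords:
            if wx2[j] <= 1e-12:
                continue
            num = np.sum(w * X[:, j] * r) + wx2[j] * beta[j]
            if design.penalized[j]:
                bj = max(0.0, (num - lam) / wx2[j])
            else:
                bj = num / wx2[j]
            if bj != beta[j]:
                r -= X[:, j] * (bj - beta[j])
                delta = max(delta, abs(bj - beta[j]))
                beta[j] = bj
        return delta

    all_coords = np.arange(p)
    for it in range(1, max_outer + 1):
        eta = X @ beta
        ll, u, w = breslow_derivatives(eta, design.time, design.status)
        z = eta + np.divide(u, w, out=np.zeros_like(u), where=w > 1e-12)
        wx2 = w @ X**2
        beta_old = beta.copy()
        r = z - X @ beta
        sweep(w, r, wx2, all_coords)
        # iterate the active set to convergence, then re-check all coords
        for _ in range(max_sweeps):
            active = np.flatnonzero((beta != 0) | ~design.penalized)
            if sweep(w, r, wx2, active) < tol:
                if sweep(w, r, wx2, all_coords) < tol:
                    break
        step = np.max(np.abs(beta - beta_old))
        # stop on coefficient stability or a likelihood plateau
        # likelihood-plateau stop scaled to the coefficient tolerance
        if step < tol or abs(ll - ll_prev) < 0.01 * tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_prev = ll
    if not converged:
        # loose-tolerance path fits report at debug level; final fits warn
        emit = log.debug if tol > 1e-6 else log.warning
        emit("lasso fit at lambda=%.4g did not converge in %d outer loops",
             lam, max_outer)
    return LassoFit(coef=beta, lam=float(lam), converged=converged, n_iter=it)


def lambda_max(design: LassoDesign) -> float:
    """Smallest lambda zeroing all penalized coefficients.

    Computed from the partial-likelihood score at the null model after
    fitting the unpenalized (eigenvector) columns alone.
    """
    p = design.X.shape[1]
    beta = np.zeros(p)
    if (~design.penalized).any():
        fit = fit_nonneg_cox_lasso(design, lam=np.inf, max_outer=50)
        beta = fit.coef
    g = _grad_beta(design, beta)
    gmax = np.max(g[design.penalized])  # nonneg constraint: only positive score matters
    return float(max(gmax, 1e-10))


def lambda_grid(design: LassoDesign, n_lambda: int = 100, ratio: float = 1e-3) -> np.ndarray:
    # top of the grid sits fractionally above lambda_max so the null model
    # is exactly reproducible there
    lmax = lambda_max(design) * 1.001
    return np.geomspace(lmax, lmax * ratio, n_lambda)


def _fit_path(design: LassoDesign, lambdas: np.ndarray,
              tol: float = 3e-4, max_outer: int = 15) -> np.ndarray:
    """Warm-started path fit; CV path points use a looser tolerance than
    the final fit (deviance curves are insensitive at that scale)."""
    betas = np.zeros((len(lambdas), design.X.shape[1]))
    beta = None
    for i, lam in enumerate(lambdas):
        fit = fit_nonneg_cox_lasso(design, lam, beta0=beta, tol=tol,
                                   max_outer=max_outer)
        beta = fit.coef
        betas[i] = beta
    return betas


def _stratified_folds(status: np.ndarray, k: int, rng: np.random.Generator):
    folds = np.empty(len(status), int)
    for cls in (0, 1):
        idx = np.flatnonzero(status == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def cv_select_lambda(
    design: LassoDesign,
    k: int = 3,
    repeats: int = 100,
    seed: int = 0,
    n_lambda: int = 100,
    max_retries: int = 10,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Repeated k-fold CV for the L1 penalty.

    Folds are stratified by event status; a fold left with no events is
    re-drawn (bounded retries). Each repeat picks the grid lambda minimising
    the mean out-of-fold Breslow deviance; the returned lambda* is the
    geometric mean of the per-repeat choices. Deterministic given ``seed``.

    Returns (lambda*, grid, mean deviance per grid point across repeats).
    """
    n_events = int(design.status.sum())
    if n_events < 5 * k:
        raise ValueError(f"need at least {5 * k} events for {k}-fold CV, have {n_events}")
    grid = lambda_grid(design, n_lambda=n_lambda)
    rng = substream(seed, "lasso-cv")
    picks = []
    dev_accum = np.zeros(len(grid))
    for rep in range(repeats):
        for _ in range(max_retries):
            folds = _stratified_folds(design.status, k, rng)
            if all(design.status[folds == f].sum() > 0 for f in range(k)):
                break
            log.warning("all-censored CV fold; re-drawing split")
        else:
            raise RuntimeError("could not draw CV folds with events in every fold")
        dev = np.zeros(len(grid))
        for f in range(k):
            test = folds == f
            train = design.subset(~test)
            betas = _fit_path(train, grid)
            for i, b in enumerate(betas):
                # Verweij-van Houwelingen out-of-fold deviance: the test
                # fold's contribution is the full-data partial likelihood
                # minus the training-fold partial likelihood
                pl_full = breslow_loglik(design.X @ b, design.time, design.status)
                pl_train = breslow_loglik(train.X @ b, train.time, train.status)
                dev[i] += -2.0 * (pl_full - pl_train)
        dev /= k
        picks.append(grid[int(np.argmin(dev))])
        dev_accum += dev
    lam_star = float(np.exp(np.mean(np.log(picks))))
    return lam_star, grid, dev_accum / repeats


def importance(
    coef: np.ndarray,
    effect_sizes: np.ndarray,
    names: list[str] | None = None,
) -> ImportanceTable:
    """Re-weighted variant importances.

    importance_p = |coef_p * beta_p| / sum_q |coef_q * beta_q| over the
    variant columns; an all-zero fit yields an empty table (the control-arm
    expectation).
    """
    coef = np.asarray(coef, float)
    effect_sizes = np.asarray(effect_sizes, float)
    if coef.shape != effect_sizes.shape:
        raise ValueError("coefficient and effect-size vectors must align")
    raw = np.abs(coef * effect_sizes)
    total = raw.sum()
    names = names or [f"v{i}" for i in range(len(coef))]
    if total == 0:
        log.info("no variants retained by the lasso")
        return ImportanceTable(pd.DataFrame(
            columns=["variant", "coefficient", "retained", "importance"]))
    tab = pd.DataFrame({
        "variant": names,
        "coefficient": coef,
        "retained": coef != 0,
        "importance": np.where(coef != 0, raw / total, 0.0),
    })
    return ImportanceTable(tab.sort_values("importance", ascending=False)
                           .reset_index(drop=True))
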