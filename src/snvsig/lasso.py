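"""l1-penalized regression: linear LASSO with sequential strong rules, and
LASSO-penalized Cox regression with cross-validated lambda tuning.

Linear case.  With standardized predictors x_ij and centered responses y_i
the objective is

    sum_i (y_i - sum_j x_ij beta_j)^2 + lambda * sum_j |beta_j|

solved by cyclic coordinate descent with soft-thresholding.  Candidate
predictors along a decreasing lambda path are pre-screened with the
sequential strong rule  |2 x_j' r(beta_prev)| >= 2*lambda_k - lambda_prev;
after convergence the full KKT conditions are checked so screened solutions
are exact (violators are added back and the problem re-solved).

Cox case.  The penalized objective is  -(1/n) log PL(beta) + lambda*||beta||_1
with the Breslow approximation for ties, maximised by iteratively reweighted
least squares: each outer step builds the diagonal quadratic expansion of the
partial likelihood in the linear predictor and solves the resulting weighted
LASSO by coordinate descent.  Lambda is tuned by k-fold cross-validated
partial-likelihood deviance (the "leave-fold-out" difference form).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genotype import SurvivalData

logger = logging.getLogger(__name__)

__all__ = [
    "LassoFit",
    "CoxLassoCV",
    "soft_threshold",
    "lasso_linear",
    "strong_rule_screen",
    "lasso_path",
    "lasso_cox",
    "cox_lambda_max",
    "cv_lasso_cox",
]

_CD_TOL = 1e-7  # inner coordinate-descent tolerance on max |delta beta|
_KKT_TOL = 1e-6


# ------------------------------------------------------------------ linear


def soft_threshold(z: np.ndarray | float, gamma: float):
    return np.sign(z) * np.maximum(np.abs(z) - gamma, 0.0)


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD
    ok = sd > 0
    Xs = np.zeros_like(X, dtype=float)
    Xs[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return Xs, mu, sd, ok


def lasso_linear(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    beta0: np.ndarray | None = None,
    candidates: np.ndarray | None = None,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Solve the l1-penalized least-squares problem at a single lambda.

    ``X`` is expected standardized and ``y`` centered (see
    :func:`lasso_path` for the user-facing wrapper).  ``candidates``
    optionally restricts coordinate updates to a screened set; the KKT
    conditions are verified over all predictors afterwards, so the returned
    solution is exact regardless of screening.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    norms2 = np.einsum("ij,ij->j", X, X)
    cand = np.arange(p) if candidates is None else np.asarray(candidates)
    r = y - X @ beta
    while True:
        for _ in range(max_iter):
            delta = 0.0
            for j in cand:
                if norms2[j] == 0.0:
                    continue
                cj = X[:, j] @ r + norms2[j] * beta[j]
                bj = soft_threshold(cj, lam / 2.0) / norms2[j]
                if bj != beta[j]:
                    r += X[:, j] * (beta[j] - bj)
                    delta = max(delta, abs(bj - beta[j]))
                    beta[j] = bj
            if delta < _CD_TOL:
                break
        # KKT over all predictors: |2 x_j' r| <= lambda for inactive j
        grad = 2.0 * (X.T @ r)
        violators = np.flatnonzero((np.abs(grad) > lam * (1 + _KKT_TOL) + _KKT_TOL) & (beta == 0.0))
        violators = np.setdiff1d(violators, cand)
        if violators.size == 0:
            return beta
        cand = np.union1d(cand, violators)


def strong_rule_screen(
    X: np.ndarray,
    y: np.ndarray,
    lam_k: float,
    lam_prev: float,
    beta_prev: np.ndarray,
) -> np.ndarray:
    """Sequential strong rule candidate set for the next path point.

    Keeps predictor j when ``|2 x_j'(y - X beta_prev)| >= 2 lam_k - lam_prev``
    (the gradient scale matches the KKT conditions of :func:`lasso_linear`).
    The rule can rarely discard a truly active predictor, which is why the
    solver re-checks KKT on the full set.
    """
    r = y - X @ beta_prev
    c = np.abs(2.0 * (X.T @ r))
    keep = c >= (2.0 * lam_k - lam_prev) - _KKT_TOL
    keep |= beta_prev != 0.0
    return np.flatnonzero(keep)


@dataclass
class LassoFit:
    """Solution path of a LASSO problem on the original predictor scale."""

    lambda_path: np.ndarray
    beta: np.ndarray  # p x n_lambda, original scale
    intercept: np.ndarray  # n_lambda
    active_sets: list[np.ndarray] = field(default_factory=list)
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None
    strong_rule_violations: int = 0

    def active(self, k: int) -> np.ndarray:
        return self.active_sets[k]


def default_lambda_grid(lam_max: float, n_points: int = 100, p: int = 1, n: int = 1) -> np.ndarray:
    ratio = 0.05 if p > n else 0.01
    return np.geomspace(lam_max, ratio * lam_max, n_points)


def lasso_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray | None = None, n_lambda: int = 100
) -> LassoFit:
    """LASSO solution path with internal standardization and strong rules.

    Predictors are standardized (population SD) and the response centered
    before solving; coefficients are mapped back to the original scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Xs, mu, sd, ok = _standardize(X)
    yc = y - y.mean()
    lam_max = 2.0 * float(np.max(np.abs(Xs.T @ yc))) if p else 0.0
    if lambdas is None:
        lambdas = default_lambda_grid(lam_max, n_lambda, p, n)
    lambdas = np.asarray(sorted(lambdas, reverse=True), dtype=float)
    betas = np.zeros((p, len(lambdas)))
    active = []
    violations = 0
    beta = np.zeros(p)
    lam_prev = lam_max
    for k, lam in enumerate(lambdas):
        cand = strong_rule_screen(Xs, yc, lam, lam_prev, beta)
        before = set(cand.tolist())
        beta = lasso_linear(Xs, yc, lam, beta0=beta, candidates=cand)
        violations += len(set(np.flatnonzero(beta != 0.0).tolist()) - before)
        betas[:, k] = beta
        active.append(np.flatnonzero(beta != 0.0))
        lam_prev = lam
    beta_orig = np.zeros_like(betas)
    beta_orig[ok, :] = betas[ok, :] / sd[ok, None]
    intercept = y.mean() - mu @ beta_orig
    return LassoFit(
        lambda_path=lambdas,
        beta=beta_orig,
        intercept=intercept,
        active_sets=active,
        mean=mu,
        scale=sd,
        strong_rule_violations=violations,
    )


# --------------------------------------------------------------------- Cox


class _CoxWork:
    """Pre-sorted structures for Breslow partial-likelihood computations."""

    def __init__(self, time: np.ndarray, event: np.ndarray):
        if event.sum() == 0:
            raise ValueError("no events: Cox partial likelihood undefined")
        self.n = len(time)
        self.order = np.argsort(time, kind="stable")
        self.t = time[self.order]
        self.e = event[self.order].astype(bool)
        self.ut = np.unique(self.t[self.e])
        self.start = np.searchsorted(self.t, self.ut, side="left")
        gi = np.searchsorted(self.ut, self.t[self.e])
        self.d = np.bincount(gi, minlength=len(self.ut)).astype(float)
        # number of event-time groups with ut <= t_i, per sorted subject
        self.n_groups_le = np.searchsorted(self.ut, self.t, side="right")

    def loglik(self, eta: np.ndarray) -> float:
        """Breslow log partial likelihood at linear predictor eta (original order)."""
        es = eta[self.order]
        w = np.exp(es)
        D = np.cumsum(w[::-1])[::-1][self.start]  # risk-set sums per event time
        return float(es[self.e].sum() - np.sum(self.d * np.log(D)))

    def grad_eta(self, eta: np.ndarray):
        """Gradient and diagonal Hessian of log PL w.r.t. eta (original order)."""
        es = eta[self.order]
        w = np.exp(es)
        D = np.cumsum(w[::-1])[::-1][self.start]
        h = np.concatenate([[0.0], np.cumsum(self.d / D)])[self.n_groups_le]
        h2 = np.concatenate([[0.0], np.cumsum(self.d / D**2)])[self.n_groups_le]
        g_sorted = self.e.astype(float) - w * h
        w_sorted = w * h - (w**2) * h2  # minus the diagonal Hessian
        g = np.empty(self.n)
        wdiag = np.empty(self.n)
        g[self.order] = g_sorted
        wdiag[self.order] = w_sorted
        return g, wdiag


def cox_lambda_max(X: np.ndarray, surv: SurvivalData, standardize: bool = True) -> float:
    """Smallest lambda for which the penalized Cox solution is beta = 0."""
    X = np.asarray(X, dtype=float)
    if standardize:
        X, _, _, _ = _standardize(X)
    work = _CoxWork(surv.time, surv.event)
    g, _ = work.grad_eta(np.zeros(X.shape[0]))
    return float(np.max(np.abs(X.T @ g)) / X.shape[0])


@njit(cache=True)
def _wcd_sweeps(Xs, WX, denom, r, beta, cand, lam, n, tol, max_sweeps):  # pragma: no cover
    """Weighted coordinate-descent sweeps over a candidate set (in place)."""
    for _ in range(max_sweeps):
        delta = 0.0
        for idx in range(cand.shape[0]):
            j = cand[idx]
            if denom[j] <= 0.0:
                continue
            num = 0.0
            for i in range(Xs.shape[0]):
                num += WX[i, j] * r[i]
            cj = num / n + denom[j] * beta[j]
            bj = np.sign(cj) * max(abs(cj) - lam, 0.0) / denom[j]
            if bj != beta[j]:
                diff = beta[j] - bj
                for i in range(Xs.shape[0]):
                    r[i] += Xs[i, j] * diff
                if abs(diff) > delta:
                    delta = abs(diff)
                beta[j] = bj
        if delta < tol:
            break


def _cox_cd(
    Xs: np.ndarray,
    work: _CoxWork,
    lam: float,
    beta: np.ndarray,
    max_irls: int = 25,
    candidates: np.ndarray | None = None,
) -> np.ndarray:
    """Penalized Cox solve at one lambda by IRLS + weighted coordinate descent."""
    n, p = Xs.shape
    beta = beta.copy()
    cand = np.arange(p) if candidates is None else np.asarray(candidates, dtype=np.int64)
    eta = Xs @ beta
    for _ in range(max_irls):
        g, wdiag = work.grad_eta(eta)
        wdiag = np.maximum(wdiag, 1e-10)
        # minimize (1/2n) sum w_i (z_i - x_i'b)^2 + lam ||b||_1,  z = eta + g/w
        r = g / wdiag
        WX = wdiag[:, None] * Xs
        denom = np.einsum("ij,ij->j", WX, Xs) / n
        beta_old = beta.copy()
        while True:
            _wcd_sweeps(Xs, WX, denom, r, beta, cand.astype(np.int64), lam, n, _CD_TOL, 5000)
            grad_q = -(WX.T @ r) / n
            viol = np.flatnonzero((np.abs(grad_q) > lam * (1 + _KKT_TOL) + _KKT_TOL) & (beta == 0.0))
            viol = np.setdiff1d(viol, cand)
            if viol.size == 0:
                break
            cand = np.union1d(cand, viol)
        eta = Xs @ beta
        if np.max(np.abs(beta - beta_old), initial=0.0) < 1e-6:
            break
    return beta


def lasso_cox(
    X: np.ndarray,
    surv: SurvivalData,
    lam: float,
    standardize: bool = True,
    beta0: np.ndarray | None = None,
) -> np.ndarray:
    """l1-penalized Cox fit at a single lambda; coefficients on the original scale."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xs, mu, sd, ok = _standardize(X) if standardize else (X, np.zeros(p), np.ones(p), np.ones(p, bool))
    work = _CoxWork(surv.time, surv.event)
    b0 = np.zeros(p) if beta0 is None else beta0 * np.where(ok, sd, 1.0)
    beta = _cox_cd(Xs, work, lam, b0)
    out = np.zeros(p)
    out[ok] = beta[ok] / sd[ok] if standardize else beta[ok]
    return out


def _cox_path(
    Xs: np.ndarray, work: _CoxWork, lambdas: np.ndarray
) -> np.ndarray:
    """Warm-started path of standardized-scale solutions (p x n_lambda)."""
    n, p = Xs.shape
    betas = np.zeros((p, len(lambdas)))
    beta = np.zeros(p)
    lam_prev = lambdas[0]
    g0, _ = work.grad_eta(np.zeros(n))
    lam_null = np.max(np.abs(Xs.T @ g0)) / n
    for k, lam in enumerate(lambdas):
        if lam >= lam_null * (1.0 - 1e-10):
            # by construction the null model solves the problem here
            lam_prev = lam
            continue
        g, _ = work.grad_eta(Xs @ beta)
        score = np.abs(Xs.T @ g) / n
        cand = np.flatnonzero((score >= 2.0 * lam - lam_prev - _KKT_TOL) | (beta != 0.0))
        beta = _cox_cd(Xs, work, lam, beta, candidates=cand)
        betas[:, k] = beta
        lam_prev = lam
    return betas


@dataclass
class CoxLassoCV:
    """k-fold CV summary for the penalized Cox path."""

    lambda_path: np.ndarray
    cv_deviance: np.ndarray  # mean over folds
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    rule: str
    folds: np.ndarray  # per-sample fold label
    beta_path: np.ndarray  # p x n_lambda, original scale (full-data fit)

    @property
    def lambda_chosen(self) -> float:
        return self.lambda_min if self.rule == "min" else self.lambda_1se


def _stratified_folds(event: np.ndarray, nfolds: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.empty(len(event), dtype=int)
    for val in (0, 1):
        idx = np.flatnonzero(event == val)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % nfolds
    return folds


def cv_lasso_cox(
    X: np.ndarray,
    surv: SurvivalData,
    nfolds: int = 10,
    rule: str = "min",
    n_lambda: int = 100,
    seed: int = 0,
    max_retries: int = 20,
) -> tuple[CoxLassoCV, np.ndarray]:
    """Tune lambda by k-fold cross-validated partial-likelihood deviance.

    Folds are stratified on event status (re-randomized, up to a retry cap,
    if a training split ends up without events).  The CV deviance for fold k
    is ``-2 [logPL_all(beta^(-k)) - logPL_train(beta^(-k))]``, the
    leave-fold-out difference form, which is well defined even for tiny
    held-out risk sets.  Returns the CV summary and the full-data
    coefficients at the chosen lambda (original scale).
    """
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < nfolds:
        raise ValueError("need at least nfolds samples")
    Xs, mu, sd, ok = _standardize(X)
    work = _CoxWork(surv.time, surv.event)
    lam_max = cox_lambda_max(X, surv)
    lambdas = default_lambda_grid(lam_max, n_lambda, p, n)

    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        folds = _stratified_folds(surv.event, nfolds, rng)
        if all(surv.event[folds != k].sum() > 0 for k in range(nfolds)):
            break
    else:
        raise RuntimeError("could not build folds with events in every training split")

    dev = np.zeros((nfolds, len(lambdas)))
    for k in range(nfolds):
        tr = folds != k
        work_tr = _CoxWork(surv.time[tr], surv.event[tr])
        betas_k = _cox_path(Xs[tr], work_tr, lambdas)
        for i in range(len(lambdas)):
            eta_all = Xs @ betas_k[:, i]
            ll_all = work.loglik(eta_all)
            ll_tr = work_tr.loglik(eta_all[tr])
            dev[k, i] = -2.0 * (ll_all - ll_tr)
    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(nfolds)
    i_min = int(np.argmin(mean))
    lam_min = float(lambdas[i_min])
    within = np.flatnonzero(mean <= mean[i_min] + se[i_min])
    lam_1se = float(lambdas[within.min()])  # largest lambda within one SE
    betas_full = _cox_path(Xs, work, lambdas)
    beta_orig = np.zeros_like(betas_full)
    beta_orig[ok, :] = betas_full[ok, :] / sd[ok, None]
    cv = CoxLassoCV(
        lambda_path=lambdas,
        cv_deviance=mean,
        cv_se=se,
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        rule=rule,
        folds=folds,
        beta_path=beta_orig,
    )
    chosen_idx = i_min if rule == "min" else int(within.min())
    logger.info(
        "cv_lasso_cox: lambda_%s=%.5g selects %d/%d features",
        rule, cv.lambda_chosen, int(np.sum(beta_orig[:, chosen_idx] != 0.0)), p,
    )
    return cv, beta_orig[:, chosen_idx]
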