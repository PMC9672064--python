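"""L1-penalized ("lasso") regression for gaussian, binomial and
right-censored Cox families, with cross-validated selection of the
regularization parameter.

Objective conventions (columns standardized internally to mean 0, SD 1;
coefficients reported on the original scale):

* gaussian:  (1/2n) ||y - b0 - X beta||^2          + lam ||beta||_1
* binomial: -(2/n) * Bernoulli log-likelihood       + lam ||beta||_1
* cox:      -(2/n) * Breslow partial log-likelihood + lam ||beta||_1

All three are fitted by cyclic coordinate descent on the iteratively
reweighted quadratic approximation with soft-thresholding, warm starts along
a 100-point log-spaced lambda grid from lambda_max (the smallest lambda with
an all-zero solution, where the coefficient vector is exactly zero by
construction) down to 0.01*lambda_max (0.05 when n < p). ``dfmax`` truncates
the path once the active set exceeds the largest model the data can support
(the event count for Cox, min(n, p) otherwise). The Cox cross-validation
criterion is the Verweij-van Houwelingen partial-likelihood deviance;
gaussian uses MSE and binomial the binomial deviance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from ._cd import wls_lasso
from ._paths import binomial_path, cox_path
from ._utils import logger
from .outcomes import Outcome, make_folds

N_LAMBDA_DEFAULT = 100
_PMIN = 1e-5
_HMIN = 1e-9


# ----------------------------------------------------------------------
# containers
@dataclass
class LassoPath:
    family: str
    lambdas: np.ndarray  # decreasing
    coefs: np.ndarray  # (n_lambda, p) original scale
    intercepts: np.ndarray  # (n_lambda,) zeros for cox
    coefs_std: np.ndarray = field(repr=False)  # standardized scale
    x_mean: np.ndarray = field(repr=False)
    x_scale: np.ndarray = field(repr=False)
    loss: np.ndarray = field(repr=False)  # smooth loss along the path
    n_sweeps: np.ndarray = field(repr=False)

    @property
    def n_nonzero(self) -> np.ndarray:
        return (self.coefs != 0).sum(axis=1)

    def coef_at(self, lam: float):
        i = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.coefs[i], self.intercepts[i]


@dataclass
class SelectedLambda:
    lambda_: float
    index: int
    lambdas: np.ndarray
    cv_deviance: np.ndarray
    cv_sd: np.ndarray
    rule: str
    n_folds_used: int


# ----------------------------------------------------------------------
# family helpers
def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    dead = sd == 0.0
    sd = np.where(dead, 1.0, sd)
    return np.ascontiguousarray(((X - mu) / sd).T), mu, sd  # XT (p, n)


def _check_inputs(X, outcome: Outcome, family: str):
    X = np.asarray(X, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in X")
    if X.shape[0] < 10:
        raise ValueError("lasso_fit needs n >= 10")
    if family == "cox":
        if outcome.family != "survival":
            raise ValueError("cox family requires a survival outcome")
        if outcome.n_events < 2:
            raise ValueError("cox fit needs >= 2 events (all-censored data rejected)")
    elif family == "binomial":
        y = outcome.y
        if y.min() == y.max():
            raise ValueError("binomial outcome is constant")
    return X


class _CoxWork:
    """Breslow risk-set bookkeeping on time-sorted data."""

    def __init__(self, time, event):
        self.order = np.argsort(time, kind="stable")
        self.time = np.asarray(time, float)[self.order]
        self.event = np.asarray(event, bool)[self.order]
        self.n = len(self.time)
        # unique event times and event counts
        et = self.time[self.event]
        self.uniq, counts = np.unique(et, return_counts=True)
        self.d = counts.astype(float)
        # index of first subject at risk for each unique event time
        self.first_at_risk = np.searchsorted(self.time, self.uniq, side="left")
        # for each subject (sorted), number of unique event times <= t_i
        self.n_et_le = np.searchsorted(self.uniq, self.time, side="right")

    def quantities(self, eta_sorted):
        """Return per-subject (sorted order) score residual g, curvature h,
        and the Breslow partial log-likelihood."""
        w = np.exp(eta_sorted)
        rev = np.cumsum(w[::-1])[::-1]  # risk-set sums from each index
        R = rev[self.first_at_risk]
        inv = self.d / R
        inv2 = self.d / R**2
        cum1 = np.concatenate([[0.0], np.cumsum(inv)])
        cum2 = np.concatenate([[0.0], np.cumsum(inv2)])
        C1 = cum1[self.n_et_le]
        C2 = cum2[self.n_et_le]
        g = self.event.astype(float) - w * C1
        h = np.maximum(w * C1 - w**2 * C2, _HMIN)
        pl = float(eta_sorted[self.event].sum() - (self.d * np.log(R)).sum())
        return g, h, pl

    def partial_loglik(self, eta_sorted) -> float:
        w = np.exp(eta_sorted)
        rev = np.cumsum(w[::-1])[::-1]
        R = rev[self.first_at_risk]
        return float(eta_sorted[self.event].sum() - (self.d * np.log(R)).sum())


def breslow_partial_loglik(time, event, eta) -> float:
    """Breslow partial log-likelihood at linear predictor ``eta``."""
    work = _CoxWork(time, event)
    return work.partial_loglik(np.asarray(eta, float)[work.order])


# ----------------------------------------------------------------------
def lambda_max(X, outcome: Outcome, family: str) -> float:
    """Smallest penalty with an all-zero solution."""
    X = _check_inputs(X, outcome, family)
    XT, mu, sd = _standardize(X)
    return _lambda_max_std(XT, outcome, family)


def _lambda_max_std(XT, outcome, family) -> float:
    n = XT.shape[1]
    if family == "gaussian":
        r = outcome.y - outcome.y.mean()
        lmax = float(np.abs(XT @ r).max() / n)
    elif family == "binomial":
        r = outcome.y - outcome.y.mean()
        lmax = float((2.0 / n) * np.abs(XT @ r).max())
    else:
        work = _CoxWork(outcome.time, outcome.event)
        g0, _, _ = work.quantities(np.zeros(n))
        g = np.empty(n)
        g[work.order] = g0
        lmax = float((2.0 / n) * np.abs(XT @ g).max())
    # tiny inflation so the boundary gradient cannot exceed lambda_max by a
    # rounding ulp: the solution at lambda_max is exactly zero by construction
    return lmax * (1.0 + 1e-10)


def lasso_fit(
    X,
    outcome: Outcome,
    family: str,
    lambda_grid=None,
    n_lambda: int = N_LAMBDA_DEFAULT,
    lambda_min_ratio: float | None = None,
    tol: float = 1e-7,
    etol: float = 1e-9,
    max_sweeps: int = 5_000,
    irls_max: int = 25,
    dfmax: int | None = None,
) -> LassoPath:
    """Fit the full regularization path with warm starts."""
    X = _check_inputs(X, outcome, family)
    n, p = X.shape
    XT, mu, sd = _standardize(X)
    if lambda_grid is None:
        lmax = _lambda_max_std(XT, outcome, family)
        if lambda_min_ratio is None:
            lambda_min_ratio = 0.05 if n < p else 0.01
        lambda_grid = lmax * np.logspace(0.0, np.log10(lambda_min_ratio), n_lambda)
    lambda_grid = np.ascontiguousarray(np.asarray(lambda_grid, float))
    if np.any(np.diff(lambda_grid) > 0):
        raise ValueError("lambda grid must be decreasing")
    if dfmax is None:
        dfmax = max(10, outcome.n_events) if family == "cox" else min(n, p)

    nl = len(lambda_grid)
    coefs_std = np.zeros((nl, p))
    intercepts = np.zeros(nl)
    loss = np.empty(nl)
    sweeps = np.zeros(nl, dtype=np.int64)

    if family == "gaussian":
        yc = np.ascontiguousarray(outcome.y - outcome.y.mean())
        beta = np.zeros(p)
        eta = np.zeros(n)
        w = np.full(n, 1.0 / n)
        for k, lam in enumerate(lambda_grid):
            sweeps[k] = wls_lasso(XT, w, yc, eta, beta, lam, tol, etol, max_sweeps)
            coefs_std[k] = beta
            intercepts[k] = outcome.y.mean()
            loss[k] = 0.5 * np.mean((yc - eta) ** 2)
            if (beta != 0).sum() > dfmax and k < nl - 1:
                coefs_std[k + 1 :] = beta
                intercepts[k + 1 :] = intercepts[k]
                loss[k + 1 :] = loss[k]
                break
    elif family == "binomial":
        y = np.ascontiguousarray(outcome.y, dtype=np.float64)
        b0_init = float(special.logit(np.clip(y.mean(), _PMIN, 1 - _PMIN)))
        k_last = binomial_path(
            XT,
            lambda_grid,
            y,
            b0_init,
            tol,
            etol,
            max_sweeps,
            irls_max,
            dfmax,
            _PMIN,
            coefs_std,
            intercepts,
            loss,
            sweeps,
        )
        if k_last < nl - 1:
            coefs_std[k_last + 1 :] = coefs_std[k_last]
            intercepts[k_last + 1 :] = intercepts[k_last]
            loss[k_last + 1 :] = loss[k_last]
    elif family == "cox":
        work = _CoxWork(outcome.time, outcome.event)
        XT_s = np.ascontiguousarray(XT[:, work.order])
        k_last = cox_path(
            XT_s,
            lambda_grid,
            work.event,
            work.first_at_risk.astype(np.int64),
            work.n_et_le.astype(np.int64),
            work.d,
            tol,
            etol,
            max_sweeps,
            irls_max,
            dfmax,
            _HMIN,
            coefs_std,
            loss,
            sweeps,
        )
        if k_last < nl - 1:
            coefs_std[k_last + 1 :] = coefs_std[k_last]
            loss[k_last + 1 :] = loss[k_last]
    else:
        raise ValueError(f"unknown family {family!r}")

    coefs = coefs_std / sd[None, :]
    if family in ("gaussian", "binomial"):
        final_int = intercepts - coefs @ mu
    else:
        final_int = np.zeros(nl)
    return LassoPath(
        family=family,
        lambdas=lambda_grid,
        coefs=coefs,
        intercepts=final_int,
        coefs_std=coefs_std,
        x_mean=mu,
        x_scale=sd,
        loss=loss,
        n_sweeps=sweeps,
    )


# ----------------------------------------------------------------------
def smooth_gradient(X, outcome: Outcome, family: str, beta, intercept=0.0):
    """Gradient of the smooth (unpenalized) loss on the standardized scale,
    used by the KKT diagnostics."""
    X = np.asarray(X, float)
    n = X.shape[0]
    XT, mu, sd = _standardize(X)
    beta_std = np.asarray(beta, float) * sd
    eta = XT.T @ beta_std
    if family == "gaussian":
        r = (outcome.y - outcome.y.mean()) - eta
        return -(XT @ r) / n
    if family == "binomial":
        b0 = intercept + float(np.asarray(beta, float) @ mu)
        pr = special.expit(b0 + eta)
        return (2.0 / n) * (XT @ (pr - outcome.y))
    work = _CoxWork(outcome.time, outcome.event)
    g, _, _ = work.quantities(eta[work.order])
    gfull = np.empty(n)
    gfull[work.order] = g
    return -(2.0 / n) * (XT @ gfull)


def kkt_max_violation(X, outcome: Outcome, path: LassoPath, k: int) -> float:
    """Maximum KKT violation at path point k: for zero coefficients
    |grad_j| <= lam, for nonzero grad_j = -lam * sign(beta_j)."""
    grad = smooth_gradient(X, outcome, path.family, path.coefs[k], path.intercepts[k])
    lam = path.lambdas[k]
    b = path.coefs_std[k]
    zero = b == 0.0
    viol = 0.0
    if zero.any():
        viol = max(viol, float((np.abs(grad[zero]) - lam).max(initial=-np.inf)))
    if (~zero).any():
        viol = max(viol, float(np.abs(grad[~zero] + lam * np.sign(b[~zero])).max()))
    return viol


# ----------------------------------------------------------------------
def _held_out_deviance(family, path, X, outcome, train_idx, test_idx, work_all=None):
    """Per-lambda held-out deviance for one inner fold."""
    nl = len(path.lambdas)
    dev = np.empty(nl)
    if family == "gaussian":
        Xt = X[test_idx]
        y = outcome.y[test_idx]
        for k in range(nl):
            pred = path.intercepts[k] + Xt @ path.coefs[k]
            dev[k] = float(np.mean((y - pred) ** 2))
    elif family == "binomial":
        Xt = X[test_idx]
        y = outcome.y[test_idx]
        for k in range(nl):
            pr = np.clip(
                special.expit(path.intercepts[k] + Xt @ path.coefs[k]), _PMIN, 1 - _PMIN
            )
            dev[k] = float(-2.0 * np.mean(y * np.log(pr) + (1 - y) * np.log(1 - pr)))
    else:
        # Verweij - van Houwelingen: -2 * (pl_all(beta) - pl_train(beta))
        train_out = outcome.subset(train_idx)
        work_train = _CoxWork(train_out.time, train_out.event)
        eta_all = X @ path.coefs.T  # (n, nl)
        pl_all = _pl_many(work_all, eta_all[work_all.order])
        eta_tr = eta_all[train_idx]
        pl_tr = _pl_many(work_train, eta_tr[work_train.order])
        dev = -2.0 * (pl_all - pl_tr)
    return dev


def _pl_many(work: "_CoxWork", eta_sorted_cols: np.ndarray) -> np.ndarray:
    """Breslow partial log-likelihood for many linear predictors at once;
    ``eta_sorted_cols`` is (n, m) already in the work's time order."""
    w = np.exp(eta_sorted_cols)
    rev = np.cumsum(w[::-1], axis=0)[::-1]
    R = rev[work.first_at_risk]  # (n_event_times, m)
    return eta_sorted_cols[work.event].sum(axis=0) - (work.d[:, None] * np.log(R)).sum(axis=0)


def lasso_select_lambda(
    X,
    outcome: Outcome,
    family: str,
    n_inner_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "min",
    n_lambda: int = N_LAMBDA_DEFAULT,
    tol: float = 1e-7,
    **solver_opts,
) -> tuple:
    """Choose lambda by internal cross-validation within the training set.

    Returns ``(selection, full_path)`` where ``selection.lambda_`` minimizes
    the mean cross-validated deviance (``lambda_rule='min'``, the default) or
    applies the one-standard-error rule (``'1se'``). Deterministic given the
    seed. Inner folds are event-stratified for the Cox family; if the fold
    count exceeds what the event count supports, the folds are rebuilt with
    fewer splits (logged).
    """
    X = _check_inputs(X, outcome, family)
    n = X.shape[0]
    full_path = lasso_fit(X, outcome, family, n_lambda=n_lambda, tol=tol, **solver_opts)
    grid = full_path.lambdas

    k = min(n_inner_folds, n)
    if family == "cox":
        # each training split needs >= 2 events; each fold should hold >= 1
        max_k = max(2, min(k, outcome.n_events))
        if max_k < k:
            logger.info("reducing inner folds %d -> %d (too few events)", k, max_k)
            k = max_k
    folds = make_folds(outcome, k=k, seed=seed)
    work_all = _CoxWork(outcome.time, outcome.event) if family == "cox" else None

    devs = []
    for f in range(k):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        sub_out = outcome.subset(train_idx)
        try:
            sub_path = lasso_fit(
                X[train_idx], sub_out, family, lambda_grid=grid, tol=tol, **solver_opts
            )
        except ValueError as exc:  # degenerate inner split (e.g. too few events)
            logger.warning("skipping inner fold %d: %s", f, exc)
            continue
        devs.append(
            _held_out_deviance(family, sub_path, X, outcome, train_idx, test_idx, work_all)
        )
    if not devs:
        logger.warning("no usable inner fold; defaulting to lambda = 0.1 * lambda_max")
        idx = int(np.argmin(np.abs(grid - 0.1 * grid[0])))
        sel = SelectedLambda(
            lambda_=float(grid[idx]),
            index=idx,
            lambdas=grid,
            cv_deviance=np.full(len(grid), np.nan),
            cv_sd=np.full(len(grid), np.nan),
            rule=lambda_rule,
            n_folds_used=0,
        )
        return sel, full_path
    devs = np.asarray(devs)
    cvm = devs.mean(axis=0)
    m = devs.shape[0]
    cvsd = devs.std(axis=0, ddof=1) / np.sqrt(m) if m > 1 else np.zeros(len(grid))
    i_min = int(np.argmin(cvm))
    if lambda_rule == "min":
        idx = i_min
    elif lambda_rule == "1se":
        ok = np.flatnonzero(cvm <= cvm[i_min] + cvsd[i_min])
        idx = int(ok[0])  # largest lambda within one SE (grid is decreasing)
    else:
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
    sel = SelectedLambda(
        lambda_=float(grid[idx]),
        index=idx,
        lambdas=grid,
        cv_deviance=cvm,
        cv_sd=cvsd,
        rule=lambda_rule,
        n_folds_used=k,
    )
    return sel, full_path


def fit_lasso_cv(
    X,
    outcome: Outcome,
    family: str,
    n_inner_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "min",
    n_lambda: int = N_LAMBDA_DEFAULT,
    tol: float = 1e-7,
    **solver_opts,
):
    """Convenience: select lambda by inner CV, return (beta, intercept,
    selection) at the chosen lambda, coefficients on the original scale."""
    sel, path = lasso_select_lambda(
        X,
        outcome,
        family,
        n_inner_folds=n_inner_folds,
        seed=seed,
        lambda_rule=lambda_rule,
        n_lambda=n_lambda,
        tol=tol,
        **solver_opts,
    )
    beta = path.coefs[sel.index].copy()
    intercept = float(path.intercepts[sel.index])
    return beta, intercept, sel
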