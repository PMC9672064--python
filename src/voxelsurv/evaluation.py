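"""Validation of risk estimates on right-censored outcomes.

* ``risk_group_cox`` — site-aware Cox comparison of the high-risk vs
  low-risk groups: a Gaussian site random intercept fitted by penalized
  partial likelihood with a Laplace-type profile over the variance
  (Ripatti-Palmgren style), falling back to site-stratified Cox for <= 2
  sites or a boundary variance estimate.
* ``kaplan_meier`` — product-limit curves per group (lifelines backend).
* ``voxelwise_survival_map`` — per-voxel univariate Cox score test at
  beta = 0 (equals the log-rank test for binary features), the statistic
  behind both the descriptive brain maps and the optional voxel screening.
* ``power_events`` / ``events_required`` — Schoenfeld approximation for the
  power of a two-group survival comparison given the number of events. This
  is an approximation and is documented as such; it need not match any
  particular external package's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._utils import as_bool_events, logger


# ----------------------------------------------------------------------
# plain / stratified Newton Cox (Breslow ties)
def _cox_derivs(X, time, event, beta, strata=None):
    """Breslow partial log-likelihood, gradient and (negative) Hessian."""
    X = np.asarray(X, float)
    n, q = X.shape
    pl = 0.0
    grad = np.zeros(q)
    hess = np.zeros((q, q))
    if strata is None:
        strata = np.zeros(n, dtype=int)
    for s in np.unique(strata):
        rows = np.flatnonzero(strata == s)
        Xs = X[rows]
        ts = np.asarray(time, float)[rows]
        ev = np.asarray(event, bool)[rows]
        if not ev.any():
            continue
        order = np.argsort(ts, kind="stable")
        Xs, ts, ev = Xs[order], ts[order], ev[order]
        eta = Xs @ beta
        w = np.exp(eta)
        # reverse cumulative risk-set sums
        rc0 = np.cumsum(w[::-1])[::-1]
        rc1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
        rc2 = np.cumsum((w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))[::-1], axis=0)[::-1]
        uniq = np.unique(ts[ev])
        first_idx = np.searchsorted(ts, uniq, side="left")
        for t_j, i0 in zip(uniq, first_idx):
            at = ev & (ts == t_j)
            d = at.sum()
            R0, R1, R2 = rc0[i0], rc1[i0], rc2[i0]
            xbar = R1 / R0
            pl += eta[at].sum() - d * np.log(R0)
            grad += Xs[at].sum(axis=0) - d * xbar
            hess += d * (R2 / R0 - np.outer(xbar, xbar))
    return pl, grad, hess


def cox_newton(X, time, event, strata=None, max_iter=100, tol=1e-10):
    """Unpenalized (optionally stratified) Cox fit by Newton-Raphson with
    step halving; returns (beta, covariance, partial log-likelihood)."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    q = X.shape[1]
    beta = np.zeros(q)
    pl, grad, hess = _cox_derivs(X, time, event, beta, strata)
    for _ in range(max_iter):
        step = np.linalg.solve(hess + 1e-12 * np.eye(q), grad)
        factor = 1.0
        for _ in range(40):
            new = beta + factor * step
            pl_new, grad_new, hess_new = _cox_derivs(X, time, event, new, strata)
            if pl_new >= pl - 1e-12:
                break
            factor /= 2.0
        if np.abs(new - beta).max() < tol:
            beta, pl, grad, hess = new, pl_new, grad_new, hess_new
            break
        beta, pl, grad, hess = new, pl_new, grad_new, hess_new
    cov = np.linalg.inv(hess + 1e-12 * np.eye(q))
    return beta, cov, pl


# ----------------------------------------------------------------------
# site random-intercept Cox via penalized partial likelihood
def _ppl_fit(X, Z, time, event, theta, max_iter=50, tol=1e-9):
    """Inner Newton for (beta, b) at fixed random-effect variance theta."""
    n, q = X.shape
    r = Z.shape[1]
    W = np.hstack([X, Z])
    phi = np.zeros(q + r)
    pen = np.zeros(q + r)
    pen[q:] = 1.0 / theta
    pl, grad, hess = _cox_derivs(W, time, event, phi)
    obj = pl - 0.5 * (pen * phi**2).sum()
    for _ in range(max_iter):
        g = grad - pen * phi
        H = hess + np.diag(pen)
        step = np.linalg.solve(H, g)
        factor = 1.0
        for _ in range(40):
            new = phi + factor * step
            pl_new, grad_new, hess_new = _cox_derivs(W, time, event, new)
            obj_new = pl_new - 0.5 * (pen * new**2).sum()
            if obj_new >= obj - 1e-12:
                break
            factor /= 2.0
        converged = np.abs(new - phi).max() < tol
        phi, pl, grad, hess, obj = new, pl_new, grad_new, hess_new, obj_new
        if converged:
            break
    return phi, pl, hess


def _laplace_marginal(X, Z, time, event, theta):
    phi, pl, hess = _ppl_fit(X, Z, time, event, theta)
    q = X.shape[1]
    b = phi[q:]
    K = hess[q:, q:]
    sign, logdet = np.linalg.slogdet(theta * K + np.eye(len(b)))
    lm = pl - (b @ b) / (2.0 * theta) - 0.5 * logdet
    return lm, phi, hess


@dataclass
class KMCurve:
    """Right-continuous product-limit survival curve."""

    times: np.ndarray
    survival: np.ndarray
    label: str = ""

    def at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, len(self.times) - 1)])
        return out if out.size > 1 else float(out[0])


@dataclass
class RiskGroupResult:
    hr: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    beta: float
    se: float
    site_variance: float
    method: str
    n_per_group: dict
    events_per_group: dict
    km_curves: dict = field(repr=False, default_factory=dict)
    unstable: bool = False

    def summary(self) -> str:
        lines = [
            "Risk-group Cox comparison (HRR vs low risk)",
            f"  method          : {self.method}",
            f"  HR              : {self.hr:.3f}  (95% CI {self.ci_low:.3f} - {self.ci_high:.3f})",
            f"  Z               : {self.z:.3f}   P = {self.p:.4f}",
            f"  site variance   : {self.site_variance:.4f}",
            f"  n (HRR / low)   : {self.n_per_group.get('HRR', 0)} / {self.n_per_group.get('low', 0)}",
            f"  events (HRR/low): {self.events_per_group.get('HRR', 0)} / {self.events_per_group.get('low', 0)}",
        ]
        if self.unstable:
            lines.append("  WARNING: all events in one group; profile-likelihood CI")
        return "\n".join(lines)


def kaplan_meier(times, events, group=None) -> dict:
    """Product-limit estimator per group; handles right censoring."""
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, float)
    events = as_bool_events(events)
    if (times <= 0).any():
        raise ValueError("times must be positive")
    if group is None:
        group = np.array(["all"] * len(times))
    group = np.asarray(group)
    curves = {}
    for g in np.unique(group):
        rows = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[rows], events[rows])
        sf = kmf.survival_function_
        curves[str(g)] = KMCurve(
            times=sf.index.to_numpy(float),
            survival=sf.iloc[:, 0].to_numpy(float),
            label=str(g),
        )
    return curves


def plot_kaplan_meier(times, events, group=None, ax=None):
    """Step plot of the per-group product-limit curves with censor ticks.

    Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib.pyplot as plt

    times = np.asarray(times, float)
    events = as_bool_events(events)
    if group is None:
        group = np.array(["all"] * len(times))
    group = np.asarray(group).astype(str)
    curves = kaplan_meier(times, events, group)
    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        (line,) = ax.step(curve.times, curve.survival, where="post", label=label)
        rows = (group == label) & ~events
        if rows.any():
            ax.plot(
                times[rows],
                curve.at(times[rows]) if rows.sum() > 1 else [curve.at(times[rows])],
                "|",
                color=line.get_color(),
                markersize=8,
            )
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def risk_group_cox(times, events, risk_group, site_labels=None) -> RiskGroupResult:
    """Compare observed relapse between estimated high- and low-risk groups
    with a site-aware Cox model.

    ``risk_group`` is boolean (True = high risk). With more than two sites a
    Gaussian site random intercept is fitted; the variance is profiled on a
    Laplace approximation to the marginal likelihood. With <= 2 sites, or
    when the variance estimate hits the zero boundary, the model falls back
    to site-stratified Cox (a single site reduces to plain Cox).
    """
    times = np.asarray(times, float)
    events = as_bool_events(events)
    risk_group = np.asarray(risk_group).astype(bool)
    if site_labels is None:
        site_labels = np.zeros(len(times), dtype=int)
    site_labels = np.asarray(site_labels)
    if risk_group.all() or (~risk_group).all():
        raise ValueError("both risk groups must be non-empty")
    if events.sum() < 2:
        raise ValueError("need >= 2 events")
    x = risk_group.astype(float)[:, None]
    sites, site_idx = np.unique(site_labels, return_inverse=True)
    n_sites = len(sites)
    ev_hi = int(events[risk_group].sum())
    ev_lo = int(events[~risk_group].sum())
    counts = {"HRR": int(risk_group.sum()), "low": int((~risk_group).sum())}
    ev_counts = {"HRR": ev_hi, "low": ev_lo}
    km = kaplan_meier(times, events, np.where(risk_group, "HRR", "low"))

    unstable = ev_hi == 0 or ev_lo == 0
    if unstable:
        # monotone partial likelihood: report the profile-likelihood interval
        logger.warning("all events in one risk group; profile-likelihood CI")
        grid = np.linspace(-12.0, 12.0, 481)
        pls = np.array([_cox_derivs(x, times, events, np.array([b]))[0] for b in grid])
        i_best = int(np.argmax(pls))
        beta_hat = float(grid[i_best])
        keep = 2.0 * (pls[i_best] - pls) <= stats.chi2.ppf(0.95, 1)
        ci = (float(grid[keep].min()), float(grid[keep].max()))
        pl0 = _cox_derivs(x, times, events, np.zeros(1))[0]
        lrt = max(0.0, 2.0 * (pls[i_best] - pl0))
        z = float(np.sign(beta_hat) * np.sqrt(lrt))
        p = float(stats.chi2.sf(lrt, 1))
        return RiskGroupResult(
            hr=float(np.exp(beta_hat)),
            ci_low=float(np.exp(ci[0])),
            ci_high=float(np.exp(ci[1])),
            z=z,
            p=p,
            beta=beta_hat,
            se=float("nan"),
            site_variance=0.0,
            method="profile",
            n_per_group=counts,
            events_per_group=ev_counts,
            km_curves=km,
            unstable=True,
        )

    method = "stratified" if n_sites <= 2 else "frailty"
    site_var = 0.0
    if method == "frailty":
        Z = np.eye(n_sites)[site_idx]
        neg = lambda lt: -_laplace_marginal(x, Z, times, events, np.exp(lt))[0]
        res = optimize.minimize_scalar(neg, bounds=(np.log(1e-4), np.log(10.0)), method="bounded")
        theta = float(np.exp(res.x))
        if theta <= 2e-4:  # boundary: no detectable site variance
            logger.info("site variance at boundary; falling back to stratified Cox")
            method = "stratified"
        else:
            site_var = theta
            _, phi, hess = _laplace_marginal(x, Z, times, events, theta)
            pen = np.zeros(1 + n_sites)
            pen[1:] = 1.0 / theta
            cov = np.linalg.inv(hess + np.diag(pen))
            beta_hat = float(phi[0])
            se = float(np.sqrt(cov[0, 0]))
    if method == "stratified":
        strata = site_idx if n_sites > 1 else None
        beta_vec, cov, _ = cox_newton(x, times, events, strata=strata)
        beta_hat = float(beta_vec[0])
        se = float(np.sqrt(cov[0, 0]))
        if n_sites == 1:
            method = "plain"
    z = beta_hat / se
    p = 2.0 * stats.norm.sf(abs(z))
    ci = (beta_hat - 1.959963984540054 * se, beta_hat + 1.959963984540054 * se)
    return RiskGroupResult(
        hr=float(np.exp(beta_hat)),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        z=float(z),
        p=float(p),
        beta=beta_hat,
        se=se,
        site_variance=site_var,
        method=method,
        n_per_group=counts,
        events_per_group=ev_counts,
        km_curves=km,
    )


# ----------------------------------------------------------------------
# voxelwise univariate survival map
def cox_score_z(X, time, event):
    """Vectorized per-column Cox score test at beta = 0.

    Returns (z, variance); z is signed by the direction of association and
    NaN for zero-variance columns.
    """
    X = np.asarray(X, float)
    time = np.asarray(time, float)
    event = as_bool_events(event)
    order = np.argsort(time, kind="stable")
    Xs, ts, ev = X[order], time[order], event[order]
    n, p = Xs.shape
    uniq = np.unique(ts[ev])
    first_idx = np.searchsorted(ts, uniq, side="left")
    # reverse cumulative sums of x and x^2 (risk-set aggregates at eta = 0)
    rc1 = np.cumsum(Xs[::-1], axis=0)[::-1]
    rc2 = np.cumsum((Xs**2)[::-1], axis=0)[::-1]
    at_risk = n - first_idx
    U = np.zeros(p)
    V = np.zeros(p)
    for t_j, i0, R in zip(uniq, first_idx, at_risk):
        at = ev & (ts == t_j)
        d = at.sum()
        S1 = rc1[i0]
        S2 = rc2[i0]
        xbar = S1 / R
        U += Xs[at].sum(axis=0) - d * xbar
        V += d * (S2 / R - xbar**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = U / np.sqrt(V)
    z[V <= 0] = np.nan
    return z, V


@dataclass
class VoxelSurvivalMap:
    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray  # two-sided P below threshold
    p_threshold: float
    excluded: np.ndarray  # zero-variance columns

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def voxelwise_survival_map(voxel_features, times, events, p_threshold=0.005) -> VoxelSurvivalMap:
    """Univariate association of each voxel with relapse hazard (Cox score
    test), thresholded at an uncorrected two-sided P."""
    events = as_bool_events(events)
    if events.sum() < 2:
        raise ValueError("need >= 2 events")
    z, V = cox_score_z(voxel_features, times, events)
    excluded = ~np.isfinite(z)
    if excluded.any():
        logger.info("voxelwise map: excluding %d zero-variance voxels", excluded.sum())
    p = np.where(excluded, 1.0, 2.0 * stats.norm.sf(np.abs(np.nan_to_num(z))))
    p = np.minimum(p, 1.0)
    significant = (p < p_threshold) & ~excluded
    return VoxelSurvivalMap(z=z, p=p, significant=significant, p_threshold=p_threshold, excluded=excluded)


# ----------------------------------------------------------------------
# survival power (Schoenfeld approximation)
def power_events(hr, n_events, prop_exposed=0.5, alpha=0.05) -> float:
    """Power of a two-group log-rank/Cox comparison with ``n_events`` events
    via the Schoenfeld approximation:
    ``Phi( sqrt(E p (1-p)) |ln hr| - z_{1-alpha/2} )``."""
    if hr <= 0:
        raise ValueError("hr must be positive")
    if not 0 < prop_exposed < 1:
        raise ValueError("prop_exposed must be in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2.0)
    drift = np.sqrt(n_events * prop_exposed * (1 - prop_exposed)) * abs(np.log(hr))
    return float(stats.norm.cdf(drift - za))


def events_required(hr, power=0.8, prop_exposed=0.5, alpha=0.05) -> int:
    """Invert the Schoenfeld approximation for the required event count."""
    if hr <= 0:
        raise ValueError("hr must be positive")
    if hr == 1:
        raise ValueError("hr = 1 needs infinitely many events")
    if not 0 < prop_exposed < 1:
        raise ValueError("prop_exposed must be in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    e = ((za + zb) / (np.sqrt(prop_exposed * (1 - prop_exposed)) * abs(np.log(hr)))) ** 2
    return int(np.ceil(e))
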