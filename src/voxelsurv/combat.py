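"""ComBat multi-site harmonization with a strict train/apply split.

Classic ComBat (empirical-Bayes location/scale batch correction with
parametric priors) estimates and removes site effects in one pass over all
data. For predictive modelling that is a leak: here ``combat_fit`` estimates
every parameter — feature-wise standardization model, pooled variance, and
EB-shrunken per-site location (gamma*) and scale (delta*) — from the
training subjects only, and ``combat_apply`` is a pure function that removes
site effects from any subjects (training or held-out) using those frozen
parameters.

The estimation follows the standard parametric ComBat algorithm exactly
(OLS standardization against batch + optional covariates, pooled residual
variance with n denominator, normal prior on location / inverse-gamma on
scale with method-of-moments hyperparameters, and the usual iterative
conditional solution for gamma*/delta*), so on its own training set
``fit + apply`` reproduces classic ComBat output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._utils import logger

DELTA_FLOOR = 1e-8  # degenerate (zero within-site variance) guard


@dataclass
class HarmonizationParams:
    sites: list
    grand_mean: np.ndarray  # (p,)
    cov_coefs: np.ndarray | None  # (n_cov, p) slopes of the standardization model
    var_pooled: np.ndarray  # (p,)
    gamma_star: np.ndarray  # (n_sites, p)
    delta_star: np.ndarray  # (n_sites, p)
    identity: bool = False
    n_covariates: int = 0
    schema_version: int = 1

    def __post_init__(self):
        if not self.identity:
            if (self.delta_star <= 0).any():
                raise ValueError("delta_star must be positive")
            if self.gamma_star.shape[0] != len(self.sites):
                raise ValueError("one (gamma*, delta*) row per site required")

    def site_index(self, label) -> int:
        try:
            return self.sites.index(label)
        except ValueError:
            raise KeyError(
                f"site {label!r} was not in the training roster {self.sites}; "
                "cannot harmonize subjects from unseen sites"
            ) from None

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "identity": self.identity,
            "sites": [str(s) for s in self.sites],
            "grand_mean": self.grand_mean.tolist(),
            "cov_coefs": None if self.cov_coefs is None else self.cov_coefs.tolist(),
            "var_pooled": self.var_pooled.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "n_covariates": self.n_covariates,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HarmonizationParams":
        return cls(
            sites=list(d["sites"]),
            grand_mean=np.asarray(d["grand_mean"], float),
            cov_coefs=None if d["cov_coefs"] is None else np.asarray(d["cov_coefs"], float),
            var_pooled=np.asarray(d["var_pooled"], float),
            gamma_star=np.asarray(d["gamma_star"], float),
            delta_star=np.asarray(d["delta_star"], float),
            identity=bool(d["identity"]),
            n_covariates=int(d.get("n_covariates", 0)),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path) -> "HarmonizationParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _identity_params(p: int) -> HarmonizationParams:
    return HarmonizationParams(
        sites=[],
        grand_mean=np.zeros(p),
        cov_coefs=None,
        var_pooled=np.ones(p),
        gamma_star=np.zeros((0, p)),
        delta_star=np.ones((0, p)),
        identity=True,
    )


def combat_fit(
    train_features: np.ndarray,
    site_labels,
    covariates: np.ndarray | None = None,
    eb: bool = True,
    conv: float = 1e-6,
    max_iter: int = 500,
) -> HarmonizationParams:
    """Estimate frozen harmonization parameters from training subjects.

    Parameters
    ----------
    train_features : (n, p) array, subjects x features.
    site_labels : length-n site labels (>= 2 sites, each with >= 2 subjects).
    covariates : optional (n, c) design of biological covariates whose
        effects the standardization model preserves.
    eb : empirical-Bayes shrinkage (parametric priors); ``False`` gives the
        method-of-moments (no-shrinkage) location/scale estimates, used as an
        internal oracle in tests.
    conv, max_iter : stopping rule of the iterative conditional EB solution
        (maximum relative parameter change below ``conv``).
    """
    X = np.asarray(train_features, dtype=np.float64)
    n, p = X.shape
    site_labels = np.asarray(site_labels)
    sites = sorted(set(site_labels.tolist()))
    if len(sites) < 2:
        logger.warning("combat_fit: single site; returning identity harmonization")
        return _identity_params(p)
    counts = {s: int((site_labels == s).sum()) for s in sites}
    if min(counts.values()) < 2:
        raise ValueError(f"every site needs >= 2 training subjects, got {counts}")

    batch = np.stack([(site_labels == s).astype(float) for s in sites], axis=1)
    design = batch if covariates is None else np.hstack([batch, np.asarray(covariates, float)])
    n_cov = design.shape[1] - batch.shape[1]
    B_hat, *_ = np.linalg.lstsq(design, X, rcond=None)  # (n_batch + c, p)
    n_batches = np.array([counts[s] for s in sites], dtype=float)
    grand_mean = (n_batches / n) @ B_hat[: len(sites)]
    cov_coefs = B_hat[len(sites):] if n_cov else None
    resid = X - design @ B_hat
    var_pooled = (resid**2).mean(axis=0)
    tiny = var_pooled <= 0
    if tiny.any():
        logger.warning("combat_fit: %d features with zero pooled variance", tiny.sum())
        var_pooled = np.where(tiny, 1e-12, var_pooled)

    stand_mean = grand_mean[None, :] + (
        0.0 if cov_coefs is None else design[:, len(sites):] @ cov_coefs
    )
    s_data = (X - stand_mean) / np.sqrt(var_pooled)[None, :]

    gamma_hat = np.stack([s_data[site_labels == s].mean(axis=0) for s in sites])
    delta_hat = np.stack([s_data[site_labels == s].var(axis=0, ddof=1) for s in sites])

    if not eb:
        gamma_star, delta_star = gamma_hat, delta_hat
    else:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i, s in enumerate(sites):
            g_hat, d_hat = gamma_hat[i], delta_hat[i]
            g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
            m, s2 = d_hat.mean(), d_hat.var(ddof=1)
            a_prior = (2 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            sdat = s_data[site_labels == s]
            ns = sdat.shape[0]
            g_old, d_old = g_hat.copy(), d_hat.copy()
            for _ in range(max_iter):
                g_new = (t2 * ns * g_hat + d_old * g_bar) / (t2 * ns + d_old)
                sum2 = ((sdat - g_new[None, :]) ** 2).sum(axis=0)
                d_new = (0.5 * sum2 + b_prior) / (ns / 2.0 + a_prior - 1.0)
                change = max(
                    np.max(np.abs(g_new - g_old) / g_old),
                    np.max(np.abs(d_new - d_old) / d_old),
                )
                g_old, d_old = g_new, d_new
                if change < conv:
                    break
            gamma_star[i], delta_star[i] = g_old, d_old
    low = delta_star < DELTA_FLOOR
    if low.any():
        logger.warning("combat_fit: flooring %d delta* values at %g", low.sum(), DELTA_FLOOR)
        delta_star = np.where(low, DELTA_FLOOR, delta_star)

    return HarmonizationParams(
        sites=sites,
        grand_mean=grand_mean,
        cov_coefs=cov_coefs,
        var_pooled=var_pooled,
        gamma_star=gamma_star,
        delta_star=delta_star,
        n_covariates=n_cov,
    )


def combat_apply(
    features: np.ndarray,
    site_labels,
    params: HarmonizationParams,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Remove site effects using frozen parameters; never re-estimates.

    ``x' = destandardize( (standardize(x) - gamma*_site) / sqrt(delta*_site) )``
    with the standardization model (grand mean, covariate slopes, pooled
    variance) frozen from the training fit. Subjects from sites absent from
    the training roster raise an explicit error.
    """
    X = np.asarray(features, dtype=np.float64)
    if params.identity:
        return X.copy()
    if params.n_covariates:
        if covariates is None or np.asarray(covariates).shape[1] != params.n_covariates:
            raise ValueError("params were fitted with covariates; provide the same design")
        cov_effect = np.asarray(covariates, float) @ params.cov_coefs
    else:
        cov_effect = 0.0
    site_labels = np.asarray(site_labels)
    site_idx = np.array([params.site_index(s) for s in site_labels])
    stand_mean = params.grand_mean[None, :] + cov_effect
    s_data = (X - stand_mean) / np.sqrt(params.var_pooled)[None, :]
    adj = (s_data - params.gamma_star[site_idx]) / np.sqrt(params.delta_star[site_idx])
    return adj * np.sqrt(params.var_pooled)[None, :] + stand_mean
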