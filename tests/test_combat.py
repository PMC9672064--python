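"""Harmonization: moments oracle, reference cross-check, leakage and
covariate-preservation properties."""

import subprocess

import numpy as np
import pytest

from voxelsurv import combat_apply, combat_fit
from voxelsurv.combat import HarmonizationParams
from voxelsurv._utils import stable_hash


def planted_sites(rng, n_per_site=100, p=30, shift=1.0, scale=0.3, sites=("a", "b")):
    """Location/scale batch effects drawn per (site, feature) — the
    generative model the EB harmonization assumes."""
    labels = np.repeat(sites, n_per_site)
    X = rng.normal(0.0, 1.0, (len(labels), p)) + rng.normal(0, 0.5, p)[None, :]
    drawn = {}
    for s in sites:
        rows = labels == s
        sh = rng.normal(0, shift, p) if shift else np.zeros(p)
        sc = np.exp(rng.normal(0, scale, p)) if scale else np.ones(p)
        X[rows] = X[rows] * sc[None, :] + sh[None, :]
        drawn[s] = (sh, sc)
    return X, labels, drawn


def test_single_site_identity():
    rng = np.random.default_rng(0)
    X = rng.normal(0, 1, (20, 5))
    params = combat_fit(X, np.array(["s"] * 20))
    assert params.identity
    assert np.array_equal(combat_apply(X, ["s"] * 20, params), X)


def test_two_site_shift_matches_moments_oracle():
    """With a pure shift and many subjects, EB-shrunken site locations match
    the method-of-moments (no-shrinkage) estimates closely and sit near
    +-c/2 in standardized units."""
    rng = np.random.default_rng(1)
    n, p = 400, 40
    labels = np.repeat(["a", "b"], n // 2)
    X = rng.normal(0, 1, (n, p))
    c = 1.0
    X[labels == "b"] += c
    eb = combat_fit(X, labels)
    mom = combat_fit(X, labels, eb=False)
    # shrinkage pulls per-feature estimates toward the site mean: site-level
    # averages agree tightly, individual features within shrinkage tolerance
    assert np.abs(eb.gamma_star.mean(axis=1) - mom.gamma_star.mean(axis=1)).max() < 0.01
    assert np.abs(eb.gamma_star - mom.gamma_star).max() < 0.15
    sd = np.sqrt(eb.var_pooled)
    # standardized shift of each site from the grand mean: -c/2 and +c/2
    expect = c / 2.0 / sd.mean()
    assert np.allclose(eb.gamma_star[0].mean(), -expect, atol=0.1)
    assert np.allclose(eb.gamma_star[1].mean(), expect, atol=0.1)


def test_fit_apply_removes_planted_site_effects():
    rng = np.random.default_rng(2)
    X, labels, _ = planted_sites(rng, n_per_site=500, p=60, shift=1.0, scale=0.3)
    params = combat_fit(X, labels)
    H = combat_apply(X, labels, params)
    pooled_sd = H.std(axis=0)
    mean_gap = np.abs(H[labels == "a"].mean(axis=0) - H[labels == "b"].mean(axis=0))
    assert (mean_gap / pooled_sd < 0.05).mean() >= 0.95
    vr = H[labels == "a"].var(axis=0) / H[labels == "b"].var(axis=0)
    assert ((vr > 0.9) & (vr < 1.1)).mean() >= 0.95


def test_matches_reference_combat_implementation(tmp_path):
    """fit+apply on the training set reproduces classic ComBat: cross-check
    against the Bioconductor reference via Rscript (same stopping rule)."""
    rng = np.random.default_rng(42)
    X, labels, _ = planted_sites(
        rng, n_per_site=20, p=25, shift=0.7, scale=0.3, sites=("a", "b", "c")
    )
    np.savetxt(tmp_path / "dat.csv", X.T, delimiter=",")
    (tmp_path / "batch.csv").write_text("\n".join(labels))
    (tmp_path / "cb.R").write_text(
        'suppressMessages(library(sva))\n'
        'dat <- as.matrix(read.csv("dat.csv", header=FALSE))\n'
        'batch <- readLines("batch.csv")\n'
        'out <- ComBat(dat=dat, batch=batch, mod=NULL, par.prior=TRUE)\n'
        'write.table(out, "out.csv", sep=",", row.names=FALSE, col.names=FALSE)\n'
    )
    res = subprocess.run(
        ["Rscript", "cb.R"], cwd=tmp_path, capture_output=True, text=True, timeout=300
    )
    assert res.returncode == 0, res.stderr
    ref = np.loadtxt(tmp_path / "out.csv", delimiter=",").T
    params = combat_fit(X, labels, conv=1e-4)  # reference stopping rule
    mine = combat_apply(X, labels, params)
    assert np.abs(mine - ref).max() < 1e-6


def test_apply_is_frozen_linear_in_perturbations():
    rng = np.random.default_rng(3)
    X, labels, _ = planted_sites(rng, n_per_site=30, p=10)
    params = combat_fit(X, labels)
    x0 = X[:1].copy()
    eps = 0.37
    x1 = x0.copy()
    x1[0, 4] += eps
    a = combat_apply(x0, labels[:1], params)
    b = combat_apply(x1, labels[:1], params)
    diff = b - a
    site_idx = params.site_index(labels[0])
    assert np.allclose(diff[0, 4], eps / np.sqrt(params.delta_star[site_idx, 4]))
    diff[0, 4] = 0.0
    assert np.abs(diff).max() < 1e-12


def test_unseen_site_errors():
    rng = np.random.default_rng(4)
    X, labels, _ = planted_sites(rng, n_per_site=20, p=5)
    params = combat_fit(X, labels)
    with pytest.raises(KeyError, match="unseen"):
        combat_apply(X[:2], np.array(["zz", "zz"]), params)


def test_fit_ignores_held_out_subjects():
    rng = np.random.default_rng(5)
    X, labels, _ = planted_sites(rng, n_per_site=40, p=8)
    train = np.arange(60)
    params1 = combat_fit(X[train], labels[train])
    X2 = X.copy()
    X2[60:] = rng.normal(10, 5, X2[60:].shape)  # mutate held-out rows only
    params2 = combat_fit(X2[train], labels[train])
    assert stable_hash(params1.to_dict()) == stable_hash(params2.to_dict())


def test_double_application_is_not_idempotent():
    rng = np.random.default_rng(6)
    X, labels, _ = planted_sites(rng, n_per_site=30, p=6, shift=1.0, scale=0.4)
    params = combat_fit(X, labels)
    once = combat_apply(X, labels, params)
    twice = combat_apply(once, labels, params)
    assert np.abs(once - twice).max() > 1e-6


def test_covariate_effect_preserved_by_fit_apply():
    """A planted age slope on the features survives harmonization within 5%
    (ComBat removes site location/scale, not biology)."""
    rng = np.random.default_rng(7)
    n = 400
    labels = np.repeat(["a", "b"], n // 2)
    age = rng.uniform(15, 50, n)
    slope = 0.05
    X = rng.normal(0, 1, (n, 20)) + slope * (age - age.mean())[:, None]
    X[labels == "b"] += 0.8
    params = combat_fit(X, labels)
    H = combat_apply(X, labels, params)
    ac = age - age.mean()
    slopes_before = (ac @ X) / (ac @ ac)
    slopes_after = (ac @ H) / (ac @ ac)
    # paired comparison cancels the sampling noise of the slope estimate
    assert np.abs(slopes_after / slopes_before - 1.0).mean() < 0.05


def test_params_json_roundtrip(tmp_path):
    rng = np.random.default_rng(8)
    X, labels, _ = planted_sites(rng, n_per_site=20, p=5)
    params = combat_fit(X, labels)
    params.to_json(tmp_path / "p.json")
    back = HarmonizationParams.from_json(tmp_path / "p.json")
    assert np.array_equal(back.gamma_star, params.gamma_star)
    assert np.allclose(combat_apply(X, labels, back), combat_apply(X, labels, params))
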