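"""Fold construction and leakage-free cross-validation orchestration."""

import numpy as np
import pytest

from voxelsurv import Outcome, PipelineConfig, make_folds, run_cv, run_setting_comparison
from voxelsurv.ensembles import EnsembleSpec
from voxelsurv.synthetic import SyntheticSpec, generate_cohort

from conftest import small_spec


def survival_outcome(n=80, n_events=16, seed=0):
    rng = np.random.default_rng(seed)
    e = np.zeros(n, bool)
    e[:n_events] = True
    rng.shuffle(e)
    t = rng.uniform(1, 24, n)
    return Outcome.survival(t, e)


def test_sixteen_events_ten_folds_event_multiset():
    out = survival_outcome(n=170, n_events=16)
    folds = make_folds(out, k=10, seed=3)
    counts = sorted(np.bincount(folds[out.event], minlength=10).tolist())
    assert counts == [1, 1, 1, 1, 2, 2, 2, 2, 2, 2]


def test_leave_one_out_and_errors():
    out = survival_outcome(n=12, n_events=4)
    folds = make_folds(out, k=12, seed=0)
    assert sorted(np.bincount(folds).tolist()) == [1] * 12
    with pytest.raises(ValueError):
        make_folds(out, k=13, seed=0)
    with pytest.raises(ValueError):
        make_folds(out, k=1, seed=0)


def test_folds_partition_and_determinism():
    out = survival_outcome(n=95, n_events=20, seed=4)
    a = make_folds(out, k=7, seed=9)
    b = make_folds(out, k=7, seed=9)
    assert np.array_equal(a, b)
    assert set(a) == set(range(7))
    sizes = np.bincount(a)
    assert sizes.max() - sizes.min() <= 1
    ev = np.bincount(a[out.event], minlength=7)
    assert ev.max() - ev.min() <= 1


# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def cv_cohort():
    return generate_cohort(small_spec(n_subjects=80, seed=31))


@pytest.fixture(scope="module")
def cv_config():
    return PipelineConfig(
        subsample_mm=6.0,
        ensemble=EnsembleSpec("none", 1),
        k_folds=5,
        n_inner_folds=4,
        seed=31,
    )


@pytest.fixture(scope="module")
def cv_result(cv_cohort, cv_config):
    return run_cv(cv_cohort, cv_config)


def test_out_of_fold_estimates_cover_every_subject_once(cv_result, cv_cohort):
    preds = cv_result.predictions
    assert len(preds) == cv_cohort.outcome.n
    assert preds["subject_id"].is_unique
    assert np.isfinite(preds["lp"]).all()
    assert set(preds["fold"]) == set(range(5))


def test_run_cv_deterministic(cv_cohort, cv_config, cv_result):
    again = run_cv(cv_cohort, cv_config)
    assert np.allclose(again.lp, cv_result.lp, atol=1e-10)


def test_leakage_sentinel_mutating_test_fold(cv_cohort, cv_config, cv_result):
    """Replacing a held-out fold's voxel data with noise changes that fold's
    predictions but not a single training-derived parameter of its models."""
    folds = cv_result.fold_assignment
    mutate = folds == 0
    rng = np.random.default_rng(99)
    vols2 = cv_cohort.volumes.copy()
    vols2.data[mutate] = rng.normal(0, 1, vols2.data[mutate].shape)
    res2 = run_cv(
        vols2,
        cv_config,
        clinical=cv_cohort.clinical,
        outcome=cv_cohort.outcome,
        fold_assignment=folds,
    )
    h1 = [m.bundle_hash() for m in cv_result.models[0]]
    h2 = [m.bundle_hash() for m in res2.models[0]]
    assert h1 == h2
    assert not np.allclose(res2.lp[mutate], cv_result.lp[mutate])


def test_site_missing_from_training_split_excluded(cv_cohort, cv_config):
    clin = cv_cohort.clinical.copy()
    # give one subject a unique site: its training splits never contain it
    clin.loc[0, "site"] = "siteX"
    res = run_cv(cv_cohort.volumes, cv_config, clinical=clin, outcome=cv_cohort.outcome)
    assert res.predictions["excluded"].iloc[0]
    assert np.isnan(res.predictions["lp"].iloc[0])
    assert res.predictions["excluded"].sum() == 1


def test_gaussian_cv_beats_null_model():
    """With planted signal, out-of-fold MAE is below the null model's
    (training-mean prediction) in each of several seeds."""
    wins = 0
    seeds = range(5)
    for seed in seeds:
        c = generate_cohort(
            small_spec(n_subjects=100, seed=200 + seed, outcome_family="gaussian")
        )
        cfg = PipelineConfig(
            family="gaussian",
            subsample_mm=6.0,
            ensemble=EnsembleSpec("none", 1),
            k_folds=5,
            n_inner_folds=4,
            seed=seed,
        )
        res = run_cv(c, cfg)
        mae = np.nanmean(res.absolute_errors())
        mae_null = np.nanmean(res.null_absolute_errors())
        wins += mae < mae_null
    assert wins == len(list(seeds))


def test_setting_comparison_self_and_noop():
    c = generate_cohort(small_spec(n_subjects=80, seed=77, outcome_family="gaussian"))
    base = dict(
        family="gaussian", subsample_mm=6.0, k_folds=5, n_inner_folds=4, seed=7
    )
    ref = PipelineConfig(ensemble=EnsembleSpec("none", 1), label="ref", **base)
    noop = PipelineConfig(ensemble=EnsembleSpec("none", 1), label="noop_twin", **base)
    comp = run_setting_comparison(c.volumes, [ref, noop], ref, clinical=c.clinical, outcome=c.outcome)
    t = comp.table.set_index("config")
    assert t.loc["ref", "p_vs_reference"] == 1.0
    assert t.loc["noop_twin", "p_vs_reference"] == 1.0
    assert np.isclose(t.loc["ref", "mae"], t.loc["noop_twin", "mae"])
    bad = PipelineConfig(ensemble=EnsembleSpec("none", 1), family="gaussian", k_folds=4, seed=7)
    with pytest.raises(ValueError, match="share"):
        run_setting_comparison(c.volumes, [bad], ref, clinical=c.clinical, outcome=c.outcome)
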