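"""Event-stratified cross-validation of the full pipeline, and the paired
parameter-comparison harness.

``run_cv`` trains every data-derived transform (harmonization,
residualization, scaling, screening, penalty selection, coefficients)
inside each training split and scores the held-out fold with the frozen
bundles, so each subject receives exactly one out-of-fold risk estimate and
no test information ever reaches a fit. ``run_setting_comparison`` runs
several configurations over the *same* fold plan and compares their
per-subject absolute errors with paired Wilcoxon tests, against a reference
configuration and against a null model (predicting the training mean for
continuous outcomes; a coin flip for binary ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import derive_seed, logger
from .evaluation import RiskGroupResult, risk_group_cox
from .features import FeatureMatrix
from .outcomes import Outcome, make_folds
from .pipeline import (
    FittedRiskModel,
    PipelineConfig,
    fit_risk_models,
    prepare_imaging,
    score,
)
from .synthetic import SyntheticCohort


@dataclass
class CVResult:
    predictions: pd.DataFrame  # subject_id, fold, lp, risk_group, excluded
    fold_assignment: np.ndarray
    models: list  # per fold: list of member FittedRiskModel
    config: PipelineConfig
    outcome: Outcome

    @property
    def lp(self) -> np.ndarray:
        return self.predictions["lp"].to_numpy()

    @property
    def included(self) -> np.ndarray:
        return ~self.predictions["excluded"].to_numpy()

    def risk_group_result(self, site_labels=None) -> RiskGroupResult:
        """Site-aware Cox comparison of out-of-fold risk groups."""
        if self.outcome.family != "survival":
            raise ValueError("risk grouping is defined for survival outcomes")
        inc = self.included
        hi = self.predictions["lp"].to_numpy() > 0
        return risk_group_cox(
            self.outcome.time[inc],
            self.outcome.event[inc],
            hi[inc],
            None if site_labels is None else np.asarray(site_labels)[inc],
        )

    def absolute_errors(self) -> np.ndarray:
        """Per-subject out-of-fold absolute error (NaN for excluded).

        gaussian: |y - prediction|; binomial: 0/1 misclassification of the
        thresholded probability. Not defined for censored survival outcomes.
        """
        pred = self.predictions["lp"].to_numpy()
        if self.outcome.family == "gaussian":
            err = np.abs(self.outcome.y - pred)
        elif self.outcome.family == "binomial":
            err = (self.outcome.y != (pred > 0).astype(float)).astype(float)
        else:
            raise ValueError("absolute errors undefined for survival outcomes")
        err = err.astype(float)
        err[~self.included] = np.nan
        return err

    def null_absolute_errors(self) -> np.ndarray:
        """Errors of the null model: per-fold training mean (gaussian) or a
        fair coin (binomial, expected error 1/2)."""
        n = self.outcome.n
        if self.outcome.family == "gaussian":
            err = np.empty(n)
            for f in np.unique(self.fold_assignment):
                test = self.fold_assignment == f
                err[test] = np.abs(self.outcome.y[test] - self.outcome.y[~test].mean())
        else:
            err = np.full(n, 0.5)
        err[~self.included] = np.nan
        return err


def _as_parts(cohort_or_volumes, clinical=None, outcome=None):
    if isinstance(cohort_or_volumes, SyntheticCohort):
        c = cohort_or_volumes
        return c.volumes, c.clinical, c.outcome
    return cohort_or_volumes, clinical, outcome


def run_cv(
    cohort_or_volumes,
    config: PipelineConfig,
    clinical: pd.DataFrame | None = None,
    outcome: Outcome | None = None,
    fold_assignment: np.ndarray | None = None,
    prepared: FeatureMatrix | None = None,
) -> CVResult:
    """Out-of-fold risk estimation for every subject.

    Subjects whose site does not occur in their training split cannot be
    harmonized and are excluded from evaluation (logged, flagged in the
    predictions table).
    """
    volumes, clinical, outcome = _as_parts(cohort_or_volumes, clinical, outcome)
    fm = prepared if prepared is not None else prepare_imaging(volumes, config, clinical)
    if fold_assignment is None:
        fold_assignment = make_folds(outcome, k=config.k_folds, seed=derive_seed(config.seed, "folds"))
    folds = np.asarray(fold_assignment)
    n = fm.n_subjects
    lp = np.full(n, np.nan)
    excluded = np.zeros(n, dtype=bool)
    models = []
    for f in np.unique(folds):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        # singleton sites cannot be harmonized (EB needs >= 2 subjects):
        # drop such training subjects from this fold's training set
        tr_sites, tr_counts = np.unique(fm.site_labels[train_idx], return_counts=True)
        lonely = set(tr_sites[tr_counts < 2])
        if lonely:
            logger.warning("fold %s: dropping %d training subjects from singleton sites %s",
                           f, sum(s in lonely for s in fm.site_labels[train_idx]), sorted(lonely))
            train_idx = train_idx[[s not in lonely for s in fm.site_labels[train_idx]]]
        fm_tr = fm.subset_subjects(train_idx)
        clin_tr = clinical.iloc[train_idx].reset_index(drop=True)
        out_tr = outcome.subset(train_idx)
        members = fit_risk_models(
            fm_tr, clin_tr, out_tr, config, seed=derive_seed(config.seed, "fold", int(f))
        )
        models.append(members)
        train_sites = set(fm_tr.site_labels.tolist()) - lonely
        ok = np.array([s in train_sites for s in fm.site_labels[test_idx]])
        if not ok.all():
            bad = test_idx[~ok]
            logger.warning(
                "fold %s: excluding %d test subjects from sites unseen in training", f, len(bad)
            )
            excluded[bad] = True
        use = test_idx[ok]
        if len(use):
            est = score(members, fm.subset_subjects(use), clinical.iloc[use].reset_index(drop=True))
            lp[use] = est.lp
    preds = pd.DataFrame(
        {
            "subject_id": fm.subject_ids,
            "fold": folds,
            "lp": lp,
            "risk_group": np.where(lp > 0, "HRR", "low"),
            "excluded": excluded,
        }
    )
    return CVResult(
        predictions=preds,
        fold_assignment=folds,
        models=models,
        config=config,
        outcome=outcome,
    )


# ----------------------------------------------------------------------
def _paired_wilcoxon(a, b) -> float:
    """Two-sided paired Wilcoxon on aligned error vectors; P = 1 when the
    two are identical (no information against the null)."""
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    if np.allclose(d, 0.0):
        return 1.0
    return float(stats.wilcoxon(a[ok], b[ok], zero_method="wilcox").pvalue)


@dataclass
class SettingComparison:
    table: pd.DataFrame
    errors: dict = field(repr=False)

    def __str__(self):  # pragma: no cover - cosmetic
        return self.table.to_string(index=False)


def run_setting_comparison(
    cohort_or_volumes,
    configs: list,
    reference_config: PipelineConfig,
    clinical: pd.DataFrame | None = None,
    outcome: Outcome | None = None,
) -> SettingComparison:
    """Paired comparison of pipeline configurations (same folds and seeds).

    Per configuration: MAE (gaussian) or accuracy (binomial), plus paired
    Wilcoxon P values of the absolute errors against the null model and
    against the reference configuration.
    """
    volumes, clinical, outcome = _as_parts(cohort_or_volumes, clinical, outcome)
    all_configs = [reference_config] + [c for c in configs if c is not reference_config]
    k0, s0 = reference_config.k_folds, reference_config.seed
    for c in all_configs:
        if c.k_folds != k0 or c.seed != s0:
            raise ValueError("all configs must share k_folds and seed (paired design)")
    folds = make_folds(outcome, k=k0, seed=derive_seed(s0, "folds"))
    errors, rows = {}, []
    ref_err = None
    for c in all_configs:
        res = run_cv(volumes, c, clinical=clinical, outcome=outcome, fold_assignment=folds)
        err = res.absolute_errors()
        null_err = res.null_absolute_errors()
        label = c.label or c.config_hash()[:8]
        errors[label] = err
        if ref_err is None:
            ref_err = err
        if outcome.family == "gaussian":
            metric_name, metric = "mae", float(np.nanmean(err))
        else:
            metric_name, metric = "accuracy", float(1.0 - np.nanmean(err))
        rows.append(
            {
                "config": label,
                metric_name: metric,
                "p_vs_null": _paired_wilcoxon(err, null_err),
                "p_vs_reference": _paired_wilcoxon(err, ref_err),
                "is_reference": c is reference_config,
            }
        )
    return SettingComparison(table=pd.DataFrame(rows), errors=errors)
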