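"""statsmodels-style front end.

:class:`RiskModel` is built from data (volumes + clinical table + outcome,
or directly from a :class:`SyntheticCohort`); ``fit()`` returns a
:class:`RiskModelResults` carrying the frozen scoring bundle(s), the sparse
coefficients and a ``summary()`` table; ``cross_validate()`` returns
:class:`CVResults` with out-of-fold risk estimates and the site-aware
accuracy statistics. Simulation lives in :mod:`voxelsurv.synthetic` and
curve data for plotting hangs off the results objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossval import CVResult, run_cv
from .evaluation import RiskGroupResult
from .features import FeatureMatrix
from .outcomes import Outcome
from .pipeline import PipelineConfig, fit_risk_models, prepare_imaging, score
from .synthetic import SyntheticCohort
from .volumes import VolumeChannelStack


class RiskModel:
    """Relapse-risk model specification: data plus a pipeline configuration.

    Parameters
    ----------
    volumes : VolumeChannelStack
        Cohort imaging data in a common template space.
    clinical : DataFrame
        Per-subject table with at least site, age, sex and the clinical
        regressors.
    outcome : Outcome
        Survival (time, event), gaussian or binomial outcome.
    config : PipelineConfig, optional
        Pipeline settings; defaults to the optimized configuration
        (4 channels, sigma = 4 mm, triple subsampling, 18 half-brain
        members).
    """

    def __init__(
        self,
        volumes: VolumeChannelStack,
        clinical: pd.DataFrame,
        outcome: Outcome,
        config: PipelineConfig | None = None,
    ):
        self.volumes = volumes
        self.clinical = clinical.reset_index(drop=True)
        self.outcome = outcome
        self.config = config or PipelineConfig()
        if volumes.n_subjects != len(self.clinical) or outcome.n != volumes.n_subjects:
            raise ValueError("volumes, clinical table and outcome must align")
        self._prepared: FeatureMatrix | None = None

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, config: PipelineConfig | None = None) -> "RiskModel":
        return cls(cohort.volumes, cohort.clinical, cohort.outcome, config=config)

    @property
    def prepared_features(self) -> FeatureMatrix:
        if self._prepared is None:
            self._prepared = prepare_imaging(self.volumes, self.config, self.clinical)
        return self._prepared

    def fit(self, seed: int | None = None) -> "RiskModelResults":
        """Fit preprocessing + penalized model (ensemble) on all subjects."""
        members = fit_risk_models(
            self.prepared_features, self.clinical, self.outcome, self.config, seed=seed
        )
        return RiskModelResults(model=self, members=members)

    def cross_validate(self, fold_assignment=None) -> "CVResults":
        """Leakage-free out-of-fold risk estimation (k folds per config)."""
        res = run_cv(
            self.volumes,
            self.config,
            clinical=self.clinical,
            outcome=self.outcome,
            fold_assignment=fold_assignment,
            prepared=self.prepared_features,
        )
        return CVResults(model=self, cv=res)


@dataclass
class RiskModelResults:
    """Fitted bundle(s) with coefficient access and scoring."""

    model: RiskModel
    members: list

    @property
    def mean_coefficients(self) -> pd.Series:
        beta = np.mean([m.beta for m in self.members], axis=0)
        return pd.Series(beta, index=self.members[0].feature_names, name="beta")

    def coefficient_table(self, min_abs: float = 0.0) -> pd.DataFrame:
        """Nonzero mean-ensemble coefficients with voxel mm coordinates."""
        names = self.members[0].feature_names
        meta = self.members[0].preprocess.imaging_meta
        affine = self.model.prepared_features.grid_affine
        beta = self.mean_coefficients.to_numpy()
        rows = []
        for j, b in enumerate(beta):
            if b == 0.0 or abs(b) < min_abs:
                continue
            row = {"feature": names[j], "beta": float(b)}
            if j < len(meta) and meta.iloc[j]["kind"] == "voxel":
                m = meta.iloc[j]
                xyz = affine[:3, :3] @ np.array([m["ix"], m["iy"], m["iz"]], float) + affine[:3, 3]
                row.update(kind="voxel", channel=m["channel"], x_mm=xyz[0], y_mm=xyz[1], z_mm=xyz[2])
            else:
                row.update(
                    kind=meta.iloc[j]["kind"] if j < len(meta) else "clinical",
                    channel=None,
                    x_mm=np.nan,
                    y_mm=np.nan,
                    z_mm=np.nan,
                )
            rows.append(row)
        df = pd.DataFrame(rows)
        if len(df):
            df = df.reindex(df["beta"].abs().sort_values(ascending=False).index).reset_index(drop=True)
        return df

    def predict(self, volumes=None, clinical=None):
        """Risk estimates for new (or the training) subjects."""
        if volumes is None:
            fm = self.model.prepared_features
            clinical = self.model.clinical
        else:
            fm = prepare_imaging(volumes, self.model.config, clinical)
        return score(self.members, fm, clinical)

    def summary(self, min_abs: float = 0.0) -> str:
        cfg = self.model.config
        tab = self.coefficient_table(min_abs=min_abs)
        head = [
            "Penalized risk model",
            f"  family       : {cfg.family}",
            f"  subjects     : {self.model.volumes.n_subjects}",
            f"  channels     : {', '.join(cfg.channels)}",
            f"  sigma        : {cfg.sigma_mm} mm, subsample {cfg.subsample_mm} mm",
            f"  ensemble     : {cfg.ensemble.method} x {len(self.members)}",
            f"  nonzero betas: {int((self.mean_coefficients != 0).sum())} of {len(self.mean_coefficients)}",
            "",
        ]
        return "\n".join(head) + (tab.to_string(index=False) if len(tab) else "  (all coefficients zero)")


@dataclass
class CVResults:
    """Out-of-fold risk estimates and accuracy statistics."""

    model: RiskModel
    cv: CVResult
    _rg: RiskGroupResult | None = field(default=None, repr=False)

    @property
    def predictions(self) -> pd.DataFrame:
        return self.cv.predictions

    def risk_group_result(self) -> RiskGroupResult:
        if self._rg is None:
            self._rg = self.cv.risk_group_result(site_labels=self.model.clinical["site"].to_numpy())
        return self._rg

    def kaplan_meier(self):
        return self.risk_group_result().km_curves

    def plot_kaplan_meier(self, ax=None):
        """Observed relapse curves of the estimated risk groups (censor
        ticks included); requires matplotlib."""
        from .evaluation import plot_kaplan_meier

        inc = self.cv.included
        hi = np.where(self.cv.lp > 0, "HRR", "low")
        return plot_kaplan_meier(
            self.cv.outcome.time[inc], self.cv.outcome.event[inc], hi[inc], ax=ax
        )

    def summary(self) -> str:
        parts = [
            "Cross-validated risk estimation",
            f"  folds    : {self.model.config.k_folds}",
            f"  subjects : {self.cv.outcome.n} ({int((~self.cv.included).sum())} excluded)",
        ]
        if self.cv.outcome.family == "survival":
            parts.append(self.risk_group_result().summary())
        else:
            err = self.cv.absolute_errors()
            if self.cv.outcome.family == "gaussian":
                parts.append(f"  out-of-fold MAE: {np.nanmean(err):.4f}")
            else:
                parts.append(f"  out-of-fold accuracy: {1 - np.nanmean(err):.4f}")
        return "\n".join(parts)
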