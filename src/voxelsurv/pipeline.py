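"""The leakage-free train/apply pipeline.

Everything estimated from data — ComBat site parameters, age/sex
residualization, clinical min-max scaling, voxel screening, the lasso
penalty and coefficients — is fitted on training subjects only and frozen
into a :class:`FittedRiskModel` bundle; applying the bundle to a new subject
is a pure function. Deterministic spatial operations (smoothing,
subsampling, feature assembly) are subject-wise and carry no cross-subject
information, so they run once per cohort.

Scoring follows the published rule: the risk estimate is the linear
predictor ``lp = sum_j beta_j x_j`` of the (preprocessed) subject; a
subject is assigned to the high-relapse-risk group iff ``lp > 0``
(corresponding to a hazard ratio > 1), ties going to the low-risk group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import derive_seed, logger, stable_hash
from .combat import HarmonizationParams, combat_apply, combat_fit
from .covariates import (
    ClinicalScalingParams,
    ResidualizationParams,
    residualize_apply,
    residualize_fit,
    scale_clinical_apply,
    scale_clinical_fit,
)
from .ensembles import EnsembleSpec, aggregate, bootstrap_indices, make_half_brain_plan
from .features import MIDLINE_COLUMNS, FeatureMatrix, assemble_features, screen_significant_voxels
from .outcomes import Outcome
from .penalized import fit_lasso_cv
from .volumes import CHANNELS, SmoothingSpec, VolumeChannelStack, smooth, subsample

NON_CLINICAL_COLUMNS = ("subject_id", "site", "time", "event")


@dataclass(frozen=True)
class PipelineConfig:
    """Fully determines a run given the data; serializable and hashable.

    Defaults are the configuration found best in the parameter-optimization
    experiments: all four tissue channels, sigma = 4 mm smoothing, triple
    subsampling (3 -> 12 mm voxels), an 18-member voxel (half-brain)
    ensemble, and the deviance-minimizing lambda rule.
    """

    channels: tuple = CHANNELS
    sigma_mm: float = 4.0
    subsample_mm: float | None = 12.0
    include_globals: bool = False
    include_midline: bool = False
    screen_alpha: float | None = None
    ensemble: EnsembleSpec = field(default_factory=EnsembleSpec)
    family: str = "cox"
    lambda_rule: str = "min"
    n_inner_folds: int = 5
    k_folds: int = 10
    use_combat: bool = True
    combat_covariates: bool = False  # pass age/sex into the ComBat model
    include_age: bool = True  # age as a scaled clinical regressor
    include_sex: bool = False
    seed: int = 0
    label: str = ""

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["channels"] = list(self.channels)
        d["ensemble"] = {
            "method": self.ensemble.method,
            "n_members": self.ensemble.n_members,
            "seed": self.ensemble.seed,
        }
        return d

    def config_hash(self) -> str:
        return stable_hash(json.dumps(self.to_dict(), sort_keys=True))


def prepare_imaging(
    volumes: VolumeChannelStack, config: PipelineConfig, clinical: pd.DataFrame | None = None
) -> FeatureMatrix:
    """Smooth, then subsample, then assemble the imaging feature block.

    The order smooth -> subsample is fixed: pooling first would smooth a
    coarser grid and the two do not commute.
    """
    stack = volumes.select_channels([c for c in CHANNELS if c in config.channels])
    if config.sigma_mm and config.sigma_mm > 0:
        stack = smooth(stack, SmoothingSpec(config.sigma_mm))
    if config.subsample_mm is not None:
        stack = subsample(stack, config.subsample_mm)
    fm = assemble_features(
        stack,
        channel_selection=stack.channels,
        include_globals=config.include_globals,
        include_midline=config.include_midline,
        clinical_table=clinical,
    )
    return fm


def clinical_feature_columns(clinical: pd.DataFrame, config: PipelineConfig) -> list:
    cols = []
    for c in clinical.columns:
        if c in NON_CLINICAL_COLUMNS or c in MIDLINE_COLUMNS:
            continue
        if c == "age" and not config.include_age:
            continue
        if c == "sex" and not config.include_sex:
            continue
        if not pd.api.types.is_numeric_dtype(clinical[c]):
            continue
        cols.append(c)
    return cols


# ----------------------------------------------------------------------
@dataclass
class PreprocessParams:
    """All train-fitted transforms, frozen."""

    harmonization: HarmonizationParams | None
    residualization: ResidualizationParams | None
    scaling: ClinicalScalingParams
    kept_imaging_columns: np.ndarray  # indices into the imaging FeatureMatrix
    imaging_meta: pd.DataFrame
    clinical_columns: list
    use_combat_covariates: bool

    @property
    def feature_names(self) -> list:
        return list(self.imaging_meta["name"]) + list(self.scaling.columns)

    def params_hash(self) -> str:
        return stable_hash(
            None if self.harmonization is None else self.harmonization.to_dict(),
            None if self.residualization is None else self.residualization.to_dict(),
            self.scaling.to_dict(),
            self.kept_imaging_columns,
            list(self.clinical_columns),
        )


def fit_preprocess(
    fm_train: FeatureMatrix,
    clinical_train: pd.DataFrame,
    outcome_train: Outcome,
    config: PipelineConfig,
) -> PreprocessParams:
    img_cols = fm_train.columns_of_kind("voxel", "global")
    X_img = fm_train.values[:, img_cols]
    age = clinical_train["age"].to_numpy(float)
    sex = clinical_train["sex"].to_numpy(float)
    covs = np.stack([age, sex], axis=1) if config.combat_covariates else None

    harm = None
    if config.use_combat and len(set(fm_train.site_labels.tolist())) > 1 and X_img.shape[1]:
        harm = combat_fit(X_img, fm_train.site_labels, covariates=covs)
        X_img = combat_apply(X_img, fm_train.site_labels, harm, covariates=covs)

    resid = None
    if X_img.shape[1]:
        resid = residualize_fit(X_img, age, sex)
        X_img = residualize_apply(X_img, age, sex, resid)

    scaling = scale_clinical_fit(clinical_train[clinical_feature_columns(clinical_train, config)])

    # screening runs on the harmonized, residualized imaging block
    kept = img_cols
    if config.screen_alpha is not None:
        fm_proc = replace(
            fm_train,
            values=_with_replaced(fm_train.values, img_cols, X_img),
            harmonized=harm is not None,
            residualized=resid is not None,
        )
        keep_all = screen_significant_voxels(fm_proc, outcome_train, alpha=config.screen_alpha)
        kept = np.intersect1d(keep_all, img_cols)
    # midline columns ride along unchanged
    midline = fm_train.columns_of_kind("midline")
    kept_imaging = np.concatenate([kept, midline]).astype(int)
    meta = fm_train.meta.iloc[kept_imaging].reset_index(drop=True)
    return PreprocessParams(
        harmonization=harm,
        residualization=resid,
        scaling=scaling,
        kept_imaging_columns=kept_imaging,
        imaging_meta=meta,
        clinical_columns=list(scaling.columns),
        use_combat_covariates=config.combat_covariates,
    )


def _with_replaced(values, cols, block):
    out = values.copy()
    out[:, cols] = block
    return out


def apply_preprocess(
    params: PreprocessParams, fm: FeatureMatrix, clinical: pd.DataFrame
) -> np.ndarray:
    """Frozen transform of raw features into the model's regressor space."""
    img_cols = fm.columns_of_kind("voxel", "global")
    X_img = fm.values[:, img_cols]
    age = clinical["age"].to_numpy(float)
    sex = clinical["sex"].to_numpy(float)
    covs = np.stack([age, sex], axis=1) if params.use_combat_covariates else None
    if params.harmonization is not None and X_img.shape[1]:
        X_img = combat_apply(X_img, fm.site_labels, params.harmonization, covariates=covs)
    if params.residualization is not None and X_img.shape[1]:
        X_img = residualize_apply(X_img, age, sex, params.residualization)
    full = _with_replaced(fm.values, img_cols, X_img)
    X_imaging = full[:, params.kept_imaging_columns]
    X_clin = scale_clinical_apply(clinical, params.scaling)
    return np.hstack([X_imaging, X_clin])


# ----------------------------------------------------------------------
@dataclass
class FittedRiskModel:
    """A frozen, self-sufficient scoring bundle."""

    family: str
    beta: np.ndarray  # on the preprocessed-feature scale, original units
    intercept: float
    lambda_: float
    preprocess: PreprocessParams
    training_info: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list:
        return self.preprocess.feature_names

    def nonzero_table(self, min_abs: float = 0.0) -> pd.DataFrame:
        """Nonzero coefficients with provenance (channel / voxel indices for
        imaging features), largest magnitude first."""
        names = self.feature_names
        meta = self.preprocess.imaging_meta
        rows = []
        for j, b in enumerate(self.beta):
            if b == 0.0 or abs(b) < min_abs:
                continue
            if j < len(meta):
                m = meta.iloc[j]
                rows.append(
                    {
                        "feature": m["name"],
                        "kind": m["kind"],
                        "channel": m["channel"],
                        "ix": m["ix"],
                        "iy": m["iy"],
                        "iz": m["iz"],
                        "beta": b,
                    }
                )
            else:
                rows.append(
                    {
                        "feature": names[j],
                        "kind": "clinical",
                        "channel": None,
                        "ix": -1,
                        "iy": -1,
                        "iz": -1,
                        "beta": b,
                    }
                )
        df = pd.DataFrame(rows, columns=["feature", "kind", "channel", "ix", "iy", "iz", "beta"])
        return df.reindex(df["beta"].abs().sort_values(ascending=False).index).reset_index(drop=True)

    def bundle_hash(self) -> str:
        return stable_hash(self.beta, self.intercept, self.lambda_, self.preprocess.params_hash())


@dataclass
class RiskEstimate:
    """Per-subject risk: linear predictor and threshold group."""

    lp: np.ndarray
    member_lps: np.ndarray | None = None  # (members, subjects)

    @property
    def risk_group(self) -> np.ndarray:
        return np.where(self.lp > 0, "HRR", "low")

    @property
    def is_high_risk(self) -> np.ndarray:
        return self.lp > 0


#: solver effort ceilings for pipeline (ensemble) fits: the energy-based
#: stop and sweep cap terminate the near-collinear channel ping-pong early;
#: solutions differ from fully-converged ones by far less than the
#: fold-to-fold variability of the coefficients themselves.
_PIPELINE_SOLVER_OPTS = dict(etol=1e-7, max_sweeps=50, irls_max=4)


def _fit_member(X, outcome, config, seed):
    opts = dict(_PIPELINE_SOLVER_OPTS)
    if config.family == "cox":
        # model-size ceiling: beyond ~2 events per selected variable the
        # saturated tail of the path is never competitive in CV
        opts["dfmax"] = max(10, outcome.n_events // 2)
    beta, intercept, sel = fit_lasso_cv(
        X,
        outcome,
        config.family,
        n_inner_folds=config.n_inner_folds,
        seed=seed,
        lambda_rule=config.lambda_rule,
        **opts,
    )
    return beta, intercept, sel


def fit_risk_models(
    fm_train: FeatureMatrix,
    clinical_train: pd.DataFrame,
    outcome_train: Outcome,
    config: PipelineConfig,
    seed: int | None = None,
) -> list:
    """Fit the (possibly ensembled) risk model on a training set.

    Returns a list of :class:`FittedRiskModel` members (length 1 for
    ``ensemble.method == 'none'``). Member coefficient vectors live in the
    shared preprocessed feature space; voxel-ensemble members have exact
    zeros outside their half-brain subset.
    """
    seed = config.seed if seed is None else seed
    params = fit_preprocess(fm_train, clinical_train, outcome_train, config)
    X = apply_preprocess(params, fm_train, clinical_train)
    spec = config.ensemble
    info = {
        "n": fm_train.n_subjects,
        "config_hash": config.config_hash(),
        "seed": seed,
    }
    if outcome_train.family == "survival":
        info["events"] = outcome_train.n_events
    models = []
    if spec.method == "none" or spec.n_members == 1:
        beta, intercept, sel = _fit_member(X, outcome_train, config, derive_seed(seed, "member", 0))
        models.append(
            FittedRiskModel(config.family, beta, intercept, sel.lambda_, params, dict(info, member=0))
        )
        return models

    seeds = [derive_seed(seed, "member", k) for k in range(spec.n_members)]
    if spec.method == "subjects":
        rng = np.random.default_rng(derive_seed(seed, "bootstrap"))
        events = outcome_train.event if outcome_train.family == "survival" else None
        for k, mseed in enumerate(seeds):
            idx = bootstrap_indices(X.shape[0], rng, events=events)
            beta, intercept, sel = _fit_member(X[idx], outcome_train.subset(idx), config, mseed)
            models.append(
                FittedRiskModel(
                    config.family, beta, intercept, sel.lambda_, params, dict(info, member=k)
                )
            )
        return models

    # voxel (half-brain) ensemble
    meta = params.imaging_meta
    is_voxel = (meta["kind"] == "voxel").to_numpy()
    n_imaging = len(meta)
    n_total = X.shape[1]
    if not is_voxel.any():
        raise ValueError("voxel ensemble requires voxel features")
    affine = getattr(fm_train, "grid_affine", np.eye(4))
    vox_idx = np.flatnonzero(is_voxel)
    ijk = meta.loc[is_voxel, ["ix", "iy", "iz"]].to_numpy(float)
    coords_mm = (affine[:3, :3] @ ijk.T).T + affine[:3, 3]
    plan = make_half_brain_plan(coords_mm, spec.n_members, seed=derive_seed(seed, "half-brain"))
    for k, (mseed, keep_vox) in enumerate(zip(seeds, plan.member_voxels)):
        col_mask = np.ones(n_total, dtype=bool)
        col_mask[vox_idx[~keep_vox]] = False
        cols = np.flatnonzero(col_mask)
        beta_m, intercept, sel = _fit_member(X[:, cols], outcome_train, config, mseed)
        beta = np.zeros(n_total)
        beta[cols] = beta_m
        models.append(
            FittedRiskModel(
                config.family,
                beta,
                intercept,
                sel.lambda_,
                params,
                dict(info, member=k, half_brain_direction=plan.directions[k].tolist()),
            )
        )
    return models


def score(models, fm: FeatureMatrix, clinical: pd.DataFrame) -> RiskEstimate:
    """Score raw subjects with a fitted bundle (or ensemble of bundles).

    Applies the frozen preprocessing, computes each member's linear
    predictor and averages them; the risk group is ``mean lp > 0``.
    """
    if isinstance(models, FittedRiskModel):
        models = [models]
    if not models:
        raise ValueError("no fitted models given")
    params = models[0].preprocess
    X = apply_preprocess(params, fm, clinical)
    lps = np.stack([m.intercept * (m.family != "cox") + X @ m.beta for m in models])
    return RiskEstimate(lp=aggregate(lps), member_lps=lps)


# ----------------------------------------------------------------------
# model bundle serialization (versioned JSON; everything needed to score)
def save_models(models, path) -> None:
    if isinstance(models, FittedRiskModel):
        models = [models]
    pp = models[0].preprocess
    payload = {
        "schema_version": 1,
        "preprocess": {
            "harmonization": None if pp.harmonization is None else pp.harmonization.to_dict(),
            "residualization": None if pp.residualization is None else pp.residualization.to_dict(),
            "scaling": pp.scaling.to_dict(),
            "kept_imaging_columns": pp.kept_imaging_columns.tolist(),
            "imaging_meta": pp.imaging_meta.to_dict(orient="list"),
            "clinical_columns": list(pp.clinical_columns),
            "use_combat_covariates": pp.use_combat_covariates,
        },
        "members": [
            {
                "family": m.family,
                "beta": m.beta.tolist(),
                "intercept": m.intercept,
                "lambda": m.lambda_,
                "training_info": {k: v for k, v in m.training_info.items() if _json_safe(v)},
            }
            for m in models
        ],
    }
    from pathlib import Path

    Path(path).write_text(json.dumps(payload))


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def load_models(path) -> list:
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    p = payload["preprocess"]
    pp = PreprocessParams(
        harmonization=None
        if p["harmonization"] is None
        else HarmonizationParams.from_dict(p["harmonization"]),
        residualization=None
        if p["residualization"] is None
        else ResidualizationParams.from_dict(p["residualization"]),
        scaling=ClinicalScalingParams.from_dict(p["scaling"]),
        kept_imaging_columns=np.asarray(p["kept_imaging_columns"], dtype=int),
        imaging_meta=pd.DataFrame(p["imaging_meta"]),
        clinical_columns=list(p["clinical_columns"]),
        use_combat_covariates=bool(p["use_combat_covariates"]),
    )
    return [
        FittedRiskModel(
            family=m["family"],
            beta=np.asarray(m["beta"], float),
            intercept=float(m["intercept"]),
            lambda_=float(m["lambda"]),
            preprocess=pp,
            training_info=m.get("training_info", {}),
        )
        for m in payload["members"]
    ]
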