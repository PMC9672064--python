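"""Train-fitted nuisance-covariate removal and clinical scaling.

Age and sex effects are removed from the imaging features with per-feature
ordinary least squares fitted on training subjects only; clinical variables
are min-max scaled to [0, 1] with training bounds. Both transforms are
frozen and applied unchanged to held-out subjects (test values may fall
outside [0, 1] — an honest out-of-range signal, logged but not clipped
unless beyond a wide guard range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import logger

GUARD_LO, GUARD_HI = -0.5, 1.5


@dataclass
class ResidualizationParams:
    """Per-feature intercept + slopes for [1, age, sex], training-fitted."""

    coefs: np.ndarray  # (n_design_cols, p)
    design_cols: list  # subset of ["intercept", "age", "sex"]

    def __post_init__(self):
        if not np.isfinite(self.coefs).all():
            raise ValueError("non-finite residualization coefficients")

    def to_dict(self) -> dict:
        return {"coefs": self.coefs.tolist(), "design_cols": list(self.design_cols)}

    @classmethod
    def from_dict(cls, d) -> "ResidualizationParams":
        return cls(np.asarray(d["coefs"], float), list(d["design_cols"]))


def _design(age, sex, cols):
    parts = {"intercept": np.ones(len(age)), "age": np.asarray(age, float), "sex": np.asarray(sex, float)}
    return np.stack([parts[c] for c in cols], axis=1)


def residualize_fit(train_features, age, sex) -> ResidualizationParams:
    """OLS of each feature on [1, age, sex] over training subjects.

    Degenerate designs (all-constant age or sex) drop the collinear column
    with a log entry rather than failing.
    """
    X = np.asarray(train_features, float)
    age = np.asarray(age, float)
    sex = np.asarray(sex, float)
    if X.shape[0] < 3:
        raise ValueError("residualization needs >= 3 training subjects")
    cols = ["intercept"]
    if np.ptp(age) > 0:
        cols.append("age")
    else:
        logger.warning("residualize_fit: age constant in training set; dropped")
    if np.ptp(sex) > 0:
        cols.append("sex")
    else:
        logger.warning("residualize_fit: sex constant in training set; dropped")
    D = _design(age, sex, cols)
    coefs, *_ = np.linalg.lstsq(D, X, rcond=None)
    return ResidualizationParams(coefs=coefs, design_cols=cols)


def residualize_apply(features, age, sex, params: ResidualizationParams) -> np.ndarray:
    """Subtract the training-fitted age/sex prediction; pure function
    (linear extrapolation beyond the training age range is intentional)."""
    X = np.asarray(features, float)
    D = _design(np.asarray(age, float), np.asarray(sex, float), params.design_cols)
    return X - D @ params.coefs


@dataclass
class ClinicalScalingParams:
    """Training min/max per clinical variable; constant columns dropped."""

    columns: list
    mins: np.ndarray
    maxs: np.ndarray
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        if (self.maxs < self.mins).any():
            raise ValueError("max < min in scaling parameters")

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "dropped": list(self.dropped),
        }

    @classmethod
    def from_dict(cls, d) -> "ClinicalScalingParams":
        return cls(
            list(d["columns"]),
            np.asarray(d["mins"], float),
            np.asarray(d["maxs"], float),
            list(d.get("dropped", [])),
        )


def scale_clinical_fit(train_clinical: pd.DataFrame) -> ClinicalScalingParams:
    """Training [min, max] per numeric clinical column. Constant columns are
    dropped (logged): they carry no information and make scaling undefined."""
    cols, mins, maxs, dropped = [], [], [], []
    for col in train_clinical.columns:
        x = train_clinical[col].to_numpy(dtype=float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi == lo:
            dropped.append(col)
            logger.info("scale_clinical_fit: dropping constant column %r", col)
            continue
        cols.append(col)
        mins.append(lo)
        maxs.append(hi)
    return ClinicalScalingParams(cols, np.asarray(mins, float), np.asarray(maxs, float), dropped)


def scale_clinical_apply(clinical: pd.DataFrame, params: ClinicalScalingParams) -> np.ndarray:
    """(x - min_train) / (max_train - min_train) per column.

    Values outside [0, 1] are allowed (and logged); only values beyond the
    [-0.5, 1.5] guard range are clipped, with a log entry.
    """
    X = clinical[params.columns].to_numpy(dtype=float)
    scaled = (X - params.mins[None, :]) / (params.maxs - params.mins)[None, :]
    outside = (scaled < 0) | (scaled > 1)
    if outside.any():
        logger.info(
            "scale_clinical_apply: %d values outside [0,1] (kept unless beyond guard)",
            int(outside.sum()),
        )
    beyond = (scaled < GUARD_LO) | (scaled > GUARD_HI)
    if beyond.any():
        logger.warning(
            "scale_clinical_apply: clipping %d values to guard range [%.1f, %.1f]",
            int(beyond.sum()),
            GUARD_LO,
            GUARD_HI,
        )
        scaled = np.clip(scaled, GUARD_LO, GUARD_HI)
    return scaled
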