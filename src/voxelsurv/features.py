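"""Feature-matrix assembly from volume stacks, plus univariate screening.

Columns are, in fixed order: voxel features per selected channel
(mask-flattened, C-order), then optional global volumes (gray matter volume
and whole-brain volume, from the modulated maps), then optional midline
binary flags from the clinical table. Clinical regressors are appended later
by the covariate-preparation step, never here, so the imaging block can be
harmonized and residualized independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import logger, stable_hash
from .outcomes import Outcome
from .volumes import CHANNELS, VolumeChannelStack

MIDLINE_COLUMNS = ("cavum_septum_pellucidum", "absent_adhesio_interthalamica")


@dataclass
class FeatureMatrix:
    """Subjects x features with per-feature provenance.

    ``meta`` has one row per column: ``kind`` in {voxel, global, midline,
    clinical}, ``channel`` (voxel features only), integer voxel indices
    ``ix, iy, iz`` in the (possibly subsampled) grid, and ``name``.
    """

    values: np.ndarray
    meta: pd.DataFrame
    subject_ids: np.ndarray
    site_labels: np.ndarray
    harmonized: bool = False  # provenance: ComBat applied exactly once
    residualized: bool = False
    grid_affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x features)")
        if len(self.meta) != self.values.shape[1]:
            raise ValueError("feature_meta length must equal number of columns")
        self.subject_ids = np.asarray(self.subject_ids)
        self.site_labels = np.asarray(self.site_labels)
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def columns_of_kind(self, *kinds) -> np.ndarray:
        return np.flatnonzero(self.meta["kind"].isin(kinds).values)

    def select_columns(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[:, idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    def subset_subjects(self, idx) -> "FeatureMatrix":
        return replace(
            self,
            values=self.values[idx],
            subject_ids=self.subject_ids[idx],
            site_labels=self.site_labels[idx],
        )

    def column_hash(self) -> str:
        return stable_hash(list(self.meta["name"].values))


def assemble_features(
    volumes: VolumeChannelStack,
    channel_selection=None,
    include_globals: bool = False,
    include_midline: bool = False,
    clinical_table: pd.DataFrame | None = None,
    site_labels=None,
) -> FeatureMatrix:
    """Build the imaging feature block for a cohort.

    Zero-variance voxel columns (possible on tiny masks or degenerate
    fixtures) are excluded with a log entry: the lasso standardization is
    undefined for them.
    """
    if channel_selection is None:
        channel_selection = volumes.channels
    for c in channel_selection:
        if c not in volumes.channels:
            raise ValueError(f"requested channel {c!r} missing from volume stack")
    channel_selection = [c for c in CHANNELS if c in channel_selection]
    mask_idx = np.argwhere(volumes.mask)  # C-order by construction
    blocks, meta_rows = [], []
    for channel in channel_selection:
        c = volumes.channel_index(channel)
        vox = volumes.data[:, c][:, volumes.mask]  # (subjects, n_mask) C-order
        blocks.append(vox)
        for ix, iy, iz in mask_idx:
            meta_rows.append(
                {
                    "kind": "voxel",
                    "channel": channel,
                    "ix": int(ix),
                    "iy": int(iy),
                    "iz": int(iz),
                    "name": f"{channel}_vox_{ix}_{iy}_{iz}",
                }
            )
    if include_globals:
        voxel_volume = float(np.prod(volumes.voxel_size_mm))
        for name, chans in (
            ("global_gm_volume", ("gm_mod",)),
            ("global_brain_volume", ("gm_mod", "wm_mod")),
        ):
            for ch in chans:
                if ch not in volumes.channels:
                    raise ValueError(
                        f"global volume features need channel {ch!r}, not present"
                    )
            total = sum(
                volumes.data[:, volumes.channel_index(ch)][:, volumes.mask].sum(axis=1)
                for ch in chans
            )
            blocks.append((total * voxel_volume)[:, None])
            meta_rows.append(
                {"kind": "global", "channel": None, "ix": -1, "iy": -1, "iz": -1, "name": name}
            )
    if include_midline:
        if clinical_table is None or not set(MIDLINE_COLUMNS) <= set(clinical_table.columns):
            raise ValueError(
                f"midline features require clinical columns {MIDLINE_COLUMNS}"
            )
        for col in MIDLINE_COLUMNS:
            blocks.append(clinical_table[col].to_numpy(float)[:, None])
            meta_rows.append(
                {"kind": "midline", "channel": None, "ix": -1, "iy": -1, "iz": -1, "name": col}
            )
    values = np.concatenate(blocks, axis=1) if blocks else np.empty((volumes.n_subjects, 0))
    meta = pd.DataFrame(meta_rows, columns=["kind", "channel", "ix", "iy", "iz", "name"])

    if site_labels is None:
        if clinical_table is not None and "site" in clinical_table.columns:
            site_labels = clinical_table["site"].to_numpy()
        else:
            site_labels = np.array(["site0"] * volumes.n_subjects)
    fm = FeatureMatrix(
        values=values,
        meta=meta,
        subject_ids=volumes.subject_ids,
        site_labels=np.asarray(site_labels),
        grid_affine=volumes.affine.copy(),
    )
    voxel_cols = fm.columns_of_kind("voxel")
    sd = fm.values[:, voxel_cols].std(axis=0)
    dead = voxel_cols[sd == 0.0]
    if len(dead):
        logger.info("excluding %d zero-variance voxel features", len(dead))
        keep = np.setdiff1d(np.arange(fm.n_features), dead)
        fm = fm.select_columns(keep)
    return fm


def screen_significant_voxels(
    features: FeatureMatrix, outcome: Outcome, alpha: float = 0.05
) -> np.ndarray:
    """Univariate screening: keep voxel columns associated with the outcome
    at P < alpha (uncorrected); non-voxel columns are always kept.

    Survival outcomes use the per-voxel Cox score test (the same statistic
    behind the voxelwise survival map); gaussian a correlation t-test;
    binomial a two-sample t-test. Returns kept column indices (never
    modifies values). An empty surviving voxel set falls back to all voxels
    with a warning.
    """
    voxel_cols = features.columns_of_kind("voxel")
    other_cols = np.setdiff1d(np.arange(features.n_features), voxel_cols)
    if len(voxel_cols) == 0:
        return np.arange(features.n_features)
    X = features.values[:, voxel_cols]
    if outcome.family == "survival":
        from .evaluation import cox_score_z  # local import: no cycle at module load

        z, _ = cox_score_z(X, outcome.time, outcome.event)
        p = 2.0 * stats.norm.sf(np.abs(np.nan_to_num(z)))
        p[~np.isfinite(z)] = 1.0
    elif outcome.family == "gaussian":
        n = X.shape[0]
        xc = X - X.mean(axis=0)
        yc = outcome.y - outcome.y.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, xc.T @ yc / np.where(denom == 0, 1, denom), 0.0)
            r = np.clip(r, -0.999999999, 0.999999999)
            t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    else:
        g = outcome.y.astype(bool)
        if g.sum() == 0 or (~g).sum() == 0:
            p = np.ones(X.shape[1])
        else:
            _, p = stats.ttest_ind(X[g], X[~g], axis=0)
            p = np.nan_to_num(p, nan=1.0)
    sig = voxel_cols[p < alpha]
    if len(sig) == 0:
        logger.warning(
            "no voxel survived screening at alpha=%.3g; falling back to all voxels",
            alpha,
        )
        sig = voxel_cols
    keep = np.sort(np.concatenate([other_cols, sig]))
    return keep
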