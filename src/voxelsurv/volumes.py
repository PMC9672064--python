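"""Voxel-based-morphometry style volume stacks: NIfTI I/O, Gaussian
smoothing and block-mean subsampling.

A :class:`VolumeChannelStack` holds a cohort of subjects on a common template
grid with up to four tissue channels: unmodulated / modulated gray matter and
white matter. Unmodulated maps are tissue concentrations; modulated maps are
scaled by the Jacobian of the spatial normalization so voxel sums reflect
absolute tissue volume — subsampling therefore preserves block *totals* for
modulated channels and block *means* for unmodulated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from ._utils import logger

CHANNELS = ("gm_unmod", "gm_mod", "wm_unmod", "wm_mod")
#: FWHM of a Gaussian with unit standard deviation.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class SmoothingSpec:
    """Isotropic Gaussian smoothing kernel, specified by sigma in mm."""

    sigma_mm: float

    def __post_init__(self):
        if self.sigma_mm <= 0:
            raise ValueError("sigma_mm must be positive")

    @property
    def fwhm_mm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_mm


@dataclass
class VolumeChannelStack:
    """Cohort voxel data: ``data[subject, channel, x, y, z]``.

    All subjects share the grid, affine and mask. A single subject is a
    stack with ``n_subjects == 1``.
    """

    data: np.ndarray
    channels: tuple
    voxel_size_mm: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    subject_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 4:  # single subject convenience
            self.data = self.data[None]
        if self.data.ndim != 5:
            raise ValueError("data must be (subjects, channels, x, y, z)")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel labels do not match data")
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        self.voxel_size_mm = np.broadcast_to(
            np.asarray(self.voxel_size_mm, dtype=float), (3,)
        ).copy()
        if (self.voxel_size_mm <= 0).any():
            raise ValueError("voxel size must be positive")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[2:]:
            raise ValueError("mask shape does not match grid")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.subject_ids is None:
            self.subject_ids = np.array(
                [f"S{i:04d}" for i in range(self.data.shape[0])]
            )
        if not np.isfinite(self.data[:, :, self.mask]).all():
            raise ValueError("non-finite voxel values inside mask")

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[2:]

    def channel_index(self, channel: str) -> int:
        if channel not in self.channels:
            raise ValueError(f"channel {channel!r} not present (have {self.channels})")
        return self.channels.index(channel)

    def select_channels(self, channels) -> "VolumeChannelStack":
        idx = [self.channel_index(c) for c in channels]
        return replace(self, data=self.data[:, idx], channels=tuple(channels))

    def copy(self) -> "VolumeChannelStack":
        return replace(
            self,
            data=self.data.copy(),
            mask=self.mask.copy(),
            affine=self.affine.copy(),
        )


# ----------------------------------------------------------------------
def smooth(stack: VolumeChannelStack, spec: SmoothingSpec) -> VolumeChannelStack:
    """Per-channel 3-D Gaussian smoothing with zero-padding at the grid edge.

    Sigma is converted to voxels per axis (anisotropic voxels allowed); the
    brain mask is re-applied afterwards so smoothed intensity does not bleed
    outside the brain.
    """
    sigma_vox = spec.sigma_mm / stack.voxel_size_mm
    out = stack.copy()
    if (sigma_vox < 0.5).all():
        # Kernel degenerates to (numerically) a delta; keep identity exact.
        logger.debug("smoothing sigma below half a voxel on all axes; identity")
        out.data[:, :, ~stack.mask] = 0.0
        return out
    flat = out.data.reshape(-1, *stack.grid_shape)
    for i in range(flat.shape[0]):
        flat[i] = ndimage.gaussian_filter(
            flat[i], sigma=tuple(sigma_vox), mode="constant", cval=0.0
        )
    out.data[:, :, ~stack.mask] = 0.0
    return out


def subsample(
    stack: VolumeChannelStack, target_voxel_mm: float
) -> VolumeChannelStack:
    """Block-mean pooling to a coarser grid.

    ``target_voxel_mm`` must be an integer multiple of the current voxel size
    on every axis. The pooled mask is true where at least half of the source
    block is inside the mask; modulated channels are multiplied by the block
    volume ratio k**3 so block totals (absolute tissue volume) are preserved.
    """
    ratios = np.asarray(target_voxel_mm, float) / stack.voxel_size_mm
    k = int(round(ratios[0]))
    if not np.allclose(ratios, k, atol=1e-9) or k < 1:
        raise ValueError(
            f"target voxel {target_voxel_mm} mm is not an integer multiple "
            f"of current voxel size {stack.voxel_size_mm} mm"
        )
    if k == 1:
        return stack.copy()
    shape = np.asarray(stack.grid_shape)
    pad = (-shape) % k
    data = stack.data
    mask = stack.mask
    if pad.any():  # zero-pad (mask False) up to a multiple of k
        data = np.pad(data, [(0, 0), (0, 0)] + [(0, p) for p in pad])
        mask = np.pad(mask, [(0, p) for p in pad])
    ns, nc = data.shape[:2]
    nx, ny, nz = (np.asarray(data.shape[2:]) // k).tolist()
    blocks = data.reshape(ns, nc, nx, k, ny, k, nz, k)
    pooled = blocks.mean(axis=(3, 5, 7))
    mask_frac = mask.reshape(nx, k, ny, k, nz, k).mean(axis=(1, 3, 5))
    new_mask = mask_frac >= 0.5
    for c, name in enumerate(stack.channels):
        if name.endswith("_mod"):
            pooled[:, c] *= k**3
    new_affine = stack.affine.copy()
    new_affine[:3, :3] = stack.affine[:3, :3] * k
    # voxel (0,0,0) of the pooled grid is centred on the mean of its block
    new_affine[:3, 3] = stack.affine[:3, 3] + stack.affine[:3, :3] @ (
        np.full(3, (k - 1) / 2.0)
    )
    return VolumeChannelStack(
        data=pooled,
        channels=stack.channels,
        voxel_size_mm=stack.voxel_size_mm * k,
        affine=new_affine,
        mask=new_mask,
        subject_ids=stack.subject_ids,
    )


# ----------------------------------------------------------------------
# NIfTI I/O
def _fname(sub: str, channel: str) -> str:
    tissue, mod = channel.split("_")
    return f"sub-{sub}_chan-{tissue}_{mod}.nii.gz"


def write_nifti_cohort(stack: VolumeChannelStack, out_dir) -> list:
    """One gzipped NIfTI per subject per channel, plus the shared mask."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for s, sub in enumerate(stack.subject_ids):
        for c, channel in enumerate(stack.channels):
            path = out_dir / _fname(str(sub), channel)
            nib.save(
                nib.Nifti1Image(stack.data[s, c].astype(np.float32), stack.affine),
                path,
            )
            written.append(path)
    mask_path = out_dir / "mask.nii.gz"
    nib.save(nib.Nifti1Image(stack.mask.astype(np.uint8), stack.affine), mask_path)
    written.append(mask_path)
    return written


def read_nifti_cohort(
    in_dir, subject_ids, channels=CHANNELS, mask_path=None
) -> VolumeChannelStack:
    in_dir = Path(in_dir)
    mask_img = nib.load(mask_path or in_dir / "mask.nii.gz")
    mask = np.asarray(mask_img.dataobj) > 0
    affine = mask_img.affine
    voxel_size = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    data = np.empty((len(subject_ids), len(channels)) + mask.shape)
    for s, sub in enumerate(subject_ids):
        for c, channel in enumerate(channels):
            img = nib.load(in_dir / _fname(str(sub), channel))
            if not np.allclose(img.affine, affine, atol=1e-4):
                raise ValueError(f"affine mismatch for subject {sub}")
            data[s, c] = np.asarray(img.dataobj, dtype=np.float64)
    return VolumeChannelStack(
        data=data,
        channels=tuple(channels),
        voxel_size_mm=voxel_size,
        affine=affine,
        mask=mask,
        subject_ids=np.asarray(subject_ids),
    )
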