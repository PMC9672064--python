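"""Subject-bootstrap and voxel "half-brain" ensembles.

Both methods train ``n_members`` (default 18) risk models and average the
per-subject linear predictors. The voxel ensemble splits the brain with
planes through the mask centroid at evenly spread angles (a spherical
Fibonacci spiral, rotated by a seed-derived random rotation); each member
keeps the voxels on one side of its plane, and every non-voxel
(clinical/global/midline) column is kept in every member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import derive_seed, logger, stable_hash


@dataclass(frozen=True)
class EnsembleSpec:
    method: str = "voxels"  # none | subjects | voxels
    n_members: int = 18
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("none", "subjects", "voxels"):
            raise ValueError(f"unknown ensemble method {self.method!r}")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


@dataclass
class HalfBrainPlan:
    directions: np.ndarray  # (n_members, 3) unit vectors, mm space
    centroid_mm: np.ndarray
    member_voxels: list = field(repr=False)  # boolean arrays over voxel columns

    def plan_hash(self) -> str:
        return stable_hash(self.directions, self.centroid_mm, [m.astype(np.uint8) for m in self.member_voxels])


def _fibonacci_sphere(m: int) -> np.ndarray:
    """Evenly spread unit directions (spiral over the full sphere; no two
    are antipodal). Full-sphere spread guarantees that the union of the
    member half-spaces covers every voxel once m >= 2."""
    k = np.arange(m)
    z = 2.0 * (k + 0.5) / m - 1.0
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    th = golden * k
    return np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def make_half_brain_plan(voxel_coords_mm: np.ndarray, n_members: int, seed: int = 0) -> HalfBrainPlan:
    """Half-spaces through the centroid of the given voxel centers.

    ``voxel_coords_mm`` is (n_voxel_columns, 3): the mm-space center of each
    voxel feature column (repeat per channel as needed). A voxel belongs to
    member k iff ``direction_k . (center - centroid) >= 0``; boundary voxels
    (dot exactly 0) are assigned to the subset, so subset and its complement
    within the mask always partition the voxel columns.
    """
    coords = np.asarray(voxel_coords_mm, float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("voxel_coords_mm must be (n, 3)")
    if len(coords) == 0:
        raise ValueError("empty voxel set")
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    centroid = coords.mean(axis=0)
    rng = np.random.default_rng(seed)
    dirs = _fibonacci_sphere(n_members) @ _random_rotation(rng).T
    rel = coords - centroid
    members = [(rel @ d) >= 0.0 for d in dirs]
    if len(np.unique(coords, axis=0)) == 1:
        logger.warning("degenerate mask (single voxel position); all members keep everything")
        members = [np.ones(len(coords), bool) for _ in dirs]
    return HalfBrainPlan(directions=dirs, centroid_mm=centroid, member_voxels=members)


def bootstrap_indices(n: int, rng: np.random.Generator, events=None, min_events: int = 2, max_attempts: int = 100):
    """Resample subjects with replacement; for survival outcomes redraw
    until the replicate carries at least ``min_events`` events."""
    for attempt in range(max_attempts):
        idx = rng.integers(0, n, size=n)
        if events is None or np.asarray(events)[idx].sum() >= min_events:
            if attempt:
                logger.info("bootstrap redraw count: %d", attempt)
            return idx
    raise RuntimeError(f"could not draw a bootstrap replicate with >= {min_events} events")


def member_seeds(spec: EnsembleSpec) -> list:
    return [derive_seed(spec.seed, "member", k) for k in range(spec.n_members)]


def aggregate(member_lps) -> np.ndarray:
    """Arithmetic mean of member linear predictors, subjects preserved."""
    arr = np.asarray(member_lps, float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("need a non-empty (members x subjects) array")
    return arr.mean(axis=0)
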