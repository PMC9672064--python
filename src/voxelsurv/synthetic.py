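"""Multi-site synthetic cohorts with known ground truth.

Emulates the data a first-episode-psychosis relapse study would provide —
per-subject VBM-style tissue maps on a common template grid, a clinical
table (site, demographics, symptom-scale items, diagnosis, treatment flags)
and a right-censored time-to-relapse outcome — so every pipeline stage can
be tested against planted truth without access-restricted patient data.

Generative model
----------------
Voxel intensities for subject *i* at voxel *v* (unmodulated channels)::

    x_iv = base_v + offset_i + age_slope * (age_i - mean_age)
           + sex_shift * sex_i + s_v * A * u_i + eps_iv

``base_v`` is a smooth spatial pattern shared by all subjects, ``offset_i``
a subject-level global intensity factor, ``u_i ~ N(0,1)`` a latent
biological factor loading only on the ``signal_voxel_count`` signal voxels
(two compact clusters: an "increase" cluster in gray matter, s_v = +1, and a
"decrease" cluster in white matter, s_v = -1), and ``eps`` i.i.d. noise.
Modulated channels are the unmodulated map times ``(1 + warp_i)``, a small
subject-level warp factor. Site effects (additive offset, multiplicative
scale) are applied uniformly within site, last.

The true per-subject log-hazard is ``lp_i = sum_v beta_v (x_iv - base_v)``
over signal voxels with ``beta_v = s_v * signal_effect`` evaluated before
site effects and measurement noise; with sign-balanced clusters this reduces
to ``lp_i = signal_effect * A * V * u_i``. Relapse times are exponential
with hazard ``baseline_hazard_rate * exp(lp_i)``, administratively censored
at ``censor_time`` months (optional uniform dropout). Continuous and binary
labels derive from the same linear predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, special

from ._utils import derive_seed, logger
from .outcomes import Outcome
from .volumes import CHANNELS, VolumeChannelStack, write_nifti_cohort

CLINICAL_SCALE_COLUMNS = (
    "panss_p2",
    "panss_n3",
    "panss_n5",
    "panss_g11",
    "gaf",
    "madrs",
    "ymrs",
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic multi-site cohort.

    Defaults describe the reference study conditions used throughout the
    test-bench: 240 subjects from 2 sites on a 16x16x16 grid of 3 mm voxels
    (ellipsoidal brain mask, ~1.8k in-mask voxels), 30 signal voxels in two
    sign-balanced clusters, and a baseline hazard tuned so ~20% of subjects
    relapse before the 24-month administrative censoring time.
    """

    n_subjects: int = 240
    n_sites: int = 2
    site_sizes: tuple | None = None
    grid_shape: tuple = (16, 16, 16)
    voxel_size_mm: float = 3.0
    signal_voxel_count: int = 30
    signal_effect: float = 0.36  # per-voxel log-hazard per intensity unit
    signal_amplitude: float = 0.10  # latent-factor loading, intensity units
    site_shift: float = 0.1
    site_scale: float = 0.1
    censor_time: float = 24.0
    baseline_hazard_rate: float = 0.0063  # events / month at lp = 0
    covariate_effects: tuple = (-0.002, 0.02)  # age slope / yr, sex shift
    outcome_family: str = "survival"
    seed: int = 0
    noise_sd: float = 0.05
    subject_offset_sd: float = 0.02
    warp_sd: float = 0.02
    dropout_rate: float = 0.0  # optional uniform early-censoring fraction
    gaussian_noise_sd: float = 0.9

    def resolved_site_sizes(self) -> np.ndarray:
        if self.site_sizes is not None:
            sizes = np.asarray(self.site_sizes, dtype=int)
        else:
            base = self.n_subjects // self.n_sites
            sizes = np.full(self.n_sites, base, dtype=int)
            sizes[: self.n_subjects - base * self.n_sites] += 1
        if sizes.sum() != self.n_subjects or (sizes <= 0).any():
            raise ValueError("site_sizes must be positive and sum to n_subjects")
        if (sizes < 3).any():
            raise ValueError(
                "each site needs >= 3 subjects (empirical-Bayes site "
                "harmonization requires >= 2, with a margin of 1)"
            )
        return sizes

    def validate(self) -> None:
        if self.censor_time <= 0 or self.baseline_hazard_rate <= 0:
            raise ValueError("censor_time and baseline_hazard_rate must be > 0")
        if self.signal_voxel_count < 0:
            raise ValueError("signal_voxel_count must be >= 0")
        n_mask = int(ellipsoid_mask(self.grid_shape).sum())
        if self.signal_voxel_count > n_mask:
            raise ValueError("more signal voxels than in-mask voxels")
        self.resolved_site_sizes()


@dataclass
class SyntheticCohort:
    volumes: VolumeChannelStack
    clinical: pd.DataFrame
    outcome: Outcome
    truth: dict = field(repr=False)

    def write(self, out_dir) -> None:
        """NIfTI per subject/channel + clinical CSV + JSON truth sidecar."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_nifti_cohort(self.volumes, out_dir)
        clin = self.clinical.copy()
        if self.outcome.family == "survival":
            clin["time"] = self.outcome.time
            clin["event"] = self.outcome.event.astype(int)
        else:
            clin["y"] = self.outcome.y
        clin.to_csv(out_dir / "clinical.csv", index=False)
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.truth.items()
        }
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))


def ellipsoid_mask(grid_shape) -> np.ndarray:
    """Inscribed ellipsoid: semi-axes half the grid extent minus half a voxel."""
    grid_shape = tuple(grid_shape)
    centers = [(n - 1) / 2.0 for n in grid_shape]
    semi = [(n - 1) / 2.0 for n in grid_shape]
    grids = np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij")
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, centers, semi))
    return r2 <= 1.0


def _smooth_field(rng, grid_shape, mean, sd) -> np.ndarray:
    raw = ndimage.gaussian_filter(rng.standard_normal(grid_shape), sigma=2.0)
    raw = (raw - raw.mean()) / raw.std()
    return mean + sd * raw


def _signal_clusters(rng, mask, count):
    """Two compact in-mask balls of ~count/2 voxels each, well separated."""
    coords = np.argwhere(mask)
    centroid = coords.mean(axis=0)
    # pick two seed voxels on opposite sides of the centroid, away from edge
    interior = coords[
        np.linalg.norm(coords - centroid, axis=1)
        < 0.55 * np.linalg.norm(coords - centroid, axis=1).max()
    ]
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    proj = (interior - centroid) @ axis
    seed_pos = interior[np.argmax(proj)]
    seed_neg = interior[np.argmin(proj)]
    n_pos = count // 2
    n_neg = count - n_pos
    out_coords, out_signs = [], []
    for seed_vox, n_take, sign in ((seed_pos, n_pos, 1), (seed_neg, n_neg, -1)):
        d = np.linalg.norm(coords - seed_vox, axis=1)
        sel = coords[np.argsort(d, kind="stable")[:n_take]]
        out_coords.append(sel)
        out_signs.append(np.full(len(sel), sign))
    return np.concatenate(out_coords), np.concatenate(out_signs)


def plant_site_effects(
    volumes: VolumeChannelStack,
    site_labels,
    shift_scale: float,
    scale_scale: float,
    seed: int = 0,
):
    """Apply per-site additive + multiplicative batch effects.

    Offsets are drawn N(0, shift_scale^2) and scales LogNormal(0,
    scale_scale^2), one pair per site, applied uniformly within site as
    ``x' = scale * x + shift``. Returns ``(volumes', drawn_params)``.
    """
    if scale_scale < 0 or shift_scale < 0:
        raise ValueError("shift_scale and scale_scale must be >= 0")
    site_labels = np.asarray(site_labels)
    sites = np.unique(site_labels)
    if len(sites) < 2:
        raise ValueError("site effects need >= 2 sites")
    rng = np.random.default_rng(seed)
    shifts = rng.normal(0.0, shift_scale, size=len(sites)) if shift_scale else np.zeros(len(sites))
    scales = (
        np.exp(rng.normal(0.0, scale_scale, size=len(sites)))
        if scale_scale
        else np.ones(len(sites))
    )
    out = volumes.copy()
    for s, shift, scale in zip(sites, shifts, scales):
        rows = site_labels == s
        out.data[rows] = scale * out.data[rows] + shift
    params = {str(s): {"shift": float(sh), "scale": float(sc)} for s, sh, sc in zip(sites, shifts, scales)}
    return out, params


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    site_sizes = spec.resolved_site_sizes()
    n = spec.n_subjects
    mask = ellipsoid_mask(spec.grid_shape)

    site_labels = np.repeat([f"site{j}" for j in range(spec.n_sites)], site_sizes)
    age = np.clip(rng.normal(25.0, 7.0, n), 15.0, 60.0)
    sex = (rng.random(n) < 0.65).astype(float)  # 1 = male

    base_gm = _smooth_field(rng, spec.grid_shape, mean=0.5, sd=0.1)
    base_wm = _smooth_field(rng, spec.grid_shape, mean=0.45, sd=0.1)
    offset = rng.normal(0.0, spec.subject_offset_sd, n)
    warp = rng.normal(0.0, spec.warp_sd, n)
    u = rng.standard_normal(n)

    if spec.signal_voxel_count > 0:
        sig_coords, sig_signs = _signal_clusters(rng, mask, spec.signal_voxel_count)
    else:
        sig_coords = np.empty((0, 3), dtype=int)
        sig_signs = np.empty(0)
    # first half of the clusters sits in gray matter, second in white matter
    sig_channel = np.where(sig_signs > 0, "gm_unmod", "wm_unmod")
    beta_true = sig_signs * spec.signal_effect

    age_slope, sex_shift = spec.covariate_effects
    cov_term = age_slope * (age - age.mean()) + sex_shift * sex  # (n,)

    data = np.zeros((n, 4) + tuple(spec.grid_shape))
    gm = base_gm[None] + (offset + cov_term)[:, None, None, None] + rng.normal(
        0.0, spec.noise_sd, (n,) + tuple(spec.grid_shape)
    )
    wm = base_wm[None] + (offset + cov_term)[:, None, None, None] + rng.normal(
        0.0, spec.noise_sd, (n,) + tuple(spec.grid_shape)
    )
    for (i_, j_, k_), sign, chan in zip(sig_coords, sig_signs, sig_channel):
        target = gm if chan == "gm_unmod" else wm
        target[:, i_, j_, k_] += sign * spec.signal_amplitude * u
    ci = {c: i for i, c in enumerate(CHANNELS)}
    data[:, ci["gm_unmod"]] = gm
    data[:, ci["wm_unmod"]] = wm
    data[:, ci["gm_mod"]] = gm * (1.0 + warp)[:, None, None, None]
    data[:, ci["wm_mod"]] = wm * (1.0 + warp)[:, None, None, None]

    # true linear predictor: biological signal only (no site/scanner terms).
    # sign-balanced clusters cancel the shared covariate term exactly when
    # the cluster sizes are equal; keep the general expression regardless.
    lp = np.zeros(n)
    for sign in sig_signs:
        lp += sign * spec.signal_effect * (cov_term + sign * spec.signal_amplitude * u)

    subject_ids = np.array([f"S{i:04d}" for i in range(n)])
    volumes = VolumeChannelStack(
        data=data,
        channels=CHANNELS,
        voxel_size_mm=spec.voxel_size_mm,
        affine=_default_affine(spec),
        mask=mask,
        subject_ids=subject_ids,
    )
    site_params = {}
    if spec.n_sites > 1 and (spec.site_shift > 0 or spec.site_scale > 0):
        volumes, site_params = plant_site_effects(
            volumes,
            site_labels,
            spec.site_shift,
            spec.site_scale,
            seed=derive_seed(spec.seed, "site-effects"),
        )

    # outcomes ---------------------------------------------------------
    hazard = spec.baseline_hazard_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = np.full(n, spec.censor_time)
    if spec.dropout_rate > 0:
        drop = rng.random(n) < spec.dropout_rate
        t_cens[drop] = rng.uniform(1e-6, spec.censor_time, int(drop.sum()))
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    time = np.maximum(time, 1e-9)
    y_gauss = lp + rng.normal(0.0, spec.gaussian_noise_sd, n)
    y_binom = (rng.random(n) < special.expit(lp)).astype(float)
    if spec.outcome_family == "survival":
        outcome = Outcome.survival(time, event, subject_ids=subject_ids)
    elif spec.outcome_family == "gaussian":
        outcome = Outcome.gaussian(y_gauss, subject_ids=subject_ids)
    else:
        outcome = Outcome.binomial(y_binom, subject_ids=subject_ids)
    logger.debug("synthetic cohort: %d events / %d subjects", int(event.sum()), n)

    clinical = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "site": site_labels,
            "age": age,
            "sex": sex,
            "panss_p2": rng.integers(1, 8, n),
            "panss_n3": rng.integers(1, 8, n),
            "panss_n5": rng.integers(1, 8, n),
            "panss_g11": rng.integers(1, 8, n),
            "gaf": rng.integers(20, 91, n),
            "madrs": rng.integers(0, 40, n),
            "ymrs": rng.integers(0, 30, n),
            "dx_schizoaffective": (rng.random(n) < 0.1).astype(int),
            "lai": (rng.random(n) < 0.3).astype(int),
            "cavum_septum_pellucidum": (rng.random(n) < 0.05).astype(int),
            "absent_adhesio_interthalamica": (rng.random(n) < 0.05).astype(int),
        }
    )

    truth = {
        "signal_coords": sig_coords,
        "signal_signs": sig_signs.astype(int),
        "signal_channel": sig_channel,
        "beta_true": beta_true,
        "lp": lp,
        "u": u,
        "site_params": site_params,
        "time_all": time,
        "event_all": event.astype(int),
        "y_gaussian": y_gauss,
        "y_binomial": y_binom,
        "spec": asdict(spec),
    }
    return SyntheticCohort(volumes=volumes, clinical=clinical, outcome=outcome, truth=truth)


def _default_affine(spec: SyntheticSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = spec.voxel_size_mm
    center = (np.asarray(spec.grid_shape) - 1) / 2.0 * spec.voxel_size_mm
    aff[:3, 3] = -center
    return aff


def expected_event_fraction(lp, baseline_hazard_rate, censor_time) -> float:
    """Closed-form P(event) for exponential hazards with administrative
    censoring, averaged over the given linear predictors."""
    h = baseline_hazard_rate * np.exp(np.asarray(lp, float))
    return float(np.mean(1.0 - np.exp(-h * censor_time)))
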