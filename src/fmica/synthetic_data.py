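"""Multi-subject synthetic fMRI generator with known ground truth.

The generator emulates the SimTB family of 2D fMRI simulations: a square
slice of smooth, spatially localized sources, each driven by its own
hemodynamic time course, summed over sources around a constant baseline
and degraded by Gaussian noise to a target contrast-to-noise ratio.

Study conditions (the defaults): 20 subjects, a 148 x 148 slice, 12
sources, 120 time points at TR = 2 s, baseline intensity 800, CNR = 1.
Two sources are task-modulated by a block design (24 s on / 24 s off, five
blocks): source 10 with task-to-unique amplitude ratio 4 and unique
amplitude 0.2, source 12 with ratio 2 and unique amplitude 0.4. All
sources receive unique events (probability 0.2 per TR; amplitude 1 for
non-task sources); event trains are convolved with the canonical
double-gamma HRF and scaled so the percent signal change of each time
course is drawn from N(3, 0.25^2) % of baseline (clipped below at 0.5%).
Per subject, every source is independently translated, rotated and scaled
(zero-mean draws; sd 1.5 voxels / 3 degrees / 0.03) with bilinear
interpolation, emulating inter-subject spatial variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from nilearn.glm.first_level.hemodynamic_models import spm_hrf
from scipy import ndimage

from .core import SubjectData

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_group_sources",
    "apply_subject_variation",
    "generate_timecourses",
    "synthesize_dataset",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-subject dataset.

    ``task_sources`` lists ``(source_index, task_amplitude_ratio,
    unique_amplitude)`` triples (0-based indices); the task event amplitude
    is ``ratio * unique_amplitude``.  ``translation_sd`` (voxels),
    ``rotation_sd`` (degrees) and ``scale_sd`` (ratio) are the per-subject
    spatial variation spreads.
    """

    n_subjects: int = 20
    grid_side: int = 148
    n_sources: int = 12
    n_timepoints: int = 120
    tr: float = 2.0
    baseline: float = 800.0
    cnr: float = 1.0
    task_sources: tuple | None = None   # default: ((9, 4.0, 0.2), (11, 2.0, 0.4))
    unique_event_prob: float = 0.2
    psc_mean: float = 3.0
    psc_sd: float = 0.25
    block_on: float = 24.0
    block_off: float = 24.0
    n_blocks: int = 5
    translation_sd: float = 1.5
    rotation_sd: float = 3.0
    scale_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.grid_side < 8:
            raise ValueError("grid_side must be >= 8")
        if not 0.0 <= self.unique_event_prob <= 1.0:
            raise ValueError("unique_event_prob must be in [0, 1]")
        if not self.cnr > 0:
            raise ValueError("cnr must be positive")
        if self.n_blocks * (self.block_on + self.block_off) / self.tr > self.n_timepoints:
            raise ValueError("block design does not fit into n_timepoints")
        if min(self.translation_sd, self.rotation_sd, self.scale_sd) < 0:
            raise ValueError("variation spreads must be non-negative")
        if self.task_sources is None:
            # sources 10 and 12 (1-based) when the atlas is large enough
            self.task_sources = tuple(
                t for t in ((9, 4.0, 0.2), (11, 2.0, 0.4)) if t[0] < self.n_sources
            )
        for idx, ratio, amp in self.task_sources:
            if not 0 <= idx < self.n_sources:
                raise ValueError(f"task source index {idx} out of range")

    @property
    def n_voxels(self) -> int:
        return self.grid_side ** 2


@dataclass
class SimTruth:
    """Ground truth underlying one synthetic dataset."""

    group_sources: np.ndarray        # (n_sources, V)
    subject_sources: np.ndarray      # (n_subjects, n_sources, V)
    timecourses: np.ndarray          # (n_subjects, T, n_sources)
    variation_params: np.ndarray     # (n_subjects, n_sources, 4): dx, dy, theta, scale
    noise_sd: np.ndarray             # (n_subjects,)
    seed_used: int = 0
    shape: tuple = field(default=None)


def _blob(grid_side: int, center, sigmas, theta: float) -> np.ndarray:
    """Anisotropic 2D Gaussian blob with unit peak."""
    ii, jj = np.mgrid[0:grid_side, 0:grid_side].astype(float)
    di, dj = ii - center[0], jj - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = ct * di + st * dj
    v = -st * di + ct * dj
    return np.exp(-0.5 * ((u / sigmas[0]) ** 2 + (v / sigmas[1]) ** 2))


def _default_layout(config: SimConfig, rng: np.random.Generator):
    """Jittered grid of blob centers with mild anisotropy per source."""
    n = config.n_sources
    side = config.grid_side
    cols = int(math.ceil(math.sqrt(n)))
    rows = int(math.ceil(n / cols))
    dx = side / rows
    dy = side / cols
    sigma0 = min(dx, dy) / 4.5
    if sigma0 < 1.0:
        raise ValueError(
            f"grid_side={side} too small to place {n} distinguishable sources"
        )
    centers, sigmas, angles = [], [], []
    k = 0
    for a in range(rows):
        for b in range(cols):
            if k >= n:
                break
            jitter = rng.uniform(-0.08, 0.08, size=2) * min(dx, dy)
            centers.append((dx * (a + 0.5) + jitter[0], dy * (b + 0.5) + jitter[1]))
            aniso = rng.uniform(0.75, 1.3, size=2)
            sigmas.append((sigma0 * aniso[0], sigma0 * aniso[1]))
            angles.append(rng.uniform(0, math.pi))
            k += 1
    return centers, sigmas, angles


def generate_group_sources(
    config: SimConfig, centers=None, sigmas=None, angles=None,
) -> np.ndarray:
    """Group-level source maps: ``n_sources`` peak-normalized Gaussian blobs.

    Centers/sigmas/orientations default to a seeded jittered grid layout
    but can be supplied to mimic any source atlas. Returns a
    (n_sources, grid_side**2) matrix; each row has max value 1.
    """
    rng = np.random.default_rng(config.seed)
    d_centers, d_sigmas, d_angles = _default_layout(config, rng)
    centers = d_centers if centers is None else centers
    sigmas = d_sigmas if sigmas is None else sigmas
    angles = d_angles if angles is None else angles
    maps = np.empty((config.n_sources, config.n_voxels))
    for k in range(config.n_sources):
        m = _blob(config.grid_side, centers[k], sigmas[k], angles[k])
        maps[k] = (m / m.max()).ravel()
    return maps


def apply_subject_variation(
    group_sources: np.ndarray,
    variation,
    seed: int,
    grid_side: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Translate/rotate/scale each source independently (bilinear, clipped).

    ``variation`` is ``(translation_sd, rotation_sd_degrees, scale_sd)``;
    draws are zero-mean (scale factor 1 + N(0, scale_sd)).  Rotation and
    scaling act about each source's center of mass, translation shifts by
    (dx, dy) in (row, column) voxels.  Returns the transformed
    (n_sources, V) matrix and the (n_sources, 4) parameter array
    ``[dx, dy, theta_deg, scale]``.
    """
    t_sd, r_sd, s_sd = variation
    if min(t_sd, r_sd, s_sd) < 0:
        raise ValueError("variation spreads must be non-negative")
    G = np.atleast_2d(np.asarray(group_sources, float))
    n, V = G.shape
    if grid_side is None:
        grid_side = int(round(math.sqrt(V)))
    if grid_side * grid_side != V:
        raise ValueError("grid_side**2 must equal the voxel count")
    rng = np.random.default_rng(seed)
    out = np.empty_like(G)
    params = np.empty((n, 4))
    for k in range(n):
        dx = rng.normal(0.0, t_sd) if t_sd > 0 else 0.0
        dy = rng.normal(0.0, t_sd) if t_sd > 0 else 0.0
        theta = rng.normal(0.0, r_sd) if r_sd > 0 else 0.0
        scale = 1.0 + (rng.normal(0.0, s_sd) if s_sd > 0 else 0.0)
        scale = float(np.clip(scale, 0.5, 2.0))
        params[k] = (dx, dy, theta, scale)
        img = G[k].reshape(grid_side, grid_side)
        if dx == 0 and dy == 0 and theta == 0 and scale == 1.0:
            out[k] = G[k]
            continue
        c = np.asarray(ndimage.center_of_mass(np.abs(img)))
        th = math.radians(theta)
        rot = np.array([[math.cos(th), -math.sin(th)],
                        [math.sin(th), math.cos(th)]])
        # output x draws from input R^{-1} (x - c - t)/s + c
        M = rot.T / scale
        offset = c - M @ (c + np.array([dx, dy]))
        out[k] = ndimage.affine_transform(
            img, M, offset=offset, order=1, mode="constant", cval=0.0
        ).ravel()
    return out, params


def task_boxcar(config: SimConfig) -> np.ndarray:
    """Block-design regressor: on for block_on s, off for block_off s, repeated."""
    n_on = int(round(config.block_on / config.tr))
    n_off = int(round(config.block_off / config.tr))
    block = np.concatenate([np.ones(n_on), np.zeros(n_off)])
    box = np.tile(block, config.n_blocks)
    out = np.zeros(config.n_timepoints)
    out[: box.size] = box
    return out


def canonical_hrf(tr: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR (peak 6 s, undershoot 16 s)."""
    return spm_hrf(tr, oversampling=1)


def generate_timecourses(config: SimConfig, seed: int, return_events: bool = False):
    """One subject's (n_timepoints, n_sources) hemodynamic time courses.

    Task-modulated sources get boxcar * task_amplitude + unique events *
    unique_amplitude; the rest get unit-amplitude unique events only. The
    neural trains are convolved with the canonical HRF, then each course is
    scaled so its peak percent signal change is a draw from
    N(psc_mean, psc_sd^2) (floored at 0.5%).  With ``return_events`` the
    binary unique-event trains are returned alongside.
    """
    rng = np.random.default_rng(seed)
    T, S = config.n_timepoints, config.n_sources
    hrf = canonical_hrf(config.tr)
    box = task_boxcar(config)
    task = {idx: (ratio, amp) for idx, ratio, amp in config.task_sources}
    tc = np.zeros((T, S))
    ev = np.zeros((T, S))
    for k in range(S):
        events = (rng.random(T) < config.unique_event_prob).astype(float)
        ev[:, k] = events
        if k in task:
            ratio, amp = task[k]
            neural = box * (ratio * amp) + events * amp
        else:
            neural = events
        bold = np.convolve(neural, hrf)[:T]
        peak = np.max(np.abs(bold))
        if peak > 0:
            psc = max(rng.normal(config.psc_mean, config.psc_sd), 0.5)
            bold = bold * (config.baseline * psc / 100.0) / peak
        tc[:, k] = bold
    return (tc, ev) if return_events else tc


def synthesize_dataset(
    config: SimConfig,
    source_maps: np.ndarray | None = None,
    dataset_id: str = "sim",
) -> tuple[list[SubjectData], SimTruth]:
    """Generate the full multi-subject dataset plus its ground truth.

    Per subject: data = baseline + sum_k TC_k (x) source_k + noise, with the
    noise sd set so that sd(mean-removed noise-free signal over in-brain
    voxels) / sd(noise) equals ``config.cnr``. ``source_maps`` overrides
    the default blob atlas (shape (n_sources, grid_side**2)).
    """
    group = generate_group_sources(config) if source_maps is None else \
        np.atleast_2d(np.asarray(source_maps, float))
    if group.shape != (config.n_sources, config.n_voxels):
        raise ValueError("source_maps shape mismatch")
    n, T, V = config.n_subjects, config.n_timepoints, config.n_voxels
    master = np.random.default_rng(config.seed)
    sub_seeds = master.integers(0, 2 ** 31, size=(n, 3))
    shape = (config.grid_side, config.grid_side)
    mask = np.ones(shape, dtype=bool)
    spreads = (config.translation_sd, config.rotation_sd, config.scale_sd)
    subjects = []
    subj_sources = np.empty((n, config.n_sources, V))
    tcs = np.empty((n, T, config.n_sources))
    var_params = np.empty((n, config.n_sources, 4))
    noise_sds = np.empty(n)
    for i in range(n):
        src, params = apply_subject_variation(
            group, spreads, int(sub_seeds[i, 0]), grid_side=config.grid_side
        )
        tc = generate_timecourses(config, int(sub_seeds[i, 1]))
        signal = tc @ src                       # (T, V)
        inbrain = np.max(np.abs(src), axis=0) > 0.05
        fluct = signal[:, inbrain] - signal[:, inbrain].mean(axis=0)
        sig_sd = float(fluct.std())
        noise_sd = 0.0 if not math.isfinite(config.cnr) else sig_sd / config.cnr
        rng_noise = np.random.default_rng(int(sub_seeds[i, 2]))
        data = config.baseline + signal
        if noise_sd > 0:
            data = data + rng_noise.normal(0.0, noise_sd, size=(T, V))
        subjects.append(
            SubjectData(
                data=data, mask=mask, shape=shape, tr=config.tr,
                subject_id=f"sub-{i + 1:02d}", dataset_id=dataset_id,
            )
        )
        subj_sources[i] = src
        tcs[i] = tc
        var_params[i] = params
        noise_sds[i] = noise_sd
    truth = SimTruth(
        group_sources=group,
        subject_sources=subj_sources,
        timecourses=tcs,
        variation_params=var_params,
        noise_sd=noise_sds,
        seed_used=config.seed,
        shape=shape,
    )
    return subjects, truth
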