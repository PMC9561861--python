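"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study design end to end: K spatially independent
"networks" (smooth Gaussian blobs inside a spherical brain), healthy-control
resting-state series that linearly mix per-subject network time courses plus
noise, patient lesions that strike the networks at dispersed locations, and
behavior scores driven by damage to one designated target network. Because
the ground truth is known, every downstream stage (connectivity, ICA,
identification, damage scoring) can be checked for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .volumes import Fmri4D, LesionCohort, Mask, Volume, VolumeGrid

__all__ = [
    "GroundTruth",
    "SimCohortConfig",
    "SyntheticCohort",
    "default_grid",
    "make_networks",
    "simulate_fmri",
    "simulate_lesions",
    "simulate_behavior",
    "make_cohort",
]

# WAB subtest ranges: (max score, generating intercept, slope, noise sd).
# Slopes are negative — damage to the target network lowers performance —
# and scale with each subtest's range so all subtests carry the same
# relative effect.  Damage is on a [0, 1] map-value scale.
_SUBTESTS = {
    "naming": (100.0, 90.0, -60.0, 8.0),
    "comprehension": (200.0, 180.0, -120.0, 16.0),
    "fluency": (10.0, 9.0, -6.0, 0.8),
    "repetition": (100.0, 90.0, -60.0, 8.0),
    "aq": (100.0, 90.0, -60.0, 8.0),
}


def default_grid(dim: int = 18, voxel_mm: float = 4.0) -> VolumeGrid:
    """Isotropic grid centred on the origin, MNI-style affine."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (dim - 1) / 2
    return VolumeGrid((dim, dim, dim), affine)


def _band_limited(rng: np.random.Generator, shape: tuple[int, ...], tr: float,
                  band: tuple[float, float] = (0.01, 0.08)) -> np.ndarray:
    """Unit-variance series with power confined to the resting-state band.

    Hemodynamic fluctuations are slow; generating sources directly in the
    analysis band means temporal filtering during preprocessing keeps the
    signal while suppressing broadband thermal noise, as with real data.
    """
    white = rng.standard_normal(shape)
    nyq = 1.0 / (2.0 * tr)
    b, a = sp_signal.butter(4, [band[0] / nyq, band[1] / nyq], btype="band")
    series = sp_signal.filtfilt(b, a, white, axis=-1)
    sd = series.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return series / sd


def _brain_sphere(grid: VolumeGrid) -> np.ndarray:
    """Boolean spherical 'brain' footprint, radius 0.45 of the smallest axis."""
    dims = np.array(grid.dims)
    centre = (dims - 1) / 2
    radius = 0.45 * dims.min()
    coords = np.indices(grid.dims).reshape(3, -1).T
    d2 = ((coords - centre) ** 2).sum(axis=1)
    return (d2 <= radius**2).reshape(grid.dims)


@dataclass
class GroundTruth:
    """Planted spatial networks plus canonical source series."""

    networks: list[Volume]
    centres: np.ndarray  # K x 3 voxel coordinates
    target_index: int
    source_series: np.ndarray  # K x T canonical draws (subjects get fresh ones)
    brain: Mask
    sigma: float
    seed: int

    @property
    def k(self) -> int:
        return len(self.networks)


def make_networks(
    grid: VolumeGrid,
    k: int,
    seed: int,
    *,
    sigma: float = 1.8,
    n_timepoints: int = 150,
    target_index: int = 0,
    min_separation: float | None = None,
) -> GroundTruth:
    """Place ``k`` well-separated Gaussian-blob networks inside the brain sphere.

    Blobs are isotropic Gaussians truncated at 2*sigma, so supports are
    compact and pairwise spatial correlations stay below 0.2. Source series
    are redrawn until pairwise |r| < 0.2 (a few draws at most for iid noise).
    """
    if k < 2:
        raise ValueError("need at least 2 networks")
    rng = np.random.default_rng(seed)
    brain = _brain_sphere(grid)
    dims = np.array(grid.dims)
    sep = min_separation if min_separation is not None else 3.8 * sigma
    brain_coords = np.argwhere(brain)
    # keep centres off the sphere edge so most of each support fits in-brain
    centre_pt = (dims - 1) / 2
    interior = brain_coords[
        np.linalg.norm(brain_coords - centre_pt, axis=1) <= 0.45 * dims.min() - sigma
    ]
    # greedy rejection sampling; restart from scratch if a draw wedges itself
    centres: list[np.ndarray] = []
    for restart in range(5):
        centres = []
        for _ in range(5000):
            if len(centres) == k:
                break
            cand = interior[rng.integers(len(interior))]
            if all(np.linalg.norm(cand - c) >= sep for c in centres):
                centres.append(cand.astype(float))
        if len(centres) == k:
            break
    if len(centres) < k:
        raise ValueError(
            f"cannot place {k} blobs with separation {sep:.1f} voxels on grid {grid.dims}"
        )
    coords = np.indices(grid.dims).reshape(3, -1).T
    networks = []
    for c in centres:
        d2 = ((coords - c) ** 2).sum(axis=1)
        blob = np.exp(-d2 / (2 * sigma**2))
        blob[d2 > (2 * sigma) ** 2] = 0.0  # truncate at 2 sd
        blob = blob.reshape(grid.dims) * brain
        networks.append(Volume(grid, blob))
    for vol in networks:
        if int((vol.data > 0).sum()) < 20:
            raise ValueError("network support smaller than 20 voxels; increase sigma")
    # canonical sources: band-limited draws, decorrelated exactly so the
    # pairwise-correlation premise holds even for short series
    sources = _band_limited(rng, (k, n_timepoints), tr=2.0)
    cov = np.cov(sources)
    sources = np.linalg.solve(np.linalg.cholesky(cov), sources - sources.mean(axis=1, keepdims=True))
    sources /= sources.std(axis=1, keepdims=True)
    return GroundTruth(
        networks=networks,
        centres=np.array(centres),
        target_index=target_index,
        source_series=sources,
        brain=Mask(grid, brain.astype(np.uint8)),
        sigma=sigma,
        seed=seed,
    )


def simulate_fmri(
    gt: GroundTruth,
    n_subjects: int,
    n_timepoints: int,
    snr: float,
    seed: int,
    *,
    tr: float = 2.0,
    global_amp: float = 0.5,
) -> list[Fmri4D]:
    """Per-subject series: network maps times fresh band-limited source series,
    plus a shared global fluctuation and white thermal noise.

    ``snr`` is sd(signal)/sd(noise) at a network's peak voxel (peak map value
    is 1 and sources have unit variance, so noise sd = 1/snr). The global
    fluctuation (amplitude ``global_amp`` at every brain voxel) emulates the
    physiological/scanner component that global-signal regression is meant
    to remove. Voxels outside the brain sphere stay exactly zero, which is
    what the brain-mask computation keys on.
    """
    if n_timepoints < 30:
        raise ValueError("need at least 30 timepoints")
    if snr <= 0:
        raise ValueError("snr must be positive")
    grid = gt.networks[0].grid
    maps = np.stack([v.flat() for v in gt.networks])  # K x n_total
    brain_flat = gt.brain.flat().astype(bool)
    noise_sd = 1.0 / snr
    out = []
    master = np.random.default_rng(seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=n_subjects)
    for s in range(n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        sources = _band_limited(rng, (gt.k, n_timepoints), tr)
        global_sig = global_amp * _band_limited(rng, (n_timepoints,), tr)
        flat = maps.T @ sources  # n_total x T
        flat[brain_flat] += global_sig[None, :]
        flat[brain_flat] += noise_sd * rng.standard_normal((int(brain_flat.sum()), n_timepoints))
        flat[~brain_flat] = 0.0
        series = flat.reshape((*grid.dims, n_timepoints), order="F")
        out.append(Fmri4D(grid, series, tr=tr, subject_id=f"hc{s:03d}", session_id="ses1"))
    return out


@dataclass
class SimulatedLesions:
    """Lesion cohort plus the per-patient ground truth used to generate behavior."""

    cohort: LesionCohort
    truth: pd.DataFrame  # patient_id, hit_network, damage per network, target_damage


def simulate_lesions(
    gt: GroundTruth,
    n_patients: int,
    hit_profile: dict[int, float] | np.ndarray | None,
    size_range: tuple[int, int],
    seed: int,
    jitter: float = 1.0,
) -> SimulatedLesions:
    """Spherical lesions centred near a network drawn from ``hit_profile``.

    Centres are jittered around the struck network's centre, so lesion
    locations are dispersed across patients (low pairwise overlap) even when
    they damage the same network — the heterogeneity regime that defeats
    overlay-based lesion network mapping.
    """
    grid = gt.networks[0].grid
    if hit_profile is None:
        probs = np.full(gt.k, 1.0 / gt.k)
    elif isinstance(hit_profile, dict):
        probs = np.zeros(gt.k)
        for net, p in hit_profile.items():
            probs[net] = p
    else:
        probs = np.asarray(hit_profile, dtype=float)
    if np.any(probs < 0) or np.any(probs > 1) or probs.sum() <= 0:
        raise ValueError("hit_profile probabilities must be in [0,1] and sum > 0")
    probs = probs / probs.sum()
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("size_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    brain_flat = gt.brain.flat().astype(bool)
    coords = np.indices(grid.dims).reshape(3, -1).T  # C-order voxel coords
    flat_pos_f = np.ravel_multi_index(coords.T, grid.dims, order="F")
    maps = np.stack([v.flat() for v in gt.networks])
    patients = []
    rows = []
    for p in range(n_patients):
        net = int(rng.choice(gt.k, p=probs))
        size = int(rng.integers(lo, hi + 1))
        radius = max(1.0, (3 * size / (4 * np.pi)) ** (1 / 3))
        for _ in range(200):
            offset = rng.uniform(-jitter * gt.sigma, jitter * gt.sigma, size=3)
            centre = gt.centres[net] + offset
            d2 = ((coords - centre) ** 2).sum(axis=1)
            inside = np.zeros(grid.n_total, dtype=bool)
            inside[flat_pos_f[d2 <= radius**2]] = True
            inside &= brain_flat
            if inside.any() and maps[net][inside].max() > 0:
                break
        lesion = Mask(grid, inside.reshape(grid.dims, order="F").astype(np.uint8))
        damage = maps[:, inside].max(axis=1) if inside.any() else np.zeros(gt.k)
        pid = f"pt{p:03d}"
        patients.append((pid, lesion))
        rows.append(
            {
                "patient_id": pid,
                "hit_network": net,
                "lesion_size": lesion.n_voxels,
                **{f"damage_net{i}": damage[i] for i in range(gt.k)},
                "target_damage": damage[gt.target_index],
            }
        )
    cohort = LesionCohort(patients, grid) if patients else LesionCohort([], grid)
    truth = pd.DataFrame(rows, columns=[
        "patient_id", "hit_network", "lesion_size",
        *[f"damage_net{i}" for i in range(gt.k)], "target_damage",
    ])
    return SimulatedLesions(cohort, truth)


def simulate_behavior(
    lesions: SimulatedLesions,
    gt: GroundTruth,
    slope: float = -60.0,
    noise_sd: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Behavior table: each score is an affine function of true target damage plus noise.

    ``slope`` applies to the AQ-like composite (range 0-100); subtest slopes
    scale with their WAB ranges. The generating slopes are stored in
    ``DataFrame.attrs`` so recovery tests can compare against them.
    """
    if slope > 0:
        raise ValueError("slope must be <= 0: damage lowers the score")
    rng = np.random.default_rng(seed)
    damage = lesions.truth["target_damage"].to_numpy()
    n = len(damage)
    table = {"patient_id": lesions.truth["patient_id"].to_numpy()}
    scale = slope / _SUBTESTS["aq"][2] if slope != 0 else 0.0
    noise_scale = noise_sd / _SUBTESTS["aq"][3]
    for name, (top, intercept, base_slope, base_sd) in _SUBTESTS.items():
        eff_slope = base_slope * scale
        eff_sd = base_sd * noise_scale
        vals = intercept + eff_slope * damage + eff_sd * rng.standard_normal(n)
        table[name] = np.clip(vals, 0.0, top)
    df = pd.DataFrame(table)
    df["lesion_size"] = lesions.truth["lesion_size"].to_numpy()
    df.attrs["generating_slope_aq"] = float(slope)
    df.attrs["noise_sd"] = float(noise_sd)
    df.attrs["true_damage"] = damage
    return df


@dataclass
class SimCohortConfig:
    """Study conditions for a synthetic cohort (defaults = the toy desk scale)."""

    grid_dim: int = 18
    voxel_mm: float = 4.0
    k_networks: int = 4
    n_hc: int = 20
    n_timepoints: int = 150
    n_patients: int = 24
    snr: float = 2.0
    global_amp: float = 0.5
    tr: float = 2.0
    target_index: int = 0
    target_hit_prob: float = 0.25  # uniform over K=4 networks by default
    network_sigma: float = 1.8
    lesion_size_range: tuple[int, int] = (20, 80)
    lesion_jitter: float = 1.0  # centre offset range in units of network_sigma
    behavior_slope: float = -60.0
    behavior_noise_sd: float = 8.0
    seed: int = 0


@dataclass
class SyntheticCohort:
    ground_truth: GroundTruth
    hc_fmris: list[Fmri4D]
    lesions: LesionCohort
    lesion_truth: pd.DataFrame = field(repr=False)
    behavior: pd.DataFrame = field(repr=False)
    config: SimCohortConfig = field(default_factory=SimCohortConfig)


def make_cohort(config: SimCohortConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a full cohort; all sub-seeds derive from the master seed."""
    cfg = config or SimCohortConfig()
    if seed is not None:
        cfg = SimCohortConfig(**{**cfg.__dict__, "seed": seed})
    master = np.random.default_rng(cfg.seed)
    sub = master.integers(0, 2**31 - 1, size=4)
    grid = default_grid(cfg.grid_dim, cfg.voxel_mm)
    gt = make_networks(
        grid, cfg.k_networks, int(sub[0]), sigma=cfg.network_sigma,
        n_timepoints=cfg.n_timepoints, target_index=cfg.target_index,
    )
    fmris = simulate_fmri(
        gt, cfg.n_hc, cfg.n_timepoints, cfg.snr, int(sub[1]),
        tr=cfg.tr, global_amp=cfg.global_amp,
    )
    rest = (1.0 - cfg.target_hit_prob) / max(cfg.k_networks - 1, 1)
    profile = np.full(cfg.k_networks, rest)
    profile[cfg.target_index] = cfg.target_hit_prob
    sim_lesions = simulate_lesions(
        gt, cfg.n_patients, profile, cfg.lesion_size_range, int(sub[2]),
        jitter=cfg.lesion_jitter,
    )
    behavior = simulate_behavior(
        sim_lesions, gt, cfg.behavior_slope, cfg.behavior_noise_sd, int(sub[3])
    )
    return SyntheticCohort(gt, fmris, sim_lesions.cohort, sim_lesions.truth, behavior, cfg)
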