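"""Deterministic streamline tractography on fiber-orientation peak fields.

White matter is defined by thresholding the per-orientation GFA-like peak
magnitudes inside the brain mask.  Trajectories are integrated
bidirectionally with an adaptive 4th-order Runge-Kutta scheme on the peak
direction field (nearest-angle peak with antipodal sign correction at each
evaluation, trilinearly interpolated between voxels), halving the step when
a proposed turn exceeds the angular limit.  Seeding cycles white-matter
voxels in randomized batches until the yield of distinct trajectories
stagnates.  Accepted fibers are length-filtered and per-bundle statistical
outliers are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .diffusion import PeakField

__all__ = [
    "TrackingConfig",
    "Streamline",
    "wm_mask",
    "integrate_streamline",
    "seed_and_track",
    "filter_fibers",
]


@dataclass
class TrackingConfig:
    """Tractography parameters (lengths in voxel units).

    ``gfa_threshold`` masks white matter (the working range on this kind of
    data is about 0.026-0.029).  ``stagnation_rel_gain`` stops seeding when
    the relative gain in distinct accepted fibers over
    ``stagnation_window`` batches falls below it.
    """

    gfa_threshold: float = 0.027
    step_size: float = 0.5
    max_angle_deg: float = 60.0
    min_length_voxels: float = 3.0
    max_steps: int = 500
    stagnation_window: int = 3
    stagnation_rel_gain: float = 0.01
    max_batches: int = 10
    mad_factor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.step_size <= 1.0):
            raise ValueError("step_size must lie in (0, 1] voxels")
        if self.min_length_voxels < 1:
            raise ValueError("min_length_voxels must be at least 1")
        if self.gfa_threshold <= 0:
            raise ValueError("gfa_threshold must be positive")


@dataclass
class Streamline:
    """Ordered polyline in voxel coordinates."""

    points: np.ndarray
    seed_voxel: tuple[int, int, int]
    length_voxels: float = field(init=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        diffs = np.diff(self.points, axis=0)
        self.length_voxels = float(np.linalg.norm(diffs, axis=1).sum())


def wm_mask(
    gfa_field: np.ndarray,
    peaks: PeakField,
    cfg: TrackingConfig,
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """White-matter mask: inside the brain mask with at least one peak whose
    GFA-like magnitude reaches the threshold."""
    gfa_field = np.asarray(gfa_field)
    if gfa_field.shape != peaks.grid_shape:
        raise ValueError("gfa field and peak field must share a grid")
    if brain_mask is None:
        brain_mask = np.ones(peaks.grid_shape, dtype=bool)
    if cfg.gfa_threshold >= 1.0:
        warnings.warn("gfa_threshold >= 1 leaves an empty white-matter mask")
        return np.zeros(peaks.grid_shape, dtype=bool)
    return brain_mask & (peaks.max_magnitude >= cfg.gfa_threshold)


def _direction_at(
    peaks: PeakField, point: np.ndarray, heading: np.ndarray
) -> np.ndarray | None:
    """Trilinearly interpolated direction: in each neighbor voxel, the peak
    best aligned with the heading (sign-corrected), blended by the trilinear
    weights.  None where no neighbor voxel has peaks."""
    shape = np.array(peaks.grid_shape)
    base = np.floor(point).astype(int)
    frac = point - base
    acc = np.zeros(3)
    wsum = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                vox = base + (dx, dy, dz)
                if np.any(vox < 0) or np.any(vox >= shape):
                    continue
                weight = (
                    (frac[0] if dx else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dz else 1 - frac[2])
                )
                if weight <= 0:
                    continue
                n = peaks.n_peaks[tuple(vox)]
                if n == 0:
                    continue
                dirs = peaks.directions[vox[0], vox[1], vox[2], :n]
                dots = dirs @ heading
                k = int(np.argmax(np.abs(dots)))
                acc += weight * np.sign(dots[k]) * dirs[k]
                wsum += weight
    if wsum <= 0:
        return None
    norm = np.linalg.norm(acc)
    if norm < 1e-12:
        return None
    return acc / norm


def _rk4_direction(
    peaks: PeakField, point: np.ndarray, heading: np.ndarray, h: float
) -> np.ndarray | None:
    k1 = _direction_at(peaks, point, heading)
    if k1 is None:
        return None
    k2 = _direction_at(peaks, point + 0.5 * h * k1, k1)
    if k2 is None:
        return None
    k3 = _direction_at(peaks, point + 0.5 * h * k2, k2)
    if k3 is None:
        return None
    k4 = _direction_at(peaks, point + h * k3, k3)
    if k4 is None:
        return None
    d = k1 + 2.0 * k2 + 2.0 * k3 + k4
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        return None
    return d / norm


def _inside_wm(wm: np.ndarray, point: np.ndarray) -> bool:
    vox = np.round(point).astype(int)
    if np.any(vox < 0) or np.any(vox >= wm.shape):
        return False
    return bool(wm[tuple(vox)])


def _half_track(
    peaks: PeakField,
    wm: np.ndarray,
    start: np.ndarray,
    heading: np.ndarray,
    cfg: TrackingConfig,
) -> list[np.ndarray]:
    cos_max = np.cos(np.deg2rad(cfg.max_angle_deg))
    min_step = cfg.step_size / 4.0
    points: list[np.ndarray] = []
    p = start.copy()
    d_prev = heading.copy()
    for _ in range(cfg.max_steps):
        h = cfg.step_size
        advanced = False
        while True:
            d = _rk4_direction(peaks, p, d_prev, h)
            if d is None:
                break
            if d @ d_prev < cos_max:
                if h > min_step:
                    h /= 2.0  # adaptive step halving on sharp turns
                    continue
                break
            p_new = p + h * d
            if not _inside_wm(wm, p_new):
                break
            points.append(p_new)
            p = p_new
            d_prev = d
            advanced = True
            break
        if not advanced:
            break
    return points


def integrate_streamline(
    peaks: PeakField,
    wm: np.ndarray,
    seed_point,
    cfg: TrackingConfig,
) -> Streamline:
    """Bidirectional RK4 integration from one seed point.

    The first step follows the strongest peak of the seed voxel; both
    half-tracks are concatenated through the seed.  Raises if the seed lies
    outside the white-matter mask.
    """
    seed_point = np.asarray(seed_point, dtype=float)
    vox = tuple(np.round(seed_point).astype(int))
    if not _inside_wm(wm, seed_point):
        raise ValueError(f"seed {seed_point} is outside the white-matter mask")
    n = peaks.n_peaks[vox]
    if n == 0:
        return Streamline(seed_point[None, :], vox)
    init = peaks.directions[vox[0], vox[1], vox[2], 0]
    fwd = _half_track(peaks, wm, seed_point, init, cfg)
    bwd = _half_track(peaks, wm, seed_point, -init, cfg)
    pts = bwd[::-1] + [seed_point] + fwd
    return Streamline(np.array(pts), vox)


def _track_key(track: Streamline) -> tuple:
    a = tuple(np.round(track.points[0]).astype(int))
    b = tuple(np.round(track.points[-1]).astype(int))
    return (min(a, b), max(a, b), int(round(track.length_voxels)))


def seed_and_track(
    peaks: PeakField,
    cfg: TrackingConfig,
    wm: np.ndarray | None = None,
) -> list[Streamline]:
    """Seed white-matter voxels in randomized batches until stagnation.

    Each batch places one jittered seed in every white-matter voxel (in a
    fresh random order).  After each batch, seeding stops when the relative
    gain in the number of distinct accepted fibers over
    ``cfg.stagnation_window`` batches drops below ``cfg.stagnation_rel_gain``
    (distinctness keyed on endpoint voxels and rounded length).
    Deterministic given ``cfg.seed``; accepted means length >=
    ``cfg.min_length_voxels``.
    """
    if wm is None:
        wm = peaks.max_magnitude >= cfg.gfa_threshold
    wm_voxels = np.argwhere(wm)
    if len(wm_voxels) == 0:
        raise ValueError("white-matter mask is empty; nothing to seed")
    rng = np.random.default_rng(cfg.seed)
    accepted: list[Streamline] = []
    distinct: set = set()
    history: list[int] = []
    for _ in range(cfg.max_batches):
        order = rng.permutation(len(wm_voxels))
        for idx in order:
            seed = wm_voxels[idx] + rng.uniform(-0.5, 0.5, 3)
            if not _inside_wm(wm, seed):
                seed = wm_voxels[idx].astype(float)
            track = integrate_streamline(peaks, wm, seed, cfg)
            if track.length_voxels >= cfg.min_length_voxels:
                accepted.append(track)
                distinct.add(_track_key(track))
        history.append(len(distinct))
        if len(history) > cfg.stagnation_window:
            prev = history[-1 - cfg.stagnation_window]
            gain = (history[-1] - prev) / max(history[-1], 1)
            if gain < cfg.stagnation_rel_gain:
                break
    return accepted


def filter_fibers(
    tracks: list[Streamline],
    cfg: TrackingConfig,
    region_pairs: list[tuple] | None = None,
) -> list[Streamline]:
    """Length filter plus per-bundle statistical outlier removal.

    Tracks shorter than ``cfg.min_length_voxels`` are dropped.  When
    ``region_pairs`` gives the connected region pair of each track, tracks
    whose length falls outside median +/- ``mad_factor`` * MAD of their
    bundle are removed as unlikely fibers (bundles with zero MAD keep all
    members; unassigned tracks are only length-filtered).
    """
    if region_pairs is not None and len(region_pairs) != len(tracks):
        raise ValueError("region_pairs must align with tracks")
    keep = [t.length_voxels >= cfg.min_length_voxels for t in tracks]
    if region_pairs is not None:
        bundles: dict[tuple, list[int]] = {}
        for i, pair in enumerate(region_pairs):
            if not keep[i] or pair is None or None in pair:
                continue
            key = tuple(sorted(pair))
            bundles.setdefault(key, []).append(i)
        for idx in bundles.values():
            lengths = np.array([tracks[i].length_voxels for i in idx])
            med = np.median(lengths)
            mad = np.median(np.abs(lengths - med))
            if mad == 0:
                continue
            for i, ln in zip(idx, lengths):
                if abs(ln - med) > cfg.mad_factor * mad:
                    keep[i] = False
    return [t for t, k in zip(tracks, keep) if k]
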