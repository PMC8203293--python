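"""Seeded generators of synthetic inputs with known ground truth.

Every pipeline stage has a matching generator here: stiffness maps with
stiff disc-shaped patches on a softer Gaussian background, SHG-like fiber
renders (anti-aliased thick sinusoidal polylines, Gaussian blur, Poisson
noise), Sirius-red RGB composites with a known red-orange patch coverage,
Hertzian force curves with additive noise, and 3D persistent-random-walk
cell tracks with controllable speed and persistence.

Reproducibility contract: a single integer seed fans out to per-object
substreams via ``numpy`` seed sequences ``default_rng([seed, k])`` where k
is the object counter, so generating one more object never perturbs the
objects before it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .afm import (
    DEFAULT_BEAD_RADIUS_M,
    DEFAULT_POISSON_RATIO,
    DEFAULT_SPRING_CONSTANT_N_PER_M,
    ForceCurve,
    hertz_force,
)
from .fibers import Fiber, FiberSet, SHGImage, path_orientation_deg
from .stiffness import StiffnessMap
from .tracking import CellTrack

__all__ = [
    "StiffnessSimSpec",
    "FiberRenderSpec",
    "TrackSimSpec",
    "gen_stiffness_map",
    "gen_fiber_image",
    "gen_sirius_red_image",
    "gen_force_curve",
    "gen_raw_approach_curve",
    "gen_tracks",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Substream ``stream`` of master ``seed`` (counter-based fan-out)."""
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# Stiffness maps


@dataclass(frozen=True)
class StiffnessSimSpec:
    """Stiffness-map simulation settings (kPa, pixels)."""

    grid_size_px: int = 64
    background_mean_kpa: float = 10.0
    background_sd_kpa: float = 3.0
    n_patches: int = 3
    patch_kpa: float = 60.0
    patch_radius_px: int = 6
    pixel_size_mm: float = 0.1
    seed: int = 0


def gen_stiffness_map(spec: StiffnessSimSpec) -> tuple[StiffnessMap, float]:
    """Generate a stiffness map and the exact fraction of pixels > 40 kPa.

    The background is a clipped Gaussian field; each patch is a rasterized
    disc whose pixels are set to ``patch_kpa``.  Overlapping patches are
    allowed; a patch that would extend off-grid raises.
    """
    n = spec.grid_size_px
    rng = _rng(spec.seed, 0)
    values = np.clip(
        rng.normal(spec.background_mean_kpa, spec.background_sd_kpa, size=(n, n)), 0, None
    )
    r = spec.patch_radius_px
    if spec.n_patches > 0 and 2 * r + 2 > n:
        raise ValueError("patch radius too large for the grid: patches would be off-grid")
    yy, xx = np.mgrid[0:n, 0:n]
    for k in range(spec.n_patches):
        prng = _rng(spec.seed, 1 + k)
        cy, cx = prng.integers(r, n - r, size=2)
        values[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = spec.patch_kpa
    smap = StiffnessMap(values, spec.pixel_size_mm, np.ones((n, n), bool), "synthetic")
    truth_fraction = float(np.count_nonzero(values > 40.0)) / values.size
    return smap, truth_fraction


# ---------------------------------------------------------------------------
# Fiber renders


@dataclass(frozen=True)
class FiberRenderSpec:
    """SHG fiber-render settings.

    Fiber length is defined tip-to-tip (the rendered extent along the fiber,
    round caps included); the drawn centerline is correspondingly shorter by
    one width.  ``waviness_amplitude`` is the sinusoidal perturbation
    amplitude as a fraction of ``waviness_wavelength_um``; 0 renders
    straight fibers.  ``alignment_kappa`` is the von Mises concentration of
    fiber orientations around a per-image random mean direction (0 =
    isotropic).
    """

    n_fibers: int = 5
    width_um_range: tuple[float, float] = (3.0, 8.0)
    length_um_range: tuple[float, float] = (40.0, 120.0)
    waviness_amplitude: float = 0.0
    waviness_wavelength_um: float = 40.0
    alignment_kappa: float = 2.0
    image_size_px: int = 384
    pixel_size_um: float = 0.5
    fiber_intensity: float = 100.0
    background_intensity: float = 5.0
    blur_um: float = 0.5
    min_separation_um: float = 3.0
    max_overlap_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        longest = self.length_um_range[1] / self.pixel_size_um
        if longest > self.image_size_px - 8:
            raise ValueError("image too small to hold the longest requested fiber")


def _fiber_path(
    chord_um: float,
    angle_rad: float,
    center_um: np.ndarray,
    amplitude_um: float,
    wavelength_um: float,
    phase: float,
    step_um: float = 0.1,
) -> np.ndarray:
    """Dense (x, y) polyline of a sinusoidally perturbed straight fiber."""
    n = max(2, int(np.ceil(chord_um / step_um)) + 1)
    s = np.linspace(-chord_um / 2.0, chord_um / 2.0, n)
    u = np.array([np.cos(angle_rad), np.sin(angle_rad)])
    p = np.array([-np.sin(angle_rad), np.cos(angle_rad)])
    offsets = (
        amplitude_um * np.sin(2.0 * np.pi * s / wavelength_um + phase)
        if amplitude_um > 0
        else np.zeros_like(s)
    )
    return center_um[None, :] + s[:, None] * u + offsets[:, None] * p


def _rasterize_path(
    path_um: np.ndarray, half_width_um: float, shape: tuple[int, int], pixel_size_um: float
) -> np.ndarray:
    """Soft-edged coverage image (0..1) of a round-capped thick polyline."""
    from scipy.spatial import cKDTree

    ps = pixel_size_um
    pad = half_width_um / ps + 2
    cmin = np.maximum(np.floor(path_um.min(axis=0) / ps - pad).astype(int), 0)
    cmax = np.minimum(
        np.ceil(path_um.max(axis=0) / ps + pad).astype(int) + 1,
        np.array([shape[1], shape[0]]),
    )
    out = np.zeros(shape, dtype=float)
    if np.any(cmax <= cmin):
        return out
    xs = np.arange(cmin[0], cmax[0]) * ps
    ys = np.arange(cmin[1], cmax[1]) * ps
    gx, gy = np.meshgrid(xs, ys)
    tree = cKDTree(path_um)
    dist, _ = tree.query(np.column_stack([gx.ravel(), gy.ravel()]), k=1)
    cover = np.clip((half_width_um + 0.5 * ps - dist) / ps, 0.0, 1.0)
    out[cmin[1] : cmax[1], cmin[0] : cmax[0]] = cover.reshape(gy.shape)
    return out


def gen_fiber_image(spec: FiberRenderSpec) -> tuple[SHGImage, FiberSet]:
    """Render a fiber field and return it with its per-fiber ground truth.

    Placement is rejection sampling: a candidate is discarded when its mask
    (dilated by ``min_separation_um``) overlaps previously placed fibers by
    more than ``max_overlap_frac``; 1000 failed attempts raise.  The ground
    truth records, per fiber, the tip-to-tip length, width, principal-axis
    orientation and centerline curvature ratio.
    """
    ps = spec.pixel_size_um
    shape = (spec.image_size_px, spec.image_size_px)
    field = np.zeros(shape, dtype=float)
    occupied = np.zeros(shape, dtype=bool)
    sep_px = max(1, int(round(spec.min_separation_um / ps)))
    truths: list[Fiber] = []
    for k in range(spec.n_fibers):
        rng = _rng(spec.seed, 1 + k)
        mu = _rng(spec.seed, 0).uniform(0, np.pi)  # shared per-image mean direction
        placed = False
        for _ in range(1000):
            w = rng.uniform(*spec.width_um_range)
            total_len = rng.uniform(*spec.length_um_range)
            chord = max(total_len - w, 2.0)
            if spec.alignment_kappa > 0:
                theta = (mu + rng.vonmises(0.0, spec.alignment_kappa) / 2.0) % np.pi
            else:
                theta = rng.uniform(0, np.pi)
            amp = spec.waviness_amplitude * spec.waviness_wavelength_um
            phase = rng.uniform(0, 2 * np.pi)
            extent_um = spec.image_size_px * ps
            center = rng.uniform(0.0, extent_um, size=2)
            path = _fiber_path(chord, theta, center, amp, spec.waviness_wavelength_um, phase)
            pad = w / 2.0 + 1.5  # keep the rendered ribbon fully in frame
            if np.any(path.min(axis=0) - pad < 0) or np.any(path.max(axis=0) + pad > extent_um):
                continue
            cover = _rasterize_path(path, w / 2.0, shape, ps)
            mask = cover > 0.25
            dilated = ndimage.binary_dilation(mask, iterations=sep_px)
            overlap = np.count_nonzero(dilated & occupied) / max(np.count_nonzero(mask), 1)
            if overlap > spec.max_overlap_frac:
                continue
            field = np.maximum(field, spec.fiber_intensity * cover)
            occupied |= mask
            arc = float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())
            chord_len = float(np.linalg.norm(path[-1] - path[0]))
            truths.append(
                Fiber(
                    path=path,
                    width_um=w,
                    length_um=arc + w,
                    orientation_deg=path_orientation_deg(path),
                    curvature_ratio=arc / chord_len,
                )
            )
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place fiber {k + 1}/{spec.n_fibers} in 1000 attempts; "
                "reduce n_fibers or fiber size"
            )
    blurred = ndimage.gaussian_filter(field, spec.blur_um / ps)
    noisy = _rng(spec.seed, 10_000).poisson(spec.background_intensity + blurred)
    image = SHGImage(noisy.astype(float), ps, source_id=f"synthetic-{spec.seed}")
    return image, FiberSet(truths, image.source_id)


def gen_sirius_red_image(
    coverage: float = 0.3,
    size_px: int = 256,
    patch_radius_px: int = 12,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """RGB Sirius-red-like composite with known red-orange patch coverage.

    Disc-shaped red-orange patches (thick packed collagen) are added onto a
    green-yellow tissue background until the patch mask covers at least
    ``coverage`` of the frame.  Returns the image (floats in [0, 1]) and the
    exact patch-pixel percentage.
    """
    if not 0 <= coverage < 1:
        raise ValueError("coverage must be in [0, 1)")
    rng = _rng(seed, 0)
    mask = np.zeros((size_px, size_px), dtype=bool)
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    guard = 0
    while mask.mean() < coverage:
        cy, cx = rng.integers(0, size_px, size=2)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= patch_radius_px**2
        guard += 1
        if guard > 100_000:
            raise RuntimeError("coverage target unreachable")
    tissue_rgb = np.array([0.55, 0.75, 0.35])
    red_rgb = np.array([0.85, 0.25, 0.10])
    img = np.where(mask[..., None], red_rgb, tissue_rgb)
    img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, 1.0)
    return img, 100.0 * float(mask.mean())


# ---------------------------------------------------------------------------
# AFM force curves


def gen_force_curve(
    E_Pa: float,
    n_points: int = 200,
    delta_max_m: float | None = None,
    noise_sd_N: float = 0.0,
    noise_frac: float = 0.0,
    bead_radius_m: float = DEFAULT_BEAD_RADIUS_M,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
    spring_constant_N_per_m: float = DEFAULT_SPRING_CONSTANT_N_PER_M,
    seed: int = 0,
) -> ForceCurve:
    """Hertzian force-indentation curve with optional additive and/or
    multiplicative Gaussian noise (seeded)."""
    if E_Pa < 0:
        raise ValueError("E_Pa must be non-negative")
    if delta_max_m is None:
        delta_max_m = bead_radius_m
    delta = np.linspace(0.0, delta_max_m, n_points)
    force = hertz_force(E_Pa, poisson_ratio, bead_radius_m, delta)
    rng = _rng(seed, 0)
    if noise_frac > 0:
        force = force * (1.0 + rng.normal(0.0, noise_frac, force.shape))
    if noise_sd_N > 0:
        force = force + rng.normal(0.0, noise_sd_N, force.shape)
    return ForceCurve(
        indentation_m=delta,
        force_N=force,
        spring_constant_N_per_m=spring_constant_N_per_m,
        bead_radius_m=bead_radius_m,
        poisson_ratio=poisson_ratio,
        curve_id=f"synthetic-E{E_Pa:g}-s{seed}",
    )


def gen_raw_approach_curve(
    E_Pa: float,
    n_points: int = 400,
    contact_index: int = 150,
    z_max_m: float = 4e-6,
    drift_slope: float = 0.0,
    baseline_offset_m: float = 0.0,
    noise_sd_m: float = 0.0,
    bead_radius_m: float = DEFAULT_BEAD_RADIUS_M,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
    spring_constant_N_per_m: float = DEFAULT_SPRING_CONSTANT_N_PER_M,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw piezo-position vs cantilever-deflection approach curve.

    Before ``contact_index`` the deflection is the (possibly drifting)
    baseline; after it the deflection solves the force balance
    ``k d = F_hertz(z - z_c - d)`` by Newton iteration.  Returns
    ``(piezo_m, deflection_m)``.
    """
    z = np.linspace(0.0, z_max_m, n_points)
    zc = z[contact_index]
    d = np.zeros_like(z)
    A = (4.0 / 3.0) * (E_Pa / (1.0 - poisson_ratio**2)) * np.sqrt(bead_radius_m)
    for i in range(contact_index, n_points):
        di = 0.0
        for _ in range(50):
            indent = max(z[i] - zc - di, 0.0)
            f = spring_constant_N_per_m * di - A * indent**1.5
            fp = spring_constant_N_per_m + 1.5 * A * np.sqrt(indent)
            step = f / fp
            di -= step
            if abs(step) < 1e-15:
                break
        d[i] = max(di, 0.0)
    d = d + baseline_offset_m + drift_slope * z
    if noise_sd_m > 0:
        d = d + _rng(seed, 0).normal(0.0, noise_sd_m, d.shape)
    return z, d


# ---------------------------------------------------------------------------
# Cell tracks


@dataclass(frozen=True)
class TrackSimSpec:
    """3D persistent-random-walk settings.

    Step length is constant (``speed_um_per_min * frame_interval / 60``);
    each step the heading is rotated by a Gaussian angle (SD
    ``turning_sd_deg``) about a random axis perpendicular to it.  Walkers
    are confined to an ``arena_um`` square in x/y and to the imaging depth
    window in z, with reflective boundaries.
    """

    n_tracks: int = 50
    speed_um_per_min: float = 3.0
    turning_sd_deg: float = 40.0
    frame_interval_s: float = 30.0
    duration_min: float = 20.0
    arena_um: float = 400.0
    z_range_um: tuple[float, float] = (15.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_min * 60.0 < 2 * self.frame_interval_s:
            raise ValueError("duration must cover at least two frames")


def _perp_axis(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v -= (v @ u) * u
    norm = np.linalg.norm(v)
    if norm < 1e-12:  # pathological draw parallel to u; retry deterministically
        return _perp_axis(u, rng)
    return v / norm


def _rotate(u: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    # Rodrigues rotation; axis is unit and perpendicular to u
    return u * np.cos(angle) + np.cross(axis, u) * np.sin(angle)


def gen_tracks(spec: TrackSimSpec) -> tuple[list[CellTrack], dict]:
    """Simulate persistent random walks; returns tracks and ground truth."""
    dt = spec.frame_interval_s
    n_steps = int(round(spec.duration_min * 60.0 / dt))
    step_len = spec.speed_um_per_min * dt / 60.0
    lo = np.array([0.0, 0.0, spec.z_range_um[0]])
    hi = np.array([spec.arena_um, spec.arena_um, spec.z_range_um[1]])
    tracks = []
    for k in range(spec.n_tracks):
        rng = _rng(spec.seed, k)
        pos = rng.uniform(lo, hi)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pts = [pos.copy()]
        for _ in range(n_steps):
            if spec.turning_sd_deg > 0:
                angle = rng.normal(0.0, np.radians(spec.turning_sd_deg))
                u = _rotate(u, _perp_axis(u, rng), angle)
                u /= np.linalg.norm(u)
            pos = pos + step_len * u
            for ax in range(3):  # reflective boundaries preserve step length
                if pos[ax] < lo[ax]:
                    pos[ax] = 2 * lo[ax] - pos[ax]
                    u[ax] = -u[ax]
                elif pos[ax] > hi[ax]:
                    pos[ax] = 2 * hi[ax] - pos[ax]
                    u[ax] = -u[ax]
            pts.append(pos.copy())
        t = np.arange(n_steps + 1, dtype=float) * dt
        tracks.append(CellTrack(f"sim-{k:04d}", t, np.array(pts), dt))
    truth = {
        "speed_um_per_min": spec.speed_um_per_min,
        "turning_sd_deg": spec.turning_sd_deg,
        "step_length_um": step_len,
        "n_steps": n_steps,
    }
    return tracks, truth
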