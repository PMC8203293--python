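"""Hertzian analysis of AFM force-indentation curves.

Tissue stiffness at the sub-cellular scale is probed by indenting the sample
with a bead-functionalized cantilever and fitting the paraxial Hertz sphere
model

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2)

to the force-vs-indentation curve, where E is the Young's modulus, nu the
Poisson ratio (0.5 for incompressible soft tissue), R the bead radius and
delta the indentation depth.  The expression is valid for delta small
compared with R; the default fit window is (0, R].

Units are SI throughout (Pa, m, N); conversion to kPa happens only at the
reporting layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_SPRING_CONSTANT_N_PER_M",
    "DEFAULT_BEAD_RADIUS_M",
    "DEFAULT_POISSON_RATIO",
    "ForceCurve",
    "ModulusMap",
    "ModulusSummary",
    "hertz_force",
    "estimate_contact_point",
    "fit_young_modulus",
    "summarize_moduli",
]

# Probe used throughout the study design this package mirrors: a 0.6 N/m
# cantilever with a 4.5 µm diameter bead, Poisson ratio 0.5.
DEFAULT_SPRING_CONSTANT_N_PER_M = 0.6
DEFAULT_BEAD_RADIUS_M = 2.25e-6
DEFAULT_POISSON_RATIO = 0.5


@dataclass
class ForceCurve:
    """An ordered force-vs-indentation curve with probe metadata (SI units)."""

    indentation_m: np.ndarray
    force_N: np.ndarray
    spring_constant_N_per_m: float = DEFAULT_SPRING_CONSTANT_N_PER_M
    bead_radius_m: float = DEFAULT_BEAD_RADIUS_M
    poisson_ratio: float = DEFAULT_POISSON_RATIO
    curve_id: str = ""

    def __post_init__(self) -> None:
        self.indentation_m = np.asarray(self.indentation_m, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        if self.indentation_m.shape != self.force_N.shape or self.indentation_m.ndim != 1:
            raise ValueError("indentation and force must be equal-length 1D arrays")
        if self.indentation_m.size < 10:
            raise ValueError("force curve needs at least 10 samples")
        if np.any(np.diff(self.indentation_m) < 0):
            raise ValueError("indentation must be non-decreasing")
        if not self.bead_radius_m > 0:
            raise ValueError("bead_radius_m must be positive")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")


@dataclass
class ModulusMap:
    """Fitted Young's moduli for one force-map scan (up to 64 points/map)."""

    moduli_Pa: np.ndarray
    sample_id: str = ""
    map_extent_um: float = 10.0

    def __post_init__(self) -> None:
        self.moduli_Pa = np.asarray(self.moduli_Pa, dtype=float).ravel()
        if np.any(self.moduli_Pa < 0):
            raise ValueError("moduli must be non-negative")


@dataclass(frozen=True)
class ModulusSummary:
    """Pooled mean ± sample SD of per-point moduli plus a histogram."""

    mean_Pa: float
    sd_Pa: float
    histogram_counts: tuple[int, ...]
    histogram_edges_Pa: tuple[float, ...]
    n_points: int


def hertz_force(
    E_Pa: float, nu: float, R_m: float, delta_m: float | np.ndarray
) -> float | np.ndarray:
    """Paraxial Hertz force (N) of a sphere of radius R at indentation delta."""
    delta = np.asarray(delta_m, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation depth must be non-negative")
    if E_Pa < 0:
        raise ValueError("Young's modulus must be non-negative")
    if not R_m > 0:
        raise ValueError("bead radius must be positive")
    if not nu < 1:
        raise ValueError("Poisson ratio must be < 1")
    out = (4.0 / 3.0) * (E_Pa / (1.0 - nu**2)) * np.sqrt(R_m) * delta**1.5
    return float(out) if np.isscalar(delta_m) else out


def estimate_contact_point(
    piezo_m: np.ndarray,
    deflection_m: np.ndarray,
    spring_constant_N_per_m: float = DEFAULT_SPRING_CONSTANT_N_PER_M,
    bead_radius_m: float = DEFAULT_BEAD_RADIUS_M,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
    baseline_fraction: float = 0.1,
    min_contrast: float = 10.0,
) -> tuple[int, ForceCurve]:
    """Locate the contact point of a raw approach curve and convert it.

    The leading ``baseline_fraction`` of samples defines a linear drift model
    that is subtracted.  The contact index is then the *latest* split whose
    pre-contact deflection variance is still at the baseline noise floor —
    the split maximizing the after/before variance ratio, with the flat
    pre-contact plateau tie-broken toward the contact onset.  Detection
    requires the after/before variance contrast at that split to exceed
    ``min_contrast``.  From the contact point on, ``force = k * deflection``
    and ``indentation = piezo displacement − deflection``, both zeroed at
    contact.

    Returns ``(contact_index, ForceCurve)``.  Raises if no contact is
    detected.
    """
    z = np.asarray(piezo_m, dtype=float)
    d = np.asarray(deflection_m, dtype=float)
    if z.shape != d.shape or z.ndim != 1 or z.size < 20:
        raise ValueError("need equal-length 1D piezo/deflection arrays (>= 20 samples)")
    if np.any(np.diff(z) < 0):
        raise ValueError("piezo position must be monotone non-decreasing")

    n = z.size
    n_base = max(10, int(baseline_fraction * n))
    slope, intercept = np.polyfit(z[:n_base], d[:n_base], 1)
    resid = d - (slope * z + intercept)
    if np.ptp(resid) == 0:
        raise ValueError("no contact detected: deflection curve is flat")

    floor = float(np.var(resid[:n_base]))
    eps = (1e-6 * float(np.ptp(resid))) ** 2 + 1e-300
    candidates = [
        i for i in range(n_base, n - 5) if float(np.var(resid[:i])) <= 2.0 * floor + eps
    ]
    contact = max(candidates) if candidates else n_base
    contrast = float(np.var(resid[contact:])) / (floor + eps)
    if contrast < min_contrast:
        raise ValueError("no contact detected: deflection curve is flat")

    d0 = resid[contact:] - resid[contact]  # drift-corrected deflection
    force = spring_constant_N_per_m * d0
    indentation = (z[contact:] - z[contact]) - d0
    keep = indentation >= 0
    curve = ForceCurve(
        indentation_m=indentation[keep],
        force_N=force[keep],
        spring_constant_N_per_m=spring_constant_N_per_m,
        bead_radius_m=bead_radius_m,
        poisson_ratio=poisson_ratio,
    )
    return contact, curve


def fit_young_modulus(
    curve: ForceCurve,
    fit_depth_max_m: float | None = None,
    max_rel_residual: float = 0.5,
) -> float:
    """Least-squares Young's modulus (Pa) from a force-indentation curve.

    The Hertz model is linear in E, so the fit is the closed-form projection
    ``E = sum(F*g) / sum(g^2)`` with ``g = (4/3) sqrt(R) delta^1.5 / (1-nu^2)``,
    clipped at 0.  The fit window is indentation in (0, ``fit_depth_max_m``],
    defaulting to one bead radius.  Curves whose relative residual exceeds
    ``max_rel_residual`` raise (they are excluded and counted by the callers
    that aggregate maps).
    """
    if fit_depth_max_m is None:
        fit_depth_max_m = curve.bead_radius_m
    delta = curve.indentation_m
    force = curve.force_N
    if not np.all(np.isfinite(force)):
        raise ValueError("force curve contains non-finite values")
    window = (delta > 0) & (delta <= fit_depth_max_m)
    if int(window.sum()) < 10:
        raise ValueError(
            f"only {int(window.sum())} points with indentation in (0, "
            f"{fit_depth_max_m:.3g}]; need >= 10"
        )
    d, f = delta[window], force[window]
    g = hertz_force(1.0, curve.poisson_ratio, curve.bead_radius_m, d)
    denom = float(g @ g)
    E = max(0.0, float(f @ g) / denom)
    f_norm = float(np.linalg.norm(f))
    if f_norm > 0:
        rel_residual = float(np.linalg.norm(f - E * g)) / f_norm
        if rel_residual > max_rel_residual:
            raise ValueError(
                f"fit rejected: relative residual {rel_residual:.2f} > {max_rel_residual}"
            )
    return E


def summarize_moduli(
    maps: list[ModulusMap] | ModulusMap, bin_width_Pa: float = 250.0
) -> ModulusSummary:
    """Pool per-point moduli over maps into mean ± sample SD and a histogram.

    All points of all maps are pooled (per-map means are *not* averaged
    first).  A single-point pool reports SD 0 with a warning.
    """
    if isinstance(maps, ModulusMap):
        maps = [maps]
    if not maps:
        raise ValueError("no modulus maps to summarize")
    pooled = np.concatenate([m.moduli_Pa for m in maps])
    if pooled.size == 0:
        raise ValueError("modulus maps contain no points")
    if pooled.size == 1:
        warnings.warn("single-point pool: SD is undefined, reporting 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(pooled, ddof=1))
    hi = max(float(pooled.max()), bin_width_Pa)
    edges = np.arange(0.0, hi + bin_width_Pa, bin_width_Pa)
    counts, edges = np.histogram(pooled, bins=edges)
    return ModulusSummary(
        mean_Pa=float(np.mean(pooled)),
        sd_Pa=sd,
        histogram_counts=tuple(int(c) for c in counts),
        histogram_edges_Pa=tuple(float(e) for e in edges),
        n_points=int(pooled.size),
    )
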