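"""Quantification of shear-wave elastography (SWE) stiffness maps.

A stiffness map is a 2D grid of Young's-modulus estimates (kPa) with an
operator-drawn region of interest (ROI) delimiting the tumor.  This module
computes the per-ROI summary statistics used to follow tumor stiffening over
time: mean/min/max/SD stiffness, tumor area, the fraction of "stiff" pixels
above a threshold (40 kPa by default, a published cut-off for very stiff
tumor regions), the normalized stiffness time series, and the caliper
estimate of xenograft volume.

Elastography dropouts — pixels the scanner could not measure, encoded as NaN
or a negative sentinel — are excluded from every statistic and reported as a
dropout fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_STIFF_THRESHOLD_KPA",
    "StiffnessMap",
    "StiffnessSummary",
    "TumorMeasurement",
    "EmptyROIError",
    "compute_roi_summary",
    "stiff_area_fraction",
    "normalized_stiffness",
    "caliper_volume",
    "load_stiffness_map",
    "load_roi_mask",
    "summary_to_row",
]

#: Published cut-off (kPa) above which a pixel counts as a "very stiff region".
DEFAULT_STIFF_THRESHOLD_KPA = 40.0


class EmptyROIError(ValueError):
    """Raised when a map has no usable tumor region."""


@dataclass
class StiffnessMap:
    """A 2D elasticity grid (kPa) with an isotropic pixel size and ROI mask.

    Coordinates are 0-based row-major, ``(row, col) == (y, x)``.
    """

    values: np.ndarray
    pixel_size_mm: float
    roi: np.ndarray
    subject_id: str = ""
    timepoint_days: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi = np.asarray(self.roi, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("stiffness map must be a 2D grid")
        if self.roi.shape != self.values.shape:
            raise ValueError(
                f"ROI shape {self.roi.shape} does not match map shape {self.values.shape}"
            )
        if not self.roi.any():
            raise EmptyROIError("ROI mask is empty: no tumor region to quantify")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")


@dataclass(frozen=True)
class StiffnessSummary:
    """Per-ROI stiffness statistics (all stiffness fields in kPa)."""

    mean_kPa: float
    min_kPa: float
    max_kPa: float
    sd_kPa: float
    area_mm2: float
    stiff_fraction: float
    threshold_kPa: float
    dropout_fraction: float = 0.0
    n_pixels: int = 0


@dataclass(frozen=True)
class TumorMeasurement:
    """A caliper measurement: longest/shortest perpendicular diameters (mm)."""

    timepoint_days: float
    x_mm: float
    y_mm: float
    volume_mm3: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "volume_mm3", caliper_volume(self.x_mm, self.y_mm))


def compute_roi_summary(
    smap: StiffnessMap, threshold_kPa: float = DEFAULT_STIFF_THRESHOLD_KPA
) -> StiffnessSummary:
    """Summarize stiffness over the in-ROI pixels of a map.

    The stiff fraction is the number of valid in-ROI pixels *strictly* above
    ``threshold_kPa`` divided by the number of valid in-ROI pixels.  NaN and
    negative pixels (dropouts) are excluded from all statistics and counted
    in ``dropout_fraction``; infinite pixels raise.
    """
    if not threshold_kPa > 0:
        raise ValueError("threshold_kPa must be positive")
    vals = smap.values[smap.roi]
    n_inf = int(np.isinf(vals).sum())
    if n_inf:
        raise ValueError(f"{n_inf} infinite pixel value(s) inside the ROI")
    dropout = np.isnan(vals) | (vals < 0)
    valid = vals[~dropout]
    if valid.size == 0:
        raise EmptyROIError("all in-ROI pixels are dropouts; no valid stiffness data")
    sd = float(np.std(valid, ddof=1)) if valid.size > 1 else 0.0
    return StiffnessSummary(
        mean_kPa=float(np.mean(valid)),
        min_kPa=float(np.min(valid)),
        max_kPa=float(np.max(valid)),
        sd_kPa=sd,
        area_mm2=float(vals.size) * smap.pixel_size_mm**2,
        stiff_fraction=float(np.count_nonzero(valid > threshold_kPa)) / valid.size,
        threshold_kPa=float(threshold_kPa),
        dropout_fraction=float(dropout.sum()) / vals.size,
        n_pixels=int(valid.size),
    )


def stiff_area_fraction(
    smap: StiffnessMap, threshold_kPa: float = DEFAULT_STIFF_THRESHOLD_KPA
) -> float:
    """Fraction (in [0, 1]) of valid ROI pixels strictly above ``threshold_kPa``."""
    return compute_roi_summary(smap, threshold_kPa).stiff_fraction


def normalized_stiffness(
    series: Sequence[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Normalize a (timepoint, mean stiffness) series by its first value.

    Returns ``(t_n, stiffness_n / stiffness_0)`` for each point; the first
    ratio is 1 by construction.
    """
    if len(series) < 1:
        raise ValueError("series must contain at least one point")
    times = [t for t, _ in series]
    if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
        raise ValueError("timepoints must be strictly increasing")
    t0, m0 = series[0]
    if not m0 > 0:
        raise ValueError("initial mean stiffness must be positive to normalize")
    return [(t, m / m0) for t, m in series]


def caliper_volume(x_mm: float, y_mm: float) -> float:
    """Ellipsoid-approximation xenograft volume ``x * y**2 / 2`` in mm³.

    ``x_mm`` is the longest and ``y_mm`` the shortest of two perpendicular
    diameters.
    """
    if not (x_mm > 0 and y_mm > 0):
        raise ValueError("diameters must be positive")
    if y_mm > x_mm:
        raise ValueError(
            "y_mm exceeds x_mm: pass the longest diameter first (swap the arguments)"
        )
    return x_mm * y_mm**2 / 2.0


# ---------------------------------------------------------------------------
# I/O


def load_stiffness_map(
    map_path: str | Path,
    roi_path: str | Path | None,
    pixel_size_mm: float,
    subject_id: str = "",
    timepoint_days: float = 0.0,
) -> StiffnessMap:
    """Load a stiffness map from TIFF or CSV, with an optional ROI sidecar.

    ``roi_path`` may be a binary TIFF mask or a JSON polygon sidecar of the
    form ``{"polygon": [[x, y], ...]}`` (image coordinates, pixels).  Without
    an ROI the full frame is used.
    """
    map_path = Path(map_path)
    if map_path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        values = np.asarray(tifffile.imread(map_path), dtype=float)
    else:
        values = np.loadtxt(map_path, delimiter=",", dtype=float, ndmin=2)
    roi = (
        np.ones(values.shape, dtype=bool)
        if roi_path is None
        else load_roi_mask(roi_path, values.shape)
    )
    return StiffnessMap(values, pixel_size_mm, roi, subject_id, timepoint_days)


def load_roi_mask(roi_path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    """Load an ROI as a binary TIFF mask or rasterize a JSON polygon sidecar."""
    roi_path = Path(roi_path)
    if roi_path.suffix.lower() == ".json":
        from skimage.draw import polygon2mask

        polygon = json.loads(roi_path.read_text())["polygon"]
        # sidecar vertices are (x, y); polygon2mask wants (row, col)
        rc = np.array([[y, x] for x, y in polygon], dtype=float)
        return polygon2mask(shape, rc)
    import tifffile

    mask = np.asarray(tifffile.imread(roi_path))
    if mask.shape != shape:
        raise ValueError(f"ROI mask shape {mask.shape} does not match map shape {shape}")
    return mask.astype(bool)


def summary_to_row(smap: StiffnessMap, summary: StiffnessSummary) -> dict:
    """Flatten a summary into the CSV row schema used by the CLI and pipeline."""
    return {
        "subject_id": smap.subject_id,
        "timepoint": smap.timepoint_days,
        "mean_kPa": summary.mean_kPa,
        "min_kPa": summary.min_kPa,
        "max_kPa": summary.max_kPa,
        "sd_kPa": summary.sd_kPa,
        "area_mm2": summary.area_mm2,
        "stiff_fraction": summary.stiff_fraction,
        "threshold_kPa": summary.threshold_kPa,
        "dropout_fraction": summary.dropout_fraction,
    }
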