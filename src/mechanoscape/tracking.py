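"""T-cell track filtering and motility statistics.

Tracks come from 3D time-lapse imaging of tumor slices (frames every 30 s
for 20 min in the study design this package mirrors).  Two filters mirror
the standard slice-imaging conventions: samples shallower than 15 µm are
discarded (cells near the cut surface behave abnormally), and only tracks
covering strictly more than 10% of the recording are analyzed.  Per-track
statistics are the mean migration speed (path length / duration, µm/min),
the displacement (3D Euclidean distance between first and last position)
and the straightness (displacement / path length; 1 = ballistic, 0 = closed
loop).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CUT_DEPTH_UM",
    "DEFAULT_MIN_DURATION_FRACTION",
    "CellTrack",
    "MotilitySummary",
    "RegionDensity",
    "depth_filter",
    "duration_filter",
    "split_on_gaps",
    "motility_summary",
    "region_density",
    "load_tracks_csv",
    "tracks_to_frame",
]

DEFAULT_CUT_DEPTH_UM = 15.0
DEFAULT_MIN_DURATION_FRACTION = 0.1


@dataclass
class CellTrack:
    """Time-stamped 3D positions of one cell at a fixed frame interval.

    ``t_s`` must be strictly increasing and each step a positive integer
    multiple of ``frame_interval_s`` (gaps from missed detections allowed).
    ``xyz_um`` is an (N, 3) array; z is depth below the slice surface.
    """

    track_id: str
    t_s: np.ndarray
    xyz_um: np.ndarray
    frame_interval_s: float = 30.0

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.xyz_um = np.asarray(self.xyz_um, dtype=float)
        if self.t_s.ndim != 1 or self.t_s.size < 2:
            raise ValueError("track needs at least two samples")
        if self.xyz_um.shape != (self.t_s.size, 3):
            raise ValueError("xyz_um must be (n_samples, 3)")
        dt = np.diff(self.t_s)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        steps = dt / self.frame_interval_s
        if not np.allclose(steps, np.round(steps), atol=1e-6):
            raise ValueError("time steps must be integer multiples of the frame interval")

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])


@dataclass(frozen=True)
class MotilitySummary:
    """Per-track motility statistics."""

    track_id: str
    speed_um_per_min: float
    displacement_um: float
    straightness: float
    path_length_um: float
    duration_s: float


@dataclass(frozen=True)
class RegionDensity:
    """Cell count density within one labeled tissue region."""

    region_label: str
    n_cells: int
    region_area_mm2: float
    cells_per_mm2: float


def depth_filter(
    tracks: Iterable[CellTrack], cut_depth_um: float = DEFAULT_CUT_DEPTH_UM
) -> list[CellTrack]:
    """Remove samples shallower than ``cut_depth_um`` (z < cut, strict).

    Tracks left with fewer than two samples are dropped entirely; an empty
    result is valid.
    """
    kept: list[CellTrack] = []
    for tr in tracks:
        keep = tr.xyz_um[:, 2] >= cut_depth_um
        if int(keep.sum()) < 2:
            continue
        kept.append(
            CellTrack(tr.track_id, tr.t_s[keep], tr.xyz_um[keep], tr.frame_interval_s)
        )
    return kept


def duration_filter(
    tracks: Iterable[CellTrack],
    recording_s: float,
    min_fraction: float = DEFAULT_MIN_DURATION_FRACTION,
) -> list[CellTrack]:
    """Keep tracks whose span is strictly > ``min_fraction * recording_s``.

    Duration is ``t_last − t_first`` (robust to gaps), and the boundary is a
    strict inequality: a track of exactly 10% of a recording is excluded.
    """
    if not recording_s > 0:
        raise ValueError("recording_s must be positive")
    cut = min_fraction * recording_s
    return [tr for tr in tracks if tr.duration_s > cut]


def split_on_gaps(track: CellTrack, max_gap_frames: int = 3) -> list[CellTrack]:
    """Split a track wherever a detection gap exceeds ``max_gap_frames``.

    Gaps up to the limit are bridged implicitly by the straight segment
    between the flanking samples; longer gaps split the track into
    independently analyzed pieces (suffix ``/0``, ``/1``...).  Pieces with
    fewer than two samples are dropped.
    """
    steps = np.diff(track.t_s) / track.frame_interval_s
    cuts = np.flatnonzero(steps > max_gap_frames) + 1
    if cuts.size == 0:
        return [track]
    pieces = []
    for k, idx in enumerate(np.split(np.arange(track.t_s.size), cuts)):
        if idx.size < 2:
            continue
        pieces.append(
            CellTrack(
                f"{track.track_id}/{k}",
                track.t_s[idx],
                track.xyz_um[idx],
                track.frame_interval_s,
            )
        )
    return pieces


def motility_summary(track: CellTrack, mode: str = "3d") -> MotilitySummary:
    """Speed (µm/min), displacement (µm) and straightness of one track.

    ``mode='2d'`` projects out z before computing all three statistics, for
    comparability with 2D trackers; the default follows the full 3D path.
    """
    if mode == "3d":
        pos = track.xyz_um
    elif mode == "2d":
        pos = track.xyz_um[:, :2]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    path_length = float(steps.sum())
    displacement = float(np.linalg.norm(pos[-1] - pos[0]))
    duration = track.duration_s
    speed = path_length / duration * 60.0
    straightness = displacement / path_length if path_length > 0 else 0.0
    return MotilitySummary(
        track_id=track.track_id,
        speed_um_per_min=speed,
        displacement_um=displacement,
        straightness=straightness,
        path_length_um=path_length,
        duration_s=duration,
    )


def region_density(
    positions_xy_mm: np.ndarray,
    region_mask: np.ndarray,
    pixel_size_mm: float,
    label_map: Mapping[int, str] = {1: "stroma", 2: "tumor_islet"},
) -> list[RegionDensity]:
    """Cells per mm² in each labeled region of a tissue mask.

    ``positions_xy_mm`` is an (N, 2) array of (x, y) cell positions in mm;
    ``region_mask`` an integer label image (0 = background) on the same
    coordinate frame.  Positions outside the frame are ignored.
    """
    positions = np.asarray(positions_xy_mm, dtype=float).reshape(-1, 2)
    mask = np.asarray(region_mask)
    if not pixel_size_mm > 0:
        raise ValueError("pixel_size_mm must be positive")
    cols = np.floor(positions[:, 0] / pixel_size_mm).astype(int)
    rows = np.floor(positions[:, 1] / pixel_size_mm).astype(int)
    inside = (rows >= 0) & (rows < mask.shape[0]) & (cols >= 0) & (cols < mask.shape[1])
    labels_at = mask[rows[inside], cols[inside]]
    out = []
    for value, name in label_map.items():
        area_px = int((mask == value).sum())
        if area_px == 0:
            raise ValueError(f"region {name!r} has zero area")
        area = area_px * pixel_size_mm**2
        count = int((labels_at == value).sum())
        out.append(RegionDensity(name, count, area, count / area))
    return out


# ---------------------------------------------------------------------------
# I/O


def load_tracks_csv(path: str | Path, frame_interval_s: float = 30.0) -> list[CellTrack]:
    """Read tracks from a CSV with columns track_id, frame, t_s, x_um, y_um, z_um."""
    df = pd.read_csv(path)
    required = {"track_id", "t_s", "x_um", "y_um", "z_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track table is missing columns: {sorted(missing)}")
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("t_s")
        tracks.append(
            CellTrack(
                str(tid),
                sub["t_s"].to_numpy(),
                sub[["x_um", "y_um", "z_um"]].to_numpy(),
                frame_interval_s,
            )
        )
    return tracks


def tracks_to_frame(tracks: Iterable[CellTrack]) -> pd.DataFrame:
    """Serialize tracks to the CSV row schema used by :func:`load_tracks_csv`."""
    rows = []
    for tr in tracks:
        frames = np.round((tr.t_s - tr.t_s[0]) / tr.frame_interval_s).astype(int)
        for f, t, (x, y, z) in zip(frames, tr.t_s, tr.xyz_um):
            rows.append(
                {"track_id": tr.track_id, "frame": f, "t_s": t, "x_um": x, "y_um": y, "z_um": z}
            )
    return pd.DataFrame(rows)
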