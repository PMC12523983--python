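"""Reading and writing the pipeline's on-disk formats.

Intensity and label stacks are TIFF (multi-page or a directory of per-frame
files, natural-sorted). Tracking tables are delimited text in either a
generic ``frame,cell,x,y`` dialect or the TrackMate spots-export dialect
(``TRACK_ID``, ``POSITION_X``, ``POSITION_Y``, ``FRAME`` with optional
non-numeric sub-header rows). Feature tables are CSV with one row per tracked
cell: ``track_id``, ``class`` and the 1083 profile feature columns.

Coordinate conventions: 0-based pixel indices, x = column, y = row. Real
tracking coordinates are rounded half-away-from-zero for label lookup.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    DimensionError,
    DuplicateRecordError,
    NoInputError,
    SchemaError,
)

logger = logging.getLogger(__name__)

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass
class LabelledMovie:
    """Paired intensity and label stacks, shape (frames, height, width)."""

    intensity: np.ndarray
    labels: np.ndarray
    pixel_size: float | None = None
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        if self.intensity.ndim != 3 or self.labels.ndim != 3:
            raise DimensionError("stacks must be 3-D (frames, height, width)")
        if self.intensity.shape != self.labels.shape:
            raise DimensionError(
                f"intensity shape {self.intensity.shape} != "
                f"label shape {self.labels.shape}"
            )
        if np.any(self.labels < 0):
            raise DimensionError("label images must be non-negative integers")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.intensity.shape[1:]

    @property
    def diagonal(self) -> float:
        h, w = self.frame_shape
        return math.hypot(h, w)


@dataclass
class Trajectory:
    """One cell's ordered (frame, centroid, mask label) records."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    xs: list[float] = field(default_factory=list)
    ys: list[float] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class CellProfile:
    """The fixed-order 1083-feature summary of one tracked cell."""

    track_id: int
    features: np.ndarray
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (1083,):
            raise DimensionError(
                f"profile must have exactly 1083 features, got {self.features.shape}"
            )


def _natural_key(name: str) -> tuple:
    """Sort key comparing digit runs numerically: t2 < t10."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def read_image_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF or a directory of per-frame TIFFs as a stack.

    Directory frames are ordered by natural sort of filenames.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES),
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise NoInputError(f"no TIFF files in {path}")
        frames = [tifffile.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise DimensionError(f"mixed frame dimensions in {path}: {sorted(shapes)}")
        return np.stack(frames)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise DimensionError(f"expected 2-D pages in {path}, got shape {stack.shape}")
    return stack


def read_movie(
    intensity_path: str | Path,
    labels_path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> LabelledMovie:
    intensity = np.asarray(read_image_stack(intensity_path), dtype=float)
    labels = read_image_stack(labels_path)
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.allclose(labels, np.round(labels)):
            raise DimensionError(f"label stack {labels_path} is not integer-valued")
        labels = np.round(labels).astype(np.int64)
    return LabelledMovie(intensity, labels.astype(np.int64), pixel_size, frame_interval)


_GENERIC_COLUMNS = {"frame", "cell", "x", "y"}
_TRACKMATE_COLUMNS = {"TRACK_ID", "POSITION_X", "POSITION_Y", "FRAME"}


def read_track_table(
    path: str | Path,
    dialect: str = "generic",
    frame_base: int = 0,
) -> pd.DataFrame:
    """Read a tracking table into columns frame, track_id, x, y.

    ``generic`` expects a ``frame,cell,x,y`` header; ``frame_base`` declares
    the dialect's first frame index (internal indices are 0-based).
    ``trackmate`` expects the spots-export columns and skips the
    non-numeric unit/description rows TrackMate writes below the header.
    """
    if dialect not in ("generic", "trackmate"):
        raise SchemaError(f"unknown track dialect {dialect!r}")
    raw = pd.read_csv(path)
    if dialect == "generic":
        missing = _GENERIC_COLUMNS - set(raw.columns)
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(sorted(missing))}")
        table = pd.DataFrame(
            {
                "frame": pd.to_numeric(raw["frame"]).astype(int) - frame_base,
                "track_id": pd.to_numeric(raw["cell"]).astype(int),
                "x": pd.to_numeric(raw["x"]).astype(float),
                "y": pd.to_numeric(raw["y"]).astype(float),
            }
        )
    else:
        missing = _TRACKMATE_COLUMNS - set(raw.columns)
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(sorted(missing))}")
        numeric = raw[["TRACK_ID", "POSITION_X", "POSITION_Y", "FRAME"]].apply(
            pd.to_numeric, errors="coerce"
        )
        keep = numeric.notna().all(axis=1)
        n_skipped = int((~keep).sum())
        if n_skipped:
            logger.info("skipped %d non-numeric sub-header row(s)", n_skipped)
        numeric = numeric[keep]
        table = pd.DataFrame(
            {
                "frame": numeric["FRAME"].astype(int),  # TrackMate is 0-based
                "track_id": numeric["TRACK_ID"].astype(int),
                "x": numeric["POSITION_X"].astype(float),
                "y": numeric["POSITION_Y"].astype(float),
            }
        )
    dup = table.duplicated(subset=["frame", "track_id"])
    if dup.any():
        pair = table.loc[dup.idxmax(), ["frame", "track_id"]]
        raise DuplicateRecordError(
            f"duplicate (frame, track) pair: ({pair['frame']}, {pair['track_id']})"
        )
    return table.reset_index(drop=True)


def _round_half_away(v: float) -> int:
    return int(math.copysign(math.floor(abs(v) + 0.5), v))


def _lookup_label(
    label_frame: np.ndarray, x: float, y: float, rescue_radius: int = 2
) -> int:
    """Label at the nearest pixel to (x, y); on background, the nearest
    non-zero label within a Chebyshev radius; 0 when none is found."""
    h, w = label_frame.shape
    col = _round_half_away(x)
    row = _round_half_away(y)
    if not (0 <= row < h and 0 <= col < w):
        return 0
    label = int(label_frame[row, col])
    if label > 0:
        return label
    candidates = []
    for dr in range(-rescue_radius, rescue_radius + 1):
        for dc in range(-rescue_radius, rescue_radius + 1):
            r, c = row + dr, col + dc
            if 0 <= r < h and 0 <= c < w and label_frame[r, c] > 0:
                candidates.append((math.hypot(r - y, c - x), int(label_frame[r, c])))
    if not candidates:
        return 0
    return min(candidates)[1]  # nearest; ties broken by smallest label


def link_tracks_to_masks(
    tracks: pd.DataFrame,
    movie: LabelledMovie,
    rescue_radius: int = 2,
) -> list[Trajectory]:
    """Associate every tracking row with a mask label and group into
    trajectories sorted by frame. Unresolvable rows are dropped with a
    warning."""
    if (tracks["frame"] < 0).any() or (tracks["frame"] >= movie.n_frames).any():
        raise DimensionError("track table frame index outside movie range")
    trajectories: dict[int, Trajectory] = {}
    n_dropped = 0
    for tid, group in tracks.groupby("track_id", sort=True):
        traj = Trajectory(track_id=int(tid))
        for row in group.sort_values("frame").itertuples(index=False):
            label = _lookup_label(
                movie.labels[int(row.frame)], row.x, row.y, rescue_radius
            )
            if label == 0:
                n_dropped += 1
                continue
            traj.frames.append(int(row.frame))
            traj.xs.append(float(row.x))
            traj.ys.append(float(row.y))
            traj.labels.append(label)
        if len(traj):
            trajectories[int(tid)] = traj
        else:
            logger.warning("track %d has no resolvable records; dropped", tid)
    if n_dropped:
        logger.warning("dropped %d tracking row(s) with no nearby mask label", n_dropped)
    return [trajectories[tid] for tid in sorted(trajectories)]


def profiles_to_frame(profiles: list[CellProfile]) -> tuple[pd.DataFrame, pd.Series]:
    """Labelled profiles as an (X, y) pair: features indexed by track_id and
    the class labels (None where unlabelled)."""
    from .summarise import PROFILE_FEATURE_NAMES

    if not profiles:
        raise NoInputError("no profiles")
    X = pd.DataFrame(
        np.vstack([p.features for p in profiles]),
        columns=list(PROFILE_FEATURE_NAMES),
        index=pd.Index([p.track_id for p in profiles], name="track_id"),
    )
    y = pd.Series([p.class_label for p in profiles], index=X.index, name="class")
    return X, y


def write_feature_table(profiles: list[CellProfile], path: str | Path) -> None:
    """Write profiles as CSV: track_id, class, then the 1083 feature columns."""
    if not profiles:
        raise NoInputError("cannot write an empty profile list")
    X, y = profiles_to_frame(profiles)
    out = X.copy()
    out.insert(0, "class", y.values)
    out.to_csv(path, index=True)


def read_feature_table(path: str | Path) -> list[CellProfile]:
    """Inverse of :func:`write_feature_table`; validates the 1083-column width."""
    from .summarise import PROFILE_FEATURE_NAMES

    table = pd.read_csv(path, index_col="track_id")
    feature_cols = [c for c in table.columns if c != "class"]
    if len(feature_cols) != 1083:
        raise DimensionError(
            f"feature table has {len(feature_cols)} feature columns, expected 1083"
        )
    if list(feature_cols) != list(PROFILE_FEATURE_NAMES):
        raise SchemaError("feature table columns do not match the profile registry")
    profiles = []
    for tid, row in table.iterrows():
        label = row["class"]
        profiles.append(
            CellProfile(
                track_id=int(tid),
                features=row[feature_cols].to_numpy(dtype=float),
                class_label=None if pd.isna(label) else str(label),
            )
        )
    return profiles
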