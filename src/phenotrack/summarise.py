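"""Summarising per-frame feature time series into fixed-length cell profiles.

Each tracked cell contributes one profile: for every one of the 72 per-frame
features, its time series over the trajectory is reduced to 15 statistics
(six distributional: mean, median, sample SD, skewness, excess kurtosis,
maximum; and nine from an orthonormal Haar wavelet decomposition: detail
energy, largest ascent and largest descent at levels 1-3). Three
whole-trajectory features (total track length, net displacement, convex hull
area of the visited centroids) complete the profile:

    72 x 15 + 3 = 1083 features, in fixed registry-major order.

Trajectories shorter than ``min_track_length`` frames (default 8, the
minimum for a level-3 Haar decomposition) are excluded. Tracking gaps of up
to ``max_gap`` frames (default 3) are filled by linear interpolation of both
centroids and per-frame feature values; longer gaps split the trajectory
into independent segments.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import ParameterError
from .features import FRAME_FEATURE_CATEGORIES, FRAME_FEATURE_NAMES
from .io import CellProfile, Trajectory

logger = logging.getLogger(__name__)

DEFAULT_MIN_TRACK_LENGTH = 8
DEFAULT_MAX_GAP = 3

SUMMARY_NAMES = (
    "Mean",
    "Median",
    "SD",
    "Skewness",
    "Kurtosis",
    "Max",
    "DetailEnergy1",
    "MaxAscent1",
    "MaxDescent1",
    "DetailEnergy2",
    "MaxAscent2",
    "MaxDescent2",
    "DetailEnergy3",
    "MaxAscent3",
    "MaxDescent3",
)

TRAJECTORY_FEATURE_NAMES = ("TotalTrackLength", "NetDisplacement", "TrajectoryArea")

PROFILE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{feat}_{summ}" for feat in FRAME_FEATURE_NAMES for summ in SUMMARY_NAMES
) + TRAJECTORY_FEATURE_NAMES

PROFILE_FEATURE_CATEGORIES: dict[str, str] = {
    **{
        f"{feat}_{summ}": FRAME_FEATURE_CATEGORIES[feat]
        for feat in FRAME_FEATURE_NAMES
        for summ in SUMMARY_NAMES
    },
    **{name: "movement" for name in TRAJECTORY_FEATURE_NAMES},
}

assert len(PROFILE_FEATURE_NAMES) == 1083


def _haar_step(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One orthonormal Haar analysis step; odd lengths are right-padded by
    repeating the final value before pairing."""
    if len(x) % 2:
        x = np.append(x, x[-1])
    pairs = x.reshape(-1, 2)
    approx = (pairs[:, 0] + pairs[:, 1]) / math.sqrt(2)
    detail = (pairs[:, 1] - pairs[:, 0]) / math.sqrt(2)
    return approx, detail


def haar_details(series: np.ndarray, level: int) -> np.ndarray:
    """Detail coefficients of the orthonormal Haar transform at one level.

    Level 1 maps the pair (x1, x2) to (x2 - x1)/sqrt(2); deeper levels act on
    the running approximation coefficients (x1 + x2)/sqrt(2).
    """
    if level not in (1, 2, 3):
        raise ParameterError(f"Haar level must be 1, 2 or 3, got {level}")
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ParameterError(
            f"series of length {len(x)} too short for Haar level {level}"
        )
    approx = x
    detail = np.zeros(0)
    for _ in range(level):
        approx, detail = _haar_step(approx)
    return detail


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def _skew(x: np.ndarray) -> float:
    m = x.mean()
    s2 = np.mean((x - m) ** 2)
    if s2 <= 0:
        return 0.0
    return float(np.mean((x - m) ** 3) / s2**1.5)


def _excess_kurtosis(x: np.ndarray) -> float:
    m = x.mean()
    s2 = np.mean((x - m) ** 2)
    if s2 <= 0:
        return 0.0
    return float(np.mean((x - m) ** 4) / s2**2 - 3.0)


def summarise_series(series: np.ndarray) -> dict[str, float]:
    """The 15 summary statistics of one feature's time series."""
    x = np.asarray(series, dtype=float)
    if len(x) < 8:
        raise ParameterError(f"series of length {len(x)} below the minimum of 8")
    out = {
        "Mean": float(x.mean()),
        "Median": float(np.median(x)),
        "SD": _sample_sd(x),
        "Skewness": _skew(x),
        "Kurtosis": _excess_kurtosis(x),
        "Max": float(x.max()),
    }
    for level in (1, 2, 3):
        d = haar_details(x, level)
        out[f"DetailEnergy{level}"] = float((d**2).sum())
        out[f"MaxAscent{level}"] = float(max(0.0, d.max()))
        out[f"MaxDescent{level}"] = float(max(0.0, -d.min()))
    return out


def trajectory_features(centroids: np.ndarray) -> dict[str, float]:
    """Track length, net displacement and convex hull area of a centroid path."""
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ParameterError("trajectory features need at least 2 (x, y) points")
    steps = np.diff(pts, axis=0)
    length = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    displacement = float(math.dist(pts[0], pts[-1]))
    try:
        area = float(ConvexHull(pts).volume)  # 2-D "volume" = area
    except QhullError:
        area = 0.0  # collinear or repeated points
    return {
        "TotalTrackLength": length,
        "NetDisplacement": displacement,
        "TrajectoryArea": area,
    }


def _split_segments(frames: list[int], max_gap: int) -> list[list[int]]:
    """Indices into the record list, split where the frame gap exceeds max_gap."""
    segments = [[0]]
    for i in range(1, len(frames)):
        if frames[i] - frames[i - 1] - 1 > max_gap:
            segments.append([i])
        else:
            segments[-1].append(i)
    return segments


def _interpolate_to_contiguous(
    frames: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """Resample values observed at (possibly gapped) frames onto the full
    contiguous frame range by linear interpolation."""
    full = np.arange(frames[0], frames[-1] + 1)
    if len(full) == len(frames):
        return values
    if values.ndim == 1:
        return np.interp(full, frames, values)
    return np.column_stack(
        [np.interp(full, frames, values[:, j]) for j in range(values.shape[1])]
    )


def summarise_trajectory(
    trajectory: Trajectory,
    frame_vectors: np.ndarray,
    class_label: str | None = None,
    min_track_length: int = DEFAULT_MIN_TRACK_LENGTH,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[CellProfile]:
    """Summarise one trajectory into zero or more 1083-feature profiles.

    ``frame_vectors`` holds the 72 per-frame features (one row per trajectory
    record, registry order). Gaps up to ``max_gap`` frames are linearly
    interpolated; longer gaps split the trajectory, and every resulting
    segment shorter than ``min_track_length`` is excluded with a logged
    reason. Split segments get track ids ``track_id * 1000 + segment``.
    """
    frame_vectors = np.asarray(frame_vectors, dtype=float)
    if frame_vectors.shape != (len(trajectory), len(FRAME_FEATURE_NAMES)):
        raise ParameterError(
            f"frame_vectors shape {frame_vectors.shape} does not match "
            f"trajectory length {len(trajectory)}"
        )
    segments = _split_segments(trajectory.frames, max_gap)
    profiles = []
    for seg_idx, seg in enumerate(segments):
        frames = np.array([trajectory.frames[i] for i in seg])
        n_contiguous = frames[-1] - frames[0] + 1
        if n_contiguous < min_track_length:
            logger.info(
                "track %d segment %d excluded: %d frames < minimum %d",
                trajectory.track_id,
                seg_idx,
                n_contiguous,
                min_track_length,
            )
            continue
        vectors = _interpolate_to_contiguous(frames, frame_vectors[seg])
        centroids = _interpolate_to_contiguous(
            frames,
            np.column_stack(
                [
                    [trajectory.xs[i] for i in seg],
                    [trajectory.ys[i] for i in seg],
                ]
            ),
        )
        values = []
        for j in range(len(FRAME_FEATURE_NAMES)):
            summary = summarise_series(vectors[:, j])
            values.extend(summary[name] for name in SUMMARY_NAMES)
        values.extend(trajectory_features(centroids).values())
        tid = (
            trajectory.track_id
            if len(segments) == 1
            else trajectory.track_id * 1000 + seg_idx
        )
        profiles.append(CellProfile(tid, np.array(values), class_label))
    return profiles


def build_profiles(
    trajectories: list[Trajectory],
    frame_table: pd.DataFrame,
    truth: dict[int, str] | None = None,
    min_track_length: int = DEFAULT_MIN_TRACK_LENGTH,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[CellProfile]:
    """Profiles for every qualifying trajectory.

    ``frame_table`` is the long-format per-frame feature table (columns
    ``frame``, ``track_id`` and the 72 registry features). ``truth`` maps
    track ids to class labels when known.
    """
    indexed = frame_table.set_index(["track_id", "frame"])
    feature_cols = list(FRAME_FEATURE_NAMES)
    profiles = []
    for traj in trajectories:
        rows = indexed.loc[
            [(traj.track_id, f) for f in traj.frames], feature_cols
        ].to_numpy(dtype=float)
        label = truth.get(traj.track_id) if truth else None
        profiles.extend(
            summarise_trajectory(
                traj, rows, label, min_track_length=min_track_length, max_gap=max_gap
            )
        )
    return profiles
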