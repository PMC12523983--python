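"""Per-frame single-cell features.

Each cell instance (one cell on one frame) is measured by a fixed registry of
72 features in five categories:

* size (8): pixel-count area, boundary-edge perimeter, convex hull measures,
  bounding box, equivalent diameter and moment-ellipse axis lengths.
* shape (12): dimensionless descriptors (circularity, aspect ratio,
  eccentricity, solidity, extent, convexity), radial distribution statistics
  of boundary-pixel distances to the centroid, and turning-angle curvature
  statistics along the traced outline.
* texture (48): first-order intensity statistics and grey-level co-occurrence
  (GLCM) statistics, each computed at three spatial scales (original, 2x and
  4x block-mean downsampled), 16 values per scale.
* movement (1): displacement of the centroid from the previous frame.
* density (3): neighbour count within a radius, nearest-neighbour distance
  and an inverse-distance local density.

Conventions that matter for reproducibility:

* Perimeter counts unit pixel edges between foreground and background, so a
  filled ``n``x``n`` square has perimeter ``4n``.
* GLCM uses 16 grey levels quantised per cell by min-max (making the texture
  statistics invariant to positive affine intensity rescaling), distance 1,
  four symmetric offsets (0, 45, 90, 135 degrees) whose per-offset
  probability matrices are averaged with equal weight.
* Zero-variance conventions: skewness and excess kurtosis of constant data
  are 0; GLCM correlation with zero marginal variance is 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy import ndimage
from skimage import measure
from skimage.morphology import convex_hull_image

from .errors import ParameterError

logger = logging.getLogger(__name__)

REGISTRY_VERSION = "1.0"

GLCM_LEVELS = 16
GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))  # 0, 45, 90, 135 degrees
TEXTURE_SCALES = (1, 2, 4)

_FIRST_ORDER_NAMES = (
    "IntensityMean",
    "IntensitySD",
    "IntensitySkewness",
    "IntensityKurtosis",
    "IntensityRange",
    "IntensityEntropy",
)
_GLCM_NAMES = (
    "ASM",
    "Contrast",
    "Correlation",
    "GLCMVariance",
    "Homogeneity",
    "SumAverage",
    "SumEntropy",
    "GLCMEntropy",
    "Dissimilarity",
    "SumVariance",
)

SIZE_NAMES = (
    "Area",
    "Perimeter",
    "ConvexArea",
    "ConvexPerimeter",
    "BoundingBoxArea",
    "EquivalentDiameter",
    "MajorAxisLength",
    "MinorAxisLength",
)
SHAPE_NAMES = (
    "Circularity",
    "AspectRatio",
    "Eccentricity",
    "Solidity",
    "Extent",
    "Convexity",
    "RadiusSD",
    "RadiusSkewness",
    "RadiusKurtosis",
    "RadiusMinMaxRatio",
    "CurvatureMean",
    "CurvatureSD",
)
TEXTURE_NAMES = tuple(
    f"{base}_s{scale}"
    for scale in TEXTURE_SCALES
    for base in _FIRST_ORDER_NAMES + _GLCM_NAMES
)
MOVEMENT_NAMES = ("DisplacementFromPrev",)
DENSITY_NAMES = ("NeighbourCount", "NearestNeighbourDistance", "LocalDensity")


@dataclass(frozen=True)
class FeatureDef:
    name: str
    category: str  # size | shape | texture | movement | density


def _build_registry() -> tuple[FeatureDef, ...]:
    defs = []
    defs += [FeatureDef(n, "size") for n in SIZE_NAMES]
    defs += [FeatureDef(n, "shape") for n in SHAPE_NAMES]
    defs += [FeatureDef(n, "texture") for n in TEXTURE_NAMES]
    defs += [FeatureDef(n, "movement") for n in MOVEMENT_NAMES]
    defs += [FeatureDef(n, "density") for n in DENSITY_NAMES]
    counts = {}
    for d in defs:
        counts[d.category] = counts.get(d.category, 0) + 1
    assert counts == {"size": 8, "shape": 12, "texture": 48, "movement": 1, "density": 3}
    assert len(defs) == 72 and len({d.name for d in defs}) == 72
    return tuple(defs)


REGISTRY: tuple[FeatureDef, ...] = _build_registry()
FRAME_FEATURE_NAMES: tuple[str, ...] = tuple(d.name for d in REGISTRY)
FRAME_FEATURE_CATEGORIES: dict[str, str] = {d.name: d.category for d in REGISTRY}


@dataclass
class CellInstance:
    """One cell on one frame: cropped binary mask plus intensity patch.

    ``offset`` is the (row, col) of the crop's top-left pixel in the full
    frame; ``centroid`` is (x, y) in full-frame pixel coordinates (x = column).
    """

    mask: np.ndarray
    intensity: np.ndarray
    offset: tuple[int, int]
    centroid: tuple[float, float]
    frame_index: int
    touches_border: bool = False

    @classmethod
    def from_label(
        cls,
        intensity_frame: np.ndarray,
        label_frame: np.ndarray,
        label: int,
        frame_index: int,
    ) -> "CellInstance":
        mask_full = label_frame == label
        if not mask_full.any():
            raise ParameterError(f"label {label} absent from frame {frame_index}")
        labelled, n = ndimage.label(mask_full, structure=np.ones((3, 3), dtype=int))
        if n > 1:
            sizes = ndimage.sum_labels(mask_full, labelled, index=np.arange(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            mask_full = labelled == keep
            logger.warning(
                "label %d on frame %d is disconnected; keeping largest component",
                label,
                frame_index,
            )
        rows, cols = np.nonzero(mask_full)
        r0, r1 = rows.min(), rows.max()
        c0, c1 = cols.min(), cols.max()
        h, w = label_frame.shape
        touches = r0 == 0 or c0 == 0 or r1 == h - 1 or c1 == w - 1
        mask = mask_full[r0 : r1 + 1, c0 : c1 + 1]
        patch = np.asarray(intensity_frame[r0 : r1 + 1, c0 : c1 + 1], dtype=float)
        centroid = (float(cols.mean()), float(rows.mean()))
        return cls(mask, patch, (int(r0), int(c0)), centroid, frame_index, touches)


@dataclass
class FrameContext:
    """Context needed for movement and density features of one instance."""

    other_centroids: list[tuple[float, float]] = field(default_factory=list)
    prev_centroid: tuple[float, float] | None = None
    image_diagonal: float = 1.0
    density_radius: float = 100.0


# ---------------------------------------------------------------------------
# size & shape


def _safe_skew(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    m = x.mean()
    s2 = np.mean((x - m) ** 2)
    if s2 <= 0:
        return 0.0
    return float(np.mean((x - m) ** 3) / s2**1.5)


def _safe_excess_kurtosis(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    m = x.mean()
    s2 = np.mean((x - m) ** 2)
    if s2 <= 0:
        return 0.0
    return float(np.mean((x - m) ** 4) / s2**2 - 3.0)


def _perimeter_edges(mask: np.ndarray) -> int:
    """Count unit edges between foreground and background (image border counts
    as background)."""
    padded = np.pad(mask, 1)
    fg = int(mask.sum())
    horiz = int(np.count_nonzero(padded[:, 1:] & padded[:, :-1]))
    vert = int(np.count_nonzero(padded[1:, :] & padded[:-1, :]))
    return 4 * fg - 2 * (horiz + vert)


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    padded = np.pad(mask, 1)
    interior = (
        padded[1:-1, 2:] & padded[1:-1, :-2] & padded[2:, 1:-1] & padded[:-2, 1:-1]
    )
    boundary = mask & ~interior
    return np.column_stack(np.nonzero(boundary))  # (row, col)


def _turning_angles(mask: np.ndarray) -> np.ndarray:
    """Absolute turning angles (radians) along the traced outer boundary."""
    contours = measure.find_contours(np.pad(mask, 1).astype(float), 0.5)
    if not contours:
        return np.zeros(0)
    contour = max(contours, key=len)
    pts = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
    n = len(pts)
    if n < 3:
        return np.zeros(0)
    prev = np.roll(pts, 1, axis=0)
    nxt = np.roll(pts, -1, axis=0)
    v1 = pts - prev
    v2 = nxt - pts
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = (v1 * v2).sum(axis=1)
    return np.abs(np.arctan2(cross, dot))


def size_shape_features(instance: CellInstance) -> dict[str, float]:
    """The 8 size and 12 shape features; see module docstring for conventions."""
    mask = instance.mask.astype(bool)
    if not mask.any():
        raise ParameterError("empty mask")
    area = float(mask.sum())
    perimeter = float(_perimeter_edges(mask))
    rows, cols = np.nonzero(mask)
    bbox_area = float((rows.max() - rows.min() + 1) * (cols.max() - cols.min() + 1))

    # convex hull of pixel centres; degenerate hulls (collinear / < 3 pixels)
    # fall back to the pixel measures themselves
    pts = np.column_stack([cols, rows]).astype(float)
    try:
        hull = ConvexHull(pts)
        convex_perimeter = float(hull.area)  # 2-D "area" attribute = perimeter
        convex_area = float(convex_hull_image(mask).sum())
    except QhullError:
        convex_perimeter = perimeter
        convex_area = area

    equiv_diam = 2.0 * math.sqrt(area / math.pi)

    rc = float(rows.mean())
    cc = float(cols.mean())
    dr = rows - rc
    dc = cols - cc
    cov = np.array(
        [[np.mean(dc * dc), np.mean(dc * dr)], [np.mean(dc * dr), np.mean(dr * dr)]]
    )
    lam = np.linalg.eigvalsh(cov)
    lam2, lam1 = float(max(lam[0], 0.0)), float(max(lam[1], 0.0))
    major = 4.0 * math.sqrt(lam1)
    minor = 4.0 * math.sqrt(lam2)
    if minor > 0:
        aspect = major / minor
    else:
        aspect = 1.0 if major == 0 else float("inf")
    eccentricity = math.sqrt(1.0 - lam2 / lam1) if lam1 > 0 else 0.0

    bpix = _boundary_pixels(mask)
    radii = np.hypot(bpix[:, 0] - rc, bpix[:, 1] - cc)
    rmax = float(radii.max())
    radius_minmax = float(radii.min()) / rmax if rmax > 0 else 1.0

    angles = _turning_angles(mask)
    curv_mean = float(angles.mean()) if angles.size else 0.0
    curv_sd = float(angles.std()) if angles.size else 0.0

    return {
        "Area": area,
        "Perimeter": perimeter,
        "ConvexArea": convex_area,
        "ConvexPerimeter": convex_perimeter,
        "BoundingBoxArea": bbox_area,
        "EquivalentDiameter": equiv_diam,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "Circularity": 4.0 * math.pi * area / perimeter**2,
        "AspectRatio": aspect,
        "Eccentricity": eccentricity,
        "Solidity": area / convex_area,
        "Extent": area / bbox_area,
        "Convexity": convex_perimeter / perimeter,
        "RadiusSD": float(radii.std()),
        "RadiusSkewness": _safe_skew(radii),
        "RadiusKurtosis": _safe_excess_kurtosis(radii),
        "RadiusMinMaxRatio": radius_minmax,
        "CurvatureMean": curv_mean,
        "CurvatureSD": curv_sd,
    }


# ---------------------------------------------------------------------------
# texture


def _block_downsample(
    mask: np.ndarray, patch: np.ndarray, b: int
) -> tuple[np.ndarray, np.ndarray]:
    """Block-mean downsample of the masked patch.

    A block is kept where at least half its pixels are foreground; its value
    is the mean intensity over the block's foreground pixels.
    """
    h, w = mask.shape
    ph = (-h) % b
    pw = (-w) % b
    m = np.pad(mask, ((0, ph), (0, pw)))
    p = np.pad(patch, ((0, ph), (0, pw)))
    H, W = m.shape
    mb = m.reshape(H // b, b, W // b, b)
    pb = p.reshape(H // b, b, W // b, b)
    counts = mb.sum(axis=(1, 3))
    sums = (pb * mb).sum(axis=(1, 3))
    keep = counts * 2 >= b * b
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return keep, values


def _quantise(values: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    vmin = values.min()
    vrange = values.max() - vmin
    if vrange <= 0:
        return np.zeros(values.shape, dtype=np.intp)
    q = np.floor((values - vmin) / vrange * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def cooccurrence_matrix(
    mask: np.ndarray, values: np.ndarray, levels: int = GLCM_LEVELS
) -> np.ndarray | None:
    """Equal-weight average of per-offset symmetric GLCM probability matrices.

    Both pixels of a pair must be inside the mask. Returns ``None`` when no
    offset yields a valid pair.
    """
    level_img = np.full(mask.shape, -1, dtype=np.intp)
    level_img[mask] = _quantise(values[mask], levels)
    mats = []
    for dr, dc in GLCM_OFFSETS:
        h, w = level_img.shape
        r0a, r1a = max(0, -dr), min(h, h - dr)
        c0a, c1a = max(0, -dc), min(w, w - dc)
        a = level_img[r0a:r1a, c0a:c1a]
        bimg = level_img[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
        valid = (a >= 0) & (bimg >= 0)
        if not valid.any():
            continue
        i = a[valid]
        j = bimg[valid]
        counts = np.zeros((levels, levels))
        np.add.at(counts, (i, j), 1.0)
        np.add.at(counts, (j, i), 1.0)
        mats.append(counts / counts.sum())
    if not mats:
        return None
    return np.mean(mats, axis=0)


def _glcm_stats(P: np.ndarray) -> dict[str, float]:
    levels = P.shape[0]
    idx = np.arange(levels, dtype=float)
    I, J = np.meshgrid(idx, idx, indexing="ij")
    px = P.sum(axis=1)  # symmetric: px == py
    mu = float((idx * px).sum())
    var = float(((idx - mu) ** 2 * px).sum())
    nz = P > 0
    entropy = float(-(P[nz] * np.log2(P[nz])).sum())
    if var > 0:
        corr = float((P * (I - mu) * (J - mu)).sum() / var)
    else:
        corr = 0.0
    # i+j marginal
    k = np.arange(2 * levels - 1, dtype=float)
    psum = np.zeros(2 * levels - 1)
    np.add.at(psum, (I + J).astype(np.intp).ravel(), P.ravel())
    sum_avg = float((k * psum).sum())
    pnz = psum > 0
    sum_entropy = float(-(psum[pnz] * np.log2(psum[pnz])).sum())
    sum_var = float(((k - sum_avg) ** 2 * psum).sum())
    return {
        "ASM": float((P**2).sum()),
        "Contrast": float((P * (I - J) ** 2).sum()),
        "Correlation": corr,
        "GLCMVariance": float((P * (I - mu) ** 2).sum()),
        "Homogeneity": float((P / (1.0 + (I - J) ** 2)).sum()),
        "SumAverage": sum_avg,
        "SumEntropy": sum_entropy,
        "GLCMEntropy": entropy,
        "Dissimilarity": float((P * np.abs(I - J)).sum()),
        "SumVariance": sum_var,
    }


def _first_order(values: np.ndarray) -> dict[str, float]:
    vmin = float(values.min())
    vmax = float(values.max())
    hist, _ = np.histogram(values, bins=16, range=(vmin, vmax) if vmax > vmin else (vmin, vmin + 1))
    p = hist / hist.sum()
    pnz = p[p > 0]
    return {
        "IntensityMean": float(values.mean()),
        "IntensitySD": float(values.std()),
        "IntensitySkewness": _safe_skew(values),
        "IntensityKurtosis": _safe_excess_kurtosis(values),
        "IntensityRange": vmax - vmin,
        "IntensityEntropy": float(-(pnz * np.log2(pnz)).sum()),
    }


def texture_features(instance: CellInstance) -> dict[str, float]:
    """48 texture features: 16 statistics at each of three spatial scales.

    Scales with no surviving foreground after downsampling report zeros; a
    scale with pixels but no valid co-occurrence pair reports the single-state
    convention (ASM 1, all other GLCM statistics 0).
    """
    mask = instance.mask.astype(bool)
    if mask.sum() < 4:
        raise ParameterError("texture features need at least 4 interior pixels")
    # crop to the mask's bounding box so the downsampling block grid is
    # anchored to the cell, making multi-scale texture translation-invariant
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    mask = mask[r0:r1, c0:c1]
    patch = instance.intensity[r0:r1, c0:c1]
    out: dict[str, float] = {}
    for scale in TEXTURE_SCALES:
        if scale == 1:
            m, v = mask, patch
        else:
            m, v = _block_downsample(mask, patch, scale)
        suffix = f"_s{scale}"
        if not m.any():
            for base in _FIRST_ORDER_NAMES + _GLCM_NAMES:
                out[base + suffix] = 0.0
            continue
        vals = np.asarray(v, dtype=float)[m]
        for base, val in _first_order(vals).items():
            out[base + suffix] = val
        P = cooccurrence_matrix(m, np.asarray(v, dtype=float))
        if P is None:
            stats = {name: 0.0 for name in _GLCM_NAMES}
            stats["ASM"] = 1.0
        else:
            stats = _glcm_stats(P)
        for base, val in stats.items():
            out[base + suffix] = val
    return out


# ---------------------------------------------------------------------------
# movement & density


def movement_density_features(
    instance: CellInstance, context: FrameContext
) -> dict[str, float]:
    """Displacement from the previous frame plus three crowding measures."""
    if context.prev_centroid is None:
        displacement = 0.0
    else:
        displacement = math.dist(instance.centroid, context.prev_centroid)
    others = context.other_centroids
    if others:
        d = np.hypot(
            np.array([c[0] for c in others]) - instance.centroid[0],
            np.array([c[1] for c in others]) - instance.centroid[1],
        )
        neighbour_count = float(np.count_nonzero(d <= context.density_radius))
        nearest = float(d.min())
        local_density = float((1.0 / np.maximum(d, 1.0)).sum())
    else:
        neighbour_count = 0.0
        nearest = context.image_diagonal
        local_density = 0.0
    return {
        "DisplacementFromPrev": displacement,
        "NeighbourCount": neighbour_count,
        "NearestNeighbourDistance": nearest,
        "LocalDensity": local_density,
    }


def extract_frame_features(
    instance: CellInstance,
    context: FrameContext,
    registry: tuple[FeatureDef, ...] = REGISTRY,
) -> np.ndarray:
    """All 72 per-frame features as a vector in registry order."""
    values = {}
    values.update(size_shape_features(instance))
    values.update(texture_features(instance))
    values.update(movement_density_features(instance, context))
    return np.array([values[d.name] for d in registry], dtype=float)


def _frame_label_centroids(label_frame: np.ndarray) -> dict[int, tuple[float, float]]:
    rows, cols = np.nonzero(label_frame)
    labs = label_frame[rows, cols]
    if labs.size == 0:
        return {}
    counts = np.bincount(labs)
    row_sums = np.bincount(labs, weights=rows)
    col_sums = np.bincount(labs, weights=cols)
    return {
        int(lbl): (col_sums[lbl] / counts[lbl], row_sums[lbl] / counts[lbl])
        for lbl in np.nonzero(counts)[0]
    }


def extract_frame_table(movie, trajectories, density_radius: float = 100.0):
    """Long-format per-frame feature table for a set of linked trajectories.

    Columns: ``frame``, ``track_id`` followed by the 72 registry features.
    Density features see every labelled cell in the frame, tracked or not;
    displacement uses the previous record of the same trajectory.
    """
    import pandas as pd

    centroids_by_frame = [
        _frame_label_centroids(movie.labels[t]) for t in range(movie.n_frames)
    ]
    diagonal = movie.diagonal
    records = []
    for traj in trajectories:
        prev: tuple[float, float] | None = None
        for frame, label in zip(traj.frames, traj.labels):
            instance = CellInstance.from_label(
                movie.intensity[frame], movie.labels[frame], label, frame
            )
            others = [
                c for lbl, c in centroids_by_frame[frame].items() if lbl != label
            ]
            context = FrameContext(
                other_centroids=others,
                prev_centroid=prev,
                image_diagonal=diagonal,
                density_radius=density_radius,
            )
            vector = extract_frame_features(instance, context)
            records.append((frame, traj.track_id, *vector))
            prev = instance.centroid
    return pd.DataFrame(
        records, columns=["frame", "track_id", *FRAME_FEATURE_NAMES]
    )
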