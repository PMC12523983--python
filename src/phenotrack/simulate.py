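"""Synthetic class-structured time-lapse movies.

Cells are rotated ellipses performing isotropic Gaussian random walks on a
constant background. Classes differ controllably in area, elongation,
interior texture noise, motility step size and (via per-class seeding
spread) local density — the axes along which real cell lines differ in
label-free imaging. The simulator emits exactly the artefacts the reader
side consumes: an intensity stack, a label stack, a tracking table and a
track-to-class truth map, so the whole pipeline is testable end to end
without any external data.

Randomness protocol: one master seed; each cell draws from its own
substream derived from (seed, cell index), so identical seeds give
bit-identical movies and adding cells does not reshuffle the draws of
existing ones. Cells reflect off the image borders and never overlap (steps
that would collide are re-drawn, keeping every centroid inside its own
label region).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import CapacityError, ParameterError
from .io import LabelledMovie

_MAX_ATTEMPTS = 100


@dataclass
class ClassSpec:
    """Parameters of one simulated cell class."""

    name: str
    n_cells: int = 10
    mean_area: float = 500.0  # px^2
    area_sd: float = 50.0
    aspect_ratio: float = 1.5  # major/minor, >= 1
    texture_sd: float = 5.0  # intensity noise inside the cell
    step_sd: float = 2.0  # random-walk step SD, px/frame
    seed_spread: float | None = None  # Gaussian seeding spread; None = uniform


@dataclass
class PopulationSpec:
    """A multi-class population plus the global movie geometry."""

    classes: list[ClassSpec] = field(default_factory=list)
    n_frames: int = 32
    height: int = 512
    width: int = 512
    base_intensity: float = 100.0
    background_intensity: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if not self.classes:
            raise ParameterError("population needs at least one class")
        if self.n_frames < 8:
            raise ParameterError("n_frames must be at least 8")
        for cls in self.classes:
            if cls.n_cells < 1:
                raise ParameterError(f"class {cls.name}: n_cells must be positive")
            if cls.aspect_ratio < 1:
                raise ParameterError(f"class {cls.name}: aspect_ratio must be >= 1")
            if cls.mean_area <= 0:
                raise ParameterError(f"class {cls.name}: mean_area must be positive")


@dataclass
class _Cell:
    track_id: int
    class_name: str
    a: float  # major semi-axis
    b: float  # minor semi-axis
    theta: float
    step_sd: float
    texture_sd: float
    rng: np.random.Generator
    pos: np.ndarray | None = None  # (x, y)


def _cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(cell_index,))
    )


def _reflect(v: float, lo: float, hi: float) -> float:
    """Reflect a scalar into [lo, hi] (triangle-wave folding)."""
    if hi <= lo:
        return lo
    if lo <= v <= hi:  # exact no-op inside the domain (zero-step walks stay put)
        return v
    span = hi - lo
    t = (v - lo) % (2 * span)
    return lo + (span - abs(t - span))


def _collides(pos: np.ndarray, radius: float, others: list[_Cell]) -> bool:
    for other in others:
        if other.pos is None:
            continue
        if float(np.hypot(*(pos - other.pos))) < radius + other.a + 1.0:
            return True
    return False


def _rasterise(cell: _Cell, height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel (rows, cols) whose centres satisfy the ellipse inequality."""
    cx, cy = cell.pos
    r = int(math.ceil(cell.a)) + 1
    r0 = max(0, int(cy) - r)
    r1 = min(height - 1, int(cy) + r)
    c0 = max(0, int(cx) - r)
    c1 = min(width - 1, int(cx) + r)
    rows, cols = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    dx = cols - cx
    dy = rows - cy
    ct, st = math.cos(cell.theta), math.sin(cell.theta)
    u = (dx * ct + dy * st) / cell.a
    v = (-dx * st + dy * ct) / cell.b
    inside = u**2 + v**2 <= 1.0
    return rows[inside], cols[inside]


def simulate_population(
    spec: PopulationSpec,
) -> tuple[LabelledMovie, pd.DataFrame, dict[int, str]]:
    """Simulate a movie; returns (movie, track table, track_id -> class)."""
    spec.validate()
    cells: list[_Cell] = []
    idx = 0
    for cls in spec.classes:
        for _ in range(cls.n_cells):
            rng = _cell_rng(spec.seed, idx)
            area = max(16.0, rng.normal(cls.mean_area, cls.area_sd))
            b = math.sqrt(area / (math.pi * cls.aspect_ratio))
            a = cls.aspect_ratio * b
            theta = rng.uniform(0.0, math.pi)
            cells.append(
                _Cell(
                    track_id=idx + 1,
                    class_name=cls.name,
                    a=a,
                    b=b,
                    theta=theta,
                    step_sd=cls.step_sd,
                    texture_sd=cls.texture_sd,
                    rng=rng,
                )
            )
            idx += 1

    h, w = spec.height, spec.width
    # per-class seeding centres (for density-structured classes) come from a
    # dedicated stream so they do not disturb per-cell substreams
    centre_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(10**6,))
    )
    class_centres = {}
    for cls in spec.classes:
        if cls.seed_spread is not None:
            class_centres[cls.name] = np.array(
                [centre_rng.uniform(0.25 * w, 0.75 * w), centre_rng.uniform(0.25 * h, 0.75 * h)]
            )
    spread_by_class = {cls.name: cls.seed_spread for cls in spec.classes}

    # initial placement with rejection sampling on bounding-circle overlap
    for cell in cells:
        margin = cell.a + 1.0
        if 2 * margin >= min(h, w):
            raise CapacityError("image too small for a cell of this size")
        placed = False
        spread = spread_by_class[cell.class_name]
        for _ in range(_MAX_ATTEMPTS):
            if spread is None:
                pos = np.array(
                    [
                        cell.rng.uniform(margin, w - 1 - margin),
                        cell.rng.uniform(margin, h - 1 - margin),
                    ]
                )
            else:
                centre = class_centres[cell.class_name]
                raw = centre + cell.rng.normal(0.0, spread, 2)
                pos = np.array(
                    [
                        _reflect(raw[0], margin, w - 1 - margin),
                        _reflect(raw[1], margin, h - 1 - margin),
                    ]
                )
            if not _collides(pos, cell.a, [c for c in cells if c is not cell]):
                cell.pos = pos
                placed = True
                break
        if not placed:
            raise CapacityError(
                f"could not place cell {cell.track_id} after {_MAX_ATTEMPTS} attempts"
            )

    n_cells = len(cells)
    intensity = np.full((spec.n_frames, h, w), spec.background_intensity, dtype=np.float32)
    labels = np.zeros((spec.n_frames, h, w), dtype=np.uint16)
    rows_out: list[tuple[int, int, float, float]] = []

    for t in range(spec.n_frames):
        for i, cell in enumerate(cells):
            if t > 0:
                margin = cell.a + 1.0
                others = cells[:i] + cells[i + 1 :]
                for _ in range(_MAX_ATTEMPTS):
                    step = cell.rng.normal(0.0, cell.step_sd, 2)
                    proposal = np.array(
                        [
                            _reflect(cell.pos[0] + step[0], margin, w - 1 - margin),
                            _reflect(cell.pos[1] + step[1], margin, h - 1 - margin),
                        ]
                    )
                    if not _collides(proposal, cell.a, others):
                        cell.pos = proposal
                        break
                # all attempts collided: the cell stays put this frame
            # per-frame labels are an arbitrary (but deterministic) permutation
            # of cell indices so that track->mask linking is genuinely exercised
            label = (i + t) % n_cells + 1
            rr, cc = _rasterise(cell, h, w)
            labels[t, rr, cc] = label
            intensity[t, rr, cc] = spec.base_intensity + cell.rng.normal(
                0.0, cell.texture_sd, rr.shape[0]
            )
            rows_out.append((t, cell.track_id, float(cell.pos[0]), float(cell.pos[1])))

    tracks = pd.DataFrame(rows_out, columns=["frame", "track_id", "x", "y"])
    truth = {cell.track_id: cell.class_name for cell in cells}
    movie = LabelledMovie(intensity.astype(float), labels.astype(np.int64))
    return movie, tracks, truth


def two_class_motility_fixture(
    seed: int,
) -> tuple[LabelledMovie, pd.DataFrame, dict[int, str]]:
    """Two classes identical in every respect except motility.

    Class ``low`` walks with step SD 0.5 px/frame, class ``high`` with
    4.0 px/frame; 20 cells per class, 32 frames, 512x512. Any feature that
    separates the classes must therefore trace back to movement.
    """
    spec = PopulationSpec(
        classes=[
            ClassSpec(name="low", n_cells=20, step_sd=0.5),
            ClassSpec(name="high", n_cells=20, step_sd=4.0),
        ],
        n_frames=32,
        height=512,
        width=512,
        seed=seed,
    )
    return simulate_population(spec)


def write_simulation(
    out_dir: str | Path,
    movie: LabelledMovie,
    tracks: pd.DataFrame,
    truth: dict[int, str],
) -> dict[str, Path]:
    """Write a simulation in the formats the reader side consumes.

    The tracking table is written in the generic ``frame,cell,x,y`` dialect.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensity": out / "intensity.tif",
        "labels": out / "labels.tif",
        "tracks": out / "tracks.csv",
        "truth": out / "truth.csv",
    }
    tifffile.imwrite(paths["intensity"], movie.intensity.astype(np.float32))
    tifffile.imwrite(paths["labels"], movie.labels.astype(np.uint16))
    tracks.rename(columns={"track_id": "cell"})[["frame", "cell", "x", "y"]].to_csv(
        paths["tracks"], index=False
    )
    pd.DataFrame(
        {"track_id": list(truth), "class": list(truth.values())}
    ).to_csv(paths["truth"], index=False)
    return paths
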