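"""Stack segmentation, axis regression, and misalignment parameters.

After every slice has a fitted circle, the stack is split into segments of
mutually stable fits (radius change < 0.5% and centre change < 2 voxels per
axis between consecutive slices, runs shorter than 5 slices dropped). The
longest segment is taken as the object's main section; independent
least-squares lines of the circle centres x0(z) and y0(z) over that segment
give the object axis, from which the misalignment quadruple follows:

* ``t_x``, ``t_y`` — axis offset from the image-stack centre, evaluated at
  the stack's physical mid-plane (mm);
* ``rot_y = atan(slope_x)``, ``rot_x = atan(slope_y)`` — tilt of the axis out
  of the z-axis, in degrees.

Sign convention (shared with :mod:`corealign.rigid_transform`): positive
``rot_x`` tips the high-z end of the object toward +y (downward image rows),
positive ``rot_y`` tips it toward +x, so that applying the detected
parameters to a centred cylinder reproduces the detected axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import NoObjectError
from .image_model import VoxelGrid
from .slice_detection import CircleFit, EdgeSearchConfig, fit_slice

__all__ = [
    "SegmentationConfig",
    "Segment",
    "AxisFit",
    "AlignmentParams",
    "DetectionResult",
    "segment_stack",
    "select_longest",
    "fit_axis",
    "derive_params",
    "detect_misalignment",
    "fits_to_dataframe",
]


@dataclass(frozen=True)
class SegmentationConfig:
    max_radius_rel_change: float = 0.005
    max_centre_change_voxels: float = 2.0
    min_segment_images: int = 5

    def __post_init__(self) -> None:
        if not (self.max_radius_rel_change > 0 and self.max_centre_change_voxels > 0 and self.min_segment_images > 0):
            raise ValueError("all segmentation thresholds must be strictly positive")


@dataclass(frozen=True)
class Segment:
    """Half-open run of slices [start_slice, end_slice) with stable fits."""

    start_slice: int
    end_slice: int

    @property
    def length(self) -> int:
        return self.end_slice - self.start_slice


@dataclass(frozen=True)
class AxisFit:
    """Least-squares lines x0(z) and y0(z) over the chosen segment (z in mm)."""

    slope_x: float
    intercept_x: float
    slope_y: float
    intercept_y: float
    segment: Segment

    def x_at(self, z: float) -> float:
        return self.intercept_x + self.slope_x * z

    def y_at(self, z: float) -> float:
        return self.intercept_y + self.slope_y * z


@dataclass(frozen=True)
class AlignmentParams:
    """Misalignment quadruple: in-plane translation (mm) + tilt (degrees)."""

    t_x: float
    t_y: float
    rot_x: float
    rot_y: float

    def __post_init__(self) -> None:
        if not (abs(self.rot_x) < 90 and abs(self.rot_y) < 90):
            raise ValueError("rotations must satisfy |rot| < 90 degrees")

    @classmethod
    def zero(cls) -> "AlignmentParams":
        return cls(0.0, 0.0, 0.0, 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.t_x, self.t_y, self.rot_x, self.rot_y], dtype=float)

    def __sub__(self, other: "AlignmentParams") -> "AlignmentParams":
        return AlignmentParams(*(self.as_array() - other.as_array()))


def segment_stack(
    fits: Sequence[CircleFit],
    config: SegmentationConfig | None = None,
    spacing_xy: float = 1.0,
) -> list[Segment]:
    """Greedy single-pass segmentation of a slice-ordered fit sequence.

    A new segment starts at any invalid fit, or whenever between consecutive
    valid fits the relative radius change reaches ``max_radius_rel_change``
    or either centre coordinate moves by ``max_centre_change_voxels`` voxels
    or more (per-axis test, chained to the previous slice). Segments shorter
    than ``min_segment_images`` are discarded.
    """
    config = config or SegmentationConfig()
    tol_c = config.max_centre_change_voxels * spacing_xy
    segments: list[Segment] = []
    start: int | None = None
    prev: CircleFit | None = None

    def close(end_index: int) -> None:
        nonlocal start
        if start is not None and end_index - start >= config.min_segment_images:
            segments.append(Segment(start, end_index))
        start = None

    for i, fit in enumerate(fits):
        if not fit.valid:
            close(i)
            prev = None
            continue
        if prev is not None:
            breaks = (
                abs(fit.r - prev.r) / abs(prev.r) >= config.max_radius_rel_change
                or abs(fit.x0 - prev.x0) >= tol_c
                or abs(fit.y0 - prev.y0) >= tol_c
            )
            if breaks:
                close(i)
        if start is None:
            start = i
        prev = fit
    close(len(fits))
    return segments


def select_longest(segments: Sequence[Segment]) -> Segment:
    """Longest segment; ties break to the smallest start slice."""
    if not segments:
        raise NoObjectError("no stable segment found: alignment correction impossible")
    return max(segments, key=lambda s: (s.length, -s.start_slice))


def fit_axis(fits: Sequence[CircleFit], segment: Segment, spacing_z: float, z_origin: float = 0.0) -> AxisFit:
    """Independent OLS of x0 and y0 against physical z over the segment."""
    sub = [fits[i] for i in range(segment.start_slice, segment.end_slice)]
    if len(sub) < 2:
        raise ValueError("axis regression needs at least 2 slices")
    z = np.array([z_origin + f.slice_index * spacing_z for f in sub])
    x0 = np.array([f.x0 for f in sub])
    y0 = np.array([f.y0 for f in sub])
    sx, ix = np.polyfit(z, x0, 1)
    sy, iy = np.polyfit(z, y0, 1)
    return AxisFit(float(sx), float(ix), float(sy), float(iy), segment)


def derive_params(axis: AxisFit, grid: VoxelGrid) -> AlignmentParams:
    """Misalignment quadruple from the fitted axis and the stack geometry.

    Translation is the axis offset from the image centre at the stack's
    physical mid-plane; rotations come from the axis slopes via atan.
    """
    xc, yc, zc = grid.centre
    return AlignmentParams(
        t_x=axis.x_at(zc) - xc,
        t_y=axis.y_at(zc) - yc,
        rot_x=math.degrees(math.atan(axis.slope_y)),
        rot_y=math.degrees(math.atan(axis.slope_x)),
    )


@dataclass
class DetectionResult:
    """Full output of the detection pipeline (steps 1-4)."""

    params: AlignmentParams
    fits: list[CircleFit]
    segments: list[Segment]
    chosen: Segment
    axis: AxisFit

    def to_json(self, path: str | Path) -> None:
        report = {
            "params": asdict(self.params),
            "chosen_segment": asdict(self.chosen),
            "axis": {
                "slope_x": self.axis.slope_x,
                "intercept_x": self.axis.intercept_x,
                "slope_y": self.axis.slope_y,
                "intercept_y": self.axis.intercept_y,
            },
            "n_segments": len(self.segments),
            "n_valid_fits": sum(f.valid for f in self.fits),
            "n_slices": len(self.fits),
        }
        Path(path).write_text(json.dumps(report, indent=2))


def fits_to_dataframe(fits: Sequence[CircleFit], segments: Sequence[Segment]) -> pd.DataFrame:
    """Per-slice fit table with the containing segment id (-1 when none)."""
    seg_id = np.full(len(fits), -1, dtype=int)
    for k, seg in enumerate(segments):
        seg_id[seg.start_slice : seg.end_slice] = k
    return pd.DataFrame(
        {
            "slice": [f.slice_index for f in fits],
            "x0_mm": [f.x0 for f in fits],
            "y0_mm": [f.y0 for f in fits],
            "r_mm": [f.r for f in fits],
            "valid": [bool(f.valid) for f in fits],
            "segment_id": seg_id,
        }
    )


def detect_misalignment(
    grid: VoxelGrid,
    edge_config: EdgeSearchConfig | None = None,
    seg_config: SegmentationConfig | None = None,
) -> DetectionResult:
    """Run detection steps 1-4 on a stack: fits, segments, axis, parameters."""
    fits = [fit_slice(grid, i, edge_config) for i in range(grid.nz)]
    segments = segment_stack(fits, seg_config, grid.spacing_xy)
    chosen = select_longest(segments)
    axis = fit_axis(fits, chosen, grid.spacing_z, grid.origin[2])
    params = derive_params(axis, grid)
    return DetectionResult(params, fits, segments, chosen, axis)
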