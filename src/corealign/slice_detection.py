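"""Per-slice detection of the cylindrical object.

Three boundary points are found on each axial slice by a 1D variance-split
edge search: the split index that minimises the (length-weighted) sum of the
grey-value variances of the two resulting sections. Two searches run along
the x-axis from either image border inward on the central row; a third runs
along the y-axis top-to-bottom on the central column — top-to-bottom so the
patient table, which sits below the object, never enters the search. The
unique circle through the three points gives the slice's object centre and
radius.

Each outside-in search is restricted to the half profile between the image
border and the central line, so exactly one air/object transition lies in the
searched window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DegenerateGeometryError, NoEdgeError
from .image_model import VoxelGrid

__all__ = [
    "EdgeSearchConfig",
    "CircleFit",
    "BoundaryTriple",
    "split_edge_index",
    "detect_boundary_points",
    "fit_circle",
    "fit_slice",
]


@dataclass(frozen=True)
class EdgeSearchConfig:
    """Variance-split objective and minimum section length.

    ``weighted_variance_sum`` (default) is the classical two-class
    within-variance criterion ``(s·Var_L + (n−s)·Var_R)/n``; ``unweighted``
    is the plain sum ``Var_L + Var_R``.
    """

    objective: Literal["weighted_variance_sum", "unweighted_variance_sum"] = "weighted_variance_sum"
    min_section_length: int = 2

    def __post_init__(self) -> None:
        if self.min_section_length < 2:
            raise ValueError("min_section_length must be >= 2")


@dataclass(frozen=True)
class CircleFit:
    """Detected object circle on one slice: centre (x0, y0) and radius r, mm."""

    x0: float
    y0: float
    r: float
    valid: bool
    slice_index: int

    @classmethod
    def invalid(cls, slice_index: int) -> "CircleFit":
        return cls(np.nan, np.nan, np.nan, False, slice_index)


@dataclass(frozen=True)
class BoundaryTriple:
    """Three boundary points (physical mm in the slice plane).

    ``a`` and ``b`` come from the opposed x-direction searches, ``c`` from the
    top-to-bottom y-direction search.
    """

    a: tuple[float, float]
    b: tuple[float, float]
    c: tuple[float, float]


def _section_objective(profile: np.ndarray, config: EdgeSearchConfig) -> np.ndarray:
    """Objective value for every admissible split index, vectorised.

    Returns an array over splits ``s`` in ``[m, n−m]``; variances are computed
    from prefix sums after centring the profile (the objective is invariant
    under adding a constant, and centring keeps the arithmetic well
    conditioned for |HU| ~ 1000).
    """
    x = profile - profile.mean()
    n = x.size
    m = config.min_section_length
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    s = np.arange(m, n - m + 1)
    nl = s.astype(float)
    nr = (n - s).astype(float)
    var_l = c2[s] / nl - (c1[s] / nl) ** 2
    var_r = (c2[n] - c2[s]) / nr - ((c1[n] - c1[s]) / nr) ** 2
    # guard tiny negative values from rounding
    var_l = np.maximum(var_l, 0.0)
    var_r = np.maximum(var_r, 0.0)
    if config.objective == "weighted_variance_sum":
        return (nl * var_l + nr * var_r) / n
    if config.objective == "unweighted_variance_sum":
        return var_l + var_r
    raise ValueError(f"unknown objective {config.objective!r}")


def split_edge_index(profile: np.ndarray, config: EdgeSearchConfig | None = None) -> int:
    """Split index minimising the two-section variance objective.

    The returned index ``s`` partitions the profile into ``[0, s)`` and
    ``[s, n)``; the edge is assigned to ``s`` itself, the first sample of the
    right section. Ties break to the smallest index. The search is an
    exhaustive scan over every admissible split, so the minimiser is exact by
    construction.
    """
    config = config or EdgeSearchConfig()
    profile = np.asarray(profile, dtype=np.float64)
    if profile.ndim != 1:
        raise ValueError("profile must be 1D")
    n = profile.size
    if n < 2 * config.min_section_length:
        raise ValueError(f"profile of length {n} too short for min_section_length={config.min_section_length}")
    if np.ptp(profile) == 0:
        raise NoEdgeError("constant profile: no edge present")
    obj = _section_objective(profile, config)
    return int(config.min_section_length + np.argmin(obj))


def detect_boundary_points(
    grid: VoxelGrid,
    slice_index: int,
    config: EdgeSearchConfig | None = None,
) -> BoundaryTriple:
    """Three object-boundary points on one slice, in physical mm.

    a: forward x search (left border → centre) on the central row;
    b: reverse x search (right border → centre), mapped back to forward
    coordinates; c: top-to-bottom y search on the central column.
    Raises :class:`NoEdgeError` if any search finds no edge.
    """
    config = config or EdgeSearchConfig()
    if not 0 <= slice_index < grid.nz:
        raise IndexError(f"slice {slice_index} out of range")
    cy = grid.ny // 2
    cx = grid.nx // 2
    row = np.asarray(grid.values[slice_index, cy, :], dtype=np.float64)
    col = np.asarray(grid.values[slice_index, :, cx], dtype=np.float64)

    # forward x: border -> central column (inclusive)
    a_col = split_edge_index(row[: cx + 1], config)
    # reverse x: opposite border -> central column; index j maps to column nx-1-j
    rev = row[cx:][::-1]
    b_col = grid.nx - 1 - split_edge_index(rev, config)
    # top-to-bottom y: top border -> central row
    c_row = split_edge_index(col[: cy + 1], config)

    y_mid = float(grid.y_mm(cy))
    return BoundaryTriple(
        a=(float(grid.x_mm(a_col)), y_mid),
        b=(float(grid.x_mm(b_col)), y_mid),
        c=(float(grid.x_mm(cx)), float(grid.y_mm(c_row))),
    )


def fit_circle(a, b, c) -> tuple[float, float, float]:
    """Unique circle through three points (perpendicular-bisector closed form).

    Returns ``(x0, y0, r)``. Raises :class:`DegenerateGeometryError` when the
    points are (near-)collinear: twice the triangle area below
    ``1e-9 ×`` the squared point span.
    """
    ax, ay = float(a[0]), float(a[1])
    bx, by = float(b[0]), float(b[1])
    cx, cy = float(c[0]), float(c[1])
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    span2 = max(
        (ax - bx) ** 2 + (ay - by) ** 2,
        (bx - cx) ** 2 + (by - cy) ** 2,
        (ax - cx) ** 2 + (ay - cy) ** 2,
    )
    if span2 == 0.0 or abs(d) < 1e-9 * span2:
        raise DegenerateGeometryError("boundary points are collinear or coincident")
    a2 = ax * ax + ay * ay
    b2 = bx * bx + by * by
    c2 = cx * cx + cy * cy
    x0 = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    y0 = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    r = float(np.hypot(ax - x0, ay - y0))
    return float(x0), float(y0), r


def fit_slice(grid: VoxelGrid, slice_index: int, config: EdgeSearchConfig | None = None) -> CircleFit:
    """Detect boundary points and fit the slice circle; never raises.

    Detection failures (no edge, degenerate geometry, implausible circle) are
    encoded as ``valid=False`` so stack-level processing can continue.
    """
    try:
        pts = detect_boundary_points(grid, slice_index, config)
        x0, y0, r = fit_circle(pts.a, pts.b, pts.c)
    except (NoEdgeError, DegenerateGeometryError):
        return CircleFit.invalid(slice_index)
    # plausibility: centre inside the slice's physical extent, positive radius
    x_lo, x_hi = float(grid.x_mm(0)), float(grid.x_mm(grid.nx - 1))
    y_lo, y_hi = float(grid.y_mm(0)), float(grid.y_mm(grid.ny - 1))
    if not (r > 0 and x_lo <= x0 <= x_hi and y_lo <= y0 <= y_hi):
        return CircleFit.invalid(slice_index)
    return CircleFit(x0, y0, r, True, slice_index)
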