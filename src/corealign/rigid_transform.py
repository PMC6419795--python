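"""Rigid misalignment application and correction by resampling.

The forward transform of an :class:`AlignmentParams` quadruple moves a point
``p`` to ``R (p - c) + c + t`` where ``c`` is the stack's physical centre,
``t = (t_x, t_y, 0)`` and ``R = R_y(rot_y) · R_x(rot_x)`` with the sign
convention of :mod:`corealign.axis_estimation` (positive ``rot_x`` tips the
high-z end toward +y, positive ``rot_y`` toward +x). Correction applies the
exact matrix inverse of that transform in a single resampling pass — never
two interpolations in a row.

Resampling goes through SimpleITK. Two exact short-circuits avoid
interpolation entirely: identity parameters return a copy, and pure
translations on the voxel lattice are applied as array shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import SimpleITK as sitk

from .axis_estimation import AlignmentParams
from .image_model import VoxelGrid, to_sitk

__all__ = [
    "ResampleConfig",
    "apply_misalignment",
    "correct_alignment",
    "invert_params",
    "rotation_matrix",
    "transform_point",
]


@dataclass(frozen=True)
class ResampleConfig:
    interpolation: Literal["linear", "nearest"] = "linear"
    fill_value: float = -1024.0
    rotation_centre: tuple[float, float, float] | None = None  # default: stack centre

    def __post_init__(self) -> None:
        if not np.isfinite(self.fill_value):
            raise ValueError("fill_value must be finite")


def rotation_matrix(params: AlignmentParams) -> np.ndarray:
    """R = R_y(rot_y) · R_x(rot_x) under the package's sign convention.

    Maps the unit z-axis to ``(cos(rx)·sin(ry), sin(rx), cos(rx)·cos(ry))``,
    i.e. axis slopes ``dx/dz = tan(rot_y)`` and ``dy/dz ≈ tan(rot_x)``.
    """
    ax = math.radians(params.rot_x)
    ay = math.radians(params.rot_y)
    rx = np.array(
        [[1, 0, 0], [0, math.cos(ax), math.sin(ax)], [0, -math.sin(ax), math.cos(ax)]]
    )
    ry = np.array(
        [[math.cos(ay), 0, math.sin(ay)], [0, 1, 0], [-math.sin(ay), 0, math.cos(ay)]]
    )
    return ry @ rx


def transform_point(p, params: AlignmentParams, centre) -> np.ndarray:
    """Apply the forward rigid transform to a physical point (mm)."""
    p = np.asarray(p, dtype=float)
    c = np.asarray(centre, dtype=float)
    t = np.array([params.t_x, params.t_y, 0.0])
    return rotation_matrix(params) @ (p - c) + c + t


def invert_params(params: AlignmentParams) -> AlignmentParams:
    """Small-angle inverse: componentwise negation.

    Exact for pure translations and pure single-axis rotations. For mixed
    parameters the quadruple family is not closed under inversion (the exact
    inverse carries a z-translation ~ sin(rot)·|t| and a z-rotation cross
    term), so the negation is an approximation with residuals of that order.
    :func:`correct_alignment` does not rely on this: it inverts the matrix
    transform exactly.
    """
    return AlignmentParams(-params.t_x, -params.t_y, -params.rot_x, -params.rot_y)


def _is_identity(params: AlignmentParams) -> bool:
    return params.t_x == params.t_y == params.rot_x == params.rot_y == 0.0


def _integer_shift_voxels(params: AlignmentParams, spacing_xy: float, sign: float, tol: float = 1e-9):
    """Lattice shift (kx, ky) if the motion is a pure in-plane integer-voxel
    translation, else None. ``sign`` is +1 for apply, -1 for correct."""
    if params.rot_x != 0.0 or params.rot_y != 0.0:
        return None
    kx = sign * params.t_x / spacing_xy
    ky = sign * params.t_y / spacing_xy
    if abs(kx - round(kx)) < tol and abs(ky - round(ky)) < tol:
        return int(round(kx)), int(round(ky))
    return None


def _shift_array(values: np.ndarray, kx: int, ky: int, fill: float) -> np.ndarray:
    """Shift content by (+kx columns, +ky rows), filling exposed voxels."""
    out = np.full_like(values, fill)
    nz, ny, nx = values.shape
    x_src = slice(max(0, -kx), min(nx, nx - kx))
    x_dst = slice(max(0, kx), min(nx, nx + kx))
    y_src = slice(max(0, -ky), min(ny, ny - ky))
    y_dst = slice(max(0, ky), min(ny, ny + ky))
    out[:, y_dst, x_dst] = values[:, y_src, x_src]
    return out


def _resample(grid: VoxelGrid, matrix: np.ndarray, translation: np.ndarray, centre, config: ResampleConfig) -> VoxelGrid:
    """Resample with the output→input map ``p ↦ matrix·(p − centre) + centre + translation``."""
    tfm = sitk.AffineTransform(3)
    tfm.SetMatrix(tuple(np.asarray(matrix, dtype=float).ravel()))
    tfm.SetCenter(tuple(float(v) for v in centre))
    tfm.SetTranslation(tuple(float(v) for v in translation))
    interp = sitk.sitkLinear if config.interpolation == "linear" else sitk.sitkNearestNeighbor
    img = to_sitk(grid)
    out = sitk.Resample(img, img, tfm, interp, float(config.fill_value), sitk.sitkFloat32)
    return VoxelGrid(sitk.GetArrayFromImage(out), grid.spacing_xy, grid.spacing_z, grid.origin)


def _centre(grid: VoxelGrid, config: ResampleConfig) -> np.ndarray:
    if config.rotation_centre is not None:
        return np.asarray(config.rotation_centre, dtype=float)
    return np.asarray(grid.centre, dtype=float)


def apply_misalignment(grid: VoxelGrid, params: AlignmentParams, config: ResampleConfig | None = None) -> VoxelGrid:
    """Rigidly move the volume content by ``params``; geometry is unchanged.

    Rotation about the rotation centre first, then in-plane translation.
    Out-of-domain voxels take ``config.fill_value``.
    """
    config = config or ResampleConfig()
    if _is_identity(params):
        return grid.copy()
    shift = _integer_shift_voxels(params, grid.spacing_xy, +1.0)
    if shift is not None:
        return VoxelGrid(
            _shift_array(grid.values, shift[0], shift[1], config.fill_value),
            grid.spacing_xy, grid.spacing_z, grid.origin,
        )
    c = _centre(grid, config)
    r = rotation_matrix(params)
    t = np.array([params.t_x, params.t_y, 0.0])
    # resampling needs the inverse of the forward motion:
    # T_fwd^-1(p) = R^T (p - c - t) + c = R^T (p - c) + c + (-R^T t)
    return _resample(grid, r.T, -(r.T @ t), c, config)


def correct_alignment(grid: VoxelGrid, params: AlignmentParams, config: ResampleConfig | None = None) -> VoxelGrid:
    """Undo ``params``: apply the exact inverse rigid transform in one pass."""
    config = config or ResampleConfig()
    if _is_identity(params):
        return grid.copy()
    shift = _integer_shift_voxels(params, grid.spacing_xy, -1.0)
    if shift is not None:
        return VoxelGrid(
            _shift_array(grid.values, shift[0], shift[1], config.fill_value),
            grid.spacing_xy, grid.spacing_z, grid.origin,
        )
    c = _centre(grid, config)
    r = rotation_matrix(params)
    t = np.array([params.t_x, params.t_y, 0.0])
    # inverse motion is T_fwd itself as the output→input map
    return _resample(grid, r, t, c, config)
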