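"""Synthetic CT stand-ins: QA phantom, sediment-core sections, misalignments.

No public CT acquisitions exist for either object class, so every stage of
the pipeline is exercised on generated volumes:

* :func:`make_phantom` — a cylindrical image-quality phantom, 143 mm long by
  default, water-equivalent body with four low-contrast cylindrical insets
  (nominally −150/−78/−49/−17 HU) in a dedicated section, 0.39 mm in-plane
  voxels and 1 mm slice increment. The field of view is sized so the largest
  sampled misalignment (15 mm, 2.86°) can never push the body outside it.
* :func:`make_core` — a sediment-core section: plastic liner annulus, an air
  gap between sediment surface and liner at the top of the image, Gaussian
  sediment texture, and high-density ellipsoidal coral clasts (~2 cm),
  0.35 mm in-plane voxels and 0.3 mm increment.
* :class:`MisalignmentSampler` — uniform signed draws of the misalignment
  quadruple, |t| ≤ 15 mm and |rot| ≤ 2.86° (0.05 rad) per axis by default.

All generators are deterministic under a fixed seed. Noise-free phantoms are
piecewise constant, so ROI means equal the nominal inset values exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .axis_estimation import AlignmentParams
from .errors import SpecError
from .image_model import ROISpec, VoxelGrid

__all__ = [
    "InsetSpec",
    "PhantomSpec",
    "CoreSpec",
    "MisalignmentSampler",
    "make_phantom",
    "make_core",
    "sample_misalignment",
]

#: Largest misalignment the validation study draws; generated phantoms must
#: keep the body inside the field of view under this motion.
MAX_TRANSLATION_MM = 15.0
MAX_ROTATION_DEG = 2.86

AIR_HU = -1000.0


@dataclass(frozen=True)
class InsetSpec:
    """One low-contrast inset rod: in-plane offset from the axis, radius, HU."""

    offset_x: float
    offset_y: float
    radius: float
    hu: float


def _default_insets() -> list[InsetSpec]:
    # four rods on a 25 mm circle at the diagonal positions, so the central
    # row/column searches never cross them at zero misalignment
    d = 25.0 / math.sqrt(2.0)
    return [
        InsetSpec(+d, -d, 7.5, -150.0),
        InsetSpec(-d, -d, 7.5, -78.0),
        InsetSpec(-d, +d, 7.5, -49.0),
        InsetSpec(+d, +d, 7.5, -17.0),
    ]


@dataclass(frozen=True)
class PhantomSpec:
    length: float = 143.0          # mm along z
    radius: float = 80.0           # mm; a 160 mm body in a ~200 mm FOV
    body_hu: float = 0.0
    insets: tuple[InsetSpec, ...] = field(default_factory=lambda: tuple(_default_insets()))
    inset_z_range: tuple[float, float] = (-50.0, -10.0)  # mm relative to mid-plane
    spacing_xy: float = 0.39
    spacing_z: float = 1.0
    noise_sigma: float = 0.0       # HU; 0 = piecewise-constant volume
    fov_margin: float = 20.0       # mm of air beyond the body radius
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.radius > 0):
            raise SpecError("length and radius must be positive")


@dataclass(frozen=True)
class CoreSpec:
    length: float = 1000.0         # mm; study sections were up to 1 m
    diameter: float = 120.0        # mm
    liner_thickness: float = 3.0   # mm
    liner_hu: float = 300.0
    gap_fraction: float = 0.03     # air-gap cap height as fraction of inner diameter
    sediment_hu_mean: float = 700.0
    sediment_hu_sd: float = 60.0
    clast_count: int = 30
    clast_semiaxis_range: tuple[float, float] = (3.0, 10.0)  # mm; clasts ~2 cm across
    clast_hu_range: tuple[float, float] = (1400.0, 2200.0)
    spacing_xy: float = 0.35
    spacing_z: float = 0.3
    fov_margin: float = 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.length <= 0 or self.length > 1000:
            raise SpecError("core length must be in (0, 1000] mm")
        if self.diameter <= 0 or self.diameter / 2 + self.fov_margin <= self.diameter / 2:
            raise SpecError("invalid diameter / fov_margin")
        if self.clast_semiaxis_range[1] > 10.5:
            raise SpecError("clast semi-axes above ~10 mm (2 cm clasts) are out of range")


@dataclass
class MisalignmentSampler:
    """Uniform misalignment sampler: each component i.i.d. on [−max, +max].

    With ``signed=False`` components are drawn on [0, max] instead (a
    sensitivity-check mode). Reproducible under a fixed seed; successive
    draws are independent.
    """

    max_translation: float = MAX_TRANSLATION_MM
    max_rotation: float = MAX_ROTATION_DEG
    signed: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.max_translation > 0 and self.max_rotation > 0):
            raise SpecError("sampler maxima must be positive")
        self._rng = np.random.default_rng(self.seed)

    def reseed(self, seed: int | None) -> None:
        self._rng = np.random.default_rng(seed)

    def sample(self) -> AlignmentParams:
        lo_t = -self.max_translation if self.signed else 0.0
        lo_r = -self.max_rotation if self.signed else 0.0
        return AlignmentParams(
            t_x=float(self._rng.uniform(lo_t, self.max_translation)),
            t_y=float(self._rng.uniform(lo_t, self.max_translation)),
            rot_x=float(self._rng.uniform(lo_r, self.max_rotation)),
            rot_y=float(self._rng.uniform(lo_r, self.max_rotation)),
        )


def sample_misalignment(sampler: MisalignmentSampler) -> AlignmentParams:
    """Draw one misalignment quadruple from the sampler."""
    return sampler.sample()


def _centred_axes(n: int, spacing: float) -> np.ndarray:
    return (np.arange(n) - (n - 1) / 2.0) * spacing


def make_phantom(spec: PhantomSpec | None = None) -> tuple[VoxelGrid, list[ROISpec]]:
    """Generate the synthetic image-quality phantom and its inset ROIs.

    The cylinder is centred on the stack axis. Each returned ROI sits well
    inside one inset (60% of the inset radius, slice range shaved by 5 mm at
    both ends), so on the noise-free volume its mean equals the nominal HU
    exactly.
    """
    spec = spec or PhantomSpec()
    for ins in spec.insets:
        if math.hypot(ins.offset_x, ins.offset_y) + ins.radius >= spec.radius:
            raise SpecError(f"inset at ({ins.offset_x}, {ins.offset_y}) extends beyond the body")
    for i, p in enumerate(spec.insets):
        for q in spec.insets[i + 1 :]:
            if math.hypot(p.offset_x - q.offset_x, p.offset_y - q.offset_y) < p.radius + q.radius:
                raise SpecError("insets overlap")
    half_fov = spec.radius + spec.fov_margin
    reach = spec.radius + MAX_TRANSLATION_MM + math.tan(math.radians(MAX_ROTATION_DEG)) * spec.length / 2.0
    if reach > half_fov:
        raise SpecError(
            f"field of view too small: body can reach {reach:.1f} mm but half-FOV is {half_fov:.1f} mm"
        )

    n_xy = 2 * int(round(half_fov / spec.spacing_xy)) + 1
    nz = int(round(spec.length / spec.spacing_z))
    xs = _centred_axes(n_xy, spec.spacing_xy)
    zs = _centred_axes(nz, spec.spacing_z)
    xx, yy = np.meshgrid(xs, xs, indexing="xy")  # yy varies along rows

    body = xx**2 + yy**2 <= spec.radius**2
    plain = np.full((n_xy, n_xy), AIR_HU, dtype=np.float32)
    plain[body] = spec.body_hu
    section = plain.copy()
    for ins in spec.insets:
        mask = (xx - ins.offset_x) ** 2 + (yy - ins.offset_y) ** 2 <= ins.radius**2
        section[mask & body] = ins.hu

    z_lo, z_hi = spec.inset_z_range
    in_section = (zs >= z_lo) & (zs <= z_hi)
    values = np.empty((nz, n_xy, n_xy), dtype=np.float32)
    values[~in_section] = plain
    values[in_section] = section

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        values += rng.standard_normal(values.shape, dtype=np.float32) * spec.noise_sigma

    origin = (float(xs[0]), float(xs[0]), float(zs[0]))
    grid = VoxelGrid(values, spec.spacing_xy, spec.spacing_z, origin)

    margin_z = min(5.0, (z_hi - z_lo) / 4.0)
    sl_lo = int(np.searchsorted(zs, z_lo + margin_z))
    sl_hi = int(np.searchsorted(zs, z_hi - margin_z, side="right"))
    rois = [
        ROISpec(ins.offset_x, ins.offset_y, 0.6 * ins.radius, sl_lo, sl_hi)
        for ins in spec.insets
    ]
    return grid, rois


def make_core(spec: CoreSpec | None = None) -> tuple[VoxelGrid, pd.DataFrame]:
    """Generate a synthetic sediment-core section and its clast manifest.

    Axial structure, outside in: air, liner annulus, then either sediment or
    the top air gap (a circular segment where the frozen sediment has settled
    away from the liner). Clast ellipsoids are placed uniformly inside the
    sediment with bounded retries; the manifest records each clast's centre
    (mm, stack coordinates with z = 0 at the first slice), semi-axes and HU.
    """
    spec = spec or CoreSpec()
    rng = np.random.default_rng(spec.seed)
    r_out = spec.diameter / 2.0
    r_in = r_out - spec.liner_thickness
    if r_in <= 0:
        raise SpecError("liner thicker than the core radius")

    half_fov = r_out + spec.fov_margin
    n_xy = 2 * int(round(half_fov / spec.spacing_xy)) + 1
    nz = int(round(spec.length / spec.spacing_z))
    xs = _centred_axes(n_xy, spec.spacing_xy)
    xx, yy = np.meshgrid(xs, xs, indexing="xy")
    rr2 = xx**2 + yy**2

    # top of the image = small y; sediment surface is a horizontal chord
    y_cut = -(r_in - spec.gap_fraction * 2.0 * r_in)
    liner = (rr2 <= r_out**2) & (rr2 > r_in**2)
    inside = rr2 <= r_in**2
    sediment = inside & (yy >= y_cut)

    template = np.full((n_xy, n_xy), AIR_HU, dtype=np.float32)
    template[liner] = spec.liner_hu
    template[sediment] = spec.sediment_hu_mean

    values = np.broadcast_to(template, (nz, n_xy, n_xy)).copy()
    if spec.sediment_hu_sd > 0:
        idx = np.flatnonzero(sediment.ravel())
        noise = rng.standard_normal((nz, idx.size), dtype=np.float32) * spec.sediment_hu_sd
        flat = values.reshape(nz, -1)
        flat[:, idx] += noise

    # clast placement
    lo, hi = spec.clast_semiaxis_range
    records = []
    zs = np.arange(nz) * spec.spacing_z
    for k in range(spec.clast_count):
        placed = False
        for _ in range(200):
            axes = rng.uniform(lo, hi, size=3)
            max_ax = float(np.max(axes[:2]))
            r_lim = r_in - max_ax - spec.spacing_xy
            if r_lim <= 0:
                continue
            rad = math.sqrt(rng.uniform(0, 1)) * r_lim
            ang = rng.uniform(0, 2 * math.pi)
            cx_, cy_ = rad * math.cos(ang), rad * math.sin(ang)
            if cy_ - axes[1] < y_cut:
                continue  # would poke through the sediment surface
            if axes[2] >= spec.length / 2 - spec.spacing_z:
                continue
            cz_ = rng.uniform(axes[2], spec.length - axes[2])
            hu = rng.uniform(*spec.clast_hu_range)
            placed = True
            break
        if not placed:
            raise SpecError(f"could not place clast {k} after bounded retries")
        z0 = max(0, int(np.searchsorted(zs, cz_ - axes[2])) - 1)
        z1 = min(nz, int(np.searchsorted(zs, cz_ + axes[2])) + 1)
        sub_z = zs[z0:z1]
        ell = (
            ((xx[None, :, :] - cx_) / axes[0]) ** 2
            + ((yy[None, :, :] - cy_) / axes[1]) ** 2
            + ((sub_z[:, None, None] - cz_) / axes[2]) ** 2
        ) <= 1.0
        ell &= sediment[None, :, :]
        values[z0:z1][ell] = hu
        records.append(
            {
                "clast": k, "x_mm": cx_, "y_mm": cy_, "z_mm": cz_,
                "ax_mm": float(axes[0]), "ay_mm": float(axes[1]), "az_mm": float(axes[2]),
                "hu": float(hu),
            }
        )

    origin = (float(xs[0]), float(xs[0]), 0.0)
    grid = VoxelGrid(values, spec.spacing_xy, spec.spacing_z, origin)
    manifest = pd.DataFrame.from_records(
        records,
        columns=["clast", "x_mm", "y_mm", "z_mm", "ax_mm", "ay_mm", "az_mm", "hu"],
    )
    return grid, manifest
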