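"""Stack segmentation, axis regression, parameter derivation."""

import numpy as np
import pytest

from corealign.axis_estimation import (
    AlignmentParams,
    AxisFit,
    Segment,
    SegmentationConfig,
    derive_params,
    detect_misalignment,
    fit_axis,
    segment_stack,
    select_longest,
)
from corealign.errors import NoObjectError
from corealign.image_model import VoxelGrid
from corealign.rigid_transform import apply_misalignment
from corealign.slice_detection import CircleFit


def make_fits(x0, y0, r, valid=None):
    n = len(x0)
    valid = valid if valid is not None else [True] * n
    return [CircleFit(x0[i], y0[i], r[i], valid[i], i) for i in range(n)]


class TestSegmentStack:
    def test_identical_fits_single_segment(self):
        fits = make_fits([5.0] * 100, [3.0] * 100, [60.0] * 100)
        assert segment_stack(fits, spacing_xy=0.39) == [Segment(0, 100)]

    def test_one_percent_radius_step_splits(self):
        r = [60.0] * 50 + [60.6] * 50  # 1% step violates the 0.5% rule
        fits = make_fits([0.0] * 100, [0.0] * 100, r)
        assert segment_stack(fits, spacing_xy=0.39) == [Segment(0, 50), Segment(50, 100)]

    def test_radius_change_just_below_half_percent_kept(self):
        r = [60.0] * 50 + [60.0 * 1.004] * 50
        fits = make_fits([0.0] * 100, [0.0] * 100, r)
        assert segment_stack(fits, spacing_xy=0.39) == [Segment(0, 100)]

    def test_centre_jump_of_two_voxels_splits(self):
        x0 = [0.0] * 30 + [2 * 0.39] * 30
        fits = make_fits(x0, [0.0] * 60, [60.0] * 60)
        assert segment_stack(fits, spacing_xy=0.39) == [Segment(0, 30), Segment(30, 60)]

    def test_alternating_validity_yields_nothing(self):
        fits = make_fits([0.0] * 20, [0.0] * 20, [60.0] * 20, valid=[i % 2 == 0 for i in range(20)])
        assert segment_stack(fits, spacing_xy=0.39) == []

    def test_short_runs_removed(self):
        fits = make_fits([0.0] * 4, [0.0] * 4, [60.0] * 4)
        assert segment_stack(fits, spacing_xy=0.39) == []

    def test_segments_disjoint_ordered_min_length(self):
        rng = np.random.default_rng(5)
        x0 = np.cumsum(rng.choice([0.0, 1.0], size=200, p=[0.9, 0.1]))
        fits = make_fits(x0, [0.0] * 200, [60.0] * 200)
        segs = segment_stack(fits, spacing_xy=0.39)
        for s in segs:
            assert s.length >= 5
        for s1, s2 in zip(segs, segs[1:]):
            assert s1.end_slice <= s2.start_slice


class TestSelectLongest:
    def test_picks_longest(self):
        segs = [Segment(0, 12), Segment(12, 92), Segment(92, 104)]
        assert select_longest(segs) == Segment(12, 92)

    def test_tie_breaks_to_first(self):
        assert select_longest([Segment(0, 40), Segment(50, 90)]) == Segment(0, 40)

    def test_empty_raises_no_object(self):
        with pytest.raises(NoObjectError):
            select_longest([])


class TestFitAxis:
    def test_exact_line_recovered(self):
        z = np.arange(50) * 2.0
        fits = make_fits(0.01 * z + 5.0, -0.02 * z + 1.0, [60.0] * 50)
        axis = fit_axis(fits, Segment(0, 50), spacing_z=2.0)
        assert axis.slope_x == pytest.approx(0.01, abs=1e-12)
        assert axis.intercept_x == pytest.approx(5.0, abs=1e-10)
        assert axis.slope_y == pytest.approx(-0.02, abs=1e-12)

    def test_constant_centres(self):
        fits = make_fits([3.0] * 10, [-2.0] * 10, [60.0] * 10)
        axis = fit_axis(fits, Segment(0, 10), spacing_z=1.0)
        assert axis.slope_x == pytest.approx(0.0, abs=1e-12)
        assert (axis.intercept_x, axis.intercept_y) == pytest.approx((3.0, -2.0))

    def test_matches_normal_equations_oracle(self):
        """OLS coefficients agree with the closed-form normal equations."""
        rng = np.random.default_rng(7)
        n, sz = 200, 0.5
        z = np.arange(n) * sz
        x0 = 0.013 * z - 4.0 + rng.normal(0, 0.05, n)
        y0 = -0.007 * z + 2.5 + rng.normal(0, 0.05, n)
        fits = make_fits(x0, y0, [60.0] * n)
        axis = fit_axis(fits, Segment(0, n), spacing_z=sz)
        for obs, slope, intercept in ((x0, axis.slope_x, axis.intercept_x), (y0, axis.slope_y, axis.intercept_y)):
            zbar, obar = z.mean(), obs.mean()
            beta = np.sum((z - zbar) * (obs - obar)) / np.sum((z - zbar) ** 2)
            assert slope == pytest.approx(beta, abs=1e-10)
            assert intercept == pytest.approx(obar - beta * zbar, abs=1e-10)

    def test_too_few_points(self):
        fits = make_fits([0.0], [0.0], [60.0])
        with pytest.raises(ValueError):
            fit_axis(fits, Segment(0, 1), spacing_z=1.0)


class TestDeriveParams:
    def _grid(self, n=11, nz=21):
        vals = np.full((nz, n, n), -1000.0, dtype=np.float32)
        sp = 1.0
        o = -(n - 1) / 2
        return VoxelGrid(vals, sp, sp, origin=(o, o, -(nz - 1) / 2))

    def test_centred_axis_is_identity(self):
        grid = self._grid()
        axis = AxisFit(0.0, 0.0, 0.0, 0.0, Segment(0, 21))
        p = derive_params(axis, grid)
        assert p.as_array() == pytest.approx(np.zeros(4), abs=1e-12)

    def test_one_degree_slope(self):
        grid = self._grid()
        axis = AxisFit(np.tan(np.radians(1.0)), 0.0, 0.0, 0.0, Segment(0, 21))
        p = derive_params(axis, grid)
        assert p.rot_y == pytest.approx(1.0, abs=1e-9)
        assert p.t_x == pytest.approx(0.0, abs=1e-12)

    def test_offset_at_midplane(self):
        grid = self._grid()
        axis = AxisFit(0.0, 7.0, 0.0, -3.0, Segment(0, 21))
        p = derive_params(axis, grid)
        assert (p.t_x, p.t_y) == pytest.approx((7.0, -3.0))

    def test_rotation_magnitude_invariant(self):
        with pytest.raises(ValueError):
            AlignmentParams(0, 0, 95.0, 0)


class TestDetectionRoundTrip:
    def test_core_magnitude_misalignment_recovered(self, small_phantom):
        """A core-scale misalignment (≈8/10 mm, ≈1°) is recovered to a voxel."""
        grid, _ = small_phantom
        applied = AlignmentParams(8.44, -9.84, 1.01, -0.07)
        detected = detect_misalignment(apply_misalignment(grid, applied)).params
        assert detected.t_x == pytest.approx(applied.t_x, abs=grid.spacing_xy)
        assert detected.t_y == pytest.approx(applied.t_y, abs=grid.spacing_xy)
        assert detected.rot_x == pytest.approx(applied.rot_x, abs=0.2)
        assert detected.rot_y == pytest.approx(applied.rot_y, abs=0.2)

    def test_idempotence_on_aligned_phantom(self, small_phantom):
        grid, _ = small_phantom
        p = detect_misalignment(grid).params
        assert abs(p.t_x) < grid.spacing_xy
        assert abs(p.t_y) < grid.spacing_xy
        assert abs(p.rot_x) < 0.1
        assert abs(p.rot_y) < 0.1

    def test_longest_segment_covers_stack(self, small_phantom):
        grid, _ = small_phantom
        res = detect_misalignment(grid)
        assert res.chosen.length >= 0.9 * grid.nz
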