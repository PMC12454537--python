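"""Voxel field construction from streamlines: FA, filtering, K/a0/D maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myofield.tract_fields import (
    StreamlineSet,
    VoxelGrid,
    compute_fa,
    discrete_divergence,
    filter_streamlines,
    resample_polyline,
    voxel_fibre_count,
    voxel_mean_orientation,
)

E2 = np.array([0.0, 1.0, 0.0])


def line(p0, p1, n=20):
    return np.linspace(p0, p1, n)


def grid_cube(n=4, spacing=2.0):
    return VoxelGrid((n, n, n), (spacing,) * 3, (0.0, 0.0, 0.0), e2=E2)


class TestComputeFA:
    @pytest.mark.parametrize(
        "eigs,expected",
        [
            ((1.0, 1.0, 1.0), 0.0),  # isotropic
            ((1.0, 0.0, 0.0), 0.5 * np.sqrt(2.0)),  # fully anisotropic
            ((3.0, 2.0, 1.0), 0.5 * np.sqrt(6.0) / np.sqrt(14.0)),
        ],
    )
    def test_printed_prefactor_examples(self, eigs, expected):
        assert compute_fa(eigs) == pytest.approx(expected, abs=1e-9)

    def test_standard_prefactor_flag(self):
        fa = compute_fa((1.0, 0.0, 0.0), prefactor=np.sqrt(0.5))
        assert fa == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_is_domain_error(self):
        with pytest.raises(ValueError):
            compute_fa((0.0, 0.0, 0.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        l1=st.floats(0.0, 10.0),
        l2=st.floats(0.0, 10.0),
        l3=st.floats(0.0, 10.0),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, l1, l2, l3, c):
        lam = np.array([l1, l2, l3])
        if np.all(lam < 1e-6):  # avoid underflow of the squared norm
            lam[0] = 1.0
        assert compute_fa(c * lam) == pytest.approx(
            compute_fa(lam), rel=1e-9, abs=1e-12
        )


class TestFilterStreamlines:
    def test_straight_100mm_kept(self):
        s = StreamlineSet([line([0, 0, 0], [0, 100, 0])])
        assert len(filter_streamlines(s)) == 1

    def test_short_track_removed(self):
        s = StreamlineSet([line([0, 0, 0], [0, 10, 0])])
        assert len(filter_streamlines(s)) == 0

    def test_sharp_bend_removed(self):
        # one 45-degree bend between segments; oracle via tangent dot product
        pts = np.array([[0, 0, 0], [0, 20, 0], [0, 40, 20.0]])
        t0 = np.array([0, 1, 0.0])
        t1 = np.array([0, 20, 20.0]) / np.linalg.norm([0, 20, 20.0])
        assert np.degrees(np.arccos(t0 @ t1)) == pytest.approx(45.0)
        s = StreamlineSet([pts])
        assert len(filter_streamlines(s, max_turn_deg=10.0)) == 0
        assert len(filter_streamlines(s, max_turn_deg=46.0)) == 1

    def test_fa_range_inclusive(self):
        s = StreamlineSet([line([0, 0, 0], [0, 100, 0], n=5)])
        ok = [np.full(5, 0.3)]
        low = [np.array([0.3, 0.05, 0.3, 0.3, 0.3])]
        assert len(filter_streamlines(s, fa_values=ok)) == 1
        assert len(filter_streamlines(s, fa_values=low)) == 0
        boundary = [np.array([0.1, 0.5, 0.3, 0.2, 0.4])]
        assert len(filter_streamlines(s, fa_values=boundary)) == 1

    def test_empty_input_gives_empty_output(self):
        assert len(filter_streamlines(StreamlineSet([]))) == 0

    def test_order_preserved(self):
        a = line([0, 0, 0], [0, 100, 0])
        b = line([1, 0, 0], [1, 80, 0])
        out = filter_streamlines(StreamlineSet([a, b]))
        assert np.allclose(out[0], a) and np.allclose(out[1], b)


class TestVoxelFibreCount:
    def test_single_streamline_through_centre(self):
        g = grid_cube(4, 2.0)
        centre = g.centres(np.array([[1, 1, 1]]))[0]
        s = StreamlineSet([line(centre - [0, 5, 0], centre + [0, 5, 0])])
        K = voxel_fibre_count(s, g, sphere_diameter_mm=2.0)
        assert K[1, 1, 1] == 1

    def test_point_outside_sphere_not_counted(self):
        # spec oracle: passing 2.0 mm from the centre, radius 1.3125 mm
        g = VoxelGrid((3, 3, 3), (2.625, 6.25, 2.625), (0, 0, 0), e2=E2)
        centre = g.centres(np.array([[1, 1, 1]]))[0]
        s = StreamlineSet(
            [line(centre + [2.0, -3, 0], centre + [2.0, 3, 0])]
        )
        K = voxel_fibre_count(s, g)
        assert K[1, 1, 1] == 0

    def test_two_visits_count_once(self):
        g = grid_cube(5, 2.0)
        c = g.centres(np.array([[2, 2, 2]]))[0]
        # in, out, and back in through the same voxel sphere
        pts = np.concatenate(
            [
                line(c - [0, 4, 0], c + [0, 4, 0], 17),
                line(c + [0, 4, 0.4], c - [0, 4, 0.4], 17),
            ]
        )
        K = voxel_fibre_count(StreamlineSet([pts], validate=False), g, 2.0)
        assert K[2, 2, 2] == 1

    def test_reversal_invariance(self):
        g = grid_cube(5, 2.0)
        rng = np.random.default_rng(3)
        tracks = [
            np.cumsum(rng.normal(0, 0.7, (30, 3)), axis=0) + [5, 5, 5]
            for _ in range(10)
        ]
        K1 = voxel_fibre_count(StreamlineSet(tracks, validate=False), g, 2.0)
        K2 = voxel_fibre_count(
            StreamlineSet([t[::-1] for t in tracks], validate=False), g, 2.0
        )
        assert np.array_equal(K1, K2)

    def test_oversized_sphere_rejected(self):
        g = grid_cube(3, 2.0)
        s = StreamlineSet([line([0, 0, 0], [0, 5, 0])])
        with pytest.raises(ValueError):
            voxel_fibre_count(s, g, sphere_diameter_mm=2.5)


class TestVoxelMeanOrientation:
    def test_parallel_fibres(self):
        g = grid_cube(3, 3.0)
        c = g.centres(np.array([[1, 1, 1]]))[0]
        tracks = [
            line(c - [dx, 4, 0], c + [-dx, 4, 0]) for dx in (0.2, -0.2)
        ]
        a0, K = voxel_mean_orientation(StreamlineSet(tracks), g, 3.0)
        assert K[1, 1, 1] == 2
        assert a0[1, 1, 1] == pytest.approx([0, 1, 0], abs=1e-9)

    def test_sign_convention_flips_antiparallel(self):
        g = grid_cube(3, 3.0)
        c = g.centres(np.array([[1, 1, 1]]))[0]
        tracks = [line(c + [0, 4, 0], c - [0, 4, 0]) for _ in range(3)]
        a0, _ = voxel_mean_orientation(
            StreamlineSet(tracks, validate=False), g, 3.0
        )
        assert a0[1, 1, 1] == pytest.approx([0, 1, 0], abs=1e-9)

    def test_mean_not_renormalised(self):
        g = grid_cube(3, 3.0)
        c = g.centres(np.array([[1, 1, 1]]))[0]
        tracks = [
            line(c - [4, 0, 0], c + [4, 0, 0]),  # +x tangent
            line(c - [0, 4, 0], c + [0, 4, 0]),  # +y tangent
        ]
        a0, _ = voxel_mean_orientation(StreamlineSet(tracks), g, 3.0)
        assert a0[1, 1, 1] == pytest.approx([0.5, 0.5, 0.0], abs=1e-9)
        assert np.linalg.norm(a0[1, 1, 1]) == pytest.approx(
            np.sqrt(0.5), abs=1e-9
        )

    def test_axis_component_non_negative_and_norm_bounded(self):
        g = grid_cube(6, 2.0)
        rng = np.random.default_rng(11)
        tracks = [
            np.cumsum(rng.normal(0, 0.6, (40, 3)), axis=0) + [6, 6, 6]
            for _ in range(25)
        ]
        a0, K = voxel_mean_orientation(
            StreamlineSet(tracks, validate=False), g, 2.0
        )
        dots = a0.reshape(-1, 3) @ E2
        assert np.all(dots[K.ravel() > 0] >= -1e-12)
        assert np.all(np.linalg.norm(a0.reshape(-1, 3), axis=1) <= 1 + 1e-9)
        assert np.all(a0.reshape(-1, 3)[K.ravel() == 0] == 0.0)


class TestDiscreteDivergence:
    def test_pass_through_contributes_zero(self):
        g = grid_cube(4, 2.0)
        c = g.centres(np.array([[1, 1, 1]]))[0]
        s = StreamlineSet([line(c - [0, 10, 0], c + [0, 10, 0])])
        D = discrete_divergence(s, g)
        assert D[1, 1, 1] == 0

    def test_three_terminating_tracks_give_plus_three(self):
        g = grid_cube(4, 2.0)
        c = g.centres(np.array([[2, 2, 2]]))[0]
        tracks = [
            line(c - [0, 4.2, 0], c + [dx, 0, 0]) for dx in (-0.3, 0.0, 0.3)
        ]
        D = discrete_divergence(StreamlineSet(tracks), g)
        assert D[2, 2, 2] == 3

    def test_origin_inside_contributes_minus_one(self):
        g = grid_cube(4, 2.0)
        c = g.centres(np.array([[1, 1, 1]]))[0]
        s = StreamlineSet([line(c, c + [0, 10, 0])])
        D = discrete_divergence(s, g)
        assert D[1, 1, 1] == -1

    def test_global_sum_rule(self):
        # sum of D equals (#endpoints inside) - (#startpoints inside),
        # with oriented tracks; exact integer identity
        g = grid_cube(6, 2.0)
        rng = np.random.default_rng(5)
        tracks = [
            np.cumsum(rng.normal(0.2, 0.8, (30, 3)), axis=0) + [2, 2, 2]
            for _ in range(40)
        ]
        sset = StreamlineSet(tracks, validate=False)
        D = discrete_divergence(sset, g, orient=False)
        n_end = sum(g.inside(g.voxel_of(t[-1:]))[0] for t in tracks)
        n_start = sum(g.inside(g.voxel_of(t[:1]))[0] for t in tracks)
        assert D.sum() == n_end - n_start

    def test_reversal_antisymmetry_without_orientation(self):
        g = grid_cube(6, 2.0)
        rng = np.random.default_rng(8)
        tracks = [
            np.cumsum(rng.normal(0.1, 0.8, (25, 3)), axis=0) + [3, 3, 3]
            for _ in range(15)
        ]
        fwd = discrete_divergence(
            StreamlineSet(tracks, validate=False), g, orient=False
        )
        rev = discrete_divergence(
            StreamlineSet([t[::-1] for t in tracks], validate=False),
            g,
            orient=False,
        )
        assert np.array_equal(fwd, -rev)
        # with the h-orientation step the map is reversal-invariant instead
        fwd_h = discrete_divergence(StreamlineSet(tracks, validate=False), g)
        rev_h = discrete_divergence(
            StreamlineSet([t[::-1] for t in tracks], validate=False), g
        )
        assert np.array_equal(fwd_h, rev_h)

    def test_fd_mode_constant_field_zero_interior(self):
        g = grid_cube(5, 2.0)
        orientation = np.tile(E2, g.shape + (1,))
        count = np.ones(g.shape, dtype=int)
        D = discrete_divergence(
            StreamlineSet([]), g, mode="fd",
            orientation_field=orientation, count=count,
        )
        assert np.allclose(D, 0.0, atol=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            discrete_divergence(StreamlineSet([]), grid_cube(), mode="bogus")


class TestResampling:
    def test_uniform_step_and_endpoints(self):
        pts = np.array([[0, 0, 0], [0, 3, 0], [0, 3, 4.0]])
        out = resample_polyline(pts, 0.5)
        seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert np.allclose(out[0], pts[0]) and np.allclose(out[-1], pts[-1])
        assert abs(seg.sum() - 7.0) < 0.1  # straightened corners shorten
        assert seg.max() <= 0.5 + 1e-9
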