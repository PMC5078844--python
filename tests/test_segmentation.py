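"""Separatrices, segment assembly, shape/ratio and flow-partition relations."""

import math

import numpy as np
import pytest

from chorioflow.flow import find_stagnation_points, velocity
from chorioflow.geometry import (
    Opening,
    OpeningConfiguration,
    generate_lattice_openings,
)
from chorioflow.segmentation import (
    build_segments,
    flow_partition,
    flow_rate_ratio_from_angles,
    interior_angles,
    ratio_from_shape,
    saddle_eigendirections,
    segments_to_geojson,
    trace_separatrices,
)


class TestEigendirections:
    def test_two_sources_axes(self, two_sources):
        saddle = find_stagnation_points(two_sources)[0]
        unstable, stable = saddle_eigendirections(two_sources, saddle)
        # w ~ -2z at the origin: physical outflow along y, inflow along x
        assert abs(abs(unstable[0][1]) - 1.0) < 1e-12
        assert abs(abs(stable[0][0]) - 1.0) < 1e-12

    def test_orthogonal_pairs(self, random_config):
        for saddle in find_stagnation_points(random_config):
            unstable, stable = saddle_eigendirections(random_config, saddle)
            assert abs(np.dot(unstable[0], stable[0])) < 1e-10

    def test_every_simple_saddle_has_index_minus_one(self, random_config):
        for saddle in find_stagnation_points(random_config):
            assert saddle.index == -1
            assert np.linalg.det(saddle.jacobian) < 0


class TestTraceSeparatrices:
    def test_dipole_has_no_separatrices(self, dipole):
        assert trace_separatrices(dipole) == []

    def test_two_sources_split_plane_along_imaginary_axis(self, two_sources):
        seps = trace_separatrices(two_sources)
        unstable = [s for s in seps if s.is_boundary]
        assert len(unstable) == 2
        for s in unstable:
            assert s.terminal == ("infinity", None)
            assert np.abs(s.polyline[:, 0]).max() < 1e-6
        stable = [s for s in seps if not s.is_boundary]
        assert sorted(s.terminal[1] for s in stable) == [0, 1]

    def test_boundary_terminals_are_never_arteriolar(self, random_config):
        seps = trace_separatrices(random_config)
        art_ids = {o.id for o in random_config.arterioles()}
        for s in seps:
            if s.is_boundary and s.terminal[0] == "opening":
                assert s.terminal[1] not in art_ids

    def test_no_flow_across_separatrices(self, random_config):
        # zero normal velocity along boundary polylines (chord-midpoint
        # comparison, away from openings where the chord resolves the curve)
        for s in trace_separatrices(random_config, max_step=0.005):
            if not s.is_boundary:
                continue
            pts = s.polyline[5:-5]
            if len(pts) < 10:
                continue
            z = pts[:, 0] + 1j * pts[:, 1]
            tang = np.diff(z)
            mid = 0.5 * (z[1:] + z[:-1])
            far = np.abs(
                mid[:, None] - random_config.positions
            ).min(axis=1) > 0.3
            if not far.any():
                continue
            u = velocity(random_config, mid[far])
            cross = np.abs((u * np.conj(tang[far])).imag) / np.abs(tang[far])
            speed = np.abs(u)
            assert (cross <= 1e-4 * np.maximum(speed, 1.0)).all()

    def test_separatrices_cross_only_at_saddles(self, random_config):
        from shapely.geometry import LineString

        seps = [s for s in trace_separatrices(random_config) if s.is_boundary]
        saddles = [s.position for s in find_stagnation_points(random_config)]
        for i in range(len(seps)):
            for j in range(i + 1, len(seps)):
                inter = LineString(seps[i].polyline).intersection(
                    LineString(seps[j].polyline)
                )
                if inter.is_empty:
                    continue
                for pt in getattr(inter, "geoms", [inter]):
                    z = complex(pt.centroid.x, pt.centroid.y)
                    near_saddle = min(abs(z - s) for s in saddles) < 1e-3
                    near_opening = (
                        np.abs(z - random_config.positions).min()
                        < 2 * random_config.radii.max()
                    )
                    assert near_saddle or near_opening


class TestBuildSegments:
    def test_dipole_single_segment_covers_domain(self, dipole):
        segs = build_segments(dipole)
        assert len(segs) == 1
        assert not segs[0].bounded
        clipped = build_segments(dipole, clip_radius=3.0)
        assert clipped[0].polygon is not None
        assert clipped[0].area_0 == pytest.approx(math.pi * 9.0, rel=1e-3)

    def test_square_lattice_interior_cell(self, central_square_segment):
        seg = central_square_segment
        assert seg.n_sides == 4
        assert seg.area_0 == pytest.approx(2.0, rel=2e-3)

    def test_partition_of_the_disc(self):
        # a generic two-source, two-drain set: the two territories tile
        # the clipped disc (tessellation conservation)
        cfg = OpeningConfiguration((
            Opening(0, "arteriolar", -1.0, 0.1, 1.0),
            Opening(1, "arteriolar", 1.0, -0.2, 1.0),
            Opening(2, "venular", 0.3, 1.8, -1.0),
            Opening(3, "venular", -0.2, -1.9, -1.0),
        ))
        segs = build_segments(cfg, clip_radius=4.0)
        areas = [s.area_0 for s in segs if s.polygon is not None]
        assert len(areas) == 2
        assert sum(areas) == pytest.approx(math.pi * 16.0, rel=1e-3)

    def test_perfused_area_scales_with_post_fraction(self, central_square_segment):
        seg = central_square_segment
        assert seg.area(0.3) == pytest.approx(0.7 * seg.area_0, rel=1e-12)

    def test_geojson_export(self, square_lattice, square_lattice_segments):
        gj = segments_to_geojson(square_lattice, square_lattice_segments)
        assert gj["type"] == "FeatureCollection"
        bounded = [f for f in gj["features"]]
        assert any(f["properties"]["n_sides"] == 4 for f in bounded)


class TestInteriorAngles:
    def test_square_cell_right_angles(self, central_square_segment):
        alpha = interior_angles(central_square_segment)
        np.testing.assert_allclose(alpha, math.pi / 2, atol=2e-3)

    def test_angle_sum_of_near_prism_segment(self, central_square_segment):
        alpha = interior_angles(central_square_segment)
        n = central_square_segment.n_sides
        assert alpha.sum() == pytest.approx((n - 2) * math.pi, rel=1e-3)

    def test_angles_in_range(self, random_config):
        for seg in build_segments(random_config):
            if seg.polygon is None or seg.n_sides < 2:
                continue
            alpha = interior_angles(seg)
            assert ((alpha > 0) & (alpha < 2 * math.pi)).all()


class TestRatioFromShape:
    def test_square_and_honeycomb_values(self):
        assert ratio_from_shape(4) == pytest.approx(1.0)
        assert ratio_from_shape(6) == pytest.approx(0.5)

    def test_below_three_sides_rejected(self):
        with pytest.raises(ValueError):
            ratio_from_shape(2)

    @pytest.mark.parametrize("n,lattice", [(4, "square"), (6, "honeycomb")])
    def test_consistency_with_lattice_counting(self, n, lattice):
        from chorioflow.geometry import bulk_opening_ratio

        cfg = generate_lattice_openings(lattice, 4)
        assert ratio_from_shape(n) == pytest.approx(bulk_opening_ratio(cfg),
                                                    rel=1e-12)

    def test_occlusion_changes_segment_shape(self):
        # removing one venular opening reshapes the adjacent segments
        cfg = generate_lattice_openings("square", 3)
        centre = cfg.opening(4)
        seg0 = [s for s in build_segments(cfg) if s.arteriole_id == 4][0]
        # drop one vertex venule of the central cell and rebalance
        drop = seg0.vertices[0]
        from chorioflow.geometry import balance_fluxes

        reduced = balance_fluxes(OpeningConfiguration(
            tuple(o for o in cfg.openings if o.id != drop),
            cfg.domain, cfg.params,
        ))
        seg1 = [s for s in build_segments(reduced) if s.arteriole_id == 4][0]
        assert seg1.n_sides != seg0.n_sides or \
            abs(seg1.area_0 - seg0.area_0) > 0.05 * seg0.area_0


class TestFlowPartition:
    def test_symmetric_square_equal_quarters(self, square_lattice,
                                             central_square_segment):
        fp = flow_partition(square_lattice, central_square_segment,
                            n_rays=2000, seed=1)
        np.testing.assert_allclose(fp.fractions, 0.25, atol=0.03)
        assert fp.fractions.sum() == pytest.approx(1.0, abs=1e-3)

    def test_conservation(self, random_config):
        seg = [s for s in build_segments(random_config) if s.bounded][0]
        fp = flow_partition(random_config, seg, n_rays=1500, seed=2)
        assert fp.fractions.sum() + fp.unresolved / fp.n_rays \
            == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_matches_angle_formula(self, random_config):
        seg = [s for s in build_segments(random_config) if s.bounded][0]
        fp = flow_partition(random_config, seg, n_rays=4000, seed=3)
        se = np.sqrt(fp.angle_fractions * (1 - fp.angle_fractions)
                     / fp.n_rays)
        assert (np.abs(fp.fractions - fp.angle_fractions) <= 3 * se).all()
        # flow-rate ratio: traced vs interior-angle prediction
        assert fp.q_ratio_mc == pytest.approx(fp.q_ratio_angles, rel=0.1)

    def test_angle_ratio_for_prism(self):
        alpha = np.full(4, math.pi / 2)
        assert flow_rate_ratio_from_angles(alpha) == pytest.approx(1.0)
        alpha6 = np.full(6, 2 * math.pi / 3)
        assert flow_rate_ratio_from_angles(alpha6) == pytest.approx(2.0)
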