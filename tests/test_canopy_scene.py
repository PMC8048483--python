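"""Geometry: organ shapes, layouts, projections and their arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopysim import (
    LeafOrgan,
    SASParams,
    Scene,
    build_rosette,
    central_selection,
    interleave_competitors,
    lamina_mesh,
    leaf_area_index,
    row_layout,
    uniform_grid,
    vertical_cover_fraction,
)
from canopysim.canopy_scene import MM, polygon_area_3d
from canopysim.fixtures import _rosette_with_leaf, _small_layout


class TestBuildRosette:
    def test_initial_state_is_empty_and_deterministic(self):
        sas = SASParams()
        a = build_rosette(sas, 0, (0.0, 0.0))
        b = build_rosette(sas, 0, (0.0, 0.0))
        assert a.leaves == [] and a.biomass == 0.0
        assert a == b

    def test_negative_germination_day_rejected(self):
        with pytest.raises(ValueError):
            build_rosette(SASParams(), -1, (0, 0))


class TestLaminaMesh:
    def test_area_converges_to_ellipse_area(self):
        leaf = LeafOrgan(rank=1, lamina_length=20.0, lamina_width=10.0,
                         petiole_angle=0.0)
        exact = math.pi * 20.0 * 10.0 / 4.0 * MM * MM
        areas = [polygon_area_3d(lamina_mesh(leaf, (0, 0), refinement=r))
                 for r in (16, 64, 512, 4096)]
        errors = [abs(a - exact) / exact for a in areas]
        assert errors == sorted(errors, reverse=True)
        assert errors[-1] < 1e-6
        assert areas[-1] == pytest.approx(157.07963e-6, rel=1e-5)

    def test_zero_dimension_lamina_gives_empty_polygon(self):
        leaf = LeafOrgan(rank=1, lamina_length=0.0, lamina_width=10.0)
        assert lamina_mesh(leaf, (0, 0)).shape == (0, 3)

    def test_centroid_on_petiole_axis_extension(self):
        leaf = LeafOrgan(rank=1, lamina_length=20.0, lamina_width=10.0,
                         petiole_length=15.0, petiole_angle=40.0, azimuth=120.0)
        mesh = lamina_mesh(leaf, (0.01, -0.02), refinement=256)
        centroid = mesh.mean(axis=0)
        d = leaf.axis_direction()
        base = np.array([0.01, -0.02, 0.0])
        along = np.dot(centroid - base, d)
        off_axis = np.linalg.norm((centroid - base) - along * d)
        assert off_axis < 1e-12
        assert along == pytest.approx((15.0 + 10.0) * MM)

    def test_vertical_leaf_has_zero_vertical_projection(self):
        leaf = LeafOrgan(rank=1, lamina_length=20.0, lamina_width=10.0,
                         petiole_angle=90.0)
        mesh = lamina_mesh(leaf, (0, 0), refinement=128)
        flat = mesh.copy()
        flat[:, 2] = 0.0
        assert polygon_area_3d(flat) < 1e-15

    @given(angle=st.floats(0, 90), azimuth=st.floats(0, 359.9),
           pet=st.floats(0, 30), lam=st.floats(0.1, 40))
    @settings(max_examples=50, deadline=None)
    def test_no_underground_foliage(self, angle, azimuth, pet, lam):
        leaf = LeafOrgan(rank=1, lamina_length=lam, lamina_width=lam / 2,
                         petiole_length=pet, petiole_angle=angle, azimuth=azimuth)
        mesh = lamina_mesh(leaf, (0, 0), refinement=64)
        assert (mesh[:, 2] >= -1e-12).all()
        assert leaf.tip_point((0, 0))[2] >= -1e-12


class TestLayouts:
    def test_default_grid_density_is_1600(self):
        layout = uniform_grid(10, 10, 0.025)
        assert layout.density == pytest.approx(1600.0, rel=5e-3)
        assert len(layout.canopy_positions) == 100

    def test_single_plant_density(self):
        assert uniform_grid(1, 1, 0.04).density == pytest.approx(1 / 0.04 ** 2)

    def test_2x2_grid_geometry_and_density(self):
        layout = uniform_grid(2, 2, 0.03)
        pos = layout.canopy_positions
        assert len(pos) == 4
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        assert np.isclose(d[d > 0].min(), 0.03)
        assert layout.density == pytest.approx(4 / 0.0036, rel=5e-3)

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(ValueError):
            uniform_grid(3, 3, 0.0)

    def test_row_layout_spacings(self):
        layout = row_layout(4, 0.05, 0.006, 10)
        assert layout.pattern == "row"
        pos = layout.canopy_positions
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        assert np.isclose(d[d > 0].min(), 0.006)

    def test_row_layout_nearest_neighbor_within_rows(self):
        layout = row_layout(3, 0.05, 0.02, 5)
        pos = layout.canopy_positions
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        assert np.isclose(d[d > 0].min(), 0.02)

    def test_single_row_is_a_line(self):
        layout = row_layout(1, 0.05, 0.0125, 6)
        assert np.allclose(layout.canopy_positions[:, 0], 0.0)

    def test_overlapping_rows_rejected(self):
        with pytest.raises(ValueError):
            row_layout(3, 0.0, 0.01, 5)


class TestInterleaveCompetitors:
    def test_16_competitors_form_centered_4x4(self):
        layout = interleave_competitors(uniform_grid(10, 10, 0.025), 16)
        comp = layout.competitor_positions
        assert len(comp) == 16
        # symmetric about the origin, on between-plant cell centres
        assert np.allclose(sorted(comp[:, 0]), sorted(-comp[:, 0]))
        assert np.allclose(np.unique(np.round(comp[:, 0], 9)),
                           [-0.075, -0.025, 0.025, 0.075])
        x0, x1, y0, y1 = layout.plot_bounds
        assert ((comp[:, 0] > x0) & (comp[:, 0] < x1)
                & (comp[:, 1] > y0) & (comp[:, 1] < y1)).all()

    def test_zero_competitors_is_identity(self):
        layout = uniform_grid(4, 4, 0.025)
        assert interleave_competitors(layout, 0) is layout

    def test_too_many_competitors_rejected(self):
        with pytest.raises(ValueError):
            interleave_competitors(uniform_grid(3, 3, 0.025), 16)


class TestCentralSelection:
    def test_middle_16_of_10x10(self):
        layout = uniform_grid(10, 10, 0.025)
        idx = central_selection(layout.canopy_positions, 16)
        pos = layout.canopy_positions[idx]
        assert len(idx) == 16
        assert np.abs(pos).max() <= 0.0375 + 1e-12  # central 4×4 block

    def test_select_all_is_identity(self):
        layout = uniform_grid(3, 3, 0.01)
        idx = central_selection(layout.canopy_positions, 9)
        assert sorted(idx) == list(range(9))

    def test_central_4_of_16(self):
        layout = interleave_competitors(uniform_grid(10, 10, 0.025), 16)
        idx = central_selection(layout.competitor_positions, 4)
        pos = layout.competitor_positions[idx]
        assert np.abs(pos).max() <= 0.025 + 1e-12


class TestCoverAndLAI:
    def test_empty_scene_zero(self, empty_scene, small_layout):
        region = small_layout.plot_bounds
        assert vertical_cover_fraction(empty_scene, region) == 0.0
        assert leaf_area_index(empty_scene, region) == 0.0

    def test_single_horizontal_leaf_cover_matches_ellipse_area(self):
        layout = _small_layout()
        plant = _rosette_with_leaf((-0.01, 0.0), 20.0, 10.0)
        scene = Scene([plant], layout)
        expected = (math.pi * 20 * 10 / 4) * MM * MM / layout.plot_area
        got = vertical_cover_fraction(scene, layout.plot_bounds, resolution=400)
        assert got == pytest.approx(expected, rel=0.02)

    def test_coincident_laminas_cover_once(self):
        layout = _small_layout()
        p1 = _rosette_with_leaf((0.0, 0.0), 20.0, 10.0, plant_id=0)
        p2 = _rosette_with_leaf((0.0, 0.0), 20.0, 10.0, plant_id=1)
        one = vertical_cover_fraction(Scene([p1], layout), layout.plot_bounds, 200)
        two = vertical_cover_fraction(Scene([p1, p2], layout), layout.plot_bounds, 200)
        assert one == two

    def test_lai_definition(self):
        layout = _small_layout(half=0.05)  # 100 cm² region
        # total lamina area 50 cm² = 5000 mm² → ellipse L=2W: L=√(8A/π)
        L = math.sqrt(8 * 5000 / math.pi)
        plant = _rosette_with_leaf((0.0, 0.0), L, L / 2)
        assert leaf_area_index(Scene([plant], layout), layout.plot_bounds) \
            == pytest.approx(0.5, rel=1e-9)

    def test_lai_invariant_under_leaf_angle(self):
        layout = _small_layout()
        flat = _rosette_with_leaf((0, 0), 20.0, 10.0, angle=0.0)
        steep = _rosette_with_leaf((0, 0), 20.0, 10.0, angle=70.0)
        assert leaf_area_index(Scene([flat], layout), layout.plot_bounds) == \
            leaf_area_index(Scene([steep], layout), layout.plot_bounds)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_cover_bounded_by_lai(self, seed):
        from conftest import random_mini_canopy

        scene = random_mini_canopy(seed)
        region = scene.layout.plot_bounds
        cover = vertical_cover_fraction(scene, region, resolution=120)
        lai = leaf_area_index(scene, region)
        assert cover <= min(1.0, lai) + 0.02  # discretisation slack


def test_scene_json_roundtrip(tmp_path):
    scene = Scene([_rosette_with_leaf((0, 0), 15.0, 7.5, petiole_length_mm=5.0)],
                  _small_layout())
    path = tmp_path / "scene.json"
    scene.to_json(path)
    import json

    data = json.loads(path.read_text())
    assert data["plants"][0]["leaves"][0]["lamina_length"] == 15.0
    assert data["layout"]["pattern"] == "uniform"
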