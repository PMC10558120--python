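"""ENL, cross sections and the fractal-dimension component of SSCI."""

import math

import numpy as np
import pytest
from shapely.geometry import Polygon

from standweave.pointcloud import PointCloud, VoxelGrid, voxelize
from standweave.ssci import (
    CrossSection,
    build_cross_sections,
    compute_ssci,
    effective_number_of_layers,
    fractal_dimension,
    mean_frac,
)


def grid_from_layers(voxels_per_layer, voxel_size=0.05):
    """Hand-built occupancy grid with given filled-voxel counts per 25 cm layer."""
    idx = []
    for layer, count in enumerate(voxels_per_layer):
        for i in range(count):
            idx.append((i, 0, layer * 5))  # 5 voxels of 5 cm per 25 cm layer
    idx = np.array(idx)
    return VoxelGrid(
        voxel_size=voxel_size,
        origin=np.zeros(3),
        indices=idx,
        shape=tuple(idx.max(axis=0) + 1),
    )


class TestENL:
    @pytest.mark.parametrize(
        "layers,expected",
        [
            ((8,), 1.0),  # everything in one layer
            ((3, 3, 3, 3), 4.0),  # four equally filled layers
            ((4, 2, 2), 1.0 / 0.375),  # p = (0.5, 0.25, 0.25) -> 2.6667
        ],
    )
    def test_inverse_simpson_hand_cases(self, layers, expected):
        enl, profile = effective_number_of_layers(grid_from_layers(layers))
        assert enl == pytest.approx(expected, abs=1e-12)
        assert profile.sum() == pytest.approx(1.0, abs=1e-15)

    def test_layer_profile_matches_direct_inverse_simpson(self, rng):
        layers = tuple(rng.integers(1, 20, size=6))
        enl, p = effective_number_of_layers(grid_from_layers(layers))
        direct = np.asarray(layers) / sum(layers)
        assert enl == pytest.approx(1.0 / np.sum(direct**2))
        np.testing.assert_allclose(p, direct)

    def test_invariant_to_point_duplication(self, random_cloud):
        enl1, _ = effective_number_of_layers(voxelize(random_cloud))
        doubled = PointCloud(np.vstack([random_cloud.points] * 2))
        enl2, _ = effective_number_of_layers(voxelize(doubled))
        assert enl1 == enl2

    def test_two_layer_stand_beats_single_layer(self, rng):
        """Vertical stratification raises ENL at equal point count."""
        xy = rng.uniform(0, 11, size=(600, 2))
        single = np.column_stack([xy, rng.uniform(2.0, 3.0, 600)])
        z_two = np.where(
            rng.random(600) < 0.5, rng.uniform(1.0, 2.0, 600), rng.uniform(5.0, 6.0, 600)
        )
        two = np.column_stack([xy, z_two])
        enl_single, _ = effective_number_of_layers(voxelize(PointCloud(single)))
        enl_two, _ = effective_number_of_layers(voxelize(PointCloud(two)))
        assert enl_two > enl_single


class TestCrossSections:
    def test_default_configuration_yields_4500_sections(self, rng):
        pts = rng.uniform([0, 0, 0], [11, 11, 6], size=(5000, 3))
        sections = build_cross_sections(PointCloud(pts), (5.5, 5.5, 1.3))
        assert len(sections) == 4500

    def test_all_points_in_one_sector(self):
        # all points at nearly identical azimuth -> one valid section
        d = np.linspace(1, 3, 10)
        pts = np.column_stack([5.5 + d, np.full(10, 5.5001), np.linspace(0, 4, 10)])
        sections = build_cross_sections(PointCloud(pts), (5.5, 5.5, 1.3), n_sections=360)
        valid = [s for s in sections if not s.is_degenerate]
        assert len(valid) == 1
        assert sum(s.is_degenerate for s in sections) == 359

    def test_area_and_perimeter_match_shapely_oracle(self, rng):
        """Shoelace values equal shapely's on the star-shaped section rings."""
        pts = rng.uniform([0, 0, 0], [11, 11, 8], size=(3000, 3))
        sections = build_cross_sections(PointCloud(pts), (5.5, 5.5, 1.3), n_sections=36)
        checked = 0
        for s in sections:
            if s.is_degenerate:
                continue
            ring = Polygon(np.vstack([[0.0, 0.0], s.vertices]))
            assert s.area == pytest.approx(ring.area, rel=1e-9)
            assert s.perimeter == pytest.approx(ring.length, rel=1e-9)
            checked += 1
        assert checked > 10

    def test_missing_scanner_origin_errors(self, random_cloud):
        with pytest.raises(ValueError, match="scanner_origin"):
            build_cross_sections(random_cloud, None)


class TestFractalDimension:
    @pytest.mark.parametrize("side", [2.0, 3.0, 7.5])
    def test_squares_attain_minimum_of_one(self, side):
        section = CrossSection(0, np.zeros((4, 2)), perimeter=4 * side, area=side**2)
        assert fractal_dimension(section) == pytest.approx(1.0)

    def test_convoluted_polygon_clamped_to_two(self):
        # 2 ln(10) / ln(4) = 3.32 before clamping
        section = CrossSection(0, np.zeros((8, 2)), perimeter=40.0, area=4.0)
        assert fractal_dimension(section) == 2.0

    def test_unit_area_section_excluded(self):
        section = CrossSection(0, np.zeros((4, 2)), perimeter=4.0, area=1.0)
        assert fractal_dimension(section) is None

    def test_degenerate_section_excluded(self):
        section = CrossSection(0, np.zeros((2, 2)), perimeter=0.0, area=0.0)
        assert fractal_dimension(section) is None

    def test_mean_frac_errors_when_nothing_valid(self):
        sections = [CrossSection(i, np.zeros((1, 2)), 0.0, 0.0) for i in range(4)]
        with pytest.raises(ValueError, match="no valid cross sections"):
            mean_frac(sections)


class TestComputeSSCI:
    def test_single_layer_cloud_has_ssci_one(self, rng):
        """ENL = 1 forces SSCI = MeanFrac**ln(1) = 1."""
        pts = np.column_stack(
            [rng.uniform(0, 11, 800), rng.uniform(0, 11, 800), rng.uniform(0.5, 0.6, 800)]
        )
        res = compute_ssci(
            PointCloud(pts), soil_height=0.0, n_sections=90, scanner_origin=(5.5, 5.5, 1.3)
        )
        assert res.enl == pytest.approx(1.0)
        assert res.ssci == pytest.approx(1.0)

    def test_ssci_equals_meanfrac_power_log_enl(self, cloud):
        res = compute_ssci(cloud, n_sections=180)
        assert res.ssci == pytest.approx(res.mean_frac ** math.log(res.enl), abs=1e-15)
        assert res.layer_profile.sum() == pytest.approx(1.0, abs=1e-12)
        assert 1.0 <= res.enl
        assert 1.0 <= res.mean_frac <= 2.0

    def test_ssci_monotone_in_enl_when_meanfrac_above_one(self):
        mfrac = 1.4
        values = [mfrac ** math.log(enl) for enl in np.linspace(1, 20, 40)]
        assert all(b > a for a, b in zip(values, values[1:]))
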