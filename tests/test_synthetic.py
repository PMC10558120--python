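"""Design combinatorics, growth, scan and light generators."""

import numpy as np
import pandas as pd
import pytest

from standweave import synthetic
from standweave.pointcloud import remove_soil_layer
from standweave.synthetic import (
    InvalidPoolError,
    default_species_pool,
    generate_design,
    layout_plot,
    planting_grid,
    simulate_growth,
    simulate_light,
    simulate_scan,
)
from standweave.synthetic.design import SpeciesSpec


class TestDesign:
    @pytest.mark.parametrize("seed", [0, 1, 7, 123456])
    def test_combinatorics_exact_for_every_seed(self, pool, seed):
        df = generate_design(pool, seed).to_frame()
        assert len(df) == 80
        assert df.groupby("richness").size().to_dict() == {1: 20, 2: 30, 4: 30}
        assert df.groupby("mycorrhizal_association").size().to_dict() == {
            "AM": 30, "EM": 30, "AM+EM": 20,
        }
        mono = df[df.richness == 1]
        assert (mono.composition.value_counts() == 2).all()
        assert mono.composition.nunique() == 10
        two = df[df.richness == 2]
        assert two.composition.nunique() == 30  # pairwise distinct
        four = df[df.richness == 4]
        mixed = four[four.mycorrhizal_association == "AM+EM"]
        assert len(mixed) == 10 and mixed.composition.nunique() == 10
        for assoc in ("AM", "EM"):
            pure = four[four.mycorrhizal_association == assoc]
            counts = pure.composition.value_counts()
            assert len(counts) == 5 and (counts == 2).all()  # all 4-subsets, twice
        assert df.block.value_counts().to_dict() == {1: 40, 2: 40}

    def test_pure_plots_contain_only_their_type(self, design):
        for plot in design.plots:
            types = {design.species_pool[s].mycorrhizal_type for s in plot.composition}
            if plot.mycorrhizal_association in ("AM", "EM"):
                assert types == {plot.mycorrhizal_association}
            else:
                assert types == {"AM", "EM"}

    def test_same_seed_reproduces_composition_lists(self, pool):
        a = generate_design(pool, 42).to_frame()
        b = generate_design(pool, 42).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_pool_rejected(self, pool):
        unbalanced = {
            k: (v if k != "EM5" else SpeciesSpec("EM5", "AM", 3.0))
            for k, v in pool.items()
        }
        with pytest.raises(InvalidPoolError):
            generate_design(unbalanced, 0)
        with pytest.raises(InvalidPoolError):
            generate_design({k: pool[k] for k in list(pool)[:8]}, 0)


class TestLayout:
    def test_grid_is_140_positions_at_metre_spacing(self):
        pos = planting_grid()
        assert len(pos) == 140
        assert len({tuple(p) for p in pos}) == 140
        # pairwise minimum spacing of 1 m on the integer grid
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(1.0)
        assert pos.min() == 0.0 and pos.max() == 11.0
        for corner in [(0, 0), (0, 11), (11, 0), (11, 11)]:
            assert corner not in {tuple(p) for p in pos}

    @pytest.mark.parametrize("richness,per_species", [(1, 140), (2, 70), (4, 35)])
    def test_exact_per_species_counts(self, design, pool, richness, per_species):
        plot = next(p for p in design.plots if p.richness == richness)
        trees = layout_plot(plot, seed=5, pool=pool)
        counts = trees.species_id.value_counts()
        assert (counts == per_species).all()
        assert counts.sum() == 140

    def test_seed_changes_positions_not_counts(self, four_species_plot, pool):
        a = layout_plot(four_species_plot, seed=1, pool=pool)
        b = layout_plot(four_species_plot, seed=2, pool=pool)
        assert a.species_id.value_counts().to_dict() == b.species_id.value_counts().to_dict()
        assert (a.species_id != b.species_id).any()


class TestGrowth:
    def test_null_effect_gives_equal_expected_growth_across_richness(self, design, pool):
        """With diversity_effect = 0 the same species grows the same in any plot."""
        sizes = {}
        for richness in (1, 4):
            plots = [p for p in design.plots if p.richness == richness and "AM1" in p.composition]
            d2 = []
            for i, plot in enumerate(plots):
                trees = layout_plot(plot, seed=i, pool=pool)
                grown = simulate_growth(trees, pool, diversity_effect=0.0,
                                        mortality_prob=0.0, seed=i)
                d2.extend(grown.loc[grown.species_id == "AM1", "D2"])
            sizes[richness] = np.mean(d2)
        assert sizes[4] == pytest.approx(sizes[1], rel=0.05)

    @pytest.mark.parametrize("p,expected_alive", [(0.0, 140), (1.0, 0)])
    def test_mortality_extremes(self, census, pool, p, expected_alive):
        out = simulate_growth(census, pool, mortality_prob=p, seed=9)
        assert int(out.alive.sum()) == expected_alive

    def test_dead_trees_keep_planting_size(self, census, pool):
        out = simulate_growth(census, pool, mortality_prob=0.5, seed=9)
        dead = out[~out.alive]
        assert (dead.D2 == dead.D1).all() and (dead.H2 == dead.H1).all()
        alive = out[out.alive]
        assert (alive.D2 >= alive.D1).all() and (alive.H2 >= alive.H1).all()

    def test_positive_effect_raises_volume_increment_with_richness(self, design, pool):
        """Mean per-tree volume increment strictly increases in S (>=200 trees/level)."""
        from standweave.productivity import stem_volume

        means = {}
        for richness in (1, 2, 4):
            plots = [p for p in design.plots if p.richness == richness][:2]
            incr = []
            for i, plot in enumerate(plots):
                trees = layout_plot(plot, seed=100 + i, pool=pool)
                grown = simulate_growth(trees, pool, diversity_effect=0.3,
                                        mortality_prob=0.0, seed=200 + i)
                incr.extend(
                    stem_volume(grown.D2, grown.H2) - stem_volume(grown.D1, grown.H1)
                )
            assert len(incr) >= 200
            means[richness] = np.mean(incr)
        assert means[1] < means[2] < means[4]


class TestScan:
    def test_seeded_determinism(self, mono_plot, census, pool):
        a = simulate_scan(mono_plot, census, pool, seed=7)
        b = simulate_scan(mono_plot, census, pool, seed=7)
        np.testing.assert_array_equal(a.points, b.points)

    def test_stem_only_points_stay_within_stem_radius(self, mono_plot, pool):
        tree = pd.DataFrame(
            {"tree_id": ["t"], "plot_id": [mono_plot.plot_id], "species_id": ["AM1"],
             "x": [5.0], "y": [5.0], "D1": [0.01], "H1": [0.5],
             "D2": [0.08], "H2": [4.0], "alive": [True]}
        )
        cloud = simulate_scan(mono_plot, tree, pool, crown_point_fraction=0.0,
                              noise_sd=0.0, n_ground_points=0, seed=1)
        r = np.hypot(cloud.points[:, 0] - 5.0, cloud.points[:, 1] - 5.0)
        assert r.max() <= 0.04 + 1e-9

    def test_cloud_height_tracks_tallest_tree(self, mono_plot, pool):
        trees = pd.DataFrame(
            {"tree_id": ["a", "b"], "plot_id": mono_plot.plot_id, "species_id": "AM1",
             "x": [3.0, 8.0], "y": [3.0, 8.0], "D1": [0.01, 0.01], "H1": [0.5, 0.5],
             "D2": [0.03, 0.08], "H2": [2.0, 8.0], "alive": True}
        )
        cloud = simulate_scan(mono_plot, trees, pool, noise_sd=0.005,
                              points_per_tree=3000, n_ground_points=0, seed=3)
        # crown points sample the ellipsoid interior, so the observed maximum
        # sits a small finite-sample gap below the 8 m crown apex
        assert cloud.points[:, 2].max() == pytest.approx(8.0, abs=0.15)
        assert cloud.points[:, 2].max() <= 8.0 + 0.05

    def test_ground_layer_removed_by_default_soil_filter(self, cloud):
        cleaned = remove_soil_layer(cloud)
        assert cleaned.points[:, 2].min() > 0.10

    def test_dead_trees_contribute_no_canopy(self, mono_plot, census, pool):
        all_dead = census.assign(alive=False)
        cloud = simulate_scan(mono_plot, all_dead, pool, n_ground_points=50, seed=2)
        assert len(cloud) == 50  # only the ground layer

    def test_empty_census_errors(self, mono_plot, pool):
        from standweave.pointcloud import EmptyCloudError

        with pytest.raises(EmptyCloudError):
            simulate_scan(mono_plot, pd.DataFrame(), pool, seed=0)

    def test_scanner_at_plot_center(self, cloud):
        assert cloud.scanner_origin == (5.5, 5.5, 1.3)


class TestLight:
    def test_no_extinction_recovers_diel_curve(self, mono_plot, census, pool):
        series = simulate_light(mono_plot, census, pool, extinction_k=0.0,
                                noise_sd=0.0, seed=4)
        noon = series[(series.hour % 24 == 12) & (series.sensor_id == 1)]
        assert noon.value.unique() == pytest.approx(1000.0)

    def test_nighttime_readings_are_zero(self, mono_plot, census, pool):
        series = simulate_light(mono_plot, census, pool, seed=4)
        night = series[(series.hour % 24 < 6) | (series.hour % 24 >= 18)]
        assert (night.value == 0).all()
        assert (series.value >= 0).all()
        assert series.sensor_id.nunique() == 4
        assert len(series) == 4 * 31 * 24

    def test_dense_canopy_darker_than_empty_plot(self, mono_plot, census, pool):
        empty = census.assign(alive=False)
        lit = simulate_light(mono_plot, empty, pool, seed=5)
        shaded = simulate_light(mono_plot, census, pool, seed=5)
        assert shaded.value.mean() < lit.value.mean()

    def test_extreme_extinction_blacks_out(self, mono_plot, census, pool):
        series = simulate_light(mono_plot, census, pool, extinction_k=1e6,
                                noise_sd=0.0, seed=6)
        assert series.value.max() == 0.0


def test_pool_stratification_zero_equalizes_species():
    pool = default_species_pool(stratification=0.0)
    h2 = {sp.h2_mean for sp in pool.values()}
    depth = {sp.crown_depth_frac for sp in pool.values()}
    assert len(h2) == 1 and len(depth) == 1


def test_pool_stratification_makes_intolerant_species_taller():
    pool = default_species_pool(stratification=1.0)
    st = np.array([sp.shade_tolerance for sp in pool.values()])
    h2 = np.array([sp.h2_mean for sp in pool.values()])
    assert np.corrcoef(st, h2)[0, 1] < -0.9
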