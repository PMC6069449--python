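"""Scene simulator contracts: grids, endmembers, truth rasters, rendering."""

import numpy as np
import pytest
import shapely

from reefspec import radiometry, scene_sim
from reefspec.core import coral_class_label
from reefspec.errors import (
    EmptyDomainError,
    InvalidParameterError,
)
from conftest import SIX_CLASSES, constant_depth_scene, render_reflectance


class TestWavelengthGrid:
    def test_sensor_grid_spacing_matches_vnir_sampling(self, grid):
        assert len(grid) == 274
        assert grid.centers[0] == 400 and grid.centers[-1] == 1000
        assert grid.spacing == pytest.approx(600 / 273, abs=1e-9)
        assert grid.spacing == pytest.approx(2.2, abs=0.01)

    def test_two_band_grid_is_the_endpoints(self):
        g = scene_sim.make_wavelength_grid(2, 400, 1000)
        assert list(g.centers) == [400, 1000]

    def test_band_nearest_540_found_by_exhaustive_search(self, grid):
        # independent brute-force nearest search over all centers
        best = min(range(len(grid)), key=lambda i: abs(grid.centers[i] - 540))
        assert best == 64
        assert grid.centers[64] == pytest.approx(540.66, abs=0.01)

    @pytest.mark.parametrize("args", [(1, 400, 1000), (274, 1000, 400)])
    def test_invalid_grid_parameters_rejected(self, args):
        with pytest.raises(InvalidParameterError):
            scene_sim.make_wavelength_grid(*args)


class TestEndmembers:
    def test_band_means_strictly_decrease_with_bleaching_level(self):
        lib = scene_sim.synth_endmembers(["Acropora"], range(1, 7), seed=7)
        means = [lib.entries[coral_class_label("Acropora", l)].mean() for l in range(1, 7)]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_same_seed_reproduces_identical_library(self):
        lib1 = scene_sim.synth_endmembers(["A", "B"], [1, 6], seed=1)
        lib2 = scene_sim.synth_endmembers(["A", "B"], [1, 6], seed=1)
        for label in lib1.entries:
            np.testing.assert_array_equal(lib1.entries[label], lib2.entries[label])

    def test_bleached_levels_elevated_near_400_and_750_nm(self, library, grid):
        l1 = library.entries[coral_class_label("Acropora", 1)]
        l6 = library.entries[coral_class_label("Acropora", 6)]
        for nm in (400.0, 750.0):
            b = int(np.argmin(np.abs(grid.centers - nm)))
            peak = int(np.argmin(np.abs(grid.centers - 565.0)))
            # relative to the healthy spectrum, the bleached one is boosted
            # at the bleaching wavelengths beyond its overall brightening
            assert l1[b] / l6[b] > l1[peak] / l6[peak]

    def test_all_spectra_within_unit_interval(self, library):
        for spec in library.entries.values():
            assert spec.min() >= 0 and spec.max() <= 1

    def test_empty_genera_rejected(self):
        with pytest.raises(InvalidParameterError):
            scene_sim.synth_endmembers([], [1], seed=0)


class TestMakeScene:
    def test_single_class_scene_is_all_sand(self):
        truth = scene_sim.make_scene((8, 8), ["sand"], 3.0, seed=0)
        assert set(truth.label_raster().ravel()) == {"sand"}

    def test_all_requested_classes_present_and_depth_spans_range(self, library):
        truth = scene_sim.make_scene(
            (128, 128), SIX_CLASSES, 6.0, seed=3, library=library
        )
        present = set(truth.label_raster().ravel())
        assert set(SIX_CLASSES) <= present
        assert truth.depth.min() == 0 and truth.depth.max() == pytest.approx(6.0)

    def test_fixed_seed_reproduces_truth(self, library):
        a = scene_sim.make_scene((32, 32), SIX_CLASSES, 3.0, seed=9, library=library)
        b = scene_sim.make_scene((32, 32), SIX_CLASSES, 3.0, seed=9, library=library)
        np.testing.assert_array_equal(a.class_ids, b.class_ids)
        np.testing.assert_array_equal(a.depth, b.depth)

    def test_more_classes_than_pixels_rejected(self, library):
        with pytest.raises(InvalidParameterError):
            scene_sim.make_scene((1, 2), SIX_CLASSES, 3.0, seed=0, library=library)


class TestRenderCube:
    def test_zero_depth_zero_noise_is_bottom_plus_offset(self, library, water):
        truth = constant_depth_scene(SIX_CLASSES[0], 0.0, library)
        cube, white = scene_sim.render_cube(truth, water, noise_sd=0.0, seed=0)
        r_obs = cube.values / white
        cid = truth.class_names.index(SIX_CLASSES[0])
        expected = library.entries[SIX_CLASSES[0]] + water.offset
        got = r_obs[truth.class_ids == cid]
        np.testing.assert_allclose(
            got, np.broadcast_to(expected, got.shape), rtol=1e-12
        )

    def test_reflectance_roundtrip_recovers_observed_reflectance(self, reef_scene, water):
        cube, white = scene_sim.render_cube(reef_scene, water, noise_sd=0.0, seed=0)
        refl = radiometry.to_reflectance(cube, white)
        np.testing.assert_allclose(refl.values, cube.values / white, atol=1e-12)

    def test_spectral_distance_between_depths_grows_with_separation(self, library, water):
        cls = SIX_CLASSES[3]
        specs = {}
        for z in (1.0, 1.6, 2.3):
            truth = constant_depth_scene(cls, z, library)
            refl = render_reflectance(truth, water)
            cid = truth.class_names.index(cls)
            specs[z] = refl.values[truth.class_ids == cid].mean(axis=0)
        d_short = np.abs(specs[1.0] - specs[1.6]).mean()
        d_long = np.abs(specs[1.0] - specs[2.3]).mean()
        assert 0 < d_short < d_long

    def test_band_mean_reflectance_nonincreasing_in_depth(self, library, water):
        cls = SIX_CLASSES[0]
        means = []
        for z in np.linspace(0, 3, 7):
            truth = constant_depth_scene(cls, z, library)
            refl = render_reflectance(truth, water)
            cid = truth.class_names.index(cls)
            means.append(refl.values[truth.class_ids == cid].mean())
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_rendered_radiance_nonnegative_under_noise(self, reef_scene, water):
        cube, _ = scene_sim.render_cube(reef_scene, water, noise_sd=0.05, seed=2)
        assert cube.values.min() >= 0

    def test_render_deterministic_for_fixed_seed(self, reef_scene, water):
        a, _ = scene_sim.render_cube(reef_scene, water, noise_sd=0.01, seed=11)
        b, _ = scene_sim.render_cube(reef_scene, water, noise_sd=0.01, seed=11)
        np.testing.assert_array_equal(a.values, b.values)


class TestSurveyTable:
    def test_records_verifiable_against_truth_raster(self, reef_scene):
        table = scene_sim.make_survey_table(reef_scene, 64, seed=5)
        assert len(table) == 64
        labels = reef_scene.label_raster()
        for _, rec in table.df.iterrows():
            r, c = int(rec["Pixel y"]), int(rec["Pixel x"])
            assert labels[r, c] == coral_class_label(
                rec["Coral Type"], rec["Lv Bleached"]
            )
            assert rec["Depth"] == pytest.approx(reef_scene.depth[r, c])

    def test_zero_points_gives_empty_table_with_header(self, reef_scene):
        table = scene_sim.make_survey_table(reef_scene, 0, seed=0)
        assert len(table) == 0
        assert list(table.df.columns)[:10] == list(
            scene_sim.SURVEY_COLUMNS
        )

    def test_latlon_roundtrip_to_own_pixel(self, reef_scene):
        from reefspec.cube_io import geo_to_pixel

        table = scene_sim.make_survey_table(reef_scene, 20, seed=6)
        for _, rec in table.df.iterrows():
            r, c = geo_to_pixel(
                reef_scene.geotransform, rec["Latitude"], rec["Longitude"]
            )
            assert (r, c) == (int(rec["Pixel y"]), int(rec["Pixel x"]))

    def test_sampling_coral_free_scene_rejected(self):
        truth = scene_sim.make_scene((8, 8), ["sand"], 3.0, seed=0)
        with pytest.raises(EmptyDomainError):
            scene_sim.make_survey_table(truth, 4, seed=0)


class TestAddSpume:
    def test_empty_polygon_set_is_identity(self, reef_scene):
        out = scene_sim.add_spume(reef_scene, [])
        np.testing.assert_array_equal(out.class_ids, reef_scene.class_ids)

    def test_polygon_covering_scene_relabels_everything(self, reef_scene):
        gt = reef_scene.geotransform
        la, lo = gt.forward(-1, -1)
        lb, lob = gt.forward(*(s + 1 for s in reef_scene.shape))
        box = shapely.box(min(lo, lob), min(la, lb), max(lo, lob), max(la, lb))
        out = scene_sim.add_spume(reef_scene, [box])
        assert set(out.label_raster().ravel()) == {scene_sim.SPUME}

    def test_integer_snapped_square_relabels_exactly_100_pixels(self, reef_scene):
        gt = reef_scene.geotransform
        la, lo = gt.forward(10 - 0.5, 20 - 0.5)
        lb, lob = gt.forward(19 + 0.5, 29 + 0.5)
        box = shapely.box(min(lo, lob), min(la, lb), max(lo, lob), max(la, lb))
        # brute-force point-in-polygon oracle over every pixel center
        expected = sum(
            shapely.Point(gt.forward(r, c)[1], gt.forward(r, c)[0]).intersects(box)
            for r in range(reef_scene.shape[0])
            for c in range(reef_scene.shape[1])
        )
        assert expected == 100
        out = scene_sim.add_spume(reef_scene, [box])
        assert int(np.sum(out.label_raster() == scene_sim.SPUME)) == 100

    def test_polygon_outside_scene_warns_and_leaves_truth_unchanged(self, reef_scene):
        box = shapely.box(0.0, 0.0, 0.1, 0.1)  # far from the reef coordinates
        with pytest.warns(UserWarning):
            out = scene_sim.add_spume(reef_scene, [box])
        np.testing.assert_array_equal(out.class_ids, reef_scene.class_ids)
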