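"""Georeferencing, signature extraction and match scoring."""

import numpy as np
import pandas as pd
import pytest

from reefspec import scene_sim, signatures
from reefspec.core import (
    SURVEY_COLUMNS,
    AttributeTable,
    GeoTransform,
    SpectralCube,
    WavelengthGrid,
    coral_class_label,
)
from reefspec.errors import InvalidParameterError, ShapeError
from reefspec.signatures import SpectralSignature
from conftest import SIX_CLASSES, render_reflectance


def make_sig(mean, sd=None, grid=None, label="x", n=1):
    mean = np.asarray(mean, dtype=float)
    grid = grid or WavelengthGrid(np.linspace(400, 700, mean.size))
    sd = np.zeros_like(mean) if sd is None else np.asarray(sd, dtype=float)
    return SpectralSignature(label=label, mean=mean, sd=sd, n_pixels=n, grid=grid)


def record(lat, lon, genus="Acropora", level=3, px=None, py=None):
    return {
        "Photo ID": 1,
        "Coral Type": genus,
        "Lv Bleached": level,
        "Bleached": "No",
        "Depth": 1.0,
        "Notes": "",
        "Latitude": lat,
        "Longitude": lon,
        "Pixel x": px,
        "Pixel y": py,
    }


class TestGeoreference:
    def test_origin_maps_to_pixel_zero(self):
        table = AttributeTable(pd.DataFrame([record(0.0, 0.0)], columns=SURVEY_COLUMNS))
        out = signatures.georeference_survey(table, GeoTransform())
        assert (out.df.loc[0, "Pixel x"], out.df.loc[0, "Pixel y"]) == (0, 0)

    def test_recovers_sampler_pixels_exactly(self, reef_scene):
        table = scene_sim.make_survey_table(reef_scene, 30, seed=4)
        blank = table.copy()
        blank.df["Pixel x"] = pd.NA
        blank.df["Pixel y"] = pd.NA
        out = signatures.georeference_survey(blank, reef_scene.geotransform)
        assert out.df["Pixel x"].tolist() == table.df["Pixel x"].tolist()
        assert out.df["Pixel y"].tolist() == table.df["Pixel y"].tolist()

    def test_out_of_bounds_record_flagged_not_dropped(self):
        gt = GeoTransform()
        table = AttributeTable(
            pd.DataFrame(
                [record(2.0, 2.0), record(2.0, 5.0)], columns=SURVEY_COLUMNS
            )
        )
        out = signatures.georeference_survey(table, gt, shape=(4, 5))
        assert len(out) == 2
        assert out.df["Out of Bounds"].tolist() == [False, True]


class TestExtractSignatures:
    def reflectance_cube(self, values):
        grid = WavelengthGrid(np.linspace(400, 700, values.shape[2]))
        return SpectralCube(values=values, grid=grid, kind="reflectance")

    def test_window_one_single_record_equals_pixel_spectrum(self):
        values = np.random.default_rng(0).random((4, 4, 6))
        cube = self.reflectance_cube(values)
        table = AttributeTable(
            pd.DataFrame([record(0, 0, px=2, py=1)], columns=SURVEY_COLUMNS)
        )
        sigs = signatures.extract_signatures(cube, table, window=1)
        sig = sigs[coral_class_label("Acropora", 3)]
        np.testing.assert_array_equal(sig.mean, values[1, 2])
        assert sig.n_pixels == 1

    def test_identical_spectra_give_zero_sd(self):
        values = np.tile(np.linspace(0.1, 0.6, 6), (4, 4, 1))
        cube = self.reflectance_cube(values)
        table = AttributeTable(
            pd.DataFrame(
                [record(0, 0, px=1, py=1), record(0, 0, px=3, py=2)],
                columns=SURVEY_COLUMNS,
            )
        )
        sigs = signatures.extract_signatures(cube, table, window=1)
        np.testing.assert_array_equal(
            sigs[coral_class_label("Acropora", 3)].sd, 0.0
        )

    def test_even_window_rejected(self):
        cube = self.reflectance_cube(np.zeros((2, 2, 3)))
        with pytest.raises(InvalidParameterError):
            signatures.extract_signatures(cube, AttributeTable.empty(), window=2)

    def test_empty_table_gives_empty_set(self):
        cube = self.reflectance_cube(np.zeros((2, 2, 3)))
        assert signatures.extract_signatures(cube, AttributeTable.empty()) == {}

    def test_noise_free_signature_matches_forward_model(self, reef_scene, water):
        refl = render_reflectance(reef_scene, water)
        table = scene_sim.make_survey_table(reef_scene, 40, seed=3)
        sigs = signatures.extract_signatures(refl, table, window=1)
        for label, sig in sigs.items():
            recs = table.df[table.class_labels() == label]
            expected = np.mean(
                [
                    reef_scene.library.entries[label]
                    * np.exp(
                        -2
                        * water.k
                        * reef_scene.depth[int(r["Pixel y"]), int(r["Pixel x"])]
                    )
                    + water.offset
                    for _, r in recs.iterrows()
                ],
                axis=0,
            )
            np.testing.assert_allclose(sig.mean, expected, atol=1e-12)

    def test_window_mean_equals_mean_of_raw_pixels(self, reef_scene, water):
        refl = render_reflectance(reef_scene, water)
        table = scene_sim.make_survey_table(reef_scene, 20, seed=9)
        sigs = signatures.extract_signatures(refl, table, window=3)
        X, y = signatures.training_pixels(refl, table, window=3)
        for label, sig in sigs.items():
            np.testing.assert_allclose(
                sig.mean, X[y == label].mean(axis=0), atol=1e-12
            )

    def test_nearest_endmember_identifies_class_on_noise_free_scene(
        self, reef_scene, water
    ):
        # oracle: exhaustive search over the depth-attenuated library
        refl = render_reflectance(reef_scene, water)
        table = scene_sim.make_survey_table(reef_scene, 30, seed=12)
        for _, rec in table.df.iterrows():
            r, c = int(rec["Pixel y"]), int(rec["Pixel x"])
            pixel = refl.values[r, c]
            z = reef_scene.depth[r, c]
            best, best_d = None, np.inf
            for label in SIX_CLASSES:
                model = (
                    reef_scene.library.entries[label] * np.exp(-2 * water.k * z)
                    + water.offset
                )
                d = np.linalg.norm(pixel - model)
                if d < best_d:
                    best, best_d = label, d
            assert best == coral_class_label(rec["Coral Type"], rec["Lv Bleached"])


class TestMatchScore:
    def test_identical_signatures_score_100(self):
        sig = make_sig(np.linspace(0.1, 0.5, 8))
        assert signatures.signature_match_score(sig, sig) == 100.0

    def test_large_uniform_offset_scores_zero(self):
        ref = make_sig(np.linspace(0.1, 0.5, 8))
        cand = make_sig(ref.mean + 10 * 0.10 * np.ptp(ref.mean))
        assert signatures.signature_match_score(cand, ref, 0.10) == 0.0

    def test_half_band_mismatch_scores_50(self):
        ref = make_sig(np.linspace(0.1, 0.5, 8))
        offset = np.zeros(8)
        offset[:4] = 10 * 0.10 * np.ptp(ref.mean)
        cand = make_sig(ref.mean + offset)
        assert signatures.signature_match_score(cand, ref, 0.10) == 50.0

    def test_score_symmetric(self):
        rng = np.random.default_rng(5)
        a = make_sig(rng.random(16) * 0.5)
        b = make_sig(rng.random(16) * 0.5)
        assert signatures.signature_match_score(
            a, b
        ) == signatures.signature_match_score(b, a)

    def test_grid_mismatch_rejected(self):
        a = make_sig(np.zeros(4))
        b = make_sig(np.zeros(5))
        with pytest.raises(ShapeError):
            signatures.signature_match_score(a, b)


class TestSeparableBands:
    def test_identical_signatures_have_no_separable_bands(self):
        sig = make_sig(np.linspace(0.1, 0.5, 8))
        assert signatures.separable_bands(sig, sig, 0.01).size == 0

    def test_disjoint_constant_signatures_all_bands(self):
        a = make_sig(np.full(8, 0.2))
        b = make_sig(np.full(8, 0.6))
        assert signatures.separable_bands(a, b, 0.1).size == 8

    def test_localized_difference_found_by_exhaustive_scan(self):
        grid = WavelengthGrid(np.linspace(390, 800, 100))
        lam = grid.centers
        bump = np.exp(-0.5 * ((lam - 400) / 15) ** 2) + np.exp(
            -0.5 * ((lam - 750) / 15) ** 2
        )
        a = make_sig(np.full(100, 0.3), grid=grid)
        b = make_sig(np.clip(0.3 + 0.2 * bump, 0, 1), grid=grid)
        bands = signatures.separable_bands(a, b, min_gap=0.05)
        expected = np.flatnonzero(np.abs(b.mean - a.mean) >= 0.05)
        np.testing.assert_array_equal(bands, expected)
        assert np.all(
            (lam[bands] < 470) | (lam[bands] > 680)
        )  # concentrated at the bump regions
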