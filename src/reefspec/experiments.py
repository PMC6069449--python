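"""Seeded end-to-end recovery experiments on synthetic reef scenes.

These functions wire the simulator and the pipeline stages into the
standard validation experiments: per-class recall on a noisy scene,
the spume-contamination/exclusion comparison, log-ratio bathymetry
rank correlation and albedo sensitivity, and the depth-effect reduction
check.  They are used by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import shapely

from . import bathymetry, classify, radiometry, scene_sim, signatures
from .core import coral_class_label
from .cube_io import rasterize_polygons

#: The six coral classes of the standard recovery scene: two genera at
#: alternating bleaching levels.
STANDARD_CLASSES = [
    coral_class_label(g, l)
    for g, l in [
        ("Acropora", 1),
        ("Acropora", 3),
        ("Acropora", 5),
        ("Porites massive", 2),
        ("Porites massive", 4),
        ("Porites massive", 6),
    ]
]


def _reflectance(truth, water, noise_sd, seed):
    cube, white = scene_sim.render_cube(truth, water, noise_sd=noise_sd, seed=seed)
    return radiometry.to_reflectance(cube, white)


def recall_experiment(
    seed: int,
    shape=(128, 128),
    max_depth: float = 3.0,
    noise_sd: float = 0.01,
    n_points: int = 64,
    window: int = 3,
) -> dict[str, float]:
    """Per-class recall of the depth-corrected RBF-SVM map vs scene truth.

    Standard conditions: six coral classes over sand, 0-3 m depth
    gradient, 1% reflectance noise, 64 survey points, 3x3 training
    windows.
    """
    truth = scene_sim.make_scene(shape, STANDARD_CLASSES, max_depth, seed=seed)
    water = scene_sim.default_water_model(truth.library.grid, max_depth)
    refl = _reflectance(truth, water, noise_sd, seed)
    corrected, _ = bathymetry.depth_correct(refl)
    table = scene_sim.make_survey_table(truth, n_points, seed=seed + 1)
    table = signatures.georeference_survey(table, truth.geotransform, truth.shape)
    X, y = signatures.training_pixels(corrected, table, window)
    model = classify.train_classifier(X, y)
    cmap = classify.predict_map(model, corrected)
    predicted = cmap.labels()
    labels = truth.label_raster()
    return {
        cls: float(np.mean(predicted[labels == cls] == cls))
        for cls in STANDARD_CLASSES
    }


def _half_blob_polygon(truth, label):
    """Axis-aligned polygon over the upper half of a class's blob."""
    tid = truth.class_names.index(label)
    rr, cc = np.where(truth.class_ids == tid)
    rmid = (rr.min() + rr.max()) // 2
    gt = truth.geotransform
    la, lo = gt.forward(rr.min() - 0.5, cc.min() - 0.5)
    lb, lob = gt.forward(rmid + 0.5, cc.max() + 0.5)
    return shapely.box(min(lo, lob), min(la, lb), max(lo, lob), max(la, lb))


def spume_experiment(
    seed: int,
    shape=(128, 128),
    max_depth: float = 3.0,
    noise_sd: float = 0.01,
    n_points: int = 64,
    window: int = 3,
):
    """Recall with and without spume exclusion on a contaminated scene.

    Spume polygons overlay parts of two coral blobs: foam obscures the
    coral recorded by the in-water survey beneath it.  Without exclusion
    those pixels enter training, mapping and assessment; with exclusion
    they are masked out of all three.  Recall is computed against the
    pre-spume coral truth over each run's assessed pixels.  Returns
    ``(recall_without_exclusion, recall_with_exclusion)``.
    """
    truth = scene_sim.make_scene(shape, STANDARD_CLASSES, max_depth, seed=seed)
    water = scene_sim.default_water_model(truth.library.grid, max_depth)
    polygons = [
        _half_blob_polygon(truth, coral_class_label("Porites massive", 4)),
        _half_blob_polygon(truth, coral_class_label("Acropora", 3)),
    ]
    contaminated = scene_sim.add_spume(truth, polygons)
    refl = _reflectance(contaminated, water, noise_sd, seed)
    corrected, _ = bathymetry.depth_correct(refl)
    table = scene_sim.make_survey_table(contaminated, n_points, seed=seed + 1)
    table = signatures.georeference_survey(table, truth.geotransform, truth.shape)
    mask = rasterize_polygons(polygons, truth.geotransform, truth.shape)
    labels = truth.label_raster()  # pre-spume ground truth

    def run(exclude: bool) -> dict[str, float]:
        X, y = signatures.training_pixels(
            corrected, table, window, exclude_mask=mask if exclude else None
        )
        model = classify.train_classifier(X, y)
        cmap = classify.predict_map(model, corrected, mask=mask if exclude else None)
        predicted = cmap.labels()
        return {
            cls: float(
                np.mean(predicted[(labels == cls) & cmap.valid] == cls)
            )
            for cls in STANDARD_CLASSES
        }

    return run(False), run(True)


def bathymetry_experiment(seed: int, shape=(64, 64), max_depth: float = 3.0):
    """Rank correlation of the relative depth index with true depth, and
    the albedo-driven vs depth-driven index spreads.

    Returns ``(spearman_rho, albedo_spread, depth_spread_per_metre)``;
    spreads are measured between bright sand and dark benthos at constant
    depths 1/1.5/2 m versus a 1 m depth change over sand.
    """
    from scipy.stats import spearmanr

    library = scene_sim.synth_endmembers(
        ["Acropora", "Porites massive"], range(1, 7), seed=seed
    )
    water = scene_sim.default_water_model(library.grid, max_depth)
    truth = scene_sim.make_scene(shape, ["sand"], max_depth, seed=seed, library=library)
    refl = _reflectance(truth, water, 0.0, seed)
    relmap = bathymetry.relative_depth_log_ratio(refl)
    rho = float(
        spearmanr(
            relmap.values[relmap.valid].ravel(), truth.depth[relmap.valid].ravel()
        ).statistic
    )

    def mean_index(cls, z):
        t = scene_sim.make_scene(
            (6, 6), [cls], max_depth, seed=seed, library=library, constant_depth=z
        )
        r = _reflectance(t, water, 0.0, seed)
        return float(np.nanmean(bathymetry.relative_depth_log_ratio(r).values))

    albedo_spread = max(
        abs(mean_index("sand", z) - mean_index("benthos", z)) for z in (1.0, 1.5, 2.0)
    )
    depth_spread = abs(mean_index("sand", 2.0) - mean_index("sand", 1.0))
    return rho, albedo_spread, depth_spread


def depth_effect_experiment(seed: int, depths=(1.0, 2.3)):
    """Mean absolute band gap between same-class spectra at two depths,
    before and after water-column correction.

    Returns ``(gap_uncorrected, gap_corrected)``.
    """
    cls = coral_class_label("Porites massive", 4)
    library = scene_sim.synth_endmembers(["Porites massive"], [4], seed=seed)
    water = scene_sim.default_water_model(library.grid)

    def class_mean(z, correct):
        truth = scene_sim.make_scene(
            (6, 6), [cls], 3.0, seed=seed, library=library, constant_depth=z
        )
        refl = _reflectance(truth, water, 0.0, seed)
        if correct:
            refl, _ = bathymetry.depth_correct(refl)
        cid = truth.class_names.index(cls)
        return refl.values[truth.class_ids == cid].mean(axis=0)

    z1, z2 = depths
    raw = float(np.abs(class_mean(z1, False) - class_mean(z2, False)).mean())
    corrected = float(np.abs(class_mean(z1, True) - class_mean(z2, True)).mean())
    return raw, corrected
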