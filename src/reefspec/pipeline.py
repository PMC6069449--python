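"""End-to-end workflow: reflectance -> depth correction -> signatures ->
indices -> classification -> accuracy report.

Stage order follows the survey-to-map workflow: radiometric conversion
first, then water-depth estimation and correction, signature extraction at
georeferenced survey points, bleaching-index evaluation, denoising,
supervised classification with optional spume exclusion, and finally the
accuracy assessment.  All randomness funnels through the single config
seed; every stage's output is persisted so subcommands can resume from
intermediate files.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import accuracy as acc
from . import bathymetry, classify, cube_io, indices, radiometry, signatures
from .core import AttributeTable, SpectralCube
from .errors import CalibrationError, OutOfRangeError, ReefspecError

log = logging.getLogger("reefspec")

#: Depth beyond which band-ratio classification degrades sharply (m).
DEPTH_LIMIT_M = 8.0


@dataclass
class PipelineConfig:
    """Paths and tunables for a full pipeline run."""

    cube_path: str = "scene.img"
    white_path: str = "white_reference.csv"
    survey_path: str = "survey.csv"
    polygons_path: str = ""  # optional GeoJSON of spume polygons
    truth_labels_path: str = ""  # optional truth label raster (EA prevalence)
    truth_classes_path: str = ""  # its id,name sidecar
    out_dir: str = "out"
    gamma_increase: float = 0.0
    blue_nm: float = 480.0
    green_nm: float = 540.0
    stretch_n: float = 1000.0
    svm_gamma: str = "scale"  # or a positive float as text
    svm_c: float = 10.0
    spectral_window: int = 5
    spatial_window: int = 3
    extract_window: int = 3
    found_window: int = 3
    ea_factor: float = 5.0
    exclude_spume: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a plain-text ``key = value`` config file."""
        cfg = cls()
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if not hasattr(cfg, key):
                raise ReefspecError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, val.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(val))
            elif isinstance(current, float):
                setattr(cfg, key, float(val))
            else:
                setattr(cfg, key, val)
        return cfg

    def to_file(self, path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    def svm_gamma_value(self):
        try:
            return float(self.svm_gamma)
        except ValueError:
            return self.svm_gamma


def _load_polygons(path):
    import shapely

    if not path:
        return []
    data = json.loads(Path(path).read_text())
    feats = data.get("features", [data]) if isinstance(data, dict) else data
    geoms = []
    for f in feats:
        geom = f.get("geometry", f) if isinstance(f, dict) else f
        geoms.append(shapely.geometry.shape(geom))
    return geoms


def run_pipeline(config: PipelineConfig):
    """Execute the full workflow; returns (ClassMap, AccuracyReport, index stack).

    Every stage's outputs are written under ``config.out_dir``; a stage
    failure aborts with the stage name so completed artifacts remain.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}
    stage = "load"
    try:
        cube = cube_io.read_cube(config.cube_path)
        grid, white = radiometry.read_white_reference(config.white_path)
        table = cube_io.read_survey_csv(config.survey_path)
        polygons = _load_polygons(config.polygons_path)

        stage = "reflectance"
        refl = radiometry.to_reflectance(cube, white)
        if config.gamma_increase > 0:
            refl = radiometry.gamma_adjust(refl, config.gamma_increase)
        manifest["stages"].append(stage)

        stage = "georeference"
        table = signatures.georeference_survey(
            table, cube.geotransform, shape=refl.values.shape[:2]
        )
        cube_io.write_survey_csv(table, out / "survey_georeferenced.csv")
        manifest["stages"].append(stage)

        stage = "depth"
        wcm = bathymetry.WaterColumnModel(
            blue_nm=config.blue_nm, green_nm=config.green_nm
        )
        relmap = bathymetry.relative_depth_log_ratio(refl, wcm, config.stretch_n)
        depth_m = None
        try:
            depth_m = bathymetry.calibrate_depth(relmap, table)
            cube_io.write_raster(
                np.nan_to_num(depth_m.values), out / "depth.img", cube.geotransform
            )
            manifest["calibration"] = {
                "slope": depth_m.slope, "intercept": depth_m.intercept
            }
            if np.nanmedian(depth_m.values) > DEPTH_LIMIT_M:
                warnings.warn(
                    "calibrated depths exceed the ~6-8 m limit of band-ratio "
                    "classification; results beyond that depth are unreliable"
                )
        except CalibrationError as exc:
            log.warning("depth calibration skipped: %s", exc)
        corrected, _ = bathymetry.depth_correct(refl, wcm)
        manifest["stages"].append(stage)

        stage = "signatures"
        sigs = signatures.extract_signatures(corrected, table, config.extract_window)
        sigs.to_csv(out / "signatures.csv")
        manifest["stages"].append(stage)

        stage = "indices"
        stack = {}
        for name, (l1, l2) in indices.ND_INDEX_REGISTRY.items():
            try:
                stack[name] = indices.nd_index(corrected, l1, l2)
            except OutOfRangeError:
                log.warning("index %s skipped: wavelengths outside grid", name)
        try:
            stack["GenusIndex"] = indices.genus_index(corrected)
        except OutOfRangeError:
            log.warning("genus index skipped: wavelengths outside grid")
        manifest["stages"].append(stage)

        stage = "denoise"
        smooth = classify.denoise(
            corrected, config.spectral_window, config.spatial_window
        )
        manifest["stages"].append(stage)

        stage = "classify"
        exclusion = cube_io.rasterize_polygons(
            polygons, cube.geotransform, smooth.values.shape[:2]
        )
        train_mask = exclusion if config.exclude_spume else None
        X, y = signatures.training_pixels(
            smooth, table, config.extract_window, exclude_mask=train_mask
        )
        model = classify.train_classifier(
            X, y, gamma=config.svm_gamma_value(), C=config.svm_c
        )
        cmap = classify.predict_map(
            model, smooth, mask=exclusion if config.exclude_spume else None
        )
        cube_io.write_raster(
            cmap.class_ids, out / "classmap.img", cube.geotransform, data_type=3
        )
        (out / "classmap.legend.txt").write_text(
            "\n".join(f"{i},{n}" for i, n in cmap.legend.items()) + "\n"
        )
        manifest["stages"].append(stage)

        stage = "assess"
        prevalence = None
        if config.truth_labels_path and config.truth_classes_path:
            truth_ids = cube_io.read_raster(config.truth_labels_path).astype(int)
            names = dict(
                line.split(",", 1)
                for line in Path(config.truth_classes_path).read_text().splitlines()
                if line.strip()
            )
            prevalence = {
                name: 100.0 * float(np.mean(truth_ids == int(i)))
                for i, name in names.items()
            }
        report = acc.build_report(
            cmap,
            table,
            sigs,
            sigs,
            reference_prevalence=prevalence,
            ea_factor=config.ea_factor,
            found_window=config.found_window,
        )
        report.to_csv(out / "accuracy_report.csv")
        manifest["stages"].append(stage)
    except ReefspecError as exc:
        raise ReefspecError(
            f"pipeline failed at stage {stage!r}: {exc}; completed stages "
            f"{manifest['stages']} persisted under {out}"
        ) from exc
    config.to_file(out / "config_echo.txt")
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return cmap, report, stack
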