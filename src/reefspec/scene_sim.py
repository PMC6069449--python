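"""Synthetic shallow-reef hyperspectral scene generation.

Provides ground-truth scenes for exercising the full mapping pipeline:
per-(genus, bleaching level) coral endmember spectra, a sand/benthos/water
background, a smooth depth gradient, Lambert-Beer two-way water-column
attenuation, per-band illumination and sensor noise, and an in-water
survey table sampled from the truth rasters.

Bleaching levels follow the six-point visual scale: level 1 is severely
bleached (brightest), level 6 unbleached.  Endmember spectra are smooth
synthetic curves built so that (a) band-mean brightness strictly decreases
from level 1 to 6 within a genus, and (b) bleached levels (1-2) carry
elevated reflectance near 400 nm and 750 nm relative to healthy coral.
They are not measured coral spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .core import (
    RADIANCE,
    SURVEY_COLUMNS,
    AttributeTable,
    GeoTransform,
    SpectralCube,
    WavelengthGrid,
    coral_class_label,
    parse_class_label,
)
from .cube_io import rasterize_polygons
from .errors import EmptyDomainError, InvalidParameterError, ShapeError

SAND = "sand"
BENTHOS = "benthos"
WATER = "water"
SPUME = "spume"
BACKGROUND_CLASSES = (SAND, BENTHOS, WATER, SPUME)

#: Flat spume (sea foam) reflectance; bright surface artifact.
SPUME_REFLECTANCE = 0.9


def make_wavelength_grid(n_bands: int, lambda_min: float, lambda_max: float) -> WavelengthGrid:
    """Uniform band-center grid from ``lambda_min`` to ``lambda_max`` (nm).

    The default sensor configuration, ``make_wavelength_grid(274, 400, 1000)``,
    reproduces a 274-band VNIR scanner with ~2.2 nm sampling.
    """
    if n_bands < 2:
        raise InvalidParameterError("need at least two bands")
    if not lambda_min < lambda_max:
        raise InvalidParameterError("lambda_min must be < lambda_max")
    return WavelengthGrid(np.linspace(lambda_min, lambda_max, int(n_bands)))


def sensor_grid() -> WavelengthGrid:
    """The default 274-band 400-1000 nm VNIR grid."""
    return make_wavelength_grid(274, 400.0, 1000.0)


# ---------------------------------------------------------------------------
# Endmember library


@dataclass
class EndmemberLibrary:
    """Reflectance spectrum per class label on a shared wavelength grid."""

    grid: WavelengthGrid
    entries: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for label, spec in self.entries.items():
            spec = np.asarray(spec, dtype=float)
            if spec.shape != (len(self.grid),):
                raise ShapeError(f"endmember {label!r} does not match the grid")
            if spec.min() < 0 or spec.max() > 1:
                raise InvalidParameterError(f"endmember {label!r} outside [0, 1]")
            self.entries[label] = spec

    def labels(self) -> list[str]:
        return list(self.entries)

    def as_matrix(self, labels) -> np.ndarray:
        return np.stack([self.entries[lb] for lb in labels])


def _gauss(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def _coral_base_shape(lam: np.ndarray) -> np.ndarray:
    # Green-brown peak around 565 nm typical of zooxanthellate coral;
    # low blue and NIR reflectance.
    return 0.12 + 0.55 * _gauss(lam, 565.0, 50.0)


def _background_spectra(lam: np.ndarray) -> dict[str, np.ndarray]:
    sand = 0.40 + 0.0002 * (lam - 400.0)
    # Benthos: dark vegetation, spectrally correlated with sand in the
    # blue-green (the regime where band-ratio bathymetry is valid) plus a
    # red-edge shoulder.
    benthos = 0.22 * sand + 0.10 / (1.0 + np.exp(-(lam - 700.0) / 20.0))
    water = np.full_like(lam, 0.02) + 0.015 * _gauss(lam, 430.0, 60.0)
    spume = np.full_like(lam, SPUME_REFLECTANCE)
    return {
        SAND: np.clip(sand, 0, 1),
        BENTHOS: np.clip(benthos, 0, 1),
        WATER: np.clip(water, 0, 1),
        SPUME: spume,
    }


def synth_endmembers(
    genera,
    levels,
    seed: int,
    grid: WavelengthGrid | None = None,
) -> EndmemberLibrary:
    """Deterministic synthetic endmember library for ``genera`` x ``levels``.

    Per genus, the spectrum at level *l* is a genus-specific smooth shape
    scaled by a strictly decreasing brightness factor, with additional
    400/750 nm bumps for bleached levels 1-2.  Genus-to-genus variation is
    confined to the red/NIR region so that the blue-green spectral slope
    (which drives the log-ratio bathymetry) is shared across corals.
    """
    genera = list(genera)
    if not genera:
        raise InvalidParameterError("empty genera list")
    levels = sorted(set(int(l) for l in levels))
    if not levels or not set(levels) <= set(range(1, 7)):
        raise InvalidParameterError("levels must be a subset of 1..6")
    grid = grid or sensor_grid()
    lam = grid.centers
    rng = np.random.default_rng(seed)
    base = _coral_base_shape(lam)
    bleach_bump = _gauss(lam, 400.0, 30.0) + _gauss(lam, 750.0, 30.0)
    bump_amp = {1: 0.18, 2: 0.09}
    entries: dict[str, np.ndarray] = {}
    for genus in genera:
        shape = base.copy()
        # red/NIR genus features only (580-720 nm)
        for _ in range(3):
            amp = rng.uniform(-0.05, 0.05)
            center = rng.uniform(580.0, 720.0)
            width = rng.uniform(25.0, 60.0)
            shape = shape + amp * _gauss(lam, center, width)
        shape = np.clip(shape, 0.05, 0.95)
        for level in levels:
            scale = 0.95 - 0.10 * (level - 1)
            spec = shape * scale + bump_amp.get(level, 0.0) * bleach_bump
            entries[coral_class_label(genus, level)] = np.clip(spec, 0.0, 1.0)
    entries.update(_background_spectra(lam))
    return EndmemberLibrary(grid=grid, entries=entries)


# ---------------------------------------------------------------------------
# Water model


@dataclass
class WaterModel:
    """Two-way Lambert-Beer water column: R_obs = R_b * exp(-2 k z) + offset."""

    grid: WavelengthGrid
    k: np.ndarray  # diffuse attenuation, 1/m, per band
    offset: np.ndarray  # water-leaving reflectance offset, per band
    max_depth: float = 6.0
    blue_nm: float = 480.0
    green_nm: float = 540.0

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        if self.k.shape != (len(self.grid),) or self.offset.shape != (len(self.grid),):
            raise ShapeError("k/offset must have one value per grid band")
        if self.k.min() < 0:
            raise InvalidParameterError("attenuation k must be non-negative")
        kb = self.k[int(np.argmin(np.abs(self.grid.centers - self.blue_nm)))]
        kg = self.k[int(np.argmin(np.abs(self.grid.centers - self.green_nm)))]
        if not kg > kb:
            raise InvalidParameterError(
                "k(green) must exceed k(blue) for log-ratio bathymetry"
            )


def default_water_model(grid: WavelengthGrid | None = None, max_depth: float = 6.0) -> WaterModel:
    """Coastal-water attenuation: rising through the visible, strong in NIR."""
    grid = grid or sensor_grid()
    lam = grid.centers
    k = np.clip(0.10 + 0.0012 * (lam - 480.0), 0.01, None)
    k = k + 0.9 / (1.0 + np.exp(-(lam - 730.0) / 25.0))
    offset = 0.005 * _gauss(lam, 450.0, 80.0)
    return WaterModel(grid=grid, k=k, offset=offset, max_depth=max_depth)


def default_illumination(grid: WavelengthGrid) -> np.ndarray:
    """Smooth solar-like downwelling radiance scale (sensor units)."""
    lam = grid.centers
    return 800.0 * (0.55 + 0.45 * _gauss(lam, 560.0, 220.0))


# ---------------------------------------------------------------------------
# Scene truth


@dataclass
class SceneTruth:
    """Ground-truth rasters: class label and depth per pixel."""

    class_ids: np.ndarray  # int raster
    class_names: list[str]  # id -> label
    depth: np.ndarray  # metres
    library: EndmemberLibrary
    geotransform: GeoTransform
    seed: int

    def __post_init__(self) -> None:
        if self.class_ids.shape != self.depth.shape:
            raise ShapeError("label and depth rasters must share shape")
        if self.depth.min() < 0:
            raise InvalidParameterError("negative depth in truth raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.class_ids.shape

    def label_raster(self) -> np.ndarray:
        return np.asarray(self.class_names, dtype=object)[self.class_ids]

    def coral_mask(self) -> np.ndarray:
        coral_ids = [
            i for i, name in enumerate(self.class_names)
            if parse_class_label(name) is not None
        ]
        return np.isin(self.class_ids, coral_ids)

    def prevalence_percent(self) -> dict[str, float]:
        """Percent of scene pixels per class (EA reference prevalence)."""
        n = self.class_ids.size
        counts = np.bincount(self.class_ids.ravel(), minlength=len(self.class_names))
        return {name: 100.0 * counts[i] / n for i, name in enumerate(self.class_names)}


def _default_geotransform() -> GeoTransform:
    # local planar approximation; ~1 m pixels at reef latitude
    return GeoTransform(lat0=18.8129, lon0=146.4267, a=1e-5, b=0.0, c=0.0, d=1e-5)


def make_scene(
    shape,
    classes,
    max_depth: float,
    seed: int,
    library: EndmemberLibrary | None = None,
    geotransform: GeoTransform | None = None,
    constant_depth: float | None = None,
) -> SceneTruth:
    """Lay out contiguous class blobs over a sand background with a smooth
    0 -> ``max_depth`` depth gradient.

    ``classes`` lists the labels to place (coral labels from
    :func:`coral_class_label`, or background names).  Non-sand classes are
    placed as one round blob each on a jittered tile layout, so every
    requested class occupies at least one pixel and blobs never overlap.
    ``constant_depth`` overrides the gradient with a flat depth (used for
    albedo-independence experiments).
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise InvalidParameterError("scene shape must be positive")
    classes = list(classes)
    if not classes:
        raise InvalidParameterError("classes must be non-empty")
    if len(classes) > rows * cols:
        raise InvalidParameterError("more classes than pixels")
    if max_depth < 0:
        raise InvalidParameterError("max_depth must be >= 0")
    rng = np.random.default_rng(seed)

    names = [SAND] + [c for c in classes if c != SAND]
    ids = np.zeros((rows, cols), dtype=np.int32)
    blob_classes = names[1:]
    if blob_classes:
        n_tiles = int(np.ceil(np.sqrt(len(blob_classes))))
        tr, tc = rows / n_tiles, cols / n_tiles
        order = rng.permutation(n_tiles * n_tiles)[: len(blob_classes)]
        for cid, tile in enumerate(order, start=1):
            ti, tj = divmod(int(tile), n_tiles)
            cy = ti * tr + tr / 2 + rng.uniform(-0.1, 0.1) * tr
            cx = tj * tc + tc / 2 + rng.uniform(-0.1, 0.1) * tc
            radius = 0.35 * min(tr, tc)
            yy, xx = np.ogrid[:rows, :cols]
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
            blob[min(int(round(cy)), rows - 1), min(int(round(cx)), cols - 1)] = True
            ids[blob] = cid

    if constant_depth is not None:
        depth = np.full((rows, cols), float(constant_depth))
    elif max_depth == 0 or rows == 1:
        depth = np.zeros((rows, cols))
    else:
        r_norm = np.arange(rows)[:, None] / (rows - 1)
        c_phase = np.sin(2 * np.pi * np.arange(cols)[None, :] / max(cols, 2))
        depth = r_norm * (1.0 + 0.02 * c_phase)
        depth -= depth.min()
        depth *= max_depth / depth.max()

    if library is None:
        pairs = [p for c in classes if (p := parse_class_label(c))]
        genera = sorted({g for g, _ in pairs})
        levels = sorted({l for _, l in pairs}) or [1]
        library = synth_endmembers(genera or ["Acropora"], levels, seed=seed)
    missing = [c for c in names if c not in library.entries]
    if missing:
        raise InvalidParameterError(f"library lacks endmembers for {missing}")
    return SceneTruth(
        class_ids=ids,
        class_names=names,
        depth=depth,
        library=library,
        geotransform=geotransform or _default_geotransform(),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Forward rendering


def render_cube(
    truth: SceneTruth,
    water: WaterModel,
    illumination: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Render a radiance cube and its white reference from scene truth.

    Per pixel: ``R_obs = R_bottom * exp(-2 k z) + offset`` (two-way
    Lambert-Beer attenuation through depth z), scaled by the illumination
    spectrum, plus i.i.d. zero-mean Gaussian noise of standard deviation
    ``noise_sd`` (reflectance units).  Spume floats at the surface and is
    not attenuated.  Returns ``(cube, white_reference)`` where the white
    reference is the radiance of a unit-reflectance panel.
    """
    if truth.library.grid != water.grid:
        raise ShapeError("truth library and water model use different grids")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    grid = water.grid
    illum = (
        default_illumination(grid)
        if illumination is None
        else np.asarray(illumination, dtype=float)
    )
    if illum.shape != (len(grid),):
        raise ShapeError("illumination must have one value per band")
    bottoms = truth.library.as_matrix(truth.class_names)  # (n_classes, bands)
    z = truth.depth[:, :, None]
    if SPUME in truth.class_names:
        z = np.where(
            (truth.class_ids == truth.class_names.index(SPUME))[:, :, None], 0.0, z
        )
    r_obs = bottoms[truth.class_ids] * np.exp(-2.0 * water.k * z) + water.offset
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r_obs = r_obs + rng.normal(0.0, noise_sd, size=r_obs.shape)
    radiance = np.clip(illum * r_obs, 0.0, None)
    cube = SpectralCube(
        values=radiance, grid=grid, geotransform=truth.geotransform, kind=RADIANCE
    )
    return cube, illum.copy()


# ---------------------------------------------------------------------------
# Survey sampling and spume


def make_survey_table(truth: SceneTruth, n_points: int, seed: int) -> AttributeTable:
    """Sample ``n_points`` in-water survey records from coral pixels."""
    import pandas as pd

    coral = np.argwhere(truth.coral_mask())
    if n_points > 0 and coral.shape[0] == 0:
        raise EmptyDomainError("scene has no coral pixels to survey")
    if n_points > coral.shape[0]:
        raise InvalidParameterError("n_points exceeds number of coral pixels")
    rng = np.random.default_rng(seed)
    pick = coral[rng.choice(coral.shape[0], size=int(n_points), replace=False)]
    records = []
    for i, (r, c) in enumerate(pick):
        label = truth.class_names[truth.class_ids[r, c]]
        genus, level = parse_class_label(label)
        lat, lon = truth.geotransform.forward(int(r), int(c))
        records.append(
            {
                "Photo ID": i + 1,
                "Coral Type": genus,
                "Lv Bleached": level,
                "Bleached": "Yes" if level <= 2 else "No",
                "Depth": float(truth.depth[r, c]),
                "Notes": "",
                "Latitude": float(lat),
                "Longitude": float(lon),
                "Pixel x": int(c),
                "Pixel y": int(r),
            }
        )
    df = pd.DataFrame(records, columns=SURVEY_COLUMNS)
    if not len(df):
        return AttributeTable.empty()
    return AttributeTable(df)


def add_spume(truth: SceneTruth, polygons) -> SceneTruth:
    """Relabel pixels under spume polygons (geographic coordinates) as spume."""
    mask = rasterize_polygons(polygons, truth.geotransform, truth.shape)
    if polygons and not mask.any():
        warnings.warn("spume polygons fall entirely outside the scene; no change")
        return truth
    if not mask.any():
        return truth
    names = list(truth.class_names)
    if SPUME not in names:
        names.append(SPUME)
    library = truth.library
    if SPUME not in library.entries:
        entries = dict(library.entries)
        entries[SPUME] = np.full(len(library.grid), SPUME_REFLECTANCE)
        library = EndmemberLibrary(grid=library.grid, entries=entries)
    ids = truth.class_ids.copy()
    ids[mask] = names.index(SPUME)
    return replace(truth, class_ids=ids, class_names=names, library=library)
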