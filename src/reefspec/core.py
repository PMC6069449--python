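"""Core containers: wavelength grids, georeferencing, datacubes and survey tables.

The in-memory model mirrors what a VNIR push-broom scanner delivers after
orthorectification: a ``lines x samples x bands`` raster with a wavelength
per band and an affine map from pixel to geographic coordinates, plus the
in-water survey attribute table that supplies ground truth (genus,
six-level bleaching score, depth, position).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ShapeError, ValidationError

#: Column schema of the in-water survey attribute table.
SURVEY_COLUMNS = [
    "Photo ID",
    "Coral Type",
    "Lv Bleached",
    "Bleached",
    "Depth",
    "Notes",
    "Latitude",
    "Longitude",
    "Pixel x",
    "Pixel y",
]

RADIANCE = "radiance"
REFLECTANCE = "reflectance"


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths in nanometres."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise InvalidParameterError("wavelength grid must be a non-empty 1-D array")
        if c.size > 1 and not np.all(np.diff(c) > 0):
            raise InvalidParameterError("wavelength centers must be strictly increasing")
        object.__setattr__(self, "centers", c)

    def __len__(self) -> int:
        return int(self.centers.size)

    @property
    def spacing(self) -> float:
        """Largest gap between consecutive band centers (nm)."""
        if len(self) < 2:
            return 0.0
        return float(np.max(np.diff(self.centers)))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.centers, other.centers
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(self.centers.tobytes())


@dataclass(frozen=True)
class GeoTransform:
    """Affine map (row, col) -> (lat, lon).

    lat = lat0 + a*row + b*col,  lon = lon0 + c*row + d*col.
    Latitude/longitude are treated as planar local coordinates; no datum
    handling is attempted.
    """

    lat0: float = 0.0
    lon0: float = 0.0
    a: float = 1.0
    b: float = 0.0
    c: float = 0.0
    d: float = 1.0

    @property
    def determinant(self) -> float:
        return self.a * self.d - self.b * self.c

    def require_invertible(self) -> None:
        if abs(self.determinant) < 1e-15:
            raise InvalidParameterError("geotransform is singular (zero determinant)")

    def forward(self, row, col):
        """Pixel (row, col) -> (lat, lon); accepts scalars or arrays."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        return (
            self.lat0 + self.a * row + self.b * col,
            self.lon0 + self.c * row + self.d * col,
        )

    def inverse(self, lat, lon):
        """(lat, lon) -> fractional (row, col)."""
        self.require_invertible()
        lat = np.asarray(lat, dtype=float) - self.lat0
        lon = np.asarray(lon, dtype=float) - self.lon0
        det = self.determinant
        row = (self.d * lat - self.b * lon) / det
        col = (-self.c * lat + self.a * lon) / det
        return row, col

    def to_list(self) -> list[float]:
        return [self.lat0, self.lon0, self.a, self.b, self.c, self.d]

    @classmethod
    def from_list(cls, vals) -> "GeoTransform":
        lat0, lon0, a, b, c, d = (float(v) for v in vals)
        return cls(lat0, lon0, a, b, c, d)


@dataclass
class SpectralCube:
    """Georeferenced hyperspectral raster (rows x cols x bands)."""

    values: np.ndarray
    grid: WavelengthGrid
    geotransform: GeoTransform = field(default_factory=GeoTransform)
    kind: str = RADIANCE

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ShapeError("cube values must be rows x cols x bands")
        if v.shape[2] != len(self.grid):
            raise ShapeError(
                f"cube has {v.shape[2]} bands but grid has {len(self.grid)}"
            )
        if self.kind not in (RADIANCE, REFLECTANCE):
            raise InvalidParameterError(f"unknown cube kind {self.kind!r}")
        self.values = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "SpectralCube":
        return SpectralCube(
            values=values,
            grid=self.grid,
            geotransform=self.geotransform,
            kind=self.kind if kind is None else kind,
        )


def coral_class_label(genus: str, level: int) -> str:
    """Canonical class label for a (genus, bleaching level) pair."""
    return f"{genus} L{int(level)}"


def parse_class_label(label: str) -> tuple[str, int] | None:
    """Invert :func:`coral_class_label`; None for non-coral labels."""
    genus, _, lv = label.rpartition(" L")
    if genus and lv.isdigit():
        return genus, int(lv)
    return None


class AttributeTable:
    """In-water survey table with the standard attribute schema.

    Wraps a :class:`pandas.DataFrame` whose columns follow
    :data:`SURVEY_COLUMNS`; extra columns (e.g. an out-of-bounds flag added
    during georeferencing) are carried through untouched.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"survey table missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        levels = pd.to_numeric(self.df["Lv Bleached"], errors="coerce")
        bad = self.df.index[~levels.isin([1, 2, 3, 4, 5, 6])]
        if len(bad):
            row = int(bad[0])
            raise ValidationError(
                f"row {row}: bleaching level {self.df.loc[row, 'Lv Bleached']!r} "
                "outside 1-6"
            )
        self.df["Lv Bleached"] = levels.astype(int)
        depth = pd.to_numeric(self.df["Depth"], errors="coerce")
        if (depth.dropna() < 0).any():
            raise ValidationError("negative survey depth")
        self.df["Depth"] = depth

    def __len__(self) -> int:
        return len(self.df)

    def class_labels(self) -> pd.Series:
        return self.df.apply(
            lambda r: coral_class_label(r["Coral Type"], r["Lv Bleached"]), axis=1
        )

    def copy(self) -> "AttributeTable":
        return AttributeTable(self.df.copy(), validate=False)

    @classmethod
    def empty(cls) -> "AttributeTable":
        return cls(pd.DataFrame(columns=SURVEY_COLUMNS), validate=False)
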