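"""ENVI-style cube persistence, survey-table CSV I/O and geo/pixel mapping.

The on-disk cube format is the classic ENVI pair: a plain-text ``.hdr``
describing ``samples/lines/bands``, data type, interleave (BIL or BSQ),
byte order and the wavelength list, next to a raw little-endian binary
payload.  Two package-specific header keys (``geo transform``, ``cube
kind``) carry the affine georeferencing and the radiometric kind; unknown
keys found on read are preserved and re-emitted verbatim on write.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .core import (
    RADIANCE,
    SURVEY_COLUMNS,
    AttributeTable,
    GeoTransform,
    SpectralCube,
    WavelengthGrid,
)
from .errors import (
    CorruptFileError,
    InvalidParameterError,
    UnsupportedFormatError,
    ValidationError,
)

_DTYPE_CODES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64}
_DTYPE_TO_CODE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}

_KNOWN_KEYS = {
    "samples",
    "lines",
    "bands",
    "header offset",
    "file type",
    "data type",
    "interleave",
    "byte order",
    "wavelength",
    "geo transform",
    "cube kind",
}


def _header_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr") if path.suffix != ".hdr" else path


def _format_header(meta: dict) -> str:
    lines = ["ENVI"]
    for key, val in meta.items():
        if isinstance(val, (list, tuple, np.ndarray)):
            body = ", ".join(str(v) for v in val)
            lines.append(f"{key} = {{ {body} }}")
        else:
            lines.append(f"{key} = {val}")
    return "\n".join(lines) + "\n"


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise CorruptFileError("missing ENVI magic in header")
    body = text.lstrip()[4:]
    meta: dict = {}
    # Brace-delimited values may span lines; join them first.
    for match in re.finditer(
        r"^\s*([^=\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", body, re.MULTILINE | re.DOTALL
    ):
        key, val = match.group(1).strip().lower(), match.group(2).strip()
        if val.startswith("{"):
            items = [s.strip() for s in val[1:-1].replace("\n", " ").split(",")]
            meta[key] = [s for s in items if s]
        else:
            meta[key] = val
    return meta


def write_cube(
    cube: SpectralCube,
    path,
    interleave: str = "bil",
    data_type: int = 4,
    extra_header: dict | None = None,
) -> None:
    """Write a cube as an ENVI header + raw binary pair.

    ``data_type`` uses ENVI codes (4 = float32 default, 5 = float64).
    """
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq"):
        raise UnsupportedFormatError(f"unsupported interleave {interleave!r}")
    if data_type not in _DTYPE_CODES:
        raise UnsupportedFormatError(f"unsupported ENVI data type {data_type}")
    if not np.all(np.isfinite(cube.values)):
        raise InvalidParameterError("cube contains non-finite values")
    path = Path(path)
    rows, cols, bands = cube.shape
    arr = cube.values.astype(_DTYPE_CODES[data_type])
    if interleave == "bil":  # [line][band][sample]
        disk = np.ascontiguousarray(np.transpose(arr, (0, 2, 1)))
    else:  # bsq: [band][line][sample]
        disk = np.ascontiguousarray(np.transpose(arr, (2, 0, 1)))
    meta = {
        "samples": cols,
        "lines": rows,
        "bands": bands,
        "header offset": 0,
        "file type": "ENVI Standard",
        "data type": data_type,
        "interleave": interleave,
        "byte order": 0,
        "wavelength": [f"{w:.6f}" for w in cube.grid.centers],
        "geo transform": [f"{v!r}" for v in cube.geotransform.to_list()],
        "cube kind": cube.kind,
    }
    for key, val in (extra_header or {}).items():
        meta.setdefault(key, val)
    path.write_bytes(disk.astype(disk.dtype.newbyteorder("<")).tobytes())
    _header_path(path).write_text(_format_header(meta))


def read_cube(path) -> SpectralCube:
    """Read an ENVI cube written by :func:`write_cube` (or compatible)."""
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists() or not path.exists():
        raise CorruptFileError(f"missing header or binary for {path}")
    meta = _parse_header(hdr.read_text())
    try:
        rows, cols, bands = int(meta["lines"]), int(meta["samples"]), int(meta["bands"])
        data_type = int(meta["data type"])
        interleave = str(meta["interleave"]).lower()
    except KeyError as exc:
        raise CorruptFileError(f"header missing required key: {exc}") from exc
    if interleave not in ("bil", "bsq"):
        raise UnsupportedFormatError(f"unsupported interleave {interleave!r}")
    if data_type not in _DTYPE_CODES:
        raise UnsupportedFormatError(f"unsupported ENVI data type {data_type}")
    dtype = np.dtype(_DTYPE_CODES[data_type]).newbyteorder("<")
    raw = path.read_bytes()
    expected = rows * cols * bands * dtype.itemsize
    if len(raw) != expected:
        raise CorruptFileError(
            f"binary size {len(raw)} != expected {expected} from header"
        )
    flat = np.frombuffer(raw, dtype=dtype)
    if interleave == "bil":
        values = np.transpose(flat.reshape(rows, bands, cols), (0, 2, 1))
    else:
        values = np.transpose(flat.reshape(bands, rows, cols), (1, 2, 0))
    wl = meta.get("wavelength")
    if wl is None:
        raise CorruptFileError("header has no wavelength list")
    grid = WavelengthGrid(np.array([float(w) for w in wl]))
    if len(grid) != bands:
        raise CorruptFileError("wavelength list length differs from band count")
    gt = (
        GeoTransform.from_list(meta["geo transform"])
        if "geo transform" in meta
        else GeoTransform()
    )
    kind = meta.get("cube kind", RADIANCE)
    cube = SpectralCube(values=np.array(values), grid=grid, geotransform=gt, kind=kind)
    cube.extra_header = {k: v for k, v in meta.items() if k not in _KNOWN_KEYS}
    return cube


def write_raster(arr, path, geotransform: GeoTransform | None = None, data_type=5) -> None:
    """Persist a single 2-D raster (labels, depth, masks) as a 1-band ENVI file."""
    arr = np.asarray(arr)
    cube = SpectralCube(
        values=arr[:, :, None].astype(float),
        grid=WavelengthGrid(np.array([0.0])),
        geotransform=geotransform or GeoTransform(),
        kind=RADIANCE,
    )
    write_cube(cube, path, interleave="bsq", data_type=data_type)


def read_raster(path) -> np.ndarray:
    return read_cube(path).values[:, :, 0]


# ---------------------------------------------------------------------------
# Survey attribute tables


def read_survey_csv(path) -> AttributeTable:
    """Read an in-water survey CSV with the standard attribute columns.

    Header matching is case-insensitive; blank depth/pixel cells become
    missing values.  A bleaching level outside 1-6 raises
    :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, skipinitialspace=True, dtype=str)
    lower = {c.lower().strip(): c for c in df.columns}
    rename = {}
    for canonical in SURVEY_COLUMNS:
        src = lower.get(canonical.lower())
        if src is None:
            raise ValidationError(f"survey CSV missing column {canonical!r}")
        rename[src] = canonical
    df = df.rename(columns=rename)
    for col in ("Latitude", "Longitude"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("Pixel x", "Pixel y", "Photo ID"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    df["Coral Type"] = df["Coral Type"].astype(str).str.strip()
    if len(df):
        levels = pd.to_numeric(df["Lv Bleached"], errors="coerce")
        bad = df.index[~levels.isin([1, 2, 3, 4, 5, 6])]
        if len(bad):
            raise ValidationError(
                f"row {int(bad[0])}: bleaching level "
                f"{df.loc[bad[0], 'Lv Bleached']!r} outside 1-6"
            )
    return AttributeTable(df)


def write_survey_csv(table: AttributeTable, path) -> None:
    cols = SURVEY_COLUMNS + [c for c in table.df.columns if c not in SURVEY_COLUMNS]
    table.df.to_csv(path, index=False, columns=cols)


# ---------------------------------------------------------------------------
# Geographic <-> pixel coordinates


def pixel_to_geo(gt: GeoTransform, row, col):
    """Pixel (row, col) -> (lat, lon) at the pixel center."""
    gt.require_invertible()
    return gt.forward(row, col)


def geo_to_pixel(gt: GeoTransform, lat, lon):
    """(lat, lon) -> nearest integer (row, col); ties round toward -inf."""
    row, col = gt.inverse(lat, lon)
    r = np.ceil(np.asarray(row) - 0.5).astype(int)
    c = np.ceil(np.asarray(col) - 0.5).astype(int)
    if np.ndim(row) == 0:
        return int(r), int(c)
    return r, c


def rasterize_polygons(polygons, gt: GeoTransform, shape) -> np.ndarray:
    """Boolean mask: True where a pixel center falls inside any polygon.

    Polygons are shapely geometries in the scene's geographic frame with
    ``x = longitude`` and ``y = latitude`` (GeoJSON axis order); boundary
    points count as inside.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise InvalidParameterError("raster shape must be positive")
    geoms = [g for g in (polygons or []) if g is not None and not g.is_empty]
    if not geoms:
        return np.zeros((rows, cols), dtype=bool)
    union = shapely.union_all(geoms)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    lat, lon = gt.forward(rr.ravel(), cc.ravel())
    inside = shapely.intersects_xy(union, lon, lat)
    return inside.reshape(rows, cols)
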