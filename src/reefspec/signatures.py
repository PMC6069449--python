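"""Survey georeferencing and per-class mean spectral-signature extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AttributeTable,
    GeoTransform,
    SpectralCube,
    WavelengthGrid,
    coral_class_label,
)
from .cube_io import geo_to_pixel
from .errors import InvalidParameterError, ShapeError


@dataclass
class SpectralSignature:
    """Mean +/- sd reflectance of one (genus, bleaching level) class."""

    label: str
    mean: np.ndarray
    sd: np.ndarray
    n_pixels: int
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        if self.mean.shape != (len(self.grid),) or self.sd.shape != (len(self.grid),):
            raise ShapeError("signature mean/sd must match the grid")
        if self.n_pixels < 1:
            raise InvalidParameterError("signature needs at least one pixel")


class SignatureSet(dict):
    """Mapping from class label to :class:`SpectralSignature`."""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, sig in self.items():
            row = {"class": label, "n_pixels": sig.n_pixels}
            row.update(
                {f"{w:.2f}": m for w, m in zip(sig.grid.centers, sig.mean)}
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def georeference_survey(
    table: AttributeTable, gt: GeoTransform, shape=None
) -> AttributeTable:
    """Fill pixel coordinates for every record from its lat/lon.

    When ``shape`` (rows, cols) is given, records falling outside the
    raster are flagged in an ``Out of Bounds`` column rather than dropped.
    """
    gt.require_invertible()
    out = table.copy()
    df = out.df
    if len(df):
        rows, cols = geo_to_pixel(
            gt, df["Latitude"].to_numpy(float), df["Longitude"].to_numpy(float)
        )
        df["Pixel x"] = pd.array(np.atleast_1d(cols), dtype="Int64")
        df["Pixel y"] = pd.array(np.atleast_1d(rows), dtype="Int64")
        if shape is not None:
            r, c = np.atleast_1d(rows), np.atleast_1d(cols)
            df["Out of Bounds"] = ~(
                (r >= 0) & (r < shape[0]) & (c >= 0) & (c < shape[1])
            )
    elif shape is not None:
        df["Out of Bounds"] = pd.Series(dtype=bool)
    return out


def extract_signatures(
    cube: SpectralCube, table: AttributeTable, window: int = 3
) -> SignatureSet:
    """Mean/sd spectrum per (genus, level) over windows around survey pixels.

    ``window`` is an odd width in pixels; the window is clipped at the
    raster border.  Groups whose records yield no valid in-bounds pixels
    are omitted with a warning.
    """
    import warnings

    if window < 1 or window % 2 == 0:
        raise InvalidParameterError("window must be odd and >= 1")
    rows_img, cols_img = cube.values.shape[:2]
    half = window // 2
    groups: dict[str, list[np.ndarray]] = {}
    for _, rec in table.df.iterrows():
        if pd.isna(rec["Pixel x"]) or pd.isna(rec["Pixel y"]):
            continue
        r, c = int(rec["Pixel y"]), int(rec["Pixel x"])
        r0, r1 = max(0, r - half), min(rows_img, r + half + 1)
        c0, c1 = max(0, c - half), min(cols_img, c + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        label = coral_class_label(rec["Coral Type"], rec["Lv Bleached"])
        block = cube.values[r0:r1, c0:c1].reshape(-1, cube.values.shape[2])
        groups.setdefault(label, []).append(block)
    out = SignatureSet()
    for label, blocks in groups.items():
        pix = np.concatenate(blocks, axis=0)
        if pix.shape[0] == 0:
            warnings.warn(f"no valid pixels for class {label!r}; omitted")
            continue
        out[label] = SpectralSignature(
            label=label,
            mean=pix.mean(axis=0),
            sd=pix.std(axis=0),
            n_pixels=pix.shape[0],
            grid=cube.grid,
        )
    return out


def training_pixels(
    cube: SpectralCube,
    table: AttributeTable,
    window: int = 3,
    exclude_mask: np.ndarray | None = None,
):
    """Labeled training spectra from windows around georeferenced survey points.

    Returns ``(X, y)`` with one row per in-window pixel, labeled by the
    record's (genus, level) class.  Pixels under ``exclude_mask`` (e.g.
    spume polygons) are dropped.
    """
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError("window must be odd and >= 1")
    rows_img, cols_img, bands = cube.values.shape
    half = window // 2
    X, y = [], []
    for _, rec in table.df.iterrows():
        if pd.isna(rec["Pixel x"]) or pd.isna(rec["Pixel y"]):
            continue
        r, c = int(rec["Pixel y"]), int(rec["Pixel x"])
        r0, r1 = max(0, r - half), min(rows_img, r + half + 1)
        c0, c1 = max(0, c - half), min(cols_img, c + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        label = coral_class_label(rec["Coral Type"], rec["Lv Bleached"])
        block = cube.values[r0:r1, c0:c1].reshape(-1, bands)
        if exclude_mask is not None:
            keep = ~exclude_mask[r0:r1, c0:c1].ravel()
            block = block[keep]
        X.append(block)
        y.extend([label] * block.shape[0])
    if not X:
        return np.empty((0, bands)), np.array([], dtype=object)
    return np.concatenate(X, axis=0), np.array(y, dtype=object)


def signature_match_score(
    candidate: SpectralSignature,
    reference: SpectralSignature,
    tolerance: float = 0.10,
) -> float:
    """Percent of bands where the two means agree within the tolerance.

    The tolerance is a fraction of the signature amplitude (the larger
    peak-to-peak range of the two means, making the score symmetric in its
    arguments).  This is one configurable interpretation of a signature
    match score; a correlation-based strategy can be swapped in where
    needed.
    """
    if candidate.grid != reference.grid:
        raise ShapeError("signatures on different wavelength grids")
    amp = max(np.ptp(candidate.mean), np.ptp(reference.mean))
    ok = np.abs(candidate.mean - reference.mean) <= tolerance * amp
    return float(100.0 * np.mean(ok))


def separable_bands(
    sig_a: SpectralSignature, sig_b: SpectralSignature, min_gap: float
) -> np.ndarray:
    """Band indices where the class means are discernibly different.

    A band qualifies when the mean gap is at least ``min_gap`` reflectance
    units and exceeds the pooled standard deviation.
    """
    if sig_a.grid != sig_b.grid:
        raise ShapeError("signatures on different wavelength grids")
    gap = np.abs(sig_a.mean - sig_b.mean)
    pooled = np.sqrt(0.5 * (sig_a.sd**2 + sig_b.sd**2))
    return np.flatnonzero((gap >= min_gap) & (gap > pooled))
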