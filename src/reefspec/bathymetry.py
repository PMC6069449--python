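"""Log-ratio relative bathymetry, water-column variance and depth correction.

Relative depth follows the standard band-ratio transform for shallow
water: ``index = ln(n * R_blue) / ln(n * R_green)`` at the grid bands
nearest the blue/green reference wavelengths.  Because water attenuates
green faster than blue, the index grows monotonically with depth and is
approximately independent of bottom brightness for spectrally correlated
bottoms.  Calibration to metres is a least-squares line against in-water
survey depths.

The water-column effect itself is summarized by an empirical quadratic in
``x = ln(R_green / R_blue)``::

    y(x) = -18.353 x^2 + 10.805 x + 0.238   (percent variance, floored at 0)

and depth correction rescales each spectrum by ``1 / (1 - y/100)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import REFLECTANCE, AttributeTable, SpectralCube
from .errors import CalibrationError, InvalidParameterError, ShapeError

#: Quadratic coefficients of the variance-vs-log-ratio model (percent).
VARIANCE_COEFFS = (-18.353, 10.805, 0.238)


@dataclass(frozen=True)
class WaterColumnModel:
    """Reference wavelengths and quadratic coefficients for water effects."""

    a: float = VARIANCE_COEFFS[0]
    b: float = VARIANCE_COEFFS[1]
    c: float = VARIANCE_COEFFS[2]
    blue_nm: float = 480.0
    green_nm: float = 540.0

    def __post_init__(self) -> None:
        if not self.blue_nm < self.green_nm:
            raise InvalidParameterError("blue wavelength must be below green")
        if not np.all(np.isfinite([self.a, self.b, self.c])):
            raise InvalidParameterError("non-finite model coefficients")


@dataclass
class DepthMap:
    """Per-pixel depth: relative index (uncalibrated) or metres."""

    values: np.ndarray
    valid: np.ndarray
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ShapeError("values and validity mask must share shape")
        if self.calibrated and np.nanmin(self.values[self.valid], initial=0) < 0:
            raise InvalidParameterError("calibrated depths must be >= 0")


def _band_pair(cube: SpectralCube, model: WaterColumnModel) -> tuple[int, int]:
    centers = cube.grid.centers
    ib = int(np.argmin(np.abs(centers - model.blue_nm)))
    ig = int(np.argmin(np.abs(centers - model.green_nm)))
    for nm, idx in ((model.blue_nm, ib), (model.green_nm, ig)):
        if abs(centers[idx] - nm) > max(cube.grid.spacing, 1e-9):
            raise InvalidParameterError(f"grid does not cover {nm} nm")
    return ib, ig


def relative_depth_log_ratio(
    cube: SpectralCube,
    model: WaterColumnModel | None = None,
    stretch_n: float = 1000.0,
) -> DepthMap:
    """Uncalibrated relative depth index ``ln(n R_blue)/ln(n R_green)``.

    Pixels where either log argument is <= 1 (too dark for the ratio to be
    stable) are flagged invalid rather than propagated as NaN/inf.
    """
    model = model or WaterColumnModel()
    if cube.kind != REFLECTANCE:
        raise InvalidParameterError("relative depth requires a reflectance cube")
    if stretch_n <= 0:
        raise InvalidParameterError("stretch_n must be positive")
    ib, ig = _band_pair(cube, model)
    rb = stretch_n * cube.values[:, :, ib]
    rg = stretch_n * cube.values[:, :, ig]
    valid = (rb > 1.0) & (rg > 1.0)
    index = np.ones_like(rb)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(np.log(rb), np.log(rg), out=index, where=valid)
    index[~valid] = np.nan
    return DepthMap(values=index, valid=valid, calibrated=False)


def calibrate_depth(relmap: DepthMap, table: AttributeTable) -> DepthMap:
    """Fit depth[m] = slope * index + intercept on survey points and apply it."""
    df = table.df
    usable = df.dropna(subset=["Depth", "Pixel x", "Pixel y"])
    rows = usable["Pixel y"].to_numpy(dtype=int)
    cols = usable["Pixel x"].to_numpy(dtype=int)
    in_bounds = (
        (rows >= 0)
        & (rows < relmap.values.shape[0])
        & (cols >= 0)
        & (cols < relmap.values.shape[1])
    )
    rows, cols = rows[in_bounds], cols[in_bounds]
    ok = relmap.valid[rows, cols]
    idx = relmap.values[rows, cols][ok]
    depths = usable["Depth"].to_numpy(dtype=float)[in_bounds][ok]
    if idx.size < 2:
        raise CalibrationError("need at least 2 usable survey points")
    if np.ptp(idx) < 1e-12:
        raise CalibrationError("degenerate calibration: all indices equal")
    slope, intercept = np.polyfit(idx, depths, 1)
    values = slope * relmap.values + intercept
    values = np.where(relmap.valid, np.clip(values, 0.0, None), np.nan)
    out = DepthMap(values=values, valid=relmap.valid.copy(), calibrated=True)
    out.slope, out.intercept = float(slope), float(intercept)
    return out


def water_column_variance(x):
    """Percent spectral variance attributable to the water column at log-ratio x.

    Evaluates the empirical quadratic ``y = a x^2 + b x + c`` and floors the
    result at zero (the polynomial extrapolates negative far from its
    fitted range).
    """
    a, b, c = VARIANCE_COEFFS
    x = np.asarray(x, dtype=float)
    y = np.maximum(a * x * x + b * x + c, 0.0)
    return float(y) if y.ndim == 0 else y


def log_ratio_green_blue(cube: SpectralCube, model: WaterColumnModel | None = None):
    """Per-pixel ``x = ln(R_green / R_blue)`` at the model's reference bands."""
    model = model or WaterColumnModel()
    ib, ig = _band_pair(cube, model)
    rb = cube.values[:, :, ib]
    rg = cube.values[:, :, ig]
    valid = (rb > 0) & (rg > 0)
    x = np.zeros_like(rb)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(rg, rb, out=x, where=valid)
        np.log(x, out=x, where=valid)
    x[~valid] = np.nan
    return x, valid


def depth_correct(
    cube: SpectralCube,
    model: WaterColumnModel | None = None,
    x: np.ndarray | None = None,
):
    """Rescale each spectrum by ``1 / (1 - y/100)`` with y from the quadratic.

    ``x`` may be supplied directly (per-pixel log green/blue ratio);
    otherwise it is computed from the cube at the model's reference bands.
    Pixels whose variance reaches 100% are capped and flagged.  Returns
    ``(corrected_cube, flagged_mask)``.
    """
    model = model or WaterColumnModel()
    if cube.kind != REFLECTANCE:
        raise InvalidParameterError("depth correction requires a reflectance cube")
    if x is None:
        x, valid = log_ratio_green_blue(cube, model)
    else:
        x = np.asarray(x, dtype=float)
        if x.shape != cube.values.shape[:2]:
            raise ShapeError("x raster must match the cube's spatial shape")
        valid = np.isfinite(x)
    y = np.where(valid, water_column_variance(np.where(valid, x, 0.0)), 0.0)
    flagged = y >= 100.0
    y = np.minimum(y, 99.0)
    factor = 1.0 / (1.0 - y / 100.0)
    values = np.clip(cube.values * factor[:, :, None], 0.0, 1.0)
    return cube.with_values(values), flagged
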