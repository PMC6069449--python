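"""Radiance-to-reflectance conversion and optional image gamma adjustment."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import RADIANCE, REFLECTANCE, SpectralCube, WavelengthGrid
from .errors import InvalidParameterError, InvalidReferenceError, ShapeError


def to_reflectance(cube: SpectralCube, white: np.ndarray) -> SpectralCube:
    """Divide each pixel's radiance by the white-reference panel radiance.

    The white reference is the per-band radiance of a unit-reflectance
    panel under the scene illumination; the quotient is clipped to [0, 1]
    (values above one arise from glint or noise and carry no radiometric
    meaning here).
    """
    white = np.asarray(white, dtype=float)
    if white.shape != (len(cube.grid),):
        raise ShapeError("white reference must have one value per band")
    if np.any(white <= 0):
        raise InvalidReferenceError("white reference must be strictly positive")
    if cube.kind != RADIANCE:
        raise InvalidParameterError("to_reflectance expects a radiance cube")
    values = np.clip(cube.values / white, 0.0, 1.0)
    return cube.with_values(values, kind=REFLECTANCE)


def gamma_adjust(cube: SpectralCube, gamma_increase: float) -> SpectralCube:
    """Brighten a reflectance cube by a gamma increase of up to 75%.

    Values map through ``v -> v ** (1 / (1 + gamma_increase))``, which
    preserves [0, 1], fixes 0 and 1, and is strictly monotone, so per-band
    rank order is unchanged.  Exposed as an optional pre-classification
    step (default off in the pipeline).
    """
    if not 0.0 <= gamma_increase <= 0.75:
        raise InvalidParameterError("gamma_increase must lie in [0, 0.75]")
    if cube.kind != REFLECTANCE:
        raise InvalidParameterError("gamma_adjust expects a reflectance cube")
    if gamma_increase == 0.0:
        return cube.with_values(cube.values.copy())
    values = np.power(cube.values, 1.0 / (1.0 + gamma_increase))
    return cube.with_values(values)


def write_white_reference(grid: WavelengthGrid, white: np.ndarray, path) -> None:
    """Persist a white reference as a 2-column CSV (wavelength nm, radiance)."""
    pd.DataFrame({"wavelength_nm": grid.centers, "radiance": white}).to_csv(
        path, index=False
    )


def read_white_reference(path) -> tuple[WavelengthGrid, np.ndarray]:
    df = pd.read_csv(path)
    grid = WavelengthGrid(df["wavelength_nm"].to_numpy(dtype=float))
    white = df["radiance"].to_numpy(dtype=float)
    if np.any(white <= 0):
        raise InvalidReferenceError("white reference must be strictly positive")
    return grid, white
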