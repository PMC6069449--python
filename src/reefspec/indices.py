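"""Normalized-difference coral bleaching indices and NDVI variants.

The index registry encodes, per genus and bleaching level, the band pairs
whose normalized difference ``(R_a - R_b)/(R_a + R_b)`` discriminates that
class, plus a four-wavelength genus index ``(R_540 - R_575)/(R_450 + R_586)``.
Wavelengths are matched to the nearest grid band (no interpolation; on a
~2.2 nm grid the difference is negligible).
"""

from __future__ import annotations

import numpy as np

from .core import REFLECTANCE, SpectralCube, WavelengthGrid
from .errors import CoverageError, InvalidParameterError, OutOfRangeError

#: Normalized-difference bleaching index registry: name -> (lambda1, lambda2) nm.
#: Naming: <genus letter>Lv<level>.<k>; A = Acropora, P = Porites massive,
#: G = Goniopora, T = Turbinaria, S = soft coral.
ND_INDEX_REGISTRY: dict[str, tuple[float, float]] = {
    # Acropora
    "Alv1.1": (395, 404),
    "Alv1.2": (575, 604),
    "Alv1.3": (711, 732),
    "Alv2.1": (404, 489),
    "Alv2.2": (595, 662),
    "Alv3.1": (446, 473),
    "Alv3.2": (531, 555),
    "Alv3.3": (586, 622),
    "Alv4.1": (446, 489),
    "Alv4.2": (569, 600),
    "Alv4.3": (611, 671),
    "Alv5.1": (484, 522),
    "Alv5.2": (695, 720),
    "Alv6.1": (400, 418),
    "Alv6.2": (460, 484),
    "Alv6.3": (724, 768),
    # Porites massive
    "PLv1.1": (437, 473),
    "PLv1.2": (680, 737),
    "PLv2.1": (411, 473),
    "PLv2.2": (640, 671),
    "PLv3.1": (429, 473),
    "PLv3.2": (576, 640),
    "PLv4.1": (406, 418),
    "PLv4.2": (533, 582),
    # Goniopora
    "GLv3.1": (409, 477),
    "GLv3.2": (640, 722),
    # Turbinaria
    "TLv5.1": (415, 442),
    "TLv5.2": (471, 486),
    "TLv5.3": (500, 544),
    "TLv5.4": (675, 717),
    # Soft coral
    "SLv5.1": (429, 444),
    "SLv5.2": (506, 544),
    "SLv5.3": (577, 604),
    "SLv5.4": (662, 708),
}

#: Four wavelengths of the genus-classification index.
GENUS_INDEX_WAVELENGTHS = (540.0, 575.0, 450.0, 586.0)

#: NDVI variants: visible band against a 750 nm NIR reference.
NDVI_BANDS = {"green": 550.0, "yellow": 600.0}
NDVI_NIR = 750.0


def nearest_band(grid: WavelengthGrid, lambda_target: float) -> int:
    """Index of the grid band center nearest ``lambda_target`` (nm).

    Ties break toward the lower index.  A target farther than one grid
    spacing from the nearest center is out of range.
    """
    if len(grid) == 0:
        raise InvalidParameterError("empty wavelength grid")
    diffs = np.abs(grid.centers - float(lambda_target))
    idx = int(np.argmin(diffs))
    tol = max(grid.spacing, 1e-9)
    if diffs[idx] > tol:
        raise OutOfRangeError(
            f"{lambda_target} nm is outside the grid span "
            f"[{grid.centers[0]}, {grid.centers[-1]}] (+/- spacing)"
        )
    return idx


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den != 0
    np.divide(num, den, out=out, where=ok)
    return out


def nd_index(cube: SpectralCube, lambda1: float, lambda2: float) -> np.ndarray:
    """Per-pixel normalized difference ``(R_l1 - R_l2)/(R_l1 + R_l2)``.

    Zero-denominator pixels are flagged invalid (NaN), never +/-inf.
    """
    if cube.kind != REFLECTANCE:
        raise InvalidParameterError("indices require a reflectance cube")
    b1 = cube.values[:, :, nearest_band(cube.grid, lambda1)]
    b2 = cube.values[:, :, nearest_band(cube.grid, lambda2)]
    return _ratio(b1 - b2, b1 + b2)


def genus_index(cube: SpectralCube) -> np.ndarray:
    """Genus-classification index ``(R_540 - R_575)/(R_450 + R_586)``."""
    if cube.kind != REFLECTANCE:
        raise InvalidParameterError("indices require a reflectance cube")
    l540, l575, l450, l586 = GENUS_INDEX_WAVELENGTHS
    r = {
        nm: cube.values[:, :, nearest_band(cube.grid, nm)]
        for nm in (l540, l575, l450, l586)
    }
    return _ratio(r[l540] - r[l575], r[l450] + r[l586])


def ndvi_variant(cube: SpectralCube, variant: str) -> np.ndarray:
    """NDVI against 750 nm with the green (550 nm) or yellow (600 nm) band."""
    if variant not in NDVI_BANDS:
        raise InvalidParameterError(f"unknown NDVI variant {variant!r}")
    return nd_index(cube, NDVI_NIR, NDVI_BANDS[variant])


def evaluate_table1(cube: SpectralCube) -> dict[str, np.ndarray]:
    """Evaluate every registry index plus the genus index as rasters.

    Requires grid coverage of 395-768 nm; missing wavelengths are listed
    in the raised :class:`CoverageError`.
    """
    needed = sorted(
        {nm for pair in ND_INDEX_REGISTRY.values() for nm in pair}
        | set(GENUS_INDEX_WAVELENGTHS)
    )
    missing = []
    for nm in needed:
        try:
            nearest_band(cube.grid, nm)
        except OutOfRangeError:
            missing.append(nm)
    if missing:
        raise CoverageError(f"grid does not cover wavelengths: {missing}")
    stack = {
        name: nd_index(cube, l1, l2) for name, (l1, l2) in ND_INDEX_REGISTRY.items()
    }
    stack["GenusIndex"] = genus_index(cube)
    return stack


def index_registry_frame():
    """The registry as a DataFrame (name, form, lambda1..lambda4)."""
    import pandas as pd

    rows = [
        {"name": n, "form": "normalized_difference", "lambda1": a, "lambda2": b,
         "lambda3": "", "lambda4": ""}
        for n, (a, b) in ND_INDEX_REGISTRY.items()
    ]
    l1, l2, l3, l4 = GENUS_INDEX_WAVELENGTHS
    rows.append(
        {"name": "GenusIndex", "form": "genus_form", "lambda1": l1, "lambda2": l2,
         "lambda3": l3, "lambda4": l4}
    )
    return pd.DataFrame(rows)
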