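"""Pixel classification: RBF-kernel SVM, k-means refinement baseline,
spectral/spatial denoising and exclusion masks.

The supervised classifier is a maximum-margin machine with the Gaussian
radial basis kernel ``K(x_i, x_j) = exp(-gamma * ||x_i - x_j||^2)``,
gamma > 0, trained one-vs-one on labeled spectra (typically windows
around in-water survey points).  An unsupervised k-means partition serves
only to flag pixels whose supervised label disagrees with the dominant
label of their cluster; it never overwrites the supervised map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter
from sklearn.cluster import KMeans
from sklearn.svm import SVC

from .core import SpectralCube
from .errors import DegenerateTrainingError, InvalidParameterError, ShapeError

EXCLUDED = -1  # class id for masked-out pixels


def rbf_kernel(xi, xj, gamma: float) -> float:
    """Gaussian RBF kernel value ``exp(-gamma ||xi - xj||^2)``."""
    if gamma <= 0:
        raise InvalidParameterError("gamma must be > 0")
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ShapeError("spectra must have equal length")
    d2 = float(np.sum((xi - xj) ** 2))
    return float(np.exp(-gamma * d2))


@dataclass
class ClassModel:
    """Fitted RBF-SVM over spectra with a class legend."""

    svc: SVC
    classes: list[str]
    gamma: float | str
    C: float
    n_bands: int


@dataclass
class ClassMap:
    """Per-pixel class-id raster with legend and validity mask."""

    class_ids: np.ndarray  # int raster; EXCLUDED where masked
    legend: dict[int, str]
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.class_ids.shape != self.valid.shape:
            raise ShapeError("class ids and validity mask must share shape")

    def labels(self) -> np.ndarray:
        out = np.full(self.class_ids.shape, None, dtype=object)
        for cid, name in self.legend.items():
            out[self.class_ids == cid] = name
        return out

    def count(self, label: str) -> int:
        ids = [cid for cid, name in self.legend.items() if name == label]
        return int(np.sum(self.valid & np.isin(self.class_ids, ids)))


def train_classifier(
    spectra: np.ndarray,
    labels,
    gamma: float | str = "scale",
    C: float = 10.0,
) -> ClassModel:
    """Fit the one-vs-one RBF-SVM on labeled spectra.

    ``gamma='scale'`` uses 1 / (n_bands * Var(spectra)); training is
    deterministic for fixed inputs.
    """
    spectra = np.asarray(spectra, dtype=float)
    labels = np.asarray(labels)
    if spectra.ndim != 2 or spectra.shape[0] != labels.shape[0]:
        raise ShapeError("spectra must be (n_samples, n_bands) matching labels")
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise DegenerateTrainingError("training needs at least two classes")
    if isinstance(gamma, (int, float)) and gamma <= 0:
        raise InvalidParameterError("gamma must be > 0")
    svc = SVC(kernel="rbf", gamma=gamma, C=C, decision_function_shape="ovo")
    svc.fit(spectra, labels)
    return ClassModel(
        svc=svc, classes=classes, gamma=gamma, C=C, n_bands=spectra.shape[1]
    )


def predict_map(
    model: ClassModel, cube: SpectralCube, mask: np.ndarray | None = None
) -> ClassMap:
    """Classify every unmasked pixel of a reflectance cube.

    ``mask`` is an exclusion raster: True pixels are left unclassified.
    """
    rows, cols, bands = cube.values.shape
    if bands != model.n_bands:
        raise ShapeError(
            f"cube has {bands} bands but model was trained on {model.n_bands}"
        )
    if mask is None:
        mask = np.zeros((rows, cols), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (rows, cols):
        raise ShapeError("mask must match the cube's spatial shape")
    legend = {i: name for i, name in enumerate(model.classes)}
    name_to_id = {name: i for i, name in legend.items()}
    ids = np.full((rows, cols), EXCLUDED, dtype=np.int32)
    flat = cube.values.reshape(-1, bands)
    keep = ~mask.ravel()
    if keep.any():
        pred = model.svc.predict(flat[keep])
        ids.ravel()[keep] = [name_to_id[p] for p in pred]
    return ClassMap(class_ids=ids, legend=legend, valid=~mask)


def unsupervised_baseline(cube: SpectralCube, k: int, seed: int) -> ClassMap:
    """k-means partition of the cube's spectra (centroid clustering).

    Used to flag regions whose supervised label disagrees with the cluster
    structure; cluster ids carry no class meaning.
    """
    rows, cols, bands = cube.values.shape
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    if k > rows * cols:
        raise InvalidParameterError("k exceeds pixel count")
    km = KMeans(n_clusters=int(k), random_state=int(seed), n_init=10)
    ids = km.fit_predict(cube.values.reshape(-1, bands)).astype(np.int32)
    return ClassMap(
        class_ids=ids.reshape(rows, cols),
        legend={i: f"cluster {i}" for i in range(int(k))},
        valid=np.ones((rows, cols), dtype=bool),
    )


def refinement_flags(supervised: ClassMap, clusters: ClassMap) -> np.ndarray:
    """Flag pixels whose supervised label is not their cluster's majority label."""
    if supervised.class_ids.shape != clusters.class_ids.shape:
        raise ShapeError("maps must share shape")
    flags = np.zeros(supervised.class_ids.shape, dtype=bool)
    for cid in clusters.legend:
        in_cluster = (clusters.class_ids == cid) & supervised.valid
        if not in_cluster.any():
            continue
        ids, counts = np.unique(supervised.class_ids[in_cluster], return_counts=True)
        majority = ids[np.argmax(counts)]
        flags[in_cluster & (supervised.class_ids != majority)] = True
    return flags


def denoise(
    cube: SpectralCube, spectral_window: int = 5, spatial_window: int = 3
) -> SpectralCube:
    """Savitzky-Golay smoothing along bands, then per-band spatial median.

    Both windows must be odd; a window of 1 disables that stage.
    """
    for w in (spectral_window, spatial_window):
        if w < 1 or w % 2 == 0:
            raise InvalidParameterError("windows must be odd and >= 1")
    values = cube.values
    if spectral_window > 1:
        order = min(2, spectral_window - 1)
        values = savgol_filter(values, spectral_window, order, axis=2)
    if spatial_window > 1:
        values = median_filter(values, size=(spatial_window, spatial_window, 1))
    return cube.with_values(np.ascontiguousarray(values))


def apply_exclusion_mask(cmap: ClassMap, mask: np.ndarray) -> ClassMap:
    """Exclude masked pixels from a class map (spume polygons etc.)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cmap.class_ids.shape:
        raise ShapeError("mask must match the class map shape")
    ids = cmap.class_ids.copy()
    ids[mask] = EXCLUDED
    return ClassMap(class_ids=ids, legend=dict(cmap.legend), valid=cmap.valid & ~mask)
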