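"""Thematic-map accuracy assessment: point detection, mapped area,
excessive-area flagging and the overall-accuracy combination rule.

Each assessed class yields one row: its signature match score, the
fraction of in-water survey points recovered by the map, the mapped pixel
count and scene-area percentage, an excessive-area (EA) flag when the
mapped area vastly exceeds the class's plausible prevalence, and an
overall accuracy that is zero for EA classes and otherwise the smaller of
the signature and point accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassMap
from .core import AttributeTable, coral_class_label
from .errors import InvalidParameterError, UndefinedDenominatorError
from .signatures import SignatureSet, signature_match_score

REPORT_COLUMNS = [
    "Coral Type",
    "Bleaching Level",
    "Signature Accuracy (%)",
    "Points Found",
    "Accuracy (%)",
    "Found Pixels",
    "Area (%)",
    "Overall Accuracy (%)",
    "ea_flag",
]


def point_detection_accuracy(found: int, total: int) -> float:
    """Percent of survey points recovered, reported to 3 decimals."""
    if total < 1:
        raise UndefinedDenominatorError("total points must be >= 1")
    if not 0 <= found <= total:
        raise InvalidParameterError("found must lie in [0, total]")
    return round(100.0 * found / total, 3)


def mapped_area_fraction(cmap: ClassMap, label: str) -> tuple[int, float]:
    """(pixel count, percent of full scene) mapped to ``label``.

    Counts only non-excluded pixels; the percentage denominator is the
    full scene pixel count.
    """
    if label not in cmap.legend.values():
        raise KeyError(f"class {label!r} not in legend")
    found = cmap.count(label)
    return found, 100.0 * found / cmap.class_ids.size


def excessive_area_flag(
    area_percent: float, reference_prevalence: float, factor: float = 5.0
) -> bool:
    """True when the mapped area exceeds ``factor`` x the reference prevalence."""
    if area_percent < 0 or reference_prevalence < 0:
        raise InvalidParameterError("percent inputs must be >= 0")
    if factor <= 1:
        raise InvalidParameterError("factor must exceed 1")
    if reference_prevalence == 0 and area_percent > 0:
        warnings.warn("nonzero mapped area for a class with zero reference prevalence")
        return True
    return area_percent > factor * reference_prevalence


def overall_accuracy(
    signature_accuracy: float, points_accuracy: float, ea_flag: bool
) -> float:
    """Combination rule: 0 for EA classes, else min of the two accuracies.

    Reported to 2 decimals.
    """
    for v in (signature_accuracy, points_accuracy):
        if not 0 <= v <= 100:
            raise InvalidParameterError("accuracies must lie in [0, 100]")
    if ea_flag:
        return 0.0
    return round(min(signature_accuracy, points_accuracy), 2)


@dataclass
class AccuracyReport:
    """Per-class assessment rows plus classes missing from the map legend."""

    rows: pd.DataFrame
    missing_classes: list[str]

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _point_found(cmap: ClassMap, row: int, col: int, label: str, window: int) -> bool:
    half = window // 2
    r0, r1 = max(0, row - half), min(cmap.class_ids.shape[0], row + half + 1)
    c0, c1 = max(0, col - half), min(cmap.class_ids.shape[1], col + half + 1)
    if r0 >= r1 or c0 >= c1:
        return False
    block = cmap.class_ids[r0:r1, c0:c1]
    ok = cmap.valid[r0:r1, c0:c1]
    ids = [cid for cid, name in cmap.legend.items() if name == label]
    return bool(np.any(ok & np.isin(block, ids)))


def build_report(
    cmap: ClassMap,
    table: AttributeTable,
    sigs: SignatureSet,
    refs: SignatureSet,
    reference_prevalence: dict[str, float] | None = None,
    ea_factor: float = 5.0,
    found_window: int = 3,
    match_tolerance: float = 0.10,
) -> AccuracyReport:
    """Assemble one accuracy row per (genus, level) present in the survey.

    A survey point counts as found when the map contains its class within
    a ``found_window`` x ``found_window`` neighborhood of its pixel.
    ``reference_prevalence`` maps class label to its plausible scene
    percentage (from scene truth on synthetic runs); classes without a
    reference entry are not EA-assessed (flag False).
    Survey classes absent from the map legend are listed in the report
    footer, not silently dropped.
    """
    reference_prevalence = reference_prevalence or {}
    df = table.df
    rows = []
    missing = []
    legend_labels = set(cmap.legend.values())
    for (genus, level), grp in df.groupby(["Coral Type", "Lv Bleached"], sort=True):
        label = coral_class_label(genus, level)
        if label not in legend_labels:
            missing.append(label)
            continue
        total = len(grp)
        found_pts = sum(
            _point_found(
                cmap, int(rec["Pixel y"]), int(rec["Pixel x"]), label, found_window
            )
            for _, rec in grp.iterrows()
            if not (pd.isna(rec["Pixel x"]) or pd.isna(rec["Pixel y"]))
        )
        pts_acc = point_detection_accuracy(found_pts, total)
        if label in sigs and label in refs:
            sig_acc = signature_match_score(sigs[label], refs[label], match_tolerance)
        else:
            sig_acc = 0.0
        found_px, area = mapped_area_fraction(cmap, label)
        if label in reference_prevalence:
            ea = excessive_area_flag(area, reference_prevalence[label], ea_factor)
        else:
            ea = False
        rows.append(
            {
                "Coral Type": genus,
                "Bleaching Level": int(level),
                "Signature Accuracy (%)": round(sig_acc, 2),
                "Points Found": f"{found_pts}/{total}",
                "Accuracy (%)": pts_acc,
                "Found Pixels": found_px,
                "Area (%)": round(area, 3),
                "Overall Accuracy (%)": overall_accuracy(sig_acc, pts_acc, ea),
                "ea_flag": bool(ea),
            }
        )
    return AccuracyReport(
        rows=pd.DataFrame(rows, columns=REPORT_COLUMNS), missing_classes=missing
    )
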