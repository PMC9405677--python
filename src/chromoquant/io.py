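"""CSV / TIFF persistence for measurement and localization tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .nuclei import NucleusMeasurement, NucleusROI
from .smlm import LOCALIZATION_COLUMNS

__all__ = [
    "write_measurements",
    "read_measurements",
    "write_localizations",
    "read_localizations",
    "write_label_image",
    "rois_to_label_image",
]

MEASUREMENT_COLUMNS = [
    "experiment",
    "condition",
    "nucleus",
    "mean_arc",
    "arc_class",
    "puncta_count",
    "mean_puncta_area",
]


def write_measurements(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, columns=[c for c in MEASUREMENT_COLUMNS if c in frame])


def read_measurements(path) -> list[NucleusMeasurement]:
    df = pd.read_csv(path)
    out = []
    for rec in df.itertuples(index=False):
        area = getattr(rec, "mean_puncta_area", None)
        if area is not None and (isinstance(area, float) and np.isnan(area)):
            area = None
        count = getattr(rec, "puncta_count", None)
        if count is not None and (isinstance(count, float) and np.isnan(count)):
            count = None
        cls = getattr(rec, "arc_class", None)
        if isinstance(cls, float) and np.isnan(cls):
            cls = None
        out.append(
            NucleusMeasurement(
                nucleus_id=int(rec.nucleus),
                experiment_id=str(rec.experiment),
                condition=str(rec.condition),
                mean_arc_intensity=float(rec.mean_arc),
                arc_class=cls,
                puncta_count=None if count is None else int(count),
                mean_puncta_area=None if area is None else float(area),
            )
        )
    return out


def write_localizations(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, columns=LOCALIZATION_COLUMNS)


def read_localizations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["channel"] = df["channel"].astype(str)
    return df


def rois_to_label_image(rois: list[NucleusROI]) -> np.ndarray:
    """Labeled image (0 background, ROI id + 1 per nucleus)."""
    if not rois:
        return np.zeros((1, 1), dtype=np.int32)
    lab = np.zeros(rois[0].image_shape, dtype=np.int32)
    for roi in rois:
        r0, c0, r1, c1 = roi.bbox
        lab[r0:r1, c0:c1][roi.mask] = roi.id + 1
    return lab


def write_label_image(path, rois: list[NucleusROI]) -> None:
    tifffile.imwrite(Path(path), rois_to_label_image(rois))
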