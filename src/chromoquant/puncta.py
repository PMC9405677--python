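"""Chromocenter puncta quantification by size and intensity thresholds.

Each nucleus is cropped individually; puncta are the 8-connected components
of the pixels exceeding an adaptive intensity threshold (mean + k*SD of the
in-nucleus pixels), filtered to a size window.  The same k and size window
are applied identically to every nucleus in a batch, reconciling
batch-constant thresholding with nucleus-to-nucleus brightness variation.
An absolute-threshold mode is available via ``absolute_threshold``.

The mean punctum area and punctum count per nucleus are the figures of
merit; a nucleus with zero detected puncta has a *missing* (None) mean area,
never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from skimage.measure import label, regionprops

from .nuclei import NucleusMeasurement, NucleusROI

__all__ = [
    "PunctaParams",
    "Punctum",
    "PunctaSet",
    "CorrelationResult",
    "crop_nucleus",
    "detect_puncta",
    "summarize_puncta",
    "correlate_arc_puncta",
]


@dataclass(frozen=True)
class PunctaParams:
    intensity_k: float = 2.0  # threshold = mean + k * SD of in-mask pixels
    min_area: int = 50  # px^2
    max_area: int = 2000  # px^2
    use_max_projection: bool = False  # max-project a z-stack crop before detection
    absolute_threshold: float | None = None  # overrides the adaptive rule

    def __post_init__(self):
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.max_area <= self.min_area:
            raise ValueError("max_area must exceed min_area")
        if self.intensity_k <= 0:
            raise ValueError("intensity_k must be positive")


@dataclass(frozen=True)
class Punctum:
    centroid: tuple[float, float]  # (row, col) in crop coordinates
    area: int  # px^2
    peak_intensity: float


@dataclass
class PunctaSet:
    nucleus_id: int
    puncta: list[Punctum]
    threshold: float  # the realized intensity threshold

    def __len__(self) -> int:
        return len(self.puncta)


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    n: int
    p_value: float
    method: str


def crop_nucleus(image: np.ndarray, roi: NucleusROI, pad: int = 0):
    """Crop the ROI bounding box (+ pad, clipped at borders) out of an image.

    Returns ``(crop, mask, offset)`` where ``mask`` is the nucleus mask
    shifted into crop coordinates and ``offset = (r0, c0)`` re-embeds the
    crop into the original image.  Works on 2D images and on (z, y, x)
    stacks (the crop then keeps the z axis).
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    img = np.asarray(image)
    rows, cols = img.shape[-2:]
    r0, c0, r1, c1 = roi.bbox
    if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
        raise ValueError("ROI bounding box lies outside the image")
    rr0, cc0 = max(r0 - pad, 0), max(c0 - pad, 0)
    rr1, cc1 = min(r1 + pad, rows), min(c1 + pad, cols)
    crop = img[..., rr0:rr1, cc0:cc1]
    mask = np.zeros((rr1 - rr0, cc1 - cc0), dtype=bool)
    mask[r0 - rr0 : r1 - rr0, c0 - cc0 : c1 - cc0] = roi.mask
    return crop, mask, (rr0, cc0)


def detect_puncta(
    crop: np.ndarray, mask: np.ndarray, params: PunctaParams = PunctaParams(),
    nucleus_id: int = -1,
) -> PunctaSet:
    """Identify puncta in one nucleus crop.

    Threshold: ``mean + intensity_k * SD`` of the in-mask pixels (or the
    absolute threshold when configured).  Components are 8-connected and
    restricted to the nucleus mask; those outside [min_area, max_area] are
    discarded.  Puncta are ordered by (centroid row, centroid col).
    """
    crop = np.asarray(crop, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if crop.ndim == 3:
        if not params.use_max_projection:
            raise ValueError("got a z-stack crop but use_max_projection is off")
        crop = crop.max(axis=0)
    if crop.shape != mask.shape:
        raise ValueError("crop and mask shapes differ")
    if not mask.any():
        raise ValueError("empty nucleus mask")
    vals = crop[mask]
    if params.absolute_threshold is not None:
        thr = float(params.absolute_threshold)
    else:
        thr = float(vals.mean() + params.intensity_k * vals.std())
    bw = (crop > thr) & mask
    lab = label(bw, connectivity=2)
    puncta = []
    for rp in regionprops(lab, intensity_image=crop):
        if not (params.min_area <= rp.area <= params.max_area):
            continue
        puncta.append(
            Punctum(
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area=int(rp.area),
                peak_intensity=float(rp.intensity_max),
            )
        )
    puncta.sort(key=lambda p: p.centroid)
    return PunctaSet(nucleus_id=nucleus_id, puncta=puncta, threshold=thr)


def summarize_puncta(puncta_set: PunctaSet) -> tuple[int, float | None]:
    """(count, mean area); mean area is None (missing) for an empty set."""
    n = len(puncta_set)
    if n == 0:
        return 0, None
    return n, float(np.mean([p.area for p in puncta_set.puncta]))


def correlate_arc_puncta(
    measurements: Sequence[NucleusMeasurement],
    metric: str = "puncta_count",
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate mean Arc intensity with a puncta property across nuclei.

    ``metric`` is ``"puncta_count"`` or ``"mean_puncta_area"``; nuclei with a
    missing value of the metric are excluded.  Pearson by default, Spearman
    via ``method="spearman"``.
    """
    if metric not in ("puncta_count", "mean_puncta_area"):
        raise ValueError(f"unknown metric {metric!r}")
    pairs = [
        (m.mean_arc_intensity, getattr(m, metric))
        for m in measurements
        if getattr(m, metric) is not None
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 complete measurements")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            "zero variance in Arc intensity or the puncta metric; "
            "correlation is undefined"
        )
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(coefficient=float(r), n=len(x), p_value=float(p), method=method)
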