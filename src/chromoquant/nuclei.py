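"""DAPI-based nucleus segmentation and Arc-responder classification.

Implements the widefield analysis chain: smooth-background subtraction,
marking nuclei on the DAPI channel, measuring the mean Arc immunofluorescence
of each nucleus over its mask, deriving a per-experiment cutoff as the
arithmetic mean of the control (unstimulated) nuclei, and classifying nuclei
as Arc-positive (strictly above the cutoff) or Arc-negative.

The cutoff is computed separately for every experiment and never pooled:
staining intensity varies between experiments, and the control cultures of
each experiment are the only valid reference for that experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import binary_fill_holes, gaussian_filter, grey_opening
from skimage.measure import label, regionprops
from skimage.morphology import disk
from skimage.segmentation import clear_border
from skimage.transform import resize

__all__ = [
    "NucleusROI",
    "NucleusMeasurement",
    "ArcCutoff",
    "SegmentationParams",
    "subtract_background",
    "segment_nuclei",
    "measure_nuclei",
    "compute_arc_cutoff",
    "classify_arc",
]


@dataclass
class NucleusROI:
    """A segmented nucleus: tight bounding box + local boolean mask."""

    id: int
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    mask: np.ndarray  # boolean, shape (r1 - r0, c1 - c0)
    centroid: tuple[float, float]  # (row, col) in full-image coordinates
    area: int
    image_shape: tuple[int, int]  # shape of the image this ROI was cut from


@dataclass(frozen=True)
class NucleusMeasurement:
    nucleus_id: int
    experiment_id: str
    condition: str  # "control" | "stimulated"
    mean_arc_intensity: float
    arc_class: str | None = None  # "positive" | "negative"; None until classified
    puncta_count: int | None = None
    mean_puncta_area: float | None = None


@dataclass(frozen=True)
class ArcCutoff:
    """Per-experiment Arc-positive threshold = mean of control nuclei."""

    experiment_id: str
    threshold: float
    n_control_nuclei: int


@dataclass(frozen=True)
class SegmentationParams:
    threshold: float | None = None  # absolute DAPI threshold; None = Otsu
    min_area: int = 10_000
    max_area: int = 300_000
    fill_holes: bool = True
    discard_border: bool = True


def subtract_background(image: np.ndarray, radius: float) -> np.ndarray:
    """Remove a smooth background estimated by grayscale opening.

    A morphological opening with a disk of the given radius (the rolling-ball
    contract: structures narrower than the disk are removed from the
    background estimate) is computed on a block-averaged copy of the image
    for speed, lightly smoothed, upsampled, and subtracted.  The output is
    clamped at zero.

    ``radius`` must exceed the half-width of every foreground object that
    should survive subtraction.
    """
    image = np.asarray(image, dtype=float)
    if radius <= 0:
        raise ValueError("radius must be positive")
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    rows, cols = image.shape
    if radius > rows and radius > cols:
        raise ValueError("radius larger than both image dimensions")

    factor = max(1, int(radius // 12))
    if factor > 1:
        pr = (-rows) % factor
        pc = (-cols) % factor
        padded = np.pad(image, ((0, pr), (0, pc)), mode="edge")
        small = padded.reshape(
            padded.shape[0] // factor, factor, padded.shape[1] // factor, factor
        ).mean(axis=(1, 3))
    else:
        small = image
    r_small = max(1, round(radius / factor))
    bg = grey_opening(small, footprint=disk(r_small))
    if factor > 1:
        bg = gaussian_filter(bg, 1.0)
        bg = resize(bg, (rows + pr, cols + pc), order=1, anti_aliasing=False)[
            :rows, :cols
        ]
    return np.clip(image - bg, 0.0, None)


def segment_nuclei(
    dapi_image: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> list[NucleusROI]:
    """Mark nuclei on a (background-subtracted) DAPI image.

    Foreground is everything above the threshold (Otsu by default, or the
    absolute value in ``params.threshold``); holes are filled, objects
    touching the border are discarded (their intensity statistics are
    biased), objects outside the area window are dropped.  ROIs are returned
    ordered by (centroid row, centroid col) with ids 0..n-1.
    """
    img = np.asarray(dapi_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D single-channel image")
    if params.threshold is None:
        from skimage.filters import threshold_otsu

        if img.max() == img.min():
            return []
        thr = threshold_otsu(img)
    else:
        thr = params.threshold
    fg = img > thr
    if params.fill_holes:
        fg = binary_fill_holes(fg)
    if params.discard_border:
        fg = clear_border(fg)
    lab = label(fg, connectivity=2)
    rois: list[NucleusROI] = []
    for rp in regionprops(lab):
        if not (params.min_area <= rp.area <= params.max_area):
            continue
        r0, c0, r1, c1 = rp.bbox
        rois.append(
            NucleusROI(
                id=-1,
                bbox=(r0, c0, r1, c1),
                mask=rp.image.copy(),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area=int(rp.area),
                image_shape=img.shape,
            )
        )
    rois.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    for i, roi in enumerate(rois):
        roi.id = i
    return rois


def measure_nuclei(
    rois: Sequence[NucleusROI],
    arc_image: np.ndarray,
    condition: str,
    experiment_id: str,
) -> list[NucleusMeasurement]:
    """Mean Arc intensity of each nucleus, taken over mask pixels only."""
    arc = np.asarray(arc_image, dtype=float)
    if rois and arc.shape != rois[0].image_shape:
        raise ValueError(
            f"arc_image shape {arc.shape} does not match segmentation input "
            f"shape {rois[0].image_shape}"
        )
    out = []
    for roi in rois:
        r0, c0, r1, c1 = roi.bbox
        vals = arc[r0:r1, c0:c1][roi.mask]
        out.append(
            NucleusMeasurement(
                nucleus_id=roi.id,
                experiment_id=experiment_id,
                condition=condition,
                mean_arc_intensity=float(vals.mean()),
            )
        )
    return out


def compute_arc_cutoff(
    control_measurements: Iterable[NucleusMeasurement], experiment_id: str
) -> ArcCutoff:
    """Arithmetic mean of control-nucleus Arc intensities for one experiment."""
    vals = [
        m.mean_arc_intensity
        for m in control_measurements
        if m.experiment_id == experiment_id
    ]
    if not vals:
        raise ValueError(f"no control measurements for experiment {experiment_id!r}")
    return ArcCutoff(
        experiment_id=experiment_id,
        threshold=float(np.mean(vals)),
        n_control_nuclei=len(vals),
    )


def classify_arc(
    measurements: Sequence[NucleusMeasurement], cutoff: ArcCutoff
) -> list[NucleusMeasurement]:
    """Set arc_class: positive iff mean intensity strictly exceeds the cutoff.

    A nucleus exactly at the cutoff is negative — the cutoff is the mean of a
    population that is (almost entirely) negative, so equality is not
    evidence of induction.
    """
    out = []
    for m in measurements:
        if m.experiment_id != cutoff.experiment_id:
            raise ValueError(
                f"measurement experiment {m.experiment_id!r} does not match "
                f"cutoff experiment {cutoff.experiment_id!r}"
            )
        cls = "positive" if m.mean_arc_intensity > cutoff.threshold else "negative"
        out.append(replace(m, arc_class=cls))
    return out
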