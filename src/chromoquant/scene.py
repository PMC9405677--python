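"""Synthetic two-channel widefield scenes with full per-nucleus ground truth.

Emulates fields of cultured neurons imaged in two channels: channel 0 is a
DAPI (DNA) image with textured nuclei containing bright chromocenter puncta,
channel 1 is an Arc immunofluorescence image in which each nucleus has a
class-dependent mean level (Arc-positive nuclei are induced, Arc-negative
nuclei sit at baseline).  Every planted object is recorded in a
:class:`SceneGroundTruth` so downstream segmentation / classification /
puncta-detection can be scored against truth.

Scale and defaults
------------------
The defaults encode the study conditions this generator stands in for:

* 49% of nuclei Arc-positive under the stimulated preset;
* per-class chromocenter puncta counts Poisson with means 11.1 (negative)
  and 15.9 (positive);
* per-class punctum areas normal around 431 px^2 (negative) and 488 px^2
  (positive);
* a vehicle (control) preset in which a small fraction of nuclei (10%)
  express Arc spontaneously.  This right-skews the control intensity
  distribution, which is what makes the mean-of-controls cutoff a usable
  class boundary (see docs/methods.md).

Nucleus size (semi-axes 170-200 px) is chosen so that ~13 puncta of ~460 px^2
cover only ~6% of the nuclear area; at much higher coverage the adaptive
mean + k*SD detection threshold would exceed the puncta peaks.

Puncta are rendered as flat-top super-Gaussian blobs
``A * exp(-(r^2 / 2 rho^2)^3)`` whose radius ``rho`` is calibrated per
nucleus so that the blob's boundary at the default batch detection threshold
(mean + detection_k * SD of in-nucleus pixels) encloses exactly the planted
area.  Chromocenters are extended chromatin domains, much larger than the
PSF, so a steep-edged profile is the realistic choice and makes "planted
area" well defined and threshold-robust.

RNG sub-streams
---------------
One seeded generator family per call.  Sub-streams are derived as
``numpy.random.default_rng([seed, TAG])`` with documented tags so that any
single stream can be re-executed independently (the re-draw oracle used in
the tests):

====================  ===  =================================================
stream                tag  draws, in order
====================  ===  =================================================
STREAM_GEOMETRY        1   per nucleus: semi-axes (2 uniforms), angle
                           (1 uniform), then center candidates (2 uniforms
                           per rejection-sampling attempt)
STREAM_CLASSES         2   one ``random(n_nuclei)`` vector for class labels,
                           then one ``standard_normal(n_nuclei)`` vector for
                           Arc level deviations
STREAM_COUNTS          3   per nucleus, in id order, one scalar
                           ``poisson(class_mean)`` call
STREAM_PUNCTA          4   per nucleus: ``normal(mean, sd, size=n)`` areas,
                           then placement draws
STREAM_NOISE           5   per nucleus: texture field; then two full-field
                           ``standard_normal`` read-noise draws (DAPI, Arc)
====================  ===  =================================================
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from numpy.random import Generator, default_rng
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneConfig",
    "PlantedPunctum",
    "GroundTruthNucleus",
    "SceneGroundTruth",
    "generate_widefield_scene",
    "stimulated_preset",
    "vehicle_preset",
    "write_scene",
]

STREAM_GEOMETRY = 1
STREAM_CLASSES = 2
STREAM_COUNTS = 3
STREAM_PUNCTA = 4
STREAM_NOISE = 5

def _area_clip(mean: float, sd: float) -> tuple[float, float]:
    """Clip window for planted punctum areas: +/- 3.5 SD, never below 30% of
    the mean.  At the defaults this is ~[151, 711] px^2 for the negative
    class, comfortably inside the detection size window [50, 2000] so the
    size filter never removes a planted punctum."""
    return (max(mean - 3.5 * sd, 0.3 * mean), mean + 3.5 * sd)


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of one synthetic widefield field of view.

    Intensities are arbitrary camera units; lengths are pixels.
    """

    field_shape: tuple[int, int] = (1900, 1900)
    n_nuclei: int = 7
    nucleus_radius_range: tuple[float, float] = (170.0, 200.0)
    arc_positive_fraction: float = 0.49
    arc_mean_levels: tuple[float, float] = (100.0, 1200.0)  # (negative, positive)
    arc_level_sd: float = 15.0
    puncta_count_mean_neg: float = 11.1
    puncta_count_mean_pos: float = 15.9
    puncta_area_mean_neg: float = 431.0
    puncta_area_mean_pos: float = 488.0
    puncta_area_sd: float = 80.0
    puncta_peak_contrast: float = 2.6  # punctum peak as multiple of local background
    dapi_background: float = 1000.0  # in-nucleus DAPI base level
    noise_sd: float = 10.0  # additive Gaussian read noise (1% of dapi_background)
    seed: int = 0
    # secondary knobs
    dapi_outside: float = 100.0  # DAPI level outside nuclei
    arc_outside: float = 50.0  # Arc level outside nuclei
    texture_rel_sd: float = 0.08  # relative sd of the low-frequency DAPI texture
    edge_sigma: float = 2.0  # Gaussian softening of the nuclear silhouette (px)
    detection_k: float = 2.0  # threshold multiplier the planted areas are calibrated to
    profile_power: int = 3  # super-Gaussian exponent of the punctum profile

    def validate(self) -> None:
        rows, cols = self.field_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("field_shape must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        lo, hi = self.nucleus_radius_range
        if not (0 < lo <= hi):
            raise ValueError("nucleus_radius_range must satisfy 0 < lo <= hi")
        if not 0.0 <= self.arc_positive_fraction <= 1.0:
            raise ValueError("arc_positive_fraction must be in [0, 1]")
        neg, pos = self.arc_mean_levels
        if not pos > neg:
            raise ValueError("positive-class Arc mean must exceed negative-class mean")
        if self.puncta_count_mean_neg < 0 or self.puncta_count_mean_pos < 0:
            raise ValueError("puncta count means must be >= 0")
        if self.puncta_area_mean_neg <= 0 or self.puncta_area_mean_pos <= 0:
            raise ValueError("puncta area means must be > 0")
        if self.puncta_peak_contrast <= 1.0:
            raise ValueError("puncta_peak_contrast must exceed 1 (peak above background)")
        if self.dapi_background <= 0 or self.noise_sd < 0:
            raise ValueError("dapi_background must be > 0 and noise_sd >= 0")
        # rough feasibility check: can n_nuclei disjoint nuclei fit at all?
        bound = hi + self.edge_sigma * 3 + 8
        if self.n_nuclei > 0 and (rows < 2 * bound or cols < 2 * bound):
            raise ValueError("field too small for even one nucleus of the given radius")


@dataclass(frozen=True)
class PlantedPunctum:
    """One planted chromocenter blob (ground truth)."""

    center: tuple[float, float]  # (row, col), global pixel coordinates
    area: float  # px^2, boundary defined at the default detection threshold
    peak_intensity: float  # absolute peak level (background + amplitude)


@dataclass
class GroundTruthNucleus:
    id: int
    center: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    mask: np.ndarray  # boolean raster local to bbox
    arc_class: str  # "positive" | "negative"
    true_mean_arc: float
    puncta: list[PlantedPunctum] = field(default_factory=list)

    @property
    def puncta_count(self) -> int:
        return len(self.puncta)


@dataclass
class SceneGroundTruth:
    config: SceneConfig
    nuclei: list[GroundTruthNucleus]

    @property
    def total_puncta(self) -> int:
        return sum(n.puncta_count for n in self.nuclei)


def stimulated_preset(**overrides) -> SceneConfig:
    """Field after pharmacological network activation: 49% Arc-positive."""
    return replace(SceneConfig(), **overrides)


def vehicle_preset(**overrides) -> SceneConfig:
    """Unstimulated control field: only spontaneous Arc expression (~10%)."""
    cfg = replace(SceneConfig(), arc_positive_fraction=0.10)
    return replace(cfg, **overrides)


# ----------------------------------------------------------------------
# geometry helpers


def _place_nuclei(cfg: SceneConfig, rng: Generator):
    """Draw ellipse parameters and disjoint centers by rejection sampling."""
    rows, cols = cfg.field_shape
    lo, hi = cfg.nucleus_radius_range
    margin = 3.0 * cfg.edge_sigma + 6.0
    placed = []  # (cy, cx, sa, sb, theta, bound_radius)
    max_tries = 200 * max(cfg.n_nuclei, 1)
    for _ in range(cfg.n_nuclei):
        sa = rng.uniform(lo, hi)
        sb = rng.uniform(lo, hi)
        theta = rng.uniform(0.0, np.pi)
        bound = max(sa, sb) + margin
        ok = False
        for _try in range(max_tries):
            cy = rng.uniform(bound, rows - bound)
            cx = rng.uniform(bound, cols - bound)
            if all(
                (cy - py) ** 2 + (cx - px) ** 2 > (bound + pb + 4.0) ** 2
                for py, px, _, _, _, pb in placed
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place {cfg.n_nuclei} disjoint nuclei of radius "
                f"{cfg.nucleus_radius_range} in a {cfg.field_shape} field"
            )
        placed.append((cy, cx, sa, sb, theta, bound))
    return placed


def _ellipse_field(cy, cx, sa, sb, theta, yy, xx):
    """Quadratic form of the ellipse: <= 1 inside."""
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / sa) ** 2 + (v / sb) ** 2


def _place_puncta(rng: Generator, sa, sb, theta, radii, max_restarts=40):
    """Disjoint punctum centers inside the ellipse (ellipse-frame sampling).

    Returns centers as (du, dv) offsets in the rotated ellipse frame; the
    caller converts to image coordinates.  Raises RuntimeError if the draw
    cannot be packed (practically unreachable at default coverage).
    """
    n = len(radii)
    for _restart in range(max_restarts):
        centers: list[tuple[float, float]] = []
        ok = True
        for i, r in enumerate(radii):
            fa = max(sa - (r + 3.0), 1.0) / sa
            fb = max(sb - (r + 3.0), 1.0) / sb
            good = False
            for _try in range(300):
                ang = rng.uniform(0.0, 2 * np.pi)
                rad = np.sqrt(rng.uniform())
                du = rad * np.cos(ang) * sa * fa
                dv = rad * np.sin(ang) * sb * fb
                # 1.45x the sum of boundary radii keeps the summed profile
                # shoulders below threshold even when the threshold sits
                # high on the flat-top profile -> no component merging
                if all(
                    (du - pu) ** 2 + (dv - pv) ** 2 > (1.45 * (r + radii[j])) ** 2
                    for j, (pu, pv) in enumerate(centers)
                ):
                    good = True
                    break
            if not good:
                ok = False
                break
            centers.append((du, dv))
        if ok:
            return centers
    raise RuntimeError(f"could not place {n} disjoint puncta in nucleus")


# ----------------------------------------------------------------------
# rendering


def _render_nucleus(
    cfg: SceneConfig,
    geom,
    arc_class: str,
    n_puncta: int,
    rng_puncta: Generator,
    rng_noise: Generator,
):
    """Render one nucleus patch; returns (bbox, dapi_patch, w, mask, puncta)."""
    rows, cols = cfg.field_shape
    cy, cx, sa, sb, theta, bound = geom
    pad = int(np.ceil(3 * cfg.edge_sigma)) + 4
    r0 = max(int(np.floor(cy - bound)) - pad, 0)
    c0 = max(int(np.floor(cx - bound)) - pad, 0)
    r1 = min(int(np.ceil(cy + bound)) + pad, rows)
    c1 = min(int(np.ceil(cx + bound)) + pad, cols)
    yy = np.arange(r0, r1, dtype=float)[:, None]
    xx = np.arange(c0, c1, dtype=float)[None, :]
    q = _ellipse_field(cy, cx, sa, sb, theta, yy, xx)
    mask = q <= 1.0
    w = gaussian_filter((q <= 1.0).astype(float), cfg.edge_sigma)

    # low-frequency multiplicative chromatin texture
    g = rng_noise.standard_normal(mask.shape)
    g = gaussian_filter(g, 0.2 * min(sa, sb))
    sd = g.std()
    if sd > 0:
        g *= cfg.texture_rel_sd / sd
    base = cfg.dapi_background * (1.0 + g)

    # puncta: areas then placement (STREAM_PUNCTA order documented above)
    if n_puncta > 0:
        area_mean = (
            cfg.puncta_area_mean_pos if arc_class == "positive" else cfg.puncta_area_mean_neg
        )
        areas = rng_puncta.normal(area_mean, cfg.puncta_area_sd, size=n_puncta)
        areas = np.clip(areas, *_area_clip(area_mean, cfg.puncta_area_sd))
        radii = np.sqrt(areas / np.pi)
        offsets = _place_puncta(rng_puncta, sa, sb, theta, radii)
        ct, st = np.cos(theta), np.sin(theta)
        centers = [
            (cy + du * st + dv * ct, cx + du * ct - dv * st) for du, dv in offsets
        ]
    else:
        areas = np.empty(0)
        centers = []

    # amplitude = (contrast - 1) * local background at the punctum center
    amps = np.array(
        [
            (cfg.puncta_peak_contrast - 1.0) * base[int(round(py)) - r0, int(round(px)) - c0]
            for py, px in centers
        ]
    )

    p = cfg.profile_power
    d2 = [
        (yy - py) ** 2 + (xx - px) ** 2 for py, px in centers
    ]  # squared distance fields, one per punctum

    def compose(rho2):
        s = np.zeros_like(base)
        for j in range(len(centers)):
            with np.errstate(over="ignore"):
                s += amps[j] * np.exp(-((d2[j] / (2.0 * rho2[j])) ** p))
        return base + s

    # calibrate rho so the blob boundary at the default detection threshold
    # (mean + detection_k * SD over in-mask pixels of the composed patch)
    # encloses exactly the planted area
    if len(centers) > 0:
        h = 0.5 * amps  # initial guess for threshold elevation above background
        rho2 = areas / (2.0 * np.pi * np.log(amps / h) ** (1.0 / p))
        for _ in range(3):
            dapi = cfg.dapi_outside + w * (compose(rho2) - cfg.dapi_outside)
            vals = dapi[mask]
            thr = vals.mean() + cfg.detection_k * vals.std()
            bg_c = np.array(
                [base[int(round(py)) - r0, int(round(px)) - c0] for py, px in centers]
            )
            h = np.clip(thr - bg_c, 0.05 * amps, 0.9 * amps)
            rho2 = areas / (2.0 * np.pi * np.log(amps / h) ** (1.0 / p))
        dapi = cfg.dapi_outside + w * (compose(rho2) - cfg.dapi_outside)
    else:
        dapi = cfg.dapi_outside + w * (base - cfg.dapi_outside)

    puncta = [
        PlantedPunctum(
            center=(float(py), float(px)),
            area=float(areas[j]),
            peak_intensity=float(amps[j] + base[int(round(py)) - r0, int(round(px)) - c0]),
        )
        for j, (py, px) in enumerate(centers)
    ]
    return (r0, c0, r1, c1), dapi, w, mask, puncta


def generate_widefield_scene(config: SceneConfig):
    """Generate one two-channel scene.

    Returns
    -------
    image : float32 ndarray, shape (2, rows, cols)
        Channel 0 = DAPI, channel 1 = Arc.
    truth : SceneGroundTruth
    """
    config.validate()
    rows, cols = config.field_shape
    seed = config.seed

    rng_geom = default_rng([seed, STREAM_GEOMETRY])
    rng_cls = default_rng([seed, STREAM_CLASSES])
    rng_cnt = default_rng([seed, STREAM_COUNTS])
    rng_pun = default_rng([seed, STREAM_PUNCTA])
    rng_noi = default_rng([seed, STREAM_NOISE])

    geoms = _place_nuclei(config, rng_geom)
    n = config.n_nuclei

    u = rng_cls.random(n)
    labels = np.where(u < config.arc_positive_fraction, "positive", "negative")
    dev = rng_cls.standard_normal(n)
    neg_mean, pos_mean = config.arc_mean_levels
    levels = np.where(labels == "positive", pos_mean, neg_mean) + dev * config.arc_level_sd
    levels = np.maximum(levels, 0.0)

    counts = [
        int(
            rng_cnt.poisson(
                config.puncta_count_mean_pos
                if labels[i] == "positive"
                else config.puncta_count_mean_neg
            )
        )
        for i in range(n)
    ]

    dapi = np.full((rows, cols), config.dapi_outside, dtype=float)
    arc = np.full((rows, cols), config.arc_outside, dtype=float)
    nuclei: list[GroundTruthNucleus] = []
    for i in range(n):
        bbox, patch, w, mask, puncta = _render_nucleus(
            config, geoms[i], labels[i], counts[i], rng_pun, rng_noi
        )
        r0, c0, r1, c1 = bbox
        dapi[r0:r1, c0:c1] += patch - config.dapi_outside
        arc[r0:r1, c0:c1] += w * (levels[i] - config.arc_outside)
        cy, cx = geoms[i][0], geoms[i][1]
        nuclei.append(
            GroundTruthNucleus(
                id=i,
                center=(float(cy), float(cx)),
                bbox=bbox,
                mask=mask,
                arc_class=str(labels[i]),
                true_mean_arc=float(levels[i]),
                puncta=puncta,
            )
        )

    if config.noise_sd > 0:
        dapi += config.noise_sd * rng_noi.standard_normal((rows, cols))
        arc += config.noise_sd * rng_noi.standard_normal((rows, cols))

    image = np.stack([dapi, arc]).astype(np.float32)
    return image, SceneGroundTruth(config=config, nuclei=nuclei)


# ----------------------------------------------------------------------
# persistence


def write_scene(out_dir, image: np.ndarray, truth: SceneGroundTruth, prefix: str = "scene"):
    """Write a scene as multi-page TIFF + ground-truth CSVs + config JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / f"{prefix}.tif", image)

    with open(out / f"{prefix}_nuclei.csv", "w") as fh:
        fh.write("id,row,col,arc_class,true_mean_arc,puncta_count\n")
        for nuc in truth.nuclei:
            fh.write(
                f"{nuc.id},{nuc.center[0]:.2f},{nuc.center[1]:.2f},"
                f"{nuc.arc_class},{nuc.true_mean_arc:.3f},{nuc.puncta_count}\n"
            )
    with open(out / f"{prefix}_puncta.csv", "w") as fh:
        fh.write("nucleus,row,col,area,peak\n")
        for nuc in truth.nuclei:
            for p in nuc.puncta:
                fh.write(
                    f"{nuc.id},{p.center[0]:.2f},{p.center[1]:.2f},"
                    f"{p.area:.2f},{p.peak_intensity:.2f}\n"
                )
    with open(out / f"{prefix}_config.json", "w") as fh:
        json.dump(dataclasses.asdict(truth.config), fh, indent=2)
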