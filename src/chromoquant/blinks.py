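"""Synthetic single-molecule blink movies (STORM-style acquisitions).

A fixed set of point emitters blinks stochastically: in every frame each
emitter fires independently with probability ``blink_rate``; an event
renders the shared Gaussian PSF model at the emitter's true position with an
expected photon budget ``photons_per_blink``, on top of a uniform Poisson
background of ``background`` photons/pixel/frame.  Pixel values are Poisson
draws over signal + background (shot noise); every event is recorded in an
:class:`EmitterTable` as ground truth.

Default acquisition length is 10,000 frames, matching the study's movies.
Physical convention: pixel centers at ``(index + 0.5) * pixel_size_nm``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from numpy.random import default_rng

from .psf import peak_amplitude_for_photons, psf_evaluate

__all__ = [
    "SMLMConfig",
    "EmitterTable",
    "generate_blink_movie",
    "alexa647_preset",
    "alexa488_preset",
    "write_blink_movie",
]


@dataclass(frozen=True)
class SMLMConfig:
    """Acquisition + photophysics parameters of one blink movie."""

    n_frames: int = 10_000
    frame_shape: tuple[int, int] = (64, 64)
    pixel_size_nm: float = 100.0  # a
    psf_sigma_nm: float = 94.0  # s ~ 0.21 * lambda / NA for 670 nm, NA 1.49
    photons_per_blink: float = 1500.0  # N, expected photons per event
    background: float = 10.0  # b, photons/pixel/frame
    n_emitters: int = 40
    emitter_positions: tuple[tuple[float, float], ...] | None = None  # (x, y) nm
    blink_rate: float = 0.003  # events / emitter / frame
    channel: str = "647"
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        rows, cols = self.frame_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("frame_shape must have positive area")
        if self.pixel_size_nm <= 0 or self.psf_sigma_nm <= 0:
            raise ValueError("pixel size and PSF sigma must be positive")
        if self.photons_per_blink <= 0:
            raise ValueError("photons_per_blink must be positive")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if not 0.0 <= self.blink_rate <= 1.0:
            raise ValueError("blink_rate must be in [0, 1]")
        if self.channel not in ("488", "647"):
            raise ValueError("channel must be '488' or '647'")

    @property
    def field_size_nm(self) -> tuple[float, float]:
        rows, cols = self.frame_shape
        return (cols * self.pixel_size_nm, rows * self.pixel_size_nm)


@dataclass
class EmitterTable:
    """Ground-truth blink events: one row per event."""

    emitter: np.ndarray  # int ids
    frame: np.ndarray  # int frame indices
    x_nm: np.ndarray
    y_nm: np.ndarray
    photons: np.ndarray  # expected photons of the event

    def __len__(self) -> int:
        return len(self.frame)


def alexa647_preset(**overrides) -> SMLMConfig:
    """Far-red channel: ~1500 photons/event, 10 bg photons/px, s = 94 nm."""
    return replace(SMLMConfig(), **overrides)


def alexa488_preset(**overrides) -> SMLMConfig:
    """Green channel: narrower PSF (s ~ 73 nm at 520 nm emission), dimmer."""
    cfg = replace(
        SMLMConfig(),
        psf_sigma_nm=73.0,
        photons_per_blink=1000.0,
        channel="488",
    )
    return replace(cfg, **overrides)


def generate_blink_movie(config: SMLMConfig):
    """Generate a blink movie.

    Returns
    -------
    movie : uint16 ndarray, shape (n_frames, rows, cols)
        Photon counts (Poisson over signal + background).
    table : EmitterTable
        Every blink event with its true position and expected photons.
    """
    config.validate()
    rng = default_rng([config.seed, 7])
    rows, cols = config.frame_shape
    a = config.pixel_size_nm
    sigma_px = config.psf_sigma_nm / a

    # emitter positions: given, or uniform in the interior (2*margin off edges)
    if config.emitter_positions is not None:
        pos = np.asarray(config.emitter_positions, dtype=float)
        if pos.size and (
            pos[:, 0].min() < 0
            or pos[:, 1].min() < 0
            or pos[:, 0].max() > cols * a
            or pos[:, 1].max() > rows * a
        ):
            raise ValueError("emitter positions outside the field")
    else:
        margin = 5.0 * config.psf_sigma_nm
        n = config.n_emitters
        pos = np.column_stack(
            [
                rng.uniform(margin, cols * a - margin, size=n),
                rng.uniform(margin, rows * a - margin, size=n),
            ]
        )

    n_emitters = len(pos)
    # blink schedule: independent Bernoulli per emitter per frame
    if n_emitters:
        fires = rng.random((config.n_frames, n_emitters)) < config.blink_rate
        frame_idx, emitter_idx = np.nonzero(fires)
    else:
        frame_idx = emitter_idx = np.empty(0, dtype=int)

    amp = peak_amplitude_for_photons(config.photons_per_blink, sigma_px)
    half = int(np.ceil(4 * sigma_px)) + 1

    signal = np.zeros((config.n_frames, rows, cols), dtype=float)
    for f, e in zip(frame_idx, emitter_idx):
        x_px = pos[e, 0] / a - 0.5  # pixel-center convention
        y_px = pos[e, 1] / a - 0.5
        c0 = max(int(round(x_px)) - half, 0)
        c1 = min(int(round(x_px)) + half + 1, cols)
        r0 = max(int(round(y_px)) - half, 0)
        r1 = min(int(round(y_px)) + half + 1, rows)
        signal[f, r0:r1, c0:c1] += psf_evaluate(
            x_px - c0, y_px - r0, sigma_px, amp, 0.0, (r1 - r0, c1 - c0)
        )

    movie = rng.poisson(signal + config.background).astype(np.uint16)
    table = EmitterTable(
        emitter=emitter_idx.astype(int),
        frame=frame_idx.astype(int),
        x_nm=pos[emitter_idx, 0] if n_emitters else np.empty(0),
        y_nm=pos[emitter_idx, 1] if n_emitters else np.empty(0),
        photons=np.full(len(frame_idx), float(config.photons_per_blink)),
    )
    return movie, table


def write_blink_movie(out_dir, movie: np.ndarray, table: EmitterTable,
                      config: SMLMConfig, prefix: str = "movie"):
    """Write the movie as a TIFF stack + emitter table CSV + config JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / f"{prefix}.tif", movie)
    with open(out / f"{prefix}_emitters.csv", "w") as fh:
        fh.write("emitter,frame,x_nm,y_nm,photons\n")
        for i in range(len(table)):
            fh.write(
                f"{table.emitter[i]},{table.frame[i]},{table.x_nm[i]:.2f},"
                f"{table.y_nm[i]:.2f},{table.photons[i]:.1f}\n"
            )
    with open(out / f"{prefix}_config.json", "w") as fh:
        import json

        json.dump(dataclasses.asdict(config), fh, indent=2)
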