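"""Synthetic inputs with known ground truth.

Three generators mirror the three data streams the analysis consumes:

* noisy FA-versus-age observations from a known maturation clock,
* axial Von Mises orientation samples on [0, 180), and
* Golgi-like raster images — dark anti-aliased strokes with Von
  Mises-distributed orientations on a light noisy background, returned
  together with the generating angles so every pipeline stage can be tested
  against ground truth.

All generators are pure functions of their arguments and the seed: the same
call produces bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .orientation import OrientationSample, RasterImage
from .trajectory import FAObservation, SpeciesFAParams, fa_at_age

__all__ = [
    "GolgiSimSpec",
    "gen_fa_observations",
    "gen_axial_angles",
    "gen_golgi_image",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GolgiSimSpec:
    """Recipe for a synthetic Golgi-like image.

    Strokes emulate stained neurite cross-sections: straight, dark,
    anti-aliased, ``stroke_width_px`` wide, with axial orientations drawn
    from a Von Mises distribution with mean ``mu_deg`` (measured from the
    image-vertical radial axis) and concentration ``kappa``.  The background
    is light with additive Gaussian noise.
    """

    image_size: tuple[int, int] = (512, 512)
    n_segments: int = 300
    mu_deg: float = 0.0
    kappa: float = 1.5
    length_px: tuple[float, float] = (30.0, 80.0)
    stroke_width_px: float = 3.0
    background_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments <= 0:
            raise InvalidInputError("n_segments must be > 0")
        if self.kappa < 0:
            raise InvalidInputError("kappa must be >= 0")
        if not (0 < self.length_px[0] <= self.length_px[1]):
            raise InvalidInputError("stroke lengths must be positive and ordered")
        if self.stroke_width_px <= 0:
            raise InvalidInputError("stroke_width_px must be > 0")
        if min(self.image_size) < 8:
            raise InvalidInputError("image must be at least 8x8 pixels")


def gen_fa_observations(
    params: SpeciesFAParams,
    ages,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[FAObservation]:
    """FA observations at the given ages (dpc): trajectory value plus
    Gaussian noise, clipped to [0, 1]."""
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    ages = np.asarray(ages, dtype=float)
    rng = np.random.default_rng(seed)
    fa = np.asarray(fa_at_age(params, ages), dtype=float)
    fa = np.clip(fa + rng.normal(0.0, noise_sd, size=fa.shape) if noise_sd else fa, 0.0, 1.0)
    return [FAObservation(float(a), float(f)) for a, f in zip(np.atleast_1d(ages), np.atleast_1d(fa))]


def gen_axial_angles(
    mu_deg: float,
    kappa: float,
    n: int,
    seed: int = 0,
    region_label: str = "synthetic",
    plane: str = "coronal",
) -> OrientationSample:
    """Sample axial angles from a Von Mises distribution on the half-circle.

    Draws from Von Mises(2*mu, kappa) on the doubled circle, halves the
    draws and folds them into [0, 180); kappa = 0 gives the uniform axial
    distribution.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if kappa < 0:
        raise InvalidInputError("kappa must be >= 0")
    rng = np.random.default_rng(seed)
    doubled = rng.vonmises(np.radians(2.0 * mu_deg), kappa, size=n)
    angles = (np.degrees(doubled) / 2.0) % 180.0
    return OrientationSample(angles_deg=angles, region_label=region_label, plane=plane)


def _paint_stroke(canvas_alpha: np.ndarray, p0: np.ndarray, p1: np.ndarray, width: float) -> None:
    """Accumulate an anti-aliased capsule (segment with round caps) into the
    alpha buffer via the exact point-to-segment distance."""
    h, w = canvas_alpha.shape
    half = width / 2.0
    pad = half + 1.5
    rmin = max(0, int(np.floor(min(p0[0], p1[0]) - pad)))
    rmax = min(h - 1, int(np.ceil(max(p0[0], p1[0]) + pad)))
    cmin = max(0, int(np.floor(min(p0[1], p1[1]) - pad)))
    cmax = min(w - 1, int(np.ceil(max(p0[1], p1[1]) + pad)))
    if rmin > rmax or cmin > cmax:
        return
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    d = p1 - p0
    L2 = float(d @ d)
    vr, vc = rr - p0[0], cc - p0[1]
    t = np.clip((vr * d[0] + vc * d[1]) / L2, 0.0, 1.0) if L2 > 0 else 0.0
    dist = np.hypot(vr - t * d[0], vc - t * d[1])
    alpha = np.clip(half + 0.5 - dist, 0.0, 1.0)
    region = canvas_alpha[rmin : rmax + 1, cmin : cmax + 1]
    np.maximum(region, alpha, out=region)


def gen_golgi_image(spec: GolgiSimSpec) -> tuple[RasterImage, OrientationSample]:
    """Render a synthetic Golgi-like image plus its ground-truth angles.

    Stroke centres are uniform over the canvas interior; orientations come
    from :func:`gen_axial_angles`.  A stroke whose drawn extent would fall
    entirely outside the canvas is re-drawn at a new centre (bounded
    retries) or dropped with a warning — with interior centres this is rare.
    Intensities are floats in [0, 1]; the stain is dark (~0.08) on a light
    (~0.9) noisy background, left un-thresholded so the analysis pipeline's
    own binarization is exercised.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    sample = gen_axial_angles(
        spec.mu_deg, spec.kappa, spec.n_segments, seed=rng.integers(0, 2**31)
    )
    alpha = np.zeros((h, w), dtype=float)
    kept_angles = []
    for theta in sample.angles_deg:
        rad = np.radians(theta)
        # radial axis is image-vertical: theta=0 runs along rows
        direction = np.array([np.cos(rad), np.sin(rad)])
        for _ in range(10):
            length = rng.uniform(*spec.length_px)
            center = np.array([rng.uniform(0, h - 1), rng.uniform(0, w - 1)])
            p0 = center - 0.5 * length * direction
            p1 = center + 0.5 * length * direction
            inside = lambda p: 0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1
            if inside(p0) or inside(p1) or inside(center):
                _paint_stroke(alpha, p0, p1, spec.stroke_width_px)
                kept_angles.append(float(theta))
                break
        else:
            log.warning("dropped a stroke that never landed on the canvas")
    background = 0.9 + rng.normal(0.0, spec.background_noise_sd, size=(h, w))
    image = np.clip(background * (1.0 - alpha) + 0.08 * alpha, 0.0, 1.0)
    truth = OrientationSample(
        angles_deg=np.array(kept_angles), region_label="ground_truth", plane="coronal"
    )
    return RasterImage(pixels=image, radial_axis="vertical"), truth
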