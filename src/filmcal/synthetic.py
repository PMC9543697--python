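"""Synthetic film measurements with the structure of a scanned-film study.

The emulated delivery is a radially symmetric dose profile with a
homogeneous central plateau (~15 mm radius) and an approximately linear
80-20% falloff between 17 and 26 mm, scaled linearly to a set of dose
levels (plateau doses in Gy) with three repetitions per level.  Film
response follows a chosen ground-truth calibration function; noise
comprises a per-film multiplicative response factor (inter-film
repeatability) and additive per-pixel OD noise that averages down as
1/sqrt(n) when pixels are rebinned by radius.

Defaults mimic an EBT3-like red-channel response (net OD ~0.11 at 1 Gy and
~0.57 at 12 Gy, about two thirds of the saturation OD); they are synthetic
stand-ins, not measured batch parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .models import CalibrationFunction
from .objective import FilmMeasurement, ObjectiveConfig
from .profiles import DEFAULT_PIXEL_SIZE, ODMap

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "default_truth",
    "P1_LEVELS",
    "MULTIFIELD_LEVELS",
    "make_dose_profile",
    "dose_profile_function",
    "simulate_measurement_set",
    "render_film_image",
    "make_multifield_image",
]

#: plateau dose levels (Gy) of the sequential 12-level proton-like session
P1_LEVELS = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 5.0, 7.5, 10.0, 12.0)

#: quadrant plateau doses (Gy) of the single-exposure four-field layout
MULTIFIELD_LEVELS = (4.0, 12.0, 2.0, 0.75)


def default_truth() -> CalibrationFunction:
    """Synthetic EBT3-like ground-truth calibration (bimolecular)."""
    return CalibrationFunction("bimolecular", np.array([0.9, 7.0, 1.0]))


@dataclass
class PhantomSpec:
    """Geometry of the common relative dose profile (normalized to 1)."""

    plateau_radius: float = 15.0
    falloff_hi: Tuple[float, float] = (17.0, 0.8)   # (r mm, relative dose)
    falloff_lo: Tuple[float, float] = (26.0, 0.2)
    cutoff_fraction: float = 0.05
    film_size: float = 67.0
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self):
        if not 0 < self.cutoff_fraction < 0.2:
            raise ValueError("cutoff_fraction must be in (0, 0.2)")
        if self.falloff_hi[0] <= self.plateau_radius:
            raise ValueError("falloff must start beyond the plateau")


@dataclass
class NoiseSpec:
    """Noise amplitudes; all zero yields an exact forward model."""

    od_sigma_rel: float = 0.01     # per-pixel, relative to local OD
    od_sigma_abs: float = 0.002    # per-pixel OD floor
    interfilm_sigma_rel: float = 0.005  # per-film multiplicative response
    seed: int = 0

    def __post_init__(self):
        if min(self.od_sigma_rel, self.od_sigma_abs, self.interfilm_sigma_rel) < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @property
    def silent(self) -> bool:
        return (
            self.od_sigma_rel == 0
            and self.od_sigma_abs == 0
            and self.interfilm_sigma_rel == 0
        )


def dose_profile_function(spec: Optional[PhantomSpec] = None):
    """Continuous normalized dose profile d(r), nonincreasing, d(0)=1.

    Plateau at 1 up to ``plateau_radius``, cosine shoulder to the 80%
    point, linear 80-20% falloff, then an exponential tail with matched
    slope below 20%.
    """
    spec = spec or PhantomSpec()
    r_p = spec.plateau_radius
    r_hi, d_hi = spec.falloff_hi
    r_lo, d_lo = spec.falloff_lo
    slope = (d_lo - d_hi) / (r_lo - r_hi)
    lam = -d_lo / slope  # tail decay length matching the linear slope

    def d(r):
        r = np.asarray(r, dtype=float)
        out = np.ones_like(r)
        sh = (r > r_p) & (r <= r_hi)
        out[sh] = d_hi + (1.0 - d_hi) * np.cos(
            np.pi / 2 * (r[sh] - r_p) / (r_hi - r_p)
        )
        lin = (r > r_hi) & (r <= r_lo)
        out[lin] = d_hi + slope * (r[lin] - r_hi)
        tail = r > r_lo
        out[tail] = d_lo * np.exp(-(r[tail] - r_lo) / lam)
        return out

    return d


def make_dose_profile(
    spec: Optional[PhantomSpec] = None,
    radii: Optional[np.ndarray] = None,
    r_max: float = 30.0,
    bin_width: float = 0.25,
):
    """Sampled normalized profile; returns ``(radii, d, excluded)``.

    ``excluded`` flags samples below ``cutoff_fraction`` of the plateau.
    """
    spec = spec or PhantomSpec()
    if radii is None:
        radii = (np.arange(int(r_max / bin_width)) + 0.5) * bin_width
    radii = np.asarray(radii, dtype=float)
    d = dose_profile_function(spec)(radii)
    return radii, d, d < spec.cutoff_fraction


def _bin_counts(radii: np.ndarray, bin_width: float, pixel_size: float):
    """Approximate pixel count per radial bin (annulus area / pixel area)."""
    return np.maximum(
        1, np.rint(2 * np.pi * radii * bin_width / pixel_size**2).astype(int)
    )


def simulate_measurement_set(
    levels: Sequence[float] = P1_LEVELS,
    reps: int = 3,
    truth: Optional[CalibrationFunction] = None,
    noise: Optional[NoiseSpec] = None,
    spec: Optional[PhantomSpec] = None,
    cfg: Optional[ObjectiveConfig] = None,
    bin_width: float = 0.25,
    r_max: float = 30.0,
) -> List[FilmMeasurement]:
    """Simulate rebinned radial measurements for each (level, repetition).

    Per film: ``o(r) = f(k d(r) | truth) * (1 + delta_film) + eps(r)`` with
    per-bin noise scaled by 1/sqrt(pixel count) to emulate rebinned pixel
    averaging.  The plateau OD is the pixel-weighted mean over
    ``r <= plateau_r_max``; the reference dose equals the plateau dose k.
    Deterministic per ``noise.seed``.
    """
    truth = truth or default_truth()
    noise = noise or NoiseSpec()
    spec = spec or PhantomSpec()
    cfg = cfg or ObjectiveConfig()
    if any(k <= 0 for k in levels):
        raise ValueError("dose levels must be positive")
    rng = np.random.default_rng(noise.seed)
    radii, d_rel, excluded = make_dose_profile(spec, r_max=r_max, bin_width=bin_width)
    counts = _bin_counts(radii, bin_width, spec.pixel_size)
    grad_mask = (radii >= cfg.r_lb) & (radii <= cfg.r_ub) & ~excluded
    plat_mask = radii <= cfg.plateau_r_max

    out: List[FilmMeasurement] = []
    for k in levels:
        for rep in range(reps):
            o = np.asarray(truth.forward_od(k * np.maximum(d_rel, 1e-9)))
            delta = rng.normal(0.0, noise.interfilm_sigma_rel)
            o = o * (1.0 + delta)
            sigma = (noise.od_sigma_abs + noise.od_sigma_rel * o) / np.sqrt(counts)
            if not noise.silent:
                o = o + rng.normal(0.0, 1.0, o.shape) * sigma
            w_plat = counts[plat_mask].astype(float)
            plateau_od = float(np.average(o[plat_mask], weights=w_plat))
            out.append(
                FilmMeasurement(
                    k=float(k),
                    level_id=f"L{k:g}",
                    gradient_r=radii[grad_mask].copy(),
                    gradient_od=o[grad_mask],
                    plateau_od=plateau_od,
                    plateau_od_std=float(np.std(o[plat_mask])),
                    reference_dose=float(k),
                    measurement_id=f"L{k:g}_rep{rep}",
                )
            )
    return out


def _render_od(
    spec: PhantomSpec,
    k: float,
    truth: CalibrationFunction,
    center: Tuple[float, float],
    shape: Tuple[int, int],
    pixel_size: float,
    rng,
    noise: NoiseSpec,
    scatter_dose: float = 0.0,
) -> np.ndarray:
    ny, nx = shape
    x = np.arange(nx) * pixel_size
    y = np.arange(ny) * pixel_size
    X, Y = np.meshgrid(x, y)
    r = np.hypot(X - center[0], Y - center[1])
    dose = k * dose_profile_function(spec)(r) + scatter_dose
    od = np.asarray(truth.forward_od(np.maximum(dose, 1e-9)))
    od *= 1.0 + rng.normal(0.0, noise.interfilm_sigma_rel)
    if not noise.silent:
        sigma = noise.od_sigma_abs + noise.od_sigma_rel * od
        od = od + rng.normal(0.0, 1.0, od.shape) * sigma
    return od


def render_film_image(
    k: float,
    truth: Optional[CalibrationFunction] = None,
    spec: Optional[PhantomSpec] = None,
    noise: Optional[NoiseSpec] = None,
    center_offset: Tuple[float, float] = (0.0, 0.0),
    pixel_size: Optional[float] = None,
    before_level: int = 40000,
):
    """Render a before/after 16-bit image pair for one film exposure.

    ``I_after = mean(I_before) * 10**(-OD)``, invertible by
    :func:`filmcal.profiles.net_optical_density` up to noise and 16-bit
    quantization.  Returns ``(before, after, true_center)``.
    """
    truth = truth or default_truth()
    spec = spec or PhantomSpec()
    noise = noise or NoiseSpec()
    pixel_size = pixel_size or spec.pixel_size
    rng = np.random.default_rng(noise.seed)
    n = int(round(spec.film_size / pixel_size))
    cx = (n - 1) / 2 * pixel_size + center_offset[0]
    cy = (n - 1) / 2 * pixel_size + center_offset[1]
    od = _render_od(spec, k, truth, (cx, cy), (n, n), pixel_size, rng, noise)
    before = np.full((n, n), before_level, dtype=float)
    if not noise.silent:
        before += rng.normal(0.0, 0.001 * before_level, before.shape)
    after = before.mean() * 10.0 ** (-od)
    if np.any(after < 1.0):
        raise ValueError("OD too high for 16-bit intensity (underflow)")
    return (
        np.clip(np.rint(before), 0, 65535).astype(np.uint16),
        np.clip(np.rint(after), 0, 65535).astype(np.uint16),
        (cx, cy),
    )


def make_multifield_image(
    levels: Sequence[float] = MULTIFIELD_LEVELS,
    spacing: float = 120.0,
    truth: Optional[CalibrationFunction] = None,
    spec: Optional[PhantomSpec] = None,
    noise: Optional[NoiseSpec] = None,
    scatter_fraction: float = 0.0,
    image_size: float = 200.0,
    pixel_size: float = 0.4,
    before_level: int = 40000,
):
    """One exposure with four radial fields in quadrant layout.

    Field centers sit on a ``spacing`` grid (quadrants I..IV, i.e. upper
    right, upper left, lower left, lower right); ``scatter_fraction`` adds
    a uniform cross-scatter dose equal to that fraction of the lowest
    plateau dose.  Returns ``(before, after, manifest)``; the manifest
    lists nominal centers, levels and render parameters.
    """
    truth = truth or default_truth()
    spec = spec or PhantomSpec()
    noise = noise or NoiseSpec()
    if len(levels) != 4:
        raise ValueError("quadrant layout takes exactly four dose levels")
    dfun = dose_profile_function(spec)
    # cutoff radius: where the profile falls below cutoff_fraction
    rr = np.linspace(0, image_size, 4096)
    r_cut = float(rr[np.argmax(dfun(rr) < spec.cutoff_fraction)])
    if spacing < 2 * r_cut:
        raise ValueError("fields overlap above the cutoff dose")
    n = int(round(image_size / pixel_size))
    mid = (n - 1) / 2 * pixel_size
    half = spacing / 2
    centers = [
        (mid + half, mid - half),   # I  upper right
        (mid - half, mid - half),   # II upper left
        (mid - half, mid + half),   # III lower left
        (mid + half, mid + half),   # IV lower right
    ]
    rng = np.random.default_rng(noise.seed)
    x = np.arange(n) * pixel_size
    X, Y = np.meshgrid(x, x)
    dose = np.zeros((n, n))
    for k, (cx, cy) in zip(levels, centers):
        dose += k * dfun(np.hypot(X - cx, Y - cy))
    scatter_dose = scatter_fraction * min(levels)
    dose += scatter_dose
    od = np.asarray(truth.forward_od(np.maximum(dose, 1e-9)))
    od *= 1.0 + rng.normal(0.0, noise.interfilm_sigma_rel)
    if not noise.silent:
        sigma = noise.od_sigma_abs + noise.od_sigma_rel * od
        od = od + rng.normal(0.0, 1.0, od.shape) * sigma
    before = np.full((n, n), before_level, dtype=float)
    if not noise.silent:
        before += rng.normal(0.0, 0.001 * before_level, before.shape)
    after = before.mean() * 10.0 ** (-od)
    if np.any(after < 1.0):
        raise ValueError("OD too high for 16-bit intensity (underflow)")
    manifest = {
        "levels": [float(k) for k in levels],
        "centers_mm": [[float(cx), float(cy)] for cx, cy in centers],
        "spacing_mm": float(spacing),
        "pixel_size_mm": float(pixel_size),
        "scatter_fraction": float(scatter_fraction),
        "cutoff_radius_mm": r_cut,
        "seed": int(noise.seed),
        "truth": truth.to_dict(),
    }
    return (
        np.clip(np.rint(before), 0, 65535).astype(np.uint16),
        np.clip(np.rint(after), 0, 65535).astype(np.uint16),
        manifest,
    )
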