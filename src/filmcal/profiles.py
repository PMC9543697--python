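"""Scanner-image front end: net OD maps, center finding, 1D profiles.

Scans are 16-bit intensity images taken before and after irradiation; the
net optical density is ``log10(mean(I_before) / I_after(x, y))`` of one
color channel (red by default).  Radially symmetric fields are reduced to
1D by locating the field center — minimizing the standard deviation of the
OD along the ring where the dose reaches 50% of the plateau — and then
rebinning OD values by radius.  Axially symmetric fields are averaged along
one symmetry axis within a band around it.

Coordinates are mm with the origin at the top-left pixel center, x
rightward, y downward.  Radius bins are half-open ``[b*dr, (b+1)*dr)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .objective import ConfigurationError, FilmMeasurement, ObjectiveConfig

__all__ = [
    "ODMap",
    "RadialProfile",
    "net_optical_density",
    "find_center",
    "radial_rebin",
    "axial_profile",
    "extract_regions",
    "measurement_from_profile",
]

#: 300 dpi scan resolution
DEFAULT_PIXEL_SIZE = 25.4 / 300.0


class DegenerateImageError(ValueError):
    """The OD map carries no radial structure to center on."""


@dataclass
class ODMap:
    values: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    channel: str = "red"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("OD map must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("OD map must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def coords(self):
        """Pixel-center x and y coordinate vectors (mm)."""
        ny, nx = self.values.shape
        return (
            np.arange(nx) * self.pixel_size,
            np.arange(ny) * self.pixel_size,
        )

    def geometric_center(self) -> Tuple[float, float]:
        ny, nx = self.values.shape
        return ((nx - 1) / 2 * self.pixel_size, (ny - 1) / 2 * self.pixel_size)


@dataclass
class RadialProfile:
    radii: np.ndarray
    od_mean: np.ndarray
    od_std: np.ndarray
    count: np.ndarray
    center: Tuple[float, float]
    bin_width: float

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.od_mean = np.asarray(self.od_mean, dtype=float)
        self.od_std = np.asarray(self.od_std, dtype=float)
        self.count = np.asarray(self.count, dtype=int)
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(self.count < 1) or np.any(self.od_std < 0):
            raise ValueError("retained bins need count >= 1 and od_std >= 0")


_CHANNELS = {"red": 0, "green": 1, "blue": 2}


def _select_channel(img: np.ndarray, channel: str) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        return img[..., _CHANNELS[channel]].astype(float)
    return img.astype(float)


def net_optical_density(
    before: np.ndarray,
    after: np.ndarray,
    channel: str = "red",
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    per_pixel_before: bool = False,
    max_flagged_fraction: float = 0.01,
) -> ODMap:
    """Net OD map ``log10(mean(I_before) / I_after)`` of one channel.

    The before-scan enters through its film-wide mean intensity (per-pixel
    division is available via ``per_pixel_before``).  Non-positive after
    pixels are flagged; if more than ``max_flagged_fraction`` of pixels are
    affected the scan is rejected.
    """
    b = _select_channel(before, channel)
    a = _select_channel(after, channel)
    if b.shape != a.shape:
        raise ValueError("before/after images must have the same shape")
    bad = a <= 0
    if bad.mean() > max_flagged_fraction:
        raise ValueError(
            f"{bad.mean():.1%} of after-pixels are zero or negative"
        )
    a = np.where(bad, np.nan, a)
    ref = b if per_pixel_before else float(b.mean())
    od = np.log10(ref / a)
    if np.any(bad):
        # flagged pixels inherit the local finite median so the map stays finite
        od = np.where(bad, np.nanmedian(od), od)
    return ODMap(od, pixel_size=pixel_size, channel=channel)


def _sigma_on_ring(od: ODMap, centers: np.ndarray, r50: float, half_band: float):
    """Std of OD over the annulus r50 +- half_band for candidate centers."""
    x, y = od.coords()
    X, Y = np.meshgrid(x, y)
    vals = od.values
    out = np.empty(len(centers))
    for n, (cx, cy) in enumerate(centers):
        r = np.hypot(X - cx, Y - cy)
        mask = np.abs(r - r50) <= half_band
        out[n] = vals[mask].std() if mask.any() else np.inf
    return out


def find_center(
    od: ODMap,
    r50: float = 21.5,
    coarse_extent: float = 5.0,
    coarse_step: float = 1.0,
    fine_extent: float = 1.0,
    fine_step: float = 0.1,
    half_band: Optional[float] = None,
) -> Tuple[float, float]:
    """Locate a radial field center by minimizing the ring OD spread.

    Two-stage grid search around the geometric image center: a rough grid
    first, then a fine grid around the rough minimum.  ``r50`` is the
    radius of the 50% dose level, where the OD gradient (hence the
    sensitivity of the ring spread to miscentering) is largest.
    """
    if half_band is None:
        half_band = max(od.pixel_size, 0.5)

    def grid(center, extent, step):
        offs = np.arange(-extent, extent + step / 2, step)
        return np.array(
            [(center[0] + dx, center[1] + dy) for dy in offs for dx in offs]
        )

    c0 = od.geometric_center()
    coarse = grid(c0, coarse_extent, coarse_step)
    s_coarse = _sigma_on_ring(od, coarse, r50, half_band)
    if np.ptp(s_coarse[np.isfinite(s_coarse)]) < 1e-12:
        raise DegenerateImageError("OD map has no radial structure")
    c1 = tuple(coarse[int(np.argmin(s_coarse))])
    fine = grid(c1, fine_extent, fine_step)
    s_fine = _sigma_on_ring(od, fine, r50, half_band)
    return tuple(fine[int(np.argmin(s_fine))])


def radial_rebin(
    od: ODMap,
    center: Tuple[float, float],
    bin_width: Optional[float] = None,
    r_max: float = 30.0,
) -> RadialProfile:
    """Rebin an OD map by radius about ``center``.

    Per-bin mean, standard deviation and pixel count; empty bins are
    dropped.  Default bin width is one pixel.
    """
    bin_width = bin_width or od.pixel_size
    x, y = od.coords()
    cx, cy = center
    if not (x[0] <= cx <= x[-1] and y[0] <= cy <= y[-1]):
        raise ValueError("center must lie inside the image")
    X, Y = np.meshgrid(x, y)
    r = np.hypot(X - cx, Y - cy).ravel()
    v = od.values.ravel()
    keep = r < r_max
    r, v = r[keep], v[keep]
    idx = np.floor(r / bin_width).astype(int)
    nb = idx.max() + 1
    count = np.bincount(idx, minlength=nb)
    mu = v.mean()  # center first: stable variance for near-constant maps
    vc = v - mu
    s1 = np.bincount(idx, weights=vc, minlength=nb)
    s2 = np.bincount(idx, weights=vc * vc, minlength=nb)
    nz = count > 0
    mean_c = s1[nz] / count[nz]
    mean = mu + mean_c
    var = np.maximum(s2[nz] / count[nz] - mean_c**2, 0.0)
    centers = (np.nonzero(nz)[0] + 0.5) * bin_width
    return RadialProfile(
        radii=centers,
        od_mean=mean,
        od_std=np.sqrt(var),
        count=count[nz],
        center=(float(cx), float(cy)),
        bin_width=float(bin_width),
    )


def axial_profile(od: ODMap, axis: str = "x", half_width: float = 10.0):
    """Profile along one symmetry axis, averaged within +-half_width of it.

    Returns ``(positions, mean, std)``; the averaging band is centered on
    the middle of the image.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    vals = od.values if axis == "x" else od.values.T
    x, y = od.coords()
    pos, perp = (x, y) if axis == "x" else (y, x)
    mid = (perp[0] + perp[-1]) / 2
    if half_width > (perp[-1] - perp[0]) / 2:
        raise ValueError("half_width exceeds the image")
    band = np.abs(perp - mid) <= half_width
    sub = vals[band, :]
    return pos.copy(), sub.mean(axis=0), sub.std(axis=0)


def extract_regions(profile: RadialProfile, cfg: Optional[ObjectiveConfig] = None):
    """Split a radial profile into plateau statistic and gradient samples.

    The plateau (r <= plateau_r_max) yields a single pixel-weighted mean OD
    used for absolute anchoring; the gradient annulus [r_lb, r_ub] yields
    the per-bin samples driving the ratio objective.  Plateau bins carry no
    ratio information (the profile is flat there) and are excluded from the
    gradient set.
    """
    cfg = cfg or ObjectiveConfig()
    plat = profile.radii <= cfg.plateau_r_max
    grad = (profile.radii >= cfg.r_lb) & (profile.radii <= cfg.r_ub)
    if not plat.any() or not grad.any():
        raise ConfigurationError("profile does not span both regions")
    w = profile.count[plat].astype(float)
    mean = float(np.average(profile.od_mean[plat], weights=w))
    # pooled std over plateau pixels
    var = np.average(
        profile.od_std[plat] ** 2 + (profile.od_mean[plat] - mean) ** 2, weights=w
    )
    plateau = (mean, float(np.sqrt(var)))
    samples = (
        profile.radii[grad].copy(),
        profile.od_mean[grad].copy(),
        np.full(grad.sum(), cfg.w_r),
    )
    return plateau, samples


def measurement_from_profile(
    profile: RadialProfile,
    k: float,
    level_id: str,
    cfg: Optional[ObjectiveConfig] = None,
    reference_dose: Optional[float] = None,
    measurement_id: str = "",
) -> FilmMeasurement:
    """Package a radial profile as a :class:`FilmMeasurement`."""
    (plateau_od, plateau_std), (r, o, w) = extract_regions(profile, cfg)
    return FilmMeasurement(
        k=k,
        level_id=level_id,
        gradient_r=r,
        gradient_od=o,
        gradient_w=w,
        plateau_od=plateau_od,
        plateau_od_std=plateau_std,
        reference_dose=reference_dose,
        measurement_id=measurement_id or level_id,
    )
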