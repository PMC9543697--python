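"""Calibration-function families mapping net optical density to dose.

A calibration function ``f`` maps dose ``d`` (Gy) to net optical density
``o`` and must be bijective over the dose range of interest; dose
reconstruction uses the inverse map ``d = f^-1(o | theta)``.  Two families
are provided:

* ``bimolecular`` — the 3-parameter saturation model
  ``f^-1(o) = theta2 * (o / (theta1 - o))**(1/theta3)`` where ``theta1`` is
  the saturation net OD, ``theta2`` the dose at half-saturation and
  ``theta3`` a shape exponent.  Its forward map is the sigmoid
  ``o = theta1 * (d/theta2)**theta3 / (1 + (d/theta2)**theta3)``.
* ``polynomial`` — a power series in net OD,
  ``f^-1(o) = sum_m theta_m * o**m`` (default degree 4); the forward map is
  obtained by bracketed monotone root finding.

Fitting happens in normalized coordinates (net OD divided by ``od_scale``,
dose divided by ``dose_scale``); ``theta`` is stored in normalized
coordinates and physical-unit parameters are derived on demand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CalibrationFunction",
    "inverse_dose",
    "forward_od",
    "parameter_gradient",
    "check_bijective",
]

_FAMILIES = ("bimolecular", "polynomial")


class CalibrationRangeError(ValueError):
    """Net OD or dose outside the validity range of a calibration."""


class BijectivityError(ValueError):
    """The calibration function is not strictly monotone over its range."""


def _eval_inverse(o: np.ndarray, theta: np.ndarray, family: str) -> np.ndarray:
    """Normalized inverse map o -> d without range checks.

    Returns non-finite values where the map is undefined (e.g. o >= theta1
    for the bimolecular family); callers decide whether that is an error or
    a penalty.
    """
    o = np.asarray(o, dtype=float)
    if family == "polynomial":
        # polyval expects highest-order first
        return np.polyval(theta[::-1], o)
    t1, t2, t3 = theta
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        u = o / (t1 - o)
        d = np.where(u > 0, t2 * np.power(np.abs(u), 1.0 / t3), np.nan)
    return d


def _eval_gradient(o: np.ndarray, theta: np.ndarray, family: str) -> np.ndarray:
    """Partials of the normalized inverse map w.r.t. theta; shape (..., n)."""
    o = np.asarray(o, dtype=float)
    if family == "polynomial":
        # component m is o**m
        powers = np.arange(len(theta))
        return np.power(o[..., None], powers)
    t1, t2, t3 = theta
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        u = o / (t1 - o)
        up = np.power(u, 1.0 / t3)
        d = t2 * up
        g1 = -d / (t3 * (t1 - o))
        g2 = up
        g3 = -d * np.log(u) / t3**2
    return np.stack([g1, g2, g3], axis=-1)


@dataclass(frozen=True)
class CalibrationFunction:
    """A fitted (or constructed) net-OD <-> dose calibration.

    Parameters are stored in normalized coordinates: the model maps
    ``o/od_scale`` to ``d/dose_scale``.  ``valid_od_range`` bounds the net
    OD (physical units) over which the calibration may be evaluated; it is
    set from the lowest and highest net OD observed in training, so the
    calibration is never extrapolated.
    """

    family: str
    theta: np.ndarray
    od_scale: float = 1.0
    dose_scale: float = 1.0
    valid_od_range: Optional[Tuple[float, float]] = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        theta = np.asarray(self.theta, dtype=float)
        if self.family == "bimolecular" and theta.shape != (3,):
            raise ValueError("bimolecular family takes exactly 3 parameters")
        if theta.ndim != 1 or theta.size < 1 or not np.all(np.isfinite(theta)):
            raise ValueError("theta must be a finite 1-D parameter vector")
        object.__setattr__(self, "theta", theta)
        if self.od_scale <= 0 or self.dose_scale <= 0:
            raise ValueError("normalization scales must be positive")
        if self.valid_od_range is not None:
            lo, hi = self.valid_od_range
            if not (0 < lo < hi):
                raise ValueError("valid_od_range must satisfy 0 < o_min < o_max")

    # -- parameter representations ------------------------------------

    @property
    def n_params(self) -> int:
        return self.theta.size

    @property
    def theta_physical(self) -> np.ndarray:
        """Parameters expressed in physical units (Gy, net OD)."""
        if self.family == "polynomial":
            m = np.arange(self.theta.size)
            return self.theta * self.dose_scale / self.od_scale**m
        t1, t2, t3 = self.theta
        return np.array([t1 * self.od_scale, t2 * self.dose_scale, t3])

    @classmethod
    def from_physical(
        cls,
        family: str,
        theta_physical: Sequence[float],
        od_scale: float = 1.0,
        dose_scale: float = 1.0,
        valid_od_range: Optional[Tuple[float, float]] = None,
        meta: Optional[dict] = None,
    ) -> "CalibrationFunction":
        tp = np.asarray(theta_physical, dtype=float)
        if family == "polynomial":
            m = np.arange(tp.size)
            theta = tp * od_scale**m / dose_scale
        else:
            theta = np.array([tp[0] / od_scale, tp[1] / dose_scale, tp[2]])
        return cls(family, theta, od_scale, dose_scale, valid_od_range, meta or {})

    # -- evaluation ----------------------------------------------------

    def _check_range(self, o: np.ndarray) -> None:
        if self.valid_od_range is None:
            return
        lo, hi = self.valid_od_range
        o = np.asarray(o, dtype=float)
        if np.any(o < lo - 1e-12) or np.any(o > hi + 1e-12):
            raise CalibrationRangeError(
                f"net OD outside valid range [{lo:g}, {hi:g}]"
            )

    def inverse_dose(self, o) -> np.ndarray:
        """Dose (Gy) reconstructed from net OD ``o``."""
        o = np.asarray(o, dtype=float)
        self._check_range(o)
        d = _eval_inverse(o / self.od_scale, self.theta, self.family)
        if self.family == "bimolecular" and not np.all(np.isfinite(d)):
            raise CalibrationRangeError(
                "net OD at or above the saturation parameter theta1"
            )
        return d * self.dose_scale

    def forward_od(self, d) -> np.ndarray:
        """Net OD produced by dose ``d`` (Gy); inverse of :meth:`inverse_dose`."""
        d = np.asarray(d, dtype=float)
        if np.any(d <= 0):
            raise ValueError("forward map requires d > 0")
        dn = d / self.dose_scale
        if self.family == "bimolecular":
            t1, t2, t3 = self.theta
            x = np.power(dn / t2, t3)
            on = t1 * x / (1.0 + x)
            return on * self.od_scale
        # polynomial: bracketed monotone root finding over valid_od_range
        if self.valid_od_range is None:
            raise ValueError(
                "polynomial forward map needs valid_od_range as a root bracket"
            )
        lo, hi = self.valid_od_range
        if not self.check_bijective()[0]:
            raise BijectivityError(
                "polynomial is not strictly increasing over valid_od_range"
            )
        d_lo = float(self.inverse_dose(lo))
        d_hi = float(self.inverse_dose(hi))
        flat = dn.reshape(-1) * self.dose_scale
        if np.any(flat < d_lo - 1e-12) or np.any(flat > d_hi + 1e-12):
            raise CalibrationRangeError(
                f"dose outside the image [{d_lo:g}, {d_hi:g}] of valid_od_range"
            )
        out = np.empty_like(flat)
        for idx, dv in np.ndenumerate(flat):
            dv = min(max(dv, d_lo), d_hi)
            out[idx] = brentq(
                lambda o: float(self.inverse_dose(o)) - dv, lo, hi, xtol=1e-12
            )
        return out.reshape(d.shape) if d.shape else float(out[0])

    def parameter_gradient(self, o) -> np.ndarray:
        """Partials of the reconstructed dose w.r.t. the normalized theta.

        Shape ``o.shape + (n_params,)``, in Gy per unit normalized
        parameter (i.e. the gradient of :meth:`inverse_dose`).
        """
        o = np.asarray(o, dtype=float)
        self._check_range(o)
        g = _eval_gradient(o / self.od_scale, self.theta, self.family)
        return g * self.dose_scale

    def check_bijective(self, n_grid: int = 512):
        """Strict monotonicity + positivity of o -> d over valid_od_range.

        Returns ``(ok, diagnostic)``; ``diagnostic`` names the violating
        interval when ``ok`` is False.
        """
        if self.valid_od_range is None:
            raise ValueError("valid_od_range must be set for a bijectivity check")
        lo, hi = self.valid_od_range
        grid = np.linspace(lo, hi, n_grid)
        d = _eval_inverse(grid / self.od_scale, self.theta, self.family)
        d = d * self.dose_scale
        if not np.all(np.isfinite(d)):
            return False, "non-finite dose over valid_od_range"
        dd = np.diff(d)
        if np.any(dd <= 0):
            i = int(np.argmax(dd <= 0))
            return False, (
                f"not strictly increasing on [{grid[i]:.4g}, {grid[i + 1]:.4g}]"
            )
        if np.any(d <= 0):
            i = int(np.argmax(d <= 0))
            return False, f"non-positive dose near o={grid[i]:.4g}"
        return True, "strictly increasing and positive"

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "theta": self.theta_physical.tolist(),
            "od_scale": self.od_scale,
            "dose_scale": self.dose_scale,
            "valid_od_range": list(self.valid_od_range)
            if self.valid_od_range is not None
            else None,
            "meta": self.meta,
        }
        if self.family == "polynomial":
            d["degree"] = self.theta.size - 1
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationFunction":
        rng = d.get("valid_od_range")
        return cls.from_physical(
            d["family"],
            d["theta"],
            od_scale=d.get("od_scale", 1.0),
            dose_scale=d.get("dose_scale", 1.0),
            valid_od_range=tuple(rng) if rng is not None else None,
            meta=d.get("meta", {}),
        )

    @classmethod
    def from_json(cls, source) -> "CalibrationFunction":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            try:
                d = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)

    def with_range(self, lo: float, hi: float) -> "CalibrationFunction":
        return replace(self, valid_od_range=(float(lo), float(hi)))


# Thin functional wrappers -------------------------------------------------

def inverse_dose(o, cal: CalibrationFunction):
    return cal.inverse_dose(o)


def forward_od(d, cal: CalibrationFunction):
    return cal.forward_od(d)


def parameter_gradient(o, cal: CalibrationFunction):
    return cal.parameter_gradient(o)


def check_bijective(cal: CalibrationFunction, n_grid: int = 512):
    return cal.check_bijective(n_grid)
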