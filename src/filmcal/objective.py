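"""Dose-ratio cost function and its analytic gradient.

The same relative dose profile ``d(r)`` delivered at different dose levels
``k_i`` produces net-OD profiles ``o_i(r) = f(k_i d(r) | theta)``.  For the
true calibration, reconstructed doses from any two levels satisfy
``k_j f^-1(o_i(r)) - k_i f^-1(o_j(r)) = 0`` at every position r, which
removes the unknown profile from the problem.  The ratio cost sums the
squared, level-normalized residual

    h_{i,j,r}^2 = (k_i k_j)^-2 (k_j f^-1(o_{i,r}) - k_i f^-1(o_{j,r}))^2

over all positions in the gradient region and over all measurement pairs
from different dose levels (chi_a).  A side objective chi_b, the standard
least-squares fit of plateau net OD against a known reference dose, anchors
the absolute dose scale; its weight is normalized by the number of summands
so the two terms are balanced.  The total cost is chi = chi_a + chi_b.

All costs here are evaluated in the normalized coordinates of the supplied
calibration (net OD / od_scale, dose / dose_scale); the gradient is taken
with respect to the normalized parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .models import CalibrationFunction, _eval_gradient, _eval_inverse

__all__ = [
    "FilmMeasurement",
    "ObjectiveConfig",
    "CostBreakdown",
    "enumerate_pairs",
    "pair_cost",
    "cost_ratio",
    "cost_side",
    "total_cost_and_gradient",
]

# Finite penalty returned when a parameter vector drives the model outside
# its domain (e.g. net OD >= theta1 for the bimolecular family); keeps line
# searches well-defined where the cost would otherwise be NaN.
PENALTY_COST = 1e10


class ConfigurationError(ValueError):
    pass


class AlignmentError(ValueError):
    """Measurements are not sampled on a common radius grid."""


@dataclass
class FilmMeasurement:
    """One film exposure of the common profile at dose level ``k`` (Gy).

    ``gradient_r``/``gradient_od`` sample the dose-falloff annulus used by
    the ratio objective; ``plateau_od`` is the mean net OD of the central
    homogeneous region, used for absolute anchoring and verification.
    Repetitions of the same delivery share ``level_id`` and are never paired
    with each other.
    """

    k: float
    level_id: str
    gradient_r: np.ndarray
    gradient_od: np.ndarray
    gradient_w: Optional[np.ndarray] = None
    plateau_od: Optional[float] = None
    plateau_od_std: Optional[float] = None
    reference_dose: Optional[float] = None
    measurement_id: str = ""

    def __post_init__(self):
        self.gradient_r = np.asarray(self.gradient_r, dtype=float)
        self.gradient_od = np.asarray(self.gradient_od, dtype=float)
        if self.gradient_r.shape != self.gradient_od.shape:
            raise ValueError("gradient radii and OD must have the same shape")
        if self.k <= 0:
            raise ValueError("dose level k must be positive")
        if np.any(self.gradient_od <= 0):
            raise ValueError("net OD samples must be positive (d, o != 0)")
        if self.gradient_w is None:
            self.gradient_w = np.ones_like(self.gradient_od)
        else:
            self.gradient_w = np.asarray(self.gradient_w, dtype=float)
            if np.any(self.gradient_w < 0):
                raise ValueError("weights must be non-negative")


@dataclass
class ObjectiveConfig:
    """Region bounds and weights of the ratio objective.

    ``r_lb``/``r_ub`` bound the gradient region (mm); ``plateau_r_max`` the
    central plateau; ``w_s`` weights the absolute-dose side objective.  By
    default only the highest training dose level contributes side-objective
    points.
    """

    r_lb: float = 15.0
    r_ub: float = 27.0
    plateau_r_max: float = 7.8
    w_r: float = 1.0
    w_s: float = 10.0
    side_objective_doses: str = "highest"  # or "all"

    def __post_init__(self):
        if not self.r_lb < self.r_ub:
            raise ConfigurationError("r_lb must be < r_ub")
        if self.w_s <= 0:
            raise ConfigurationError("w_s must be positive")


@dataclass
class CostBreakdown:
    chi_a: float
    chi_b: float
    chi: float
    grad: np.ndarray
    n_pairs: int
    n_positions: int
    w_b: float = 0.0
    penalized: bool = False


def enumerate_pairs(measurements: Sequence[FilmMeasurement]) -> List[Tuple[int, int]]:
    """All unordered index pairs (i < j) from different dose levels.

    Repetitions of the same level share ``level_id`` and are excluded; for
    N levels with 3 repetitions each this yields 9 N (N-1) / 2 pairs.
    """
    if len(measurements) < 2:
        raise ConfigurationError("need at least two measurements")
    levels = [m.level_id for m in measurements]
    if len(set(levels)) < 2:
        raise ConfigurationError("need at least two distinct dose levels")
    return [
        (i, j)
        for i in range(len(measurements))
        for j in range(i + 1, len(measurements))
        if levels[i] != levels[j]
    ]


def _common_radii(measurements: Sequence[FilmMeasurement], cfg: ObjectiveConfig):
    """Shared radius grid restricted to [r_lb, r_ub]; error if grids differ."""
    r0 = measurements[0].gradient_r
    for m in measurements[1:]:
        if m.gradient_r.shape != r0.shape or not np.allclose(
            m.gradient_r, r0, atol=1e-9
        ):
            raise AlignmentError(
                "measurements must be rebinned to a common radius grid"
            )
    mask = (r0 >= cfg.r_lb) & (r0 <= cfg.r_ub)
    if not np.any(mask):
        raise ConfigurationError("no gradient samples inside [r_lb, r_ub]")
    return r0, mask


def _gradient_arrays(measurements, cfg):
    """Stack per-measurement OD/weight arrays over the shared grid."""
    _, mask = _common_radii(measurements, cfg)
    od = np.stack([m.gradient_od[mask] for m in measurements])
    w = np.stack([m.gradient_w[mask] for m in measurements]) * cfg.w_r
    k = np.array([m.k for m in measurements], dtype=float)
    return od, w, k, int(mask.sum())


def _side_points(measurements: Sequence[FilmMeasurement], cfg: ObjectiveConfig):
    """(plateau OD, reference dose) points entering chi_b.

    One point per dose level: repetitions are averaged to a single plateau
    OD, so with the default "highest" selection N_d = 1.
    """
    with_ref = [
        m
        for m in measurements
        if m.reference_dose is not None and m.plateau_od is not None
    ]
    if not with_ref:
        raise ConfigurationError(
            "side objective needs at least one measurement with a reference dose"
        )
    if cfg.side_objective_doses == "highest":
        kmax = max(m.k for m in with_ref)
        with_ref = [m for m in with_ref if m.k == kmax]
    od, dose = [], []
    for lid in dict.fromkeys(m.level_id for m in with_ref):
        grp = [m for m in with_ref if m.level_id == lid]
        od.append(np.mean([m.plateau_od for m in grp]))
        dose.append(np.mean([m.reference_dose for m in grp]))
    return np.array(od), np.array(dose)


def side_weight(cfg: ObjectiveConfig, n_pairs: int, n_positions: int, n_d: int) -> float:
    """Balance weight w_b = w_s * (chi_a summand count) / (chi_b count)."""
    return cfg.w_s * n_pairs * n_positions / n_d


# -- core evaluation (normalized coordinates) ------------------------------

def _core_cost(theta, family, od_n, w, k_n, pairs, side_od_n, side_d_n, w_b,
               with_grad=True):
    """chi_a, chi_b and gradient in normalized coordinates.

    ``od_n``: (M, Nr) normalized gradient OD; ``k_n``: (M,) normalized dose
    levels; ``pairs``: (P, 2) int array.  Non-finite model output yields a
    large finite penalty (with a restoring gradient for the bimolecular
    saturation parameter) instead of NaN.
    """
    n_par = len(theta)
    o_all = np.concatenate([od_n.ravel(), side_od_n])
    o_max = float(np.max(o_all))
    if family == "bimolecular" and (theta[0] <= o_max or theta[2] == 0.0):
        viol = max(o_max * 1.001 - theta[0], 0.0) + (theta[2] == 0.0)
        grad = np.zeros(n_par)
        grad[0] = -PENALTY_COST
        return PENALTY_COST * (1.0 + viol), 0.0, grad, True

    d = _eval_inverse(od_n, theta, family)  # (M, Nr)
    d_side = _eval_inverse(side_od_n, theta, family)
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(d_side))):
        return PENALTY_COST, 0.0, np.zeros(n_par), True

    I, J = pairs[:, 0], pairs[:, 1]
    ki, kj = k_n[I], k_n[J]
    inv = 1.0 / (ki * kj)
    h = inv[:, None] * (kj[:, None] * d[I] - ki[:, None] * d[J])  # (P, Nr)
    wp = np.sqrt(w[I] * w[J])  # both default 1; geometric mean for per-pos w_r
    chi_a = float(np.sum(wp * h**2))
    res = d_side - side_d_n
    chi_b = float(w_b * np.sum(res**2))

    if not with_grad:
        return chi_a, chi_b, None, False

    g = _eval_gradient(od_n, theta, family)  # (M, Nr, n_par)
    g_side = _eval_gradient(side_od_n, theta, family)  # (Nd, n_par)
    dh = inv[:, None, None] * (
        kj[:, None, None] * g[I] - ki[:, None, None] * g[J]
    )  # (P, Nr, n_par)
    grad_a = 2.0 * np.einsum("pr,pr,prm->m", wp, h, dh)
    grad_b = 2.0 * w_b * np.einsum("i,im->m", res, g_side)
    return chi_a, chi_b, grad_a + grad_b, False


def _core_residuals(theta, family, od_n, w, k_n, pairs, side_od_n, side_d_n, w_b,
                    with_jac=True):
    """Stacked residual vector [sqrt(w) h_{ij,r}, sqrt(w_b) side] and Jacobian.

    chi equals the sum of squares of this vector; the trust-region
    least-squares minimizer consumes this form directly.
    """
    d = _eval_inverse(od_n, theta, family)
    d_side = _eval_inverse(side_od_n, theta, family)
    I, J = pairs[:, 0], pairs[:, 1]
    ki, kj = k_n[I], k_n[J]
    inv = 1.0 / (ki * kj)
    h = inv[:, None] * (kj[:, None] * d[I] - ki[:, None] * d[J])
    sw = np.sqrt(np.sqrt(w[I] * w[J]))  # sqrt of the pair weight
    res = np.concatenate(
        [(sw * h).ravel(), np.sqrt(w_b) * (d_side - side_d_n)]
    )
    if not with_jac:
        return res, None
    g = _eval_gradient(od_n, theta, family)
    g_side = _eval_gradient(side_od_n, theta, family)
    dh = inv[:, None, None] * (
        kj[:, None, None] * g[I] - ki[:, None, None] * g[J]
    )
    jac = np.concatenate(
        [
            (sw[..., None] * dh).reshape(-1, len(theta)),
            np.sqrt(w_b) * g_side,
        ]
    )
    return res, jac


def _prepare(measurements, cal: CalibrationFunction, cfg: ObjectiveConfig):
    od, w, k, nr = _gradient_arrays(measurements, cfg)
    pairs = np.array(enumerate_pairs(measurements), dtype=int)
    side_od, side_d = _side_points(measurements, cfg)
    w_b = side_weight(cfg, len(pairs), nr, len(side_od))
    return (
        od / cal.od_scale,
        w,
        k / cal.dose_scale,
        pairs,
        side_od / cal.od_scale,
        side_d / cal.dose_scale,
        w_b,
        nr,
    )


# -- public operations -----------------------------------------------------

def pair_cost(
    mi: FilmMeasurement,
    mj: FilmMeasurement,
    cal: CalibrationFunction,
    cfg: Optional[ObjectiveConfig] = None,
) -> float:
    """Ratio cost of a single measurement pair, summed over positions."""
    cfg = cfg or ObjectiveConfig()
    _, mask = _common_radii([mi, mj], cfg)
    ki, kj = mi.k / cal.dose_scale, mj.k / cal.dose_scale
    di = _eval_inverse(mi.gradient_od[mask] / cal.od_scale, cal.theta, cal.family)
    dj = _eval_inverse(mj.gradient_od[mask] / cal.od_scale, cal.theta, cal.family)
    if not (np.all(np.isfinite(di)) and np.all(np.isfinite(dj))):
        raise ValueError("net OD outside the calibration domain")
    w = np.sqrt(mi.gradient_w[mask] * mj.gradient_w[mask]) * cfg.w_r
    h2 = (ki * kj) ** -2 * (kj * di - ki * dj) ** 2
    return float(np.sum(w * h2))


def cost_ratio(measurements, cal, cfg: Optional[ObjectiveConfig] = None):
    """Total ratio cost chi_a over all cross-level pairs.

    Returns ``(chi_a, n_pairs, n_positions)``.
    """
    cfg = cfg or ObjectiveConfig()
    od, w, k, nr = _gradient_arrays(measurements, cfg)
    pairs = np.array(enumerate_pairs(measurements), dtype=int)
    chi_a, _, _, pen = _core_cost(
        cal.theta, cal.family, od / cal.od_scale, w, k / cal.dose_scale,
        pairs, np.empty(0), np.empty(0), 0.0, with_grad=False,
    )
    if pen:
        raise ValueError("net OD outside the calibration domain")
    return chi_a, len(pairs), nr


def cost_side(measurements, cal, cfg: Optional[ObjectiveConfig] = None) -> float:
    """Absolute-dose side objective chi_b (normalized coordinates)."""
    cfg = cfg or ObjectiveConfig()
    _, _, k, nr = _gradient_arrays(measurements, cfg)
    n_pairs = len(enumerate_pairs(measurements))
    side_od, side_d = _side_points(measurements, cfg)
    w_b = side_weight(cfg, n_pairs, nr, len(side_od))
    d = _eval_inverse(side_od / cal.od_scale, cal.theta, cal.family)
    if not np.all(np.isfinite(d)):
        raise ValueError("plateau OD outside the calibration domain")
    return float(w_b * np.sum((d - side_d / cal.dose_scale) ** 2))


def total_cost_and_gradient(
    measurements, cal, cfg: Optional[ObjectiveConfig] = None
) -> CostBreakdown:
    """chi = chi_a + chi_b with its analytic parameter gradient."""
    cfg = cfg or ObjectiveConfig()
    od_n, w, k_n, pairs, s_od, s_d, w_b, nr = _prepare(measurements, cal, cfg)
    chi_a, chi_b, grad, pen = _core_cost(
        cal.theta, cal.family, od_n, w, k_n, pairs, s_od, s_d, w_b
    )
    return CostBreakdown(
        chi_a=chi_a,
        chi_b=chi_b,
        chi=chi_a + chi_b,
        grad=grad,
        n_pairs=len(pairs),
        n_positions=nr,
        w_b=w_b,
        penalized=pen,
    )
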