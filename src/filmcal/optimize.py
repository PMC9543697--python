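"""Parameter estimation for the ratio and standard calibration methods.

Both methods minimize a smooth cost with its analytic gradient using an
unconstrained quasi-Newton minimizer, after normalizing net OD and dose of
the training data to [0, 1].  Start parameters are drawn from a normal
distribution; starts that are not physically meaningful (non-finite cost,
or a fitted function that fails the bijectivity check) are rejected, and
the lowest-cost accepted restart wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

from .models import CalibrationFunction
from .objective import (
    ConfigurationError,
    FilmMeasurement,
    ObjectiveConfig,
    PENALTY_COST,
    _core_cost,
    _core_residuals,
    _gradient_arrays,
    _side_points,
    enumerate_pairs,
    side_weight,
)

__all__ = [
    "FitConfig",
    "OptimizationResult",
    "ConvergenceError",
    "random_start",
    "fit_ratio_method",
    "fit_standard_method",
]


class ConvergenceError(RuntimeError):
    """No restart produced an accepted (bijective, finite-cost) fit."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class FitConfig:
    """Optimizer settings.

    ``start_scale`` is the standard deviation of the normal start-value
    distribution in normalized coordinates; small values avoid the
    oscillation / start-value cross-correlation seen with polynomial
    models.  ``require_highest_dose`` enforces that the highest-dose
    training measurement carries a reference dose so the side objective
    anchors the top of the curve.
    """

    family: str = "polynomial"
    degree: int = 4
    n_restarts: int = 20
    start_scale: float = 0.1
    seed: int = 0
    grad_tol: float = 1e-10
    max_iter: int = 1000
    require_highest_dose: bool = True
    #: "trf" = trust-region least squares (default); "BFGS" = quasi-Newton
    method: str = "trf"

    @property
    def n_params(self) -> int:
        return 3 if self.family == "bimolecular" else self.degree + 1


@dataclass
class OptimizationResult:
    cal: CalibrationFunction
    final_cost: float
    n_iterations: int
    n_restarts_used: int
    start_seed: int
    converged: bool
    rejected_starts: int
    diagnostics: List[dict] = field(default_factory=list)


def random_start(n_params: int, seed: int, scale: float = 0.1) -> np.ndarray:
    """I.i.d. normal(0, scale^2) start vector; deterministic per seed."""
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    if scale < 0:
        raise ValueError("scale must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, scale, n_params)


def _family_start(z: np.ndarray, family: str, o_max_n: float) -> np.ndarray:
    """Map a zero-centered draw to a physically meaningful start.

    Zero-centered values are fine for the polynomial family but infeasible
    for the saturation model, whose theta1 must exceed the largest observed
    net OD; its draws are re-centered on a feasible anchor.
    """
    if family == "polynomial":
        return z.copy()
    theta0 = np.array([1.2 * o_max_n, 0.5, 1.0]) + z
    if theta0[0] <= o_max_n:
        theta0[0] = o_max_n * 1.2 + abs(z[0])
    return theta0


def _minimize_one(cost_fn, resid_fn, theta0, fit_cfg: FitConfig, o_max_n: float):
    """One start -> (theta, cost, n_iter) with the configured minimizer."""
    if fit_cfg.method == "trf":
        n_res = resid_fn(theta0)[0].size

        def fun(theta):
            res, _ = resid_fn(theta, with_jac=False)
            if res is None or not np.all(np.isfinite(res)):
                return np.full(n_res, 1e6)
            return res

        def jac(theta):
            res, J = resid_fn(theta)
            if J is None or not np.all(np.isfinite(J)):
                return np.zeros((n_res, theta.size))
            return J

        if fit_cfg.family == "bimolecular":
            # domain restriction: saturation OD above every observed net OD
            lo = np.full(fit_cfg.n_params, -np.inf)
            lo[0] = o_max_n * (1.0 + 1e-9)
            bounds = (lo, np.full(fit_cfg.n_params, np.inf))
        else:
            bounds = (-np.inf, np.inf)
        res = least_squares(
            fun,
            theta0,
            jac=jac,
            method="trf",
            bounds=bounds,
            gtol=fit_cfg.grad_tol,
            ftol=1e-14,
            xtol=1e-14,
            max_nfev=fit_cfg.max_iter,
        )
        return res.x, float(2.0 * res.cost), int(res.nfev)
    res = minimize(
        cost_fn,
        theta0,
        jac=True,
        method=fit_cfg.method,
        options={"gtol": fit_cfg.grad_tol, "maxiter": fit_cfg.max_iter},
    )
    return res.x, float(res.fun), int(res.nit)


def _run_restarts(cost_fn, resid_fn, fit_cfg: FitConfig, o_max_n: float, scales,
                  od_range):
    """Multi-restart minimization; returns the best accepted fit."""
    od_scale, dose_scale = scales
    best = None
    rejected = 0
    diagnostics = []
    root = np.random.SeedSequence(fit_cfg.seed)
    child_seeds = root.generate_state(fit_cfg.n_restarts, dtype=np.uint32)
    for r, s in enumerate(child_seeds):
        z = random_start(fit_cfg.n_params, int(s), fit_cfg.start_scale)
        theta0 = _family_start(z, fit_cfg.family, o_max_n)
        c0, _ = cost_fn(theta0)
        if not np.isfinite(c0) or c0 >= PENALTY_COST:
            rejected += 1
            diagnostics.append({"restart": r, "status": "rejected_start"})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theta_fit, _, nit = _minimize_one(
                cost_fn, resid_fn, theta0, fit_cfg, o_max_n
            )
        cost = float(cost_fn(theta_fit)[0])
        cal = CalibrationFunction(
            fit_cfg.family,
            theta_fit,
            od_scale=od_scale,
            dose_scale=dose_scale,
            valid_od_range=od_range,
        )
        ok, why = cal.check_bijective()
        if not ok or not np.isfinite(cost) or cost >= PENALTY_COST:
            rejected += 1
            diagnostics.append(
                {"restart": r, "status": "rejected_fit", "reason": why,
                 "cost": cost}
            )
            continue
        diagnostics.append(
            {"restart": r, "status": "accepted", "cost": cost, "n_iter": nit}
        )
        if best is None or cost < best[0]:
            best = (cost, cal, nit, r)
    if best is None:
        raise ConvergenceError(
            "no restart produced an accepted calibration", diagnostics
        )
    cost, cal, nit, _ = best
    return OptimizationResult(
        cal=cal,
        final_cost=cost,
        n_iterations=nit,
        n_restarts_used=fit_cfg.n_restarts,
        start_seed=fit_cfg.seed,
        converged=True,
        rejected_starts=rejected,
        diagnostics=diagnostics,
    )


def _training_scales(measurements: Sequence[FilmMeasurement], cfg: ObjectiveConfig):
    """Normalization scales and valid range from the training data."""
    ods = [m.gradient_od for m in measurements]
    ods += [np.array([m.plateau_od]) for m in measurements if m.plateau_od is not None]
    all_od = np.concatenate(ods)
    doses = [m.k for m in measurements]
    doses += [m.reference_dose for m in measurements if m.reference_dose is not None]
    od_scale = float(np.max(all_od))
    dose_scale = float(np.max(doses))
    od_range = (float(np.min(all_od)), float(np.max(all_od)))
    return od_scale, dose_scale, od_range


def fit_ratio_method(
    measurements: Sequence[FilmMeasurement],
    cfg: Optional[ObjectiveConfig] = None,
    fit_cfg: Optional[FitConfig] = None,
) -> OptimizationResult:
    """Fit a calibration by minimizing chi = chi_a + chi_b.

    Needs at least two distinct dose levels; by default the highest-dose
    training measurement must carry a reference dose (the side objective
    anchor), since validity never extends above the measured range.
    """
    cfg = cfg or ObjectiveConfig()
    fit_cfg = fit_cfg or FitConfig()
    pairs = np.array(enumerate_pairs(measurements), dtype=int)

    k_max = max(m.k for m in measurements)
    anchored = [
        m for m in measurements
        if m.reference_dose is not None and m.plateau_od is not None
    ]
    if not anchored or max(m.k for m in anchored) < k_max:
        msg = "highest-dose training measurement has no reference dose"
        if fit_cfg.require_highest_dose:
            raise ConfigurationError(msg)
        warnings.warn(msg)

    od_scale, dose_scale, od_range = _training_scales(measurements, cfg)
    od, w, k, nr = _gradient_arrays(measurements, cfg)
    side_od, side_d = _side_points(measurements, cfg)
    w_b = side_weight(cfg, len(pairs), nr, len(side_od))

    od_n = od / od_scale
    k_n = k / dose_scale
    s_od_n = side_od / od_scale
    s_d_n = side_d / dose_scale

    def cost_fn(theta):
        chi_a, chi_b, grad, _ = _core_cost(
            theta, fit_cfg.family, od_n, w, k_n, pairs, s_od_n, s_d_n, w_b
        )
        return chi_a + chi_b, grad

    def resid_fn(theta, with_jac=True):
        return _core_residuals(
            theta, fit_cfg.family, od_n, w, k_n, pairs, s_od_n, s_d_n, w_b,
            with_jac=with_jac,
        )

    return _run_restarts(
        cost_fn, resid_fn, fit_cfg, float(np.max(od_n)),
        (od_scale, dose_scale), od_range,
    )


def fit_standard_method(
    measurements: Sequence[FilmMeasurement],
    fit_cfg: Optional[FitConfig] = None,
) -> OptimizationResult:
    """Least-squares fit of plateau net OD against reference dose.

    The classical calibration from spatially homogeneous exposures; only
    evaluated when the number of (plateau OD, dose) points strictly exceeds
    the number of free parameters.
    """
    fit_cfg = fit_cfg or FitConfig()
    pts = [
        (m.plateau_od, m.reference_dose)
        for m in measurements
        if m.plateau_od is not None and m.reference_dose is not None
    ]
    if len(pts) <= fit_cfg.n_params:
        raise ConfigurationError(
            f"standard method needs more than {fit_cfg.n_params} "
            f"(plateau OD, dose) points; got {len(pts)}"
        )
    od = np.array([p[0] for p in pts])
    dose = np.array([p[1] for p in pts])
    od_scale = float(np.max(od))
    dose_scale = float(np.max(dose))
    # validity spans everything measured on the training films (gradient
    # region included), not just the fitted plateau points
    all_od = np.concatenate(
        [m.gradient_od for m in measurements] + [od]
    )
    od_range = (float(np.min(all_od)), float(np.max(all_od)))
    od_n = od / od_scale
    d_n = dose / dose_scale
    empty_od = np.empty((0, 1))
    empty_w = np.empty((0, 1))
    empty_k = np.empty(0)
    no_pairs = np.empty((0, 2), dtype=int)

    def cost_fn(theta):
        chi_a, chi_b, grad, _ = _core_cost(
            theta, fit_cfg.family, empty_od, empty_w, empty_k, no_pairs,
            od_n, d_n, 1.0,
        )
        return chi_a + chi_b, grad

    def resid_fn(theta, with_jac=True):
        return _core_residuals(
            theta, fit_cfg.family, empty_od, empty_w, empty_k, no_pairs,
            od_n, d_n, 1.0, with_jac=with_jac,
        )

    return _run_restarts(
        cost_fn, resid_fn, fit_cfg, float(np.max(od_n)),
        (od_scale, dose_scale), od_range,
    )
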