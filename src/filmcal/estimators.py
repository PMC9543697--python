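"""Scikit-learn style calibration estimators.

:class:`RatioCalibrator` fits the dose-ratio objective on a list of
:class:`~filmcal.objective.FilmMeasurement`; :class:`StandardCalibrator`
fits plateau (net OD, dose) points directly.  After ``fit`` both expose
``predict(od) -> dose`` (and ``inverse_transform(dose) -> od``), so a
calibrator drops into sklearn pipelines and model-selection utilities via
``get_params`` / ``set_params`` / ``clone``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .objective import FilmMeasurement, ObjectiveConfig
from .optimize import FitConfig, fit_ratio_method, fit_standard_method

__all__ = ["RatioCalibrator", "StandardCalibrator"]


class _BaseCalibrator(RegressorMixin, BaseEstimator):
    def __init__(
        self,
        family: str = "polynomial",
        degree: int = 4,
        n_restarts: int = 20,
        start_scale: float = 0.1,
        grad_tol: float = 1e-10,
        max_iter: int = 1000,
        random_state: int = 0,
    ):
        self.family = family
        self.degree = degree
        self.n_restarts = n_restarts
        self.start_scale = start_scale
        self.grad_tol = grad_tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _fit_cfg(self, **extra) -> FitConfig:
        return FitConfig(
            family=self.family,
            degree=self.degree,
            n_restarts=self.n_restarts,
            start_scale=self.start_scale,
            seed=self.random_state,
            grad_tol=self.grad_tol,
            max_iter=self.max_iter,
            **extra,
        )

    def predict(self, od):
        """Dose (Gy) from net OD; input may be any array shape."""
        check_is_fitted(self, "calibration_")
        od = np.asarray(od, dtype=float)
        return self.calibration_.inverse_dose(od.ravel()).reshape(od.shape)

    def inverse_transform(self, dose):
        """Net OD from dose (Gy); the forward film-response map."""
        check_is_fitted(self, "calibration_")
        return self.calibration_.forward_od(dose)


class RatioCalibrator(_BaseCalibrator):
    """Calibration from dose ratios of a profile scaled to several levels.

    Parameters mirror :class:`~filmcal.optimize.FitConfig` and
    :class:`~filmcal.objective.ObjectiveConfig`.  Fitted attributes:

    ``calibration_`` : CalibrationFunction
        Accepted lowest-cost fit (physical units, validity range set from
        training).
    ``result_`` : OptimizationResult
        Restart diagnostics and final cost.
    """

    def __init__(
        self,
        family: str = "polynomial",
        degree: int = 4,
        r_lb: float = 15.0,
        r_ub: float = 27.0,
        plateau_r_max: float = 7.8,
        w_s: float = 10.0,
        side_objective_doses: str = "highest",
        n_restarts: int = 20,
        start_scale: float = 0.1,
        grad_tol: float = 1e-10,
        max_iter: int = 1000,
        require_highest_dose: bool = True,
        random_state: int = 0,
    ):
        super().__init__(
            family=family,
            degree=degree,
            n_restarts=n_restarts,
            start_scale=start_scale,
            grad_tol=grad_tol,
            max_iter=max_iter,
            random_state=random_state,
        )
        self.r_lb = r_lb
        self.r_ub = r_ub
        self.plateau_r_max = plateau_r_max
        self.w_s = w_s
        self.side_objective_doses = side_objective_doses
        self.require_highest_dose = require_highest_dose

    def fit(self, measurements: Sequence[FilmMeasurement], y=None):
        cfg = ObjectiveConfig(
            r_lb=self.r_lb,
            r_ub=self.r_ub,
            plateau_r_max=self.plateau_r_max,
            w_s=self.w_s,
            side_objective_doses=self.side_objective_doses,
        )
        result = fit_ratio_method(
            measurements,
            cfg,
            self._fit_cfg(require_highest_dose=self.require_highest_dose),
        )
        self.result_ = result
        self.calibration_ = result.cal
        self.n_features_in_ = 1
        return self


class StandardCalibrator(_BaseCalibrator):
    """Classical calibration from homogeneous exposures.

    ``fit`` accepts either a list of measurements carrying plateau OD and
    reference dose, or explicit arrays ``(od, dose)``.
    """

    def fit(self, X, y: Optional[np.ndarray] = None):
        if y is not None:
            od = np.asarray(X, dtype=float).ravel()
            dose = np.asarray(y, dtype=float).ravel()
            measurements = [
                FilmMeasurement(
                    k=float(d),
                    level_id=f"L{i}",
                    gradient_r=np.array([20.0]),
                    gradient_od=np.array([o]),
                    plateau_od=float(o),
                    reference_dose=float(d),
                )
                for i, (o, d) in enumerate(zip(od, dose))
            ]
        else:
            measurements = X
        result = fit_standard_method(measurements, self._fit_cfg())
        self.result_ = result
        self.calibration_ = result.cal
        self.n_features_in_ = 1
        return self
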