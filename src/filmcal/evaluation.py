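"""Verification experiments: held-out RMSD, random splits, ratio sweep.

A fitted calibration is scored on held-out plateau points: the relative
dose deviation 100*(f^-1(plateau OD) - d_ref)/d_ref per measurement, and
their root-mean-square (RMSD, %).  Experiments repeat fits over random
train/test splits of the dose levels with fresh random start values, and
summarize the RMSD distribution by its quartiles.  Test points whose
plateau OD falls outside the fitted validity range are excluded from the
RMSD but counted, since a calibration is only valid between the lowest and
highest net OD seen in training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import CalibrationFunction
from .objective import ConfigurationError, FilmMeasurement, ObjectiveConfig
from .optimize import (
    ConvergenceError,
    FitConfig,
    OptimizationResult,
    fit_ratio_method,
    fit_standard_method,
)
from .profiles import (
    ODMap,
    find_center,
    measurement_from_profile,
    net_optical_density,
    radial_rebin,
)

__all__ = [
    "ExperimentSummary",
    "dose_residuals",
    "rmsd",
    "split_experiment",
    "ratio_sweep",
    "single_measurement_calibration",
]


@dataclass
class ExperimentSummary:
    """RMSD distribution over repeated random splits for one method."""

    method: str
    n_train_levels: int
    n_repeats: int
    seed: int
    rmsd_train: List[float]
    rmsd_test: List[float]
    percentiles_train: Dict[int, float]
    percentiles_test: Dict[int, float]
    records: pd.DataFrame = field(repr=False, default=None)


def dose_residuals(
    cal: CalibrationFunction,
    measurements: Sequence[FilmMeasurement],
    strict: bool = True,
) -> np.ndarray:
    """Relative dose deviations (%) on plateau points.

    With ``strict=False``, points whose plateau OD is outside the
    calibration's valid range are returned as NaN instead of raising, so
    callers can count them separately.
    """
    out = np.empty(len(measurements))
    lo, hi = cal.valid_od_range if cal.valid_od_range else (-np.inf, np.inf)
    for n, m in enumerate(measurements):
        if m.reference_dose is None or m.plateau_od is None:
            raise ValueError("measurement lacks plateau OD or reference dose")
        if not (lo - 1e-12 <= m.plateau_od <= hi + 1e-12):
            if strict:
                raise ValueError("plateau OD outside the calibration range")
            out[n] = np.nan
            continue
        d = float(cal.inverse_dose(m.plateau_od))
        out[n] = 100.0 * (d - m.reference_dose) / m.reference_dose
    return out


def rmsd(residuals) -> float:
    """Root mean square of percent residuals."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size == 0:
        raise ValueError("rmsd of an empty residual list")
    return float(np.sqrt(np.mean(residuals**2)))


def _levels(dataset: Sequence[FilmMeasurement]) -> List[str]:
    seen: List[str] = []
    for m in dataset:
        if m.level_id not in seen:
            seen.append(m.level_id)
    return seen


def _fit_once(train, method, cfg, fit_cfg):
    if method == "ratio":
        return fit_ratio_method(train, cfg, fit_cfg)
    return fit_standard_method(train, fit_cfg)


def _score(cal, train, test):
    """Train/test RMSD; out-of-range test points are dropped but counted."""
    res_train = dose_residuals(cal, train, strict=False)
    res_test = dose_residuals(cal, test, strict=False)
    n_oor = int(np.isnan(res_test).sum())
    res_test = res_test[~np.isnan(res_test)]
    res_train = res_train[~np.isnan(res_train)]
    return (
        rmsd(res_train) if res_train.size else np.nan,
        rmsd(res_test) if res_test.size else np.nan,
        n_oor,
    )


def split_experiment(
    dataset: Sequence[FilmMeasurement],
    n_train: int,
    n_repeats: int = 200,
    seed: int = 0,
    method: str = "ratio",
    cfg: Optional[ObjectiveConfig] = None,
    fit_cfg: Optional[FitConfig] = None,
) -> ExperimentSummary:
    """Repeated random level-wise train/test splits with fresh starts.

    Dose levels are sampled as units (a level and all its repetitions move
    together).  Each repeat uses a single fresh random start; the repeat's
    level choice and start seed derive only from ``(seed, repeat)``, so the
    same splits and start values are reused when the experiment is re-run
    with the other method.
    """
    cfg = cfg or ObjectiveConfig()
    fit_cfg = fit_cfg or FitConfig()
    levels = _levels(dataset)
    if len(levels) < n_train + 1:
        raise ConfigurationError("need at least n_train + 1 dose levels")
    by_level = {lv: [m for m in dataset if m.level_id == lv] for lv in levels}
    recs = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        chosen = list(rng.choice(levels, size=n_train, replace=False))
        start_seed = int(rng.integers(0, 2**31 - 1))
        train = [m for lv in chosen for m in by_level[lv]]
        test = [m for lv in levels if lv not in chosen for m in by_level[lv]]
        rep_fit_cfg = replace(
            fit_cfg, n_restarts=1, seed=start_seed, require_highest_dose=False
        )
        rec = {
            "repeat": rep,
            "levels": ",".join(chosen),
            "start_seed": start_seed,
            "method": method,
        }
        try:
            result = _fit_once(train, method, cfg, rep_fit_cfg)
        except (ConvergenceError, ConfigurationError) as err:
            rec.update(status=type(err).__name__, rmsd_train=np.nan,
                       rmsd_test=np.nan, n_out_of_range=0)
            recs.append(rec)
            continue
        tr, te, n_oor = _score(result.cal, train, test)
        rec.update(status="ok", rmsd_train=tr, rmsd_test=te,
                   n_out_of_range=n_oor, final_cost=result.final_cost)
        recs.append(rec)
    records = pd.DataFrame(recs)
    ok = records[records.status == "ok"]

    def q(col):
        vals = ok[col].to_numpy(dtype=float) if len(ok) else np.array([np.nan])
        if np.all(np.isnan(vals)):
            return {p: float("nan") for p in (25, 50, 75)}
        return {p: float(np.nanpercentile(vals, p)) for p in (25, 50, 75)}
    return ExperimentSummary(
        method=method,
        n_train_levels=n_train,
        n_repeats=n_repeats,
        seed=seed,
        rmsd_train=ok.rmsd_train.tolist(),
        rmsd_test=ok.rmsd_test.tolist(),
        percentiles_train=q("rmsd_train"),
        percentiles_test=q("rmsd_test"),
        records=records,
    )


def ratio_sweep(
    dataset: Sequence[FilmMeasurement],
    n_repeats: int = 50,
    seed: int = 0,
    cfg: Optional[ObjectiveConfig] = None,
    fit_cfg: Optional[FitConfig] = None,
    require_highest: bool = True,
) -> pd.DataFrame:
    """Two-level calibration quality as a function of the training dose ratio.

    For each admissible pair of dose levels, repeated fits with fresh
    random starts; rows report the dose ratio ``k_max/k_min`` and RMSD
    quartiles over the held-out levels.  By default only pairs containing
    the highest dose level are admissible (the side objective anchors the
    top of the curve); other pairs are flagged, not fitted.
    """
    cfg = cfg or ObjectiveConfig()
    fit_cfg = fit_cfg or FitConfig()
    levels = _levels(dataset)
    if len(levels) < 3:
        raise ConfigurationError("sweep needs at least three dose levels")
    by_level = {lv: [m for m in dataset if m.level_id == lv] for lv in levels}
    k_of = {lv: by_level[lv][0].k for lv in levels}
    k_max = max(k_of.values())
    rows = []
    for a in range(len(levels)):
        for b in range(a + 1, len(levels)):
            la, lb = levels[a], levels[b]
            ratio = max(k_of[la], k_of[lb]) / min(k_of[la], k_of[lb])
            admissible = k_max in (k_of[la], k_of[lb]) or not require_highest
            row = {
                "level_a": la, "level_b": lb, "dose_ratio": ratio,
                "admissible": admissible,
            }
            if not admissible:
                rows.append(row)
                continue
            train = by_level[la] + by_level[lb]
            test = [m for lv in levels if lv not in (la, lb)
                    for m in by_level[lv]]
            vals = []
            n_failed = 0
            for rep in range(n_repeats):
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, a, b, rep])
                )
                rep_cfg = replace(
                    fit_cfg, n_restarts=1,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    require_highest_dose=False,
                )
                try:
                    result = _fit_once(train, "ratio", cfg, rep_cfg)
                    _, te, _ = _score(result.cal, train, test)
                    vals.append(te)
                except (ConvergenceError, ConfigurationError):
                    n_failed += 1
            vals = np.asarray(vals, dtype=float)
            vals = vals[~np.isnan(vals)]
            row.update(
                n_fits=len(vals), n_failed=n_failed,
                rmsd_p25=float(np.percentile(vals, 25)) if vals.size else np.nan,
                rmsd_p50=float(np.percentile(vals, 50)) if vals.size else np.nan,
                rmsd_p75=float(np.percentile(vals, 75)) if vals.size else np.nan,
            )
            rows.append(row)
    return pd.DataFrame(rows).sort_values("dose_ratio").reset_index(drop=True)


def single_measurement_calibration(
    before: np.ndarray,
    after: np.ndarray,
    manifest: dict,
    cfg: Optional[ObjectiveConfig] = None,
    fit_cfg: Optional[FitConfig] = None,
    crop_half_width: float = 35.0,
    refine_centers: bool = True,
) -> Tuple[OptimizationResult, pd.DataFrame]:
    """End-to-end calibration from one four-field exposure.

    Crops a fixed window around each nominal field center, finds each
    field's center, rebins by radius, extracts regions and runs the ratio
    fit on the four levels.  Returns the fit and a per-field residual
    report on the plateau points.
    """
    cfg = cfg or ObjectiveConfig()
    fit_cfg = fit_cfg or FitConfig()
    pixel_size = float(manifest["pixel_size_mm"])
    od = net_optical_density(before, after, pixel_size=pixel_size)
    half_px = int(round(crop_half_width / pixel_size))
    measurements = []
    for k, (cx, cy) in zip(manifest["levels"], manifest["centers_mm"]):
        ix = int(round(cx / pixel_size))
        iy = int(round(cy / pixel_size))
        sub = od.values[iy - half_px: iy + half_px + 1,
                        ix - half_px: ix + half_px + 1]
        sub_map = ODMap(sub, pixel_size=pixel_size, channel=od.channel)
        if refine_centers:
            center = find_center(sub_map)
        else:
            center = (
                cx - (ix - half_px) * pixel_size,
                cy - (iy - half_px) * pixel_size,
            )
        profile = radial_rebin(sub_map, center, bin_width=0.25)
        measurements.append(
            measurement_from_profile(
                profile, k=float(k), level_id=f"L{k:g}", cfg=cfg,
                reference_dose=float(k), measurement_id=f"field_{k:g}",
            )
        )
    result = fit_ratio_method(measurements, cfg, fit_cfg)
    res = dose_residuals(result.cal, measurements, strict=False)
    report = pd.DataFrame(
        {
            "level": [m.k for m in measurements],
            "plateau_od": [m.plateau_od for m in measurements],
            "residual_pct": res,
        }
    )
    return result, report
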