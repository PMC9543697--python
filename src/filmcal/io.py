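"""Serialization of measurement sets and profiles.

Measurement sets travel as a long-format CSV (one row per sampled position,
``region`` distinguishing gradient samples from the plateau statistic) plus
a JSON manifest holding dose levels, reference doses and provenance.
Radial profiles are CSV with a JSON sidecar (center, bin width, channel).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .objective import FilmMeasurement
from .profiles import RadialProfile

__all__ = [
    "measurements_to_frame",
    "frame_to_measurements",
    "save_measurements",
    "load_measurements",
    "save_profile",
    "load_profile",
]


def measurements_to_frame(measurements: Sequence[FilmMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        for r, o, w in zip(m.gradient_r, m.gradient_od, m.gradient_w):
            rows.append(
                dict(
                    measurement_id=m.measurement_id,
                    level_id=m.level_id,
                    k=m.k,
                    r_mm=r,
                    net_od=o,
                    weight=w,
                    region="gradient",
                )
            )
        if m.plateau_od is not None:
            rows.append(
                dict(
                    measurement_id=m.measurement_id,
                    level_id=m.level_id,
                    k=m.k,
                    r_mm=0.0,
                    net_od=m.plateau_od,
                    weight=1.0,
                    region="plateau",
                )
            )
    return pd.DataFrame(rows)


def frame_to_measurements(
    frame: pd.DataFrame, reference_doses: Optional[dict] = None
) -> List[FilmMeasurement]:
    reference_doses = reference_doses or {}
    out = []
    for mid, g in frame.groupby("measurement_id", sort=False):
        grad = g[g.region == "gradient"]
        plat = g[g.region == "plateau"]
        out.append(
            FilmMeasurement(
                k=float(g.k.iloc[0]),
                level_id=str(g.level_id.iloc[0]),
                gradient_r=grad.r_mm.to_numpy(),
                gradient_od=grad.net_od.to_numpy(),
                gradient_w=grad.weight.to_numpy(),
                plateau_od=float(plat.net_od.iloc[0]) if len(plat) else None,
                reference_dose=reference_doses.get(str(mid)),
                measurement_id=str(mid),
            )
        )
    return out


def save_measurements(measurements: Sequence[FilmMeasurement], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    measurements_to_frame(measurements).to_csv(
        directory / "measurements.csv", index=False
    )
    manifest = {
        "measurements": [
            {
                "measurement_id": m.measurement_id,
                "level_id": m.level_id,
                "k": m.k,
                "reference_dose": m.reference_dose,
            }
            for m in measurements
        ]
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_measurements(directory) -> List[FilmMeasurement]:
    directory = Path(directory)
    frame = pd.read_csv(directory / "measurements.csv")
    manifest = json.loads((directory / "manifest.json").read_text())
    refs = {
        e["measurement_id"]: e["reference_dose"]
        for e in manifest["measurements"]
        if e.get("reference_dose") is not None
    }
    return frame_to_measurements(frame, refs)


def save_profile(profile: RadialProfile, csv_path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "r_mm": profile.radii,
            "od_mean": profile.od_mean,
            "od_std": profile.od_std,
            "count": profile.count,
        }
    ).to_csv(csv_path, index=False)
    sidecar = {
        "center_mm": list(profile.center),
        "bin_width_mm": profile.bin_width,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_profile(csv_path) -> RadialProfile:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    return RadialProfile(
        radii=frame.r_mm.to_numpy(),
        od_mean=frame.od_mean.to_numpy(),
        od_std=frame.od_std.to_numpy(),
        count=frame["count"].to_numpy(),
        center=tuple(sidecar["center_mm"]),
        bin_width=float(sidecar["bin_width_mm"]),
    )
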