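"""CSV/YAML readers and writers for the pipeline's external interfaces."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .length_models import derive_bhdf, validate_records
from .photogrammetry import AltitudeSeries, CameraModel, DEFAULT_CAMERAS

__all__ = [
    "load_morphometrics",
    "load_measurements",
    "load_altitude_log",
    "load_cameras",
    "write_morphometrics",
]

_MORPH_RENAME = {"age_years": "age", "tl_cm": "tl", "bhdf_cm": "bhdf"}


def load_morphometrics(path: str | Path) -> pd.DataFrame:
    """Read morphometrics.csv into the canonical records table.

    Accepts either a ``bhdf_cm`` column or the pair ``tip_to_dorsal_cm`` /
    ``tip_to_blowhole_cm``, from which BHDF is derived by subtraction.
    """
    df = pd.read_csv(path).rename(columns=_MORPH_RENAME)
    if "bhdf" not in df.columns:
        if {"tip_to_dorsal_cm", "tip_to_blowhole_cm"} <= set(df.columns):
            df["bhdf"] = [
                derive_bhdf(d, b)
                for d, b in zip(df["tip_to_dorsal_cm"], df["tip_to_blowhole_cm"])
            ]
        else:
            raise ValueError(
                f"{path}: need bhdf_cm or tip_to_dorsal_cm + tip_to_blowhole_cm"
            )
    if "assessment_id" not in df.columns:
        df["assessment_id"] = [f"S{i:05d}" for i in range(len(df))]
    return validate_records(df)


def write_morphometrics(df: pd.DataFrame, path: str | Path) -> None:
    out = df.rename(columns={v: k for k, v in _MORPH_RENAME.items()})
    out.to_csv(path, index=False)


def load_measurements(path: str | Path) -> pd.DataFrame:
    """Read measurements.csv (image-level pixel measurements)."""
    df = pd.read_csv(path)
    required = {"animal_id", "behavior", "altitude_m", "measure_kind", "pixel_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def load_altitude_log(path: str | Path) -> AltitudeSeries:
    """Read altitude_log.csv (timestamp_s, altitude_m)."""
    df = pd.read_csv(path)
    return AltitudeSeries(
        timestamps=df["timestamp_s"].to_numpy(float),
        raw=df["altitude_m"].to_numpy(float),
    )


def load_cameras(path: str | Path | None) -> dict[str, CameraModel]:
    """Read a cameras.yaml registry; None returns the built-in registry."""
    if path is None:
        return dict(DEFAULT_CAMERAS)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        name: CameraModel.from_dict(name, entry)
        for name, entry in raw.get("cameras", raw).items()
    }
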