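"""Convert raw drone measurements into metric lengths and quantify their error.

A nadir-pointing camera at altitude ``h`` images the sea surface with a ground
sample distance (GSD) of ``h * pixel_pitch / focal_length`` metres per pixel,
so an animal spanning ``p`` pixels is ``p * GSD`` metres long.  Altitude comes
from a laser altimeter whose log occasionally contains spurious readings;
those are despiked with a running-median filter before scaling.  Accuracy is
quantified as the percent difference between UAS estimates and physical
(tape-measure) references, summarised per group as mean, SD and SE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

logger = logging.getLogger(__name__)

__all__ = [
    "CameraModel",
    "AltitudeSeries",
    "ImageMeasurement",
    "ErrorEstimate",
    "smooth_altitude",
    "pixel_to_metric",
    "percent_difference",
    "summarize_measurement_error",
    "error_report",
]


@dataclass(frozen=True)
class CameraModel:
    """Physical camera description used for pixel-to-metric scaling.

    Parameters
    ----------
    name
        Registry key, e.g. ``"zenmuse_x5s"``.
    focal_length
        Lens focal length in metres (25 mm lens -> 0.025).
    pixel_pitch
        Physical sensor pixel size in metres per pixel, at the recorded
        image resolution (video crops change the effective pitch).
    image_width, image_height
        Recorded image size in pixels.
    """

    name: str
    focal_length: float
    pixel_pitch: float
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        if self.focal_length <= 0:
            raise ValueError(f"focal_length must be > 0, got {self.focal_length}")
        if self.pixel_pitch <= 0:
            raise ValueError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be > 0")

    @classmethod
    def from_dict(cls, name: str, d: Mapping[str, float]) -> "CameraModel":
        """Build from a registry entry with mm/µm units (cameras.yaml)."""
        return cls(
            name=name,
            focal_length=float(d["focal_length_mm"]) * 1e-3,
            pixel_pitch=float(d["pixel_pitch_um"]) * 1e-6,
            image_width=int(d["image_width"]),
            image_height=int(d["image_height"]),
        )


#: Cameras used on the two survey platforms: a DJI Zenmuse X5S recording 4K
#: video and an Olympus E-PM2 taking stills, both Micro Four Thirds (17.3 mm
#: sensor width) behind a 25 mm lens.
DEFAULT_CAMERAS: dict[str, CameraModel] = {
    "zenmuse_x5s": CameraModel("zenmuse_x5s", 0.025, 17.3e-3 / 3840, 3840, 2160),
    "olympus_epm2": CameraModel("olympus_epm2", 0.025, 17.3e-3 / 4608, 4608, 3456),
}


@dataclass
class AltitudeSeries:
    """Laser-altimeter time series; ``smoothed`` is filled by smooth_altitude."""

    timestamps: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.timestamps.shape != self.raw.shape:
            raise ValueError("timestamps and raw altitudes must have equal length")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be monotone non-decreasing")


@dataclass(frozen=True)
class ImageMeasurement:
    """One pixel-length measurement digitised from a single image."""

    animal_id: str
    platform: str
    behavior: str  # "stationary" | "surfacing"
    altitude: float  # metres
    measure_kind: str  # "TL" | "BHDF"
    pixel_length: float
    observer: str = ""

    def __post_init__(self) -> None:
        if self.behavior not in ("stationary", "surfacing"):
            raise ValueError(f"behavior must be stationary|surfacing, got {self.behavior!r}")
        if self.measure_kind not in ("TL", "BHDF"):
            raise ValueError(f"measure_kind must be TL|BHDF, got {self.measure_kind!r}")
        if self.pixel_length <= 0:
            raise ValueError("pixel_length must be > 0")
        if self.altitude <= 0:
            raise ValueError("altitude must be > 0")


@dataclass(frozen=True)
class ErrorEstimate:
    """Relative-error summary of a group of UAS-vs-physical comparisons.

    Relative errors are stored as dimensionless fractions (3.3% -> 0.033);
    percent rendering happens only in reports.
    """

    mean_rel_error: float
    sd_rel_error: float
    se_rel_error: float
    n: int
    measure_kind: str = "TL"  # "TL" | "BHDF" | "TL_from_BHDF"
    behavior: str | None = None
    group: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_rel_error < 0:
            raise ValueError("sd_rel_error must be >= 0")

    @property
    def mean_pct(self) -> float:
        return 100.0 * self.mean_rel_error

    @property
    def sd_pct(self) -> float:
        return 100.0 * self.sd_rel_error

    @property
    def se_pct(self) -> float:
        return 100.0 * self.se_rel_error


def smooth_altitude(
    series: AltitudeSeries,
    window: int = 5,
    spike_threshold: float = 1.0,
    max_passes: int = 100,
) -> AltitudeSeries:
    """Despike a laser-altimeter series with running-median replacement.

    Points deviating from the running median (width ``window``, edges
    extended by the nearest value) by more than ``spike_threshold`` metres
    are replaced by that median; all other points pass through unchanged.
    The pass is iterated until a fixed point, so the operation is idempotent.

    Raises
    ------
    ValueError
        On an empty series, an even/too-small window, or if any smoothed
        value is non-positive (the offending index is named).
    """
    if series.raw.size == 0:
        raise ValueError("cannot smooth an empty altitude series")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if spike_threshold <= 0:
        raise ValueError("spike_threshold must be > 0")

    x = series.raw.astype(float).copy()
    for _ in range(max_passes):
        med = median_filter(x, size=min(window, x.size | 1), mode="nearest")
        spikes = np.abs(x - med) > spike_threshold
        if not spikes.any():
            break
        x[spikes] = med[spikes]

    bad = np.nonzero(x <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive smoothed altitude at index {bad[0]}")
    return replace(series, smoothed=x)


def pixel_to_metric(pixel_length: float, altitude: float, camera: CameraModel) -> float:
    """Convert a pixel length to centimetres via the ground sample distance.

    GSD (m/px) = altitude * pixel_pitch / focal_length for a nadir camera;
    the result is ``pixel_length * GSD`` expressed in cm.
    """
    if altitude <= 0:
        raise ValueError(f"altitude must be > 0, got {altitude}")
    if pixel_length <= 0:
        raise ValueError(f"pixel_length must be > 0, got {pixel_length}")
    gsd = altitude * camera.pixel_pitch / camera.focal_length
    return float(pixel_length * gsd * 100.0)


def percent_difference(estimate: float, reference: float) -> float:
    """Signed percent difference of an estimate from its reference.

    Positive values are overestimates: ``100 * (estimate - reference) / reference``.
    """
    if np.any(np.asarray(reference) <= 0):
        raise ValueError("reference must be > 0")
    return 100.0 * (np.asarray(estimate) - reference) / reference


def _summarize(pct: np.ndarray, measure_kind: str, behavior: str | None, group: tuple) -> ErrorEstimate:
    n = pct.size
    sd = float(np.std(pct, ddof=1)) if n > 1 else 0.0
    return ErrorEstimate(
        mean_rel_error=float(np.mean(pct)) / 100.0,
        sd_rel_error=sd / 100.0,
        se_rel_error=(sd / np.sqrt(n)) / 100.0,
        n=int(n),
        measure_kind=measure_kind,
        behavior=behavior,
        group=group,
    )


def summarize_measurement_error(
    measurements: pd.DataFrame | Iterable[tuple[float, float]],
    group_keys: Sequence[str] = (),
    estimate_col: str = "estimate",
    reference_col: str = "reference",
    measure_kind: str = "TL",
    behavior: str | None = None,
) -> dict[tuple, ErrorEstimate]:
    """Summarise percent differences per group of (estimate, reference) pairs.

    Accepts either a DataFrame (with estimate/reference columns plus any
    grouping columns) or a bare iterable of pairs, which is treated as a
    single pooled group keyed by ``()``.  Groups that are empty after
    dropping invalid rows are omitted with a logged warning.
    """
    if not isinstance(measurements, pd.DataFrame):
        pairs = list(measurements)
        if not pairs:
            raise ValueError("at least one (estimate, reference) pair required")
        df = pd.DataFrame(pairs, columns=[estimate_col, reference_col])
        group_keys = ()
    else:
        df = measurements
        if df.empty:
            raise ValueError("empty measurement table")

    if np.any(df[reference_col] <= 0):
        raise ValueError("all references must be > 0")

    pct_all = percent_difference(df[estimate_col].to_numpy(float), df[reference_col].to_numpy(float))
    if not group_keys:
        return {(): _summarize(np.asarray(pct_all), measure_kind, behavior, ())}

    out: dict[tuple, ErrorEstimate] = {}
    for key, idx in df.groupby(list(group_keys)).indices.items():
        key_t = key if isinstance(key, tuple) else (key,)
        if len(idx) == 0:  # pragma: no cover - groupby never yields empty groups
            logger.warning("group %s empty; omitted from error summary", key_t)
            continue
        out[key_t] = _summarize(np.asarray(pct_all)[idx], measure_kind, behavior, key_t)
    return out


def error_report(estimates: dict[tuple, ErrorEstimate], group_keys: Sequence[str] = ()) -> pd.DataFrame:
    """Render a group->ErrorEstimate mapping as the error_report.csv table."""
    rows = []
    for key, e in estimates.items():
        row = dict(zip(group_keys, key))
        row.update(n=e.n, mean_pct=e.mean_pct, sd_pct=e.sd_pct, se_pct=e.se_pct)
        rows.append(row)
    return pd.DataFrame(rows)
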