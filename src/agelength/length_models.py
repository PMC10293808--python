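"""Allometric estimators of total body length (TL) from blowhole-to-dorsal-fin
distance (BHDF).

BHDF is measurable on a surfacing dolphin when the full body is not, making
it a practical proxy for TL.  Three estimator families are supported:

* ``ratio`` — BHDF as a fixed percentage of TL (mean of per-record ratios);
* ``linear`` — ordinary least squares of TL on BHDF;
* ``loglinear`` — OLS of ln(TL) on ln(BHDF), back-transformed by
  exponentiation (standard allometry; no smearing correction, consistent
  with the near-zero bias the estimators show on physical BHDF).

Records live in a pandas DataFrame with columns ``animal_id``,
``assessment_id``, ``age``, ``sex``, ``tl``, ``bhdf`` (cm) and ``source``;
:class:`MorphometricRecord` is the row-level view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .photogrammetry import ErrorEstimate, percent_difference

__all__ = [
    "MorphometricRecord",
    "LengthModel",
    "to_frame",
    "validate_records",
    "average_per_animal",
    "derive_bhdf",
    "fit_ratio_model",
    "fit_linear_model",
    "fit_loglinear_model",
    "predict_tl",
    "evaluate_model",
]

REQUIRED_COLUMNS = ("animal_id", "age", "tl", "bhdf")


@dataclass(frozen=True)
class MorphometricRecord:
    """One physical assessment of one animal."""

    animal_id: str
    age: float  # years, may be fractional
    tl: float  # total length, cm
    bhdf: float  # blowhole to dorsal fin, cm
    assessment_id: str = ""
    sex: str = "unknown"  # F | M | unknown
    source: str = ""

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.tl <= 0 or self.bhdf <= 0:
            raise ValueError("tl and bhdf must be > 0")
        if not self.bhdf < self.tl:
            raise ValueError(f"bhdf ({self.bhdf}) must be < tl ({self.tl})")
        if self.sex not in ("F", "M", "unknown"):
            raise ValueError(f"sex must be F|M|unknown, got {self.sex!r}")


def to_frame(records: Iterable[MorphometricRecord]) -> pd.DataFrame:
    """Stack records into the canonical morphometrics DataFrame."""
    rows = [vars(r) for r in records]
    if not rows:
        raise ValueError("no records")
    return pd.DataFrame(rows)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants a morphometrics table must satisfy."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"morphometrics table missing columns: {missing}")
    if df.empty:
        raise ValueError("morphometrics table is empty")
    if (df["tl"] <= 0).any() or (df["bhdf"] <= 0).any():
        raise ValueError("tl and bhdf must be > 0")
    if (df["bhdf"] >= df["tl"]).any():
        raise ValueError("bhdf must be < tl for every record")
    if (df["age"] < 0).any():
        raise ValueError("age must be >= 0")
    return df


def average_per_animal(df: pd.DataFrame) -> pd.DataFrame:
    """Average repeated assessments per animal (used for facility fits, where
    each animal was measured 7-10 times at essentially one age)."""
    agg = {"age": "mean", "tl": "mean", "bhdf": "mean"}
    out = df.groupby("animal_id", as_index=False).agg(agg)
    return out


def derive_bhdf(tip_to_dorsal: float, tip_to_blowhole: float) -> float:
    """BHDF by subtraction of two rostrum-anchored distances.

    Long-term catch-and-release datasets record rostrum-to-blowhole and
    rostrum-to-dorsal-fin; their difference is the BHDF proxy.
    """
    if tip_to_dorsal <= 0 or tip_to_blowhole <= 0:
        raise ValueError("both distances must be > 0")
    diff = tip_to_dorsal - tip_to_blowhole
    if diff <= 0:
        raise ValueError(
            f"inconsistent measurements: tip_to_dorsal ({tip_to_dorsal}) must "
            f"exceed tip_to_blowhole ({tip_to_blowhole})"
        )
    return float(diff)


@dataclass(frozen=True)
class LengthModel:
    """A fitted TL~BHDF estimator.

    ``coefficients`` holds ``{"ratio_pct": r}`` for the ratio family
    (BHDF as % of TL), ``{"intercept": a, "slope": b}`` for linear (cm,
    cm/cm), or the same keys on the natural-log scale for loglinear.
    """

    kind: str  # ratio | linear | loglinear
    coefficients: dict[str, float]
    n_fit: int
    r_squared: float | None = None
    diagnostics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("ratio", "linear", "loglinear"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "ratio":
            r = self.coefficients.get("ratio_pct")
            if r is None or not (0 < r < 100):
                raise ValueError("ratio coefficient must lie in (0, 100)")

    def to_card(self) -> dict:
        """JSON-serialisable model card."""
        return {
            "kind": self.kind,
            "coefficients": dict(self.coefficients),
            "n_fit": self.n_fit,
            "r_squared": self.r_squared,
            "diagnostics": dict(self.diagnostics),
        }


def _prep(records: pd.DataFrame | Iterable[MorphometricRecord], per_animal: bool) -> pd.DataFrame:
    df = records if isinstance(records, pd.DataFrame) else to_frame(records)
    validate_records(df)
    return average_per_animal(df) if per_animal else df


def fit_ratio_model(
    records: pd.DataFrame | Iterable[MorphometricRecord],
    per_animal: bool = False,
    ratio_of_means: bool = False,
) -> LengthModel:
    """Fit the ratio estimator: BHDF as a percentage of TL.

    The coefficient is the mean over records of ``100 * bhdf / tl``
    (weighting animals equally); ``ratio_of_means`` switches to
    ``100 * mean(bhdf) / mean(tl)``.
    """
    df = _prep(records, per_animal)
    if ratio_of_means:
        r = 100.0 * df["bhdf"].mean() / df["tl"].mean()
    else:
        r = float(np.mean(100.0 * df["bhdf"] / df["tl"]))
    return LengthModel(kind="ratio", coefficients={"ratio_pct": float(r)}, n_fit=len(df))


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float, dict[str, float]]:
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    intercept, slope = fit.params
    diag = {
        "slope_se": float(fit.bse[1]),
        "intercept_se": float(fit.bse[0]),
        "p_value_slope": float(fit.pvalues[1]),
        "resid_sd": float(np.sqrt(fit.mse_resid)),
    }
    return float(intercept), float(slope), float(fit.rsquared), diag


def fit_linear_model(
    records: pd.DataFrame | Iterable[MorphometricRecord], per_animal: bool = False
) -> LengthModel:
    """OLS of TL on BHDF."""
    df = _prep(records, per_animal)
    if len(df) < 3:
        raise ValueError("linear fit requires >= 3 records")
    if np.isclose(df["bhdf"].std(ddof=0), 0):
        raise ValueError("bhdf values are degenerate (zero spread)")
    intercept, slope, r2, diag = _ols(df["tl"].to_numpy(float), df["bhdf"].to_numpy(float))
    return LengthModel(
        kind="linear",
        coefficients={"intercept": intercept, "slope": slope},
        n_fit=len(df),
        r_squared=r2,
        diagnostics=diag,
    )


def fit_loglinear_model(
    records: pd.DataFrame | Iterable[MorphometricRecord], per_animal: bool = False
) -> LengthModel:
    """OLS of ln(TL) on ln(BHDF); predictions back-transform by exp."""
    df = _prep(records, per_animal)
    if len(df) < 3:
        raise ValueError("loglinear fit requires >= 3 records")
    log_bhdf = np.log(df["bhdf"].to_numpy(float))
    if np.isclose(log_bhdf.std(), 0):
        raise ValueError("bhdf values are degenerate (zero spread)")
    intercept, slope, r2, diag = _ols(np.log(df["tl"].to_numpy(float)), log_bhdf)
    return LengthModel(
        kind="loglinear",
        coefficients={"intercept": intercept, "slope": slope},
        n_fit=len(df),
        r_squared=r2,
        diagnostics=diag,
    )


def predict_tl(model: LengthModel, bhdf):
    """Predict TL (cm) from BHDF (cm) under a fitted model.

    Accepts scalars or arrays.  Ratio and loglinear predictions are
    strictly positive for any bhdf > 0; linear predictions can in
    principle go negative outside the fitted range.
    """
    b = np.asarray(bhdf, dtype=float)
    if np.any(b <= 0):
        raise ValueError("bhdf must be > 0")
    c = model.coefficients
    if model.kind == "ratio":
        out = 100.0 * b / c["ratio_pct"]
    elif model.kind == "linear":
        out = c["intercept"] + c["slope"] * b
    else:
        out = np.exp(c["intercept"] + c["slope"] * np.log(b))
    return out if out.ndim else float(out)


def evaluate_model(
    model: LengthModel,
    records: pd.DataFrame | Iterable[MorphometricRecord],
    bhdf_source: str = "physical",
) -> ErrorEstimate:
    """Percent error of model-predicted TL against physical TL per record.

    ``bhdf_source`` selects the predictor column: ``"physical"`` uses
    ``bhdf``; ``"uas"`` uses ``bhdf_uas`` (UAS-measured BHDF attached to the
    same records).  Returns mean, SD and SE of the signed percent
    differences (stored as fractions) plus n.
    """
    df = records if isinstance(records, pd.DataFrame) else to_frame(records)
    if df.empty:
        raise ValueError("no records to evaluate")
    col = {"physical": "bhdf", "uas": "bhdf_uas"}.get(bhdf_source)
    if col is None:
        raise ValueError(f"bhdf_source must be physical|uas, got {bhdf_source!r}")
    if col not in df.columns:
        raise ValueError(f"records lack the {col!r} column required for source {bhdf_source!r}")
    pred = predict_tl(model, df[col].to_numpy(float))
    pct = percent_difference(pred, df["tl"].to_numpy(float))
    n = len(df)
    sd = float(np.std(pct, ddof=1)) if n > 1 else 0.0
    return ErrorEstimate(
        mean_rel_error=float(np.mean(pct)) / 100.0,
        sd_rel_error=sd / 100.0,
        se_rel_error=(sd / np.sqrt(n)) / 100.0,
        n=n,
        measure_kind="TL_from_BHDF",
    )
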