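"""Monte-Carlo simulation of UAS photogrammetry measurements.

Physical reference lengths are perturbed by the measured relative-error
distribution of the drone method: a simulated BHDF is
``bhdf_physical * (1 + eps)`` with ``eps ~ Normal(mean, sd)``, and a
simulated TL applies a second, independent multiplicative draw to the
model-predicted TL computed from that simulated BHDF.  With the
"zero-bias" preset the mean error is set to 0 and only the measured SD is
propagated, which avoids transferring a facility-specific bias onto the
study population.

A Normal multiplier can in principle produce a non-positive length at
extreme draws (impossible at the measured sd of about 0.03 but possible
under user configurations); such draws are redrawn up to a bounded retry
count, preserving the stated distribution to negligible approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .length_models import LengthModel, predict_tl

__all__ = [
    "NoiseSpec",
    "SimulatedReplicate",
    "paper_default_noise",
    "simulate_bhdf",
    "simulate_tl",
    "simulate_dataset",
    "simulate_dataset_frame",
]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class NoiseSpec:
    """Relative-error distribution of a UAS measurement stage.

    ``mean_rel_error`` and ``sd_rel_error`` are dimensionless fractions
    (a 3.1% SD is 0.031); ``target`` names the stage the spec applies to.
    """

    mean_rel_error: float = 0.0
    sd_rel_error: float = 0.0
    target: str = "BHDF"  # "BHDF" | "TL"

    def __post_init__(self) -> None:
        if self.sd_rel_error < 0:
            raise ValueError("sd_rel_error must be >= 0")
        if self.target not in ("BHDF", "TL"):
            raise ValueError(f"target must be BHDF|TL, got {self.target!r}")


def paper_default_noise(sd_bhdf: float = 0.031, sd_tl: float = 0.031) -> tuple[NoiseSpec, NoiseSpec]:
    """The zero-bias preset: mean error 0, measured SDs only, both stages."""
    return NoiseSpec(0.0, sd_bhdf, "BHDF"), NoiseSpec(0.0, sd_tl, "TL")


def _multipliers(noise: NoiseSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``1 + eps`` multipliers, redrawing non-positive values."""
    m = 1.0 + rng.normal(noise.mean_rel_error, noise.sd_rel_error, size=size)
    for _ in range(_MAX_REDRAWS):
        bad = m <= 0
        if not bad.any():
            return m
        m[bad] = 1.0 + rng.normal(noise.mean_rel_error, noise.sd_rel_error, size=int(bad.sum()))
    raise RuntimeError(
        "could not draw a positive length multiplier after "
        f"{_MAX_REDRAWS} redraws (noise {noise})"
    )


def simulate_bhdf(bhdf_physical, noise: NoiseSpec, rng: np.random.Generator):
    """One UAS-simulated BHDF draw per input value (scalar or array)."""
    b = np.asarray(bhdf_physical, dtype=float)
    if np.any(b <= 0):
        raise ValueError("bhdf_physical must be > 0")
    out = b * _multipliers(noise, b.size, rng).reshape(b.shape)
    return out if out.ndim else float(out)


def simulate_tl(bhdf_sim, model: LengthModel, noise: NoiseSpec, rng: np.random.Generator):
    """UAS-simulated TL: model prediction from simulated BHDF times a fresh
    independent error draw."""
    pred = np.asarray(predict_tl(model, bhdf_sim), dtype=float)
    out = pred * _multipliers(noise, pred.size, rng).reshape(pred.shape)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SimulatedReplicate:
    """One replicate of UAS-simulated measurements for every assessment."""

    replicate_id: int
    animal_id: np.ndarray
    assessment_id: np.ndarray
    age: np.ndarray
    bhdf_sim: np.ndarray
    tl_sim: np.ndarray


def simulate_dataset(
    records: pd.DataFrame,
    model: LengthModel,
    bhdf_noise: NoiseSpec,
    tl_noise: NoiseSpec,
    n_replicates: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    two_stage: bool = True,
) -> Iterator[SimulatedReplicate]:
    """Stream independent replicates of simulated BHDF and TL per assessment.

    Each assessment row gets one BHDF-stage and one TL-stage draw per
    replicate; repeated assessments of one animal are simulated
    independently.  Output is reproducible given ``seed``.  With
    ``two_stage=False`` the TL-stage noise is skipped and ``tl_sim`` is the
    deterministic model prediction from the simulated BHDF (the mode in
    which the measured SD is taken to capture the total TL error).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if records.empty:
        raise ValueError("no records to simulate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    bhdf_phys = records["bhdf"].to_numpy(float)
    animal = records["animal_id"].to_numpy()
    assess = (
        records["assessment_id"].to_numpy()
        if "assessment_id" in records.columns
        else records.index.to_numpy()
    )
    age = records["age"].to_numpy(float)

    for rep in range(n_replicates):
        bhdf_sim = simulate_bhdf(bhdf_phys, bhdf_noise, rng)
        if two_stage:
            tl_sim = simulate_tl(bhdf_sim, model, tl_noise, rng)
        else:
            tl_sim = np.asarray(predict_tl(model, bhdf_sim), dtype=float)
        yield SimulatedReplicate(rep, animal, assess, age, np.atleast_1d(bhdf_sim), np.atleast_1d(tl_sim))


def simulate_dataset_frame(
    records: pd.DataFrame,
    model: LengthModel,
    bhdf_noise: NoiseSpec,
    tl_noise: NoiseSpec,
    n_replicates: int,
    seed,
    two_stage: bool = True,
) -> pd.DataFrame:
    """Collect the replicate stream into one long table (simulated.csv)."""
    frames = []
    for rep in simulate_dataset(records, model, bhdf_noise, tl_noise, n_replicates, seed, two_stage):
        frames.append(
            pd.DataFrame(
                {
                    "replicate_id": rep.replicate_id,
                    "assessment_id": rep.assessment_id,
                    "animal_id": rep.animal_id,
                    "age_years": rep.age,
                    "bhdf_sim_cm": rep.bhdf_sim,
                    "tl_sim_cm": rep.tl_sim,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
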