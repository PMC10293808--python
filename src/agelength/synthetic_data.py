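"""Synthetic bottlenose-dolphin-like populations for end-to-end testing.

Real reference data for this pipeline are long-term catch-and-release
morphometric catalogues, which are not freely redistributable.  This
module generates populations with the statistical structure the analysis
relies on:

* a von Bertalanffy growth curve ``L(a) = L_inf * (1 - exp(-k (a - a0)))``
  that plateaus at 10-15 years, calibrated so birth length is ~115 cm and
  the population TL mean/SD land near 235 +- 26 cm under a uniform age
  distribution;
* BHDF as a fixed allometric fraction of TL (~29% by default) with a
  small lognormal scatter;
* between-animal size variation as a lognormal multiplier on L_inf;
* repeated assessments per animal at different ages, and
* facility-style panels pairing known truth with replicated noisy "UAS"
  estimates.

Ages enter the growth curve deterministically (within an animal, longer
always means older); all scatter comes from the between-animal multiplier
and the BHDF noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthParams",
    "PopulationConfig",
    "growth_curve_tl",
    "generate_population",
    "generate_facility_panel",
]


@dataclass(frozen=True)
class GrowthParams:
    """von Bertalanffy parameters for total length at age.

    Defaults: asymptote 250 cm, rate 0.35 / year, theoretical age at
    length zero -1.76 years (birth length ~115 cm, age-10 length >= 97%
    of the asymptote), 4% between-animal CV on the asymptote.
    """

    l_inf: float = 250.0
    k: float = 0.35
    a0: float = -1.76
    between_animal_cv: float = 0.04

    def __post_init__(self) -> None:
        if self.l_inf <= 0:
            raise ValueError("l_inf must be > 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.between_animal_cv < 0:
            raise ValueError("between_animal_cv must be >= 0")


@dataclass(frozen=True)
class PopulationConfig:
    """Sampling design of a synthetic population.

    ``allometry_c`` is the BHDF fraction of TL (0.292 by default, i.e. a
    ratio coefficient of 29.2) and ``allometry_d`` its exponent (1.0 =
    pure proportionality, under which all three TL~BHDF model families
    are correctly specified).  Assessments per animal are drawn uniformly
    from ``assessments_per_animal`` (inclusive), each with its own age.

    ``age_distribution`` is either ``("uniform",)`` — ages uniform on
    ``age_range`` — or ``("binned", edges, weights)``, which samples an
    age bin with the given weights and an age uniformly within it; the
    latter reproduces a catalogue's published per-bin sample sizes.
    """

    n_animals: int = 263
    assessments_per_animal: tuple[int, int] = (1, 5)
    age_range: tuple[float, float] = (0.0, 45.0)
    age_distribution: tuple = ("uniform",)
    allometry_c: float = 0.292
    allometry_d: float = 1.0
    bhdf_noise_cv: float = 0.03

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not (0 < self.allometry_c < 1):
            raise ValueError("allometry_c must lie in (0, 1)")
        if self.bhdf_noise_cv < 0:
            raise ValueError("bhdf_noise_cv must be >= 0")
        lo, hi = self.assessments_per_animal
        if lo < 1 or hi < lo:
            raise ValueError("assessments_per_animal must be a valid (lo, hi) range")
        if self.age_range[1] <= self.age_range[0] or self.age_range[0] < 0:
            raise ValueError("age_range must be an ascending non-negative interval")
        kind = self.age_distribution[0]
        if kind not in ("uniform", "binned"):
            raise ValueError(f"unknown age_distribution kind {kind!r}")
        if kind == "binned":
            _, edges, weights = self.age_distribution
            e = np.asarray(edges, float)
            w = np.asarray(weights, float)
            if e.size != w.size + 1 or np.any(np.diff(e) <= 0) or e[0] < 0:
                raise ValueError("binned age_distribution needs ascending edges, len(weights)+1")
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("binned age_distribution weights must be non-negative, not all 0")

    def draw_ages(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.age_distribution[0] == "uniform":
            return rng.uniform(self.age_range[0], self.age_range[1], size=size)
        _, edges, weights = self.age_distribution
        e = np.asarray(edges, float)
        w = np.asarray(weights, float)
        bins = rng.choice(w.size, size=size, p=w / w.sum())
        return rng.uniform(e[bins], e[bins + 1])


def growth_curve_tl(age, params: GrowthParams = GrowthParams()):
    """Total length (cm) at age under the von Bertalanffy curve."""
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    out = params.l_inf * (1.0 - np.exp(-params.k * (a - params.a0)))
    return out if out.ndim else float(out)


def generate_population(
    config: PopulationConfig = PopulationConfig(),
    growth: GrowthParams = GrowthParams(),
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate a morphometrics table of repeated assessments.

    Per animal: an l_inf multiplier ~ lognormal(0, between_animal_cv), a
    number of assessments, one age per assessment, TL from the growth
    curve, and BHDF = c * TL^d * lognormal(0, bhdf_noise_cv).
    Reproducible given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = config.assessments_per_animal
    counts = rng.integers(lo, hi + 1, size=config.n_animals)
    total = int(counts.sum())

    animal_idx = np.repeat(np.arange(config.n_animals), counts)
    mult = rng.lognormal(0.0, growth.between_animal_cv, size=config.n_animals)
    sexes = rng.choice(["F", "M"], size=config.n_animals)
    ages = config.draw_ages(total, rng)

    tl = growth_curve_tl(ages, growth) * mult[animal_idx]
    bhdf = (
        config.allometry_c
        * tl**config.allometry_d
        * rng.lognormal(0.0, config.bhdf_noise_cv, size=total)
    )

    return pd.DataFrame(
        {
            "animal_id": [f"A{i:04d}" for i in animal_idx],
            "assessment_id": [f"S{j:05d}" for j in range(total)],
            "age": ages,
            "sex": sexes[animal_idx],
            "tl": tl,
            "bhdf": bhdf,
            "source": "synthetic",
        }
    )


def generate_facility_panel(
    n_animals: int = 5,
    replicate_count: int = 15,
    measurement_cv: float = 0.031,
    bias: float = 0.0,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    growth: GrowthParams = GrowthParams(),
    allometry_c: float = 0.292,
    age_range: tuple[float, float] = (5.0, 40.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate a facility ground-truthing design: known physical lengths plus
    replicated noisy UAS estimates.

    Returns ``(physical, panel)``: one physical record per animal, and a
    long table of paired (estimate, reference) values per measure with
    relative error ~ Normal(bias, measurement_cv), ready for
    ``summarize_measurement_error``.
    """
    if replicate_count < 1:
        raise ValueError("replicate_count must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ages = rng.uniform(*age_range, size=n_animals)
    tl = growth_curve_tl(ages, growth) * rng.lognormal(0.0, growth.between_animal_cv, n_animals)
    bhdf = allometry_c * tl

    physical = pd.DataFrame(
        {
            "animal_id": [f"F{i:02d}" for i in range(n_animals)],
            "assessment_id": [f"FP{i:02d}" for i in range(n_animals)],
            "age": ages,
            "sex": "unknown",
            "tl": tl,
            "bhdf": bhdf,
            "source": "synthetic-facility",
        }
    )

    rows = []
    for measure, truth in (("TL", tl), ("BHDF", bhdf)):
        eps = rng.normal(bias, measurement_cv, size=(n_animals, replicate_count))
        est = truth[:, None] * (1.0 + eps)
        for i in range(n_animals):
            for r in range(replicate_count):
                rows.append(
                    {
                        "animal_id": f"F{i:02d}",
                        "measure_kind": measure,
                        "replicate": r,
                        "estimate": est[i, r],
                        "reference": truth[i],
                    }
                )
    return physical, pd.DataFrame(rows)
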