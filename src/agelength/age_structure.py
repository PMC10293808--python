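"""Length-based age classification and Monte-Carlo performance scoring.

Age-class bins are half-open intervals [X, Y) in years with an unbounded
oldest bin [X, inf).  For each bin the physical length distribution (mean,
SD, min, max, n) of the chosen measure — TL or BHDF — is summarised from
records of known age; an individual of unknown age is then assigned to
bins with probabilities proportional to each bin's Normal density at its
measured length.  Classifier performance is scored by simulating UAS
measurement error on records of known age over many replicates and
accumulating a row-normalised confusion matrix (rows = actual bin,
columns = assigned bin, in percent).

Because the growth curve plateaus at 10-15 years, bins above the plateau
share nearly identical length distributions: narrow adult bins are
intrinsically confusable, and performance rises as bins are merged.  The
"within-band" accuracy (mass within +-k bins of the truth) quantifies how
far off the misassignments land.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .length_models import LengthModel
from .uas_simulator import NoiseSpec, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "AgeBinScenario",
    "BinLengthStats",
    "AssignmentDistribution",
    "ClassifierPerformance",
    "builtin_scenarios",
    "bin_index",
    "compute_bin_stats",
    "assignment_probabilities",
    "score_replicate",
    "run_classifier_experiment",
    "within_band_accuracy",
    "population_age_structure",
]


@dataclass(frozen=True)
class AgeBinScenario:
    """Half-open age-class bins: edges (e0=0, e1, ..., em) define bins
    [e0,e1), ..., [e_{m-1}, e_m), [e_m, inf)."""

    name: str
    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, float)
        if e.size < 2:
            raise ValueError("a scenario needs >= 2 edges (>= 2 bins)")
        if e[0] != 0:
            raise ValueError("first edge must be 0")
        if np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly ascending")

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    @property
    def labels(self) -> tuple[str, ...]:
        def fmt(x: float) -> str:
            return str(int(x)) if float(x).is_integer() else str(x)

        inner = [f"{fmt(a)}–{fmt(b)}" for a, b in zip(self.edges, self.edges[1:])]
        return tuple(inner + [f"{fmt(self.edges[-1])}+"])


def builtin_scenarios() -> dict[str, AgeBinScenario]:
    """The five standard bin scenarios, from narrow (A, 7 bins) to broad
    (E, 2 bins: immature vs mature around the age-10 growth plateau)."""
    return {
        "A": AgeBinScenario("A", (0, 3, 7, 15, 25, 35, 40)),
        "B": AgeBinScenario("B", (0, 2, 4, 6, 8, 10)),
        "C": AgeBinScenario("C", (0, 3, 8, 15)),
        "D": AgeBinScenario("D", (0, 2, 10)),
        "E": AgeBinScenario("E", (0, 10)),
    }


def bin_index(age, scenario: AgeBinScenario):
    """Index of the [X, Y) bin containing each age; the last bin is open above."""
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    idx = np.searchsorted(np.asarray(scenario.edges[1:], float), a, side="right")
    return idx if idx.ndim else int(idx)


@dataclass(frozen=True)
class BinLengthStats:
    """Per-bin length distribution summaries for one measure (TL or BHDF)."""

    scenario: AgeBinScenario
    measure: str  # "TL" | "BHDF"
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    n: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.mean.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.scenario.labels,
                "mean": self.mean,
                "sd": self.sd,
                "min": self.min,
                "max": self.max,
                "n": self.n,
            }
        )


@dataclass(frozen=True)
class AssignmentDistribution:
    """Probability over bins of one assessment's bin membership."""

    assessment_id: object
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(self.probabilities.sum()) - 1.0) > 1e-9:
            raise ValueError("assignment probabilities must sum to 1")


_MEASURE_COL = {"TL": "tl", "BHDF": "bhdf"}


def compute_bin_stats(
    records: pd.DataFrame, scenario: AgeBinScenario, measure: str = "TL"
) -> BinLengthStats:
    """Mean/SD/min/max/n of the chosen measure per age-class bin.

    Every bin must contain at least two assessments, otherwise the bin's SD
    (and hence the classifier) is undefined there and an error names it.
    """
    col = _MEASURE_COL.get(measure)
    if col is None:
        raise ValueError(f"measure must be TL|BHDF, got {measure!r}")
    vals = records[col].to_numpy(float)
    bins = bin_index(records["age"].to_numpy(float), scenario)
    k = scenario.n_bins
    mean = np.empty(k)
    sd = np.empty(k)
    mn = np.empty(k)
    mx = np.empty(k)
    n = np.empty(k, dtype=int)
    for i in range(k):
        v = vals[bins == i]
        if v.size < 2:
            raise ValueError(
                f"bin '{scenario.labels[i]}' of scenario {scenario.name} holds "
                f"{v.size} record(s); >= 2 required for a length distribution"
            )
        mean[i], sd[i] = v.mean(), v.std(ddof=1)
        mn[i], mx[i], n[i] = v.min(), v.max(), v.size
    return BinLengthStats(scenario, measure, mean, sd, mn, mx, n)


def _probability_matrix(
    values: np.ndarray, stats: BinLengthStats, truncate: bool, sd_floor: float
) -> np.ndarray:
    """(n_values, n_bins) matrix of normalized Normal-density weights.

    Computed in log space (shifted by the row max) so that values far from
    every bin mean still normalise without underflow.
    """
    v = np.atleast_1d(np.asarray(values, float))[:, None]
    sd = np.maximum(stats.sd, sd_floor)[None, :]
    mu = stats.mean[None, :]
    logw = -0.5 * ((v - mu) / sd) ** 2 - np.log(sd)
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    if truncate:
        inside = (v >= stats.min[None, :]) & (v <= stats.max[None, :])
        wt = np.where(inside, w, 0.0)
        rowsum = wt.sum(axis=1, keepdims=True)
        # fall back to untruncated weights for values outside every bin's range
        w = np.where(rowsum > 0, wt, w)
    return w / w.sum(axis=1, keepdims=True)


def assignment_probabilities(
    value,
    stats: BinLengthStats,
    truncate: bool = False,
    sd_floor: float = 1e-6,
    assessment_id: object = None,
) -> AssignmentDistribution:
    """Probability of each age-class bin given one measured length.

    The unnormalised weight of a bin is its Normal density (bin mean, bin
    SD) at the value; with ``truncate`` the weight is zeroed when the value
    lies outside the bin's observed [min, max], falling back to the
    untruncated weights if that zeroes every bin.  Probabilities are the
    weights normalised to sum 1.
    """
    p = _probability_matrix(np.asarray([value], float), stats, truncate, sd_floor)[0]
    return AssignmentDistribution(assessment_id, p)


def score_replicate(
    values: np.ndarray,
    true_bins: np.ndarray,
    stats: BinLengthStats,
    mode: str = "probabilistic",
    truncate: bool = False,
    sd_floor: float = 1e-6,
) -> np.ndarray:
    """Confusion-matrix increment for one simulated replicate.

    Probabilistic mode adds each assessment's full probability vector to
    its actual-bin row; argmax mode adds an indicator at the
    highest-probability bin, ties resolving to the younger bin.
    Rows are actual bins, columns assigned bins, unnormalised counts.
    """
    if mode not in ("probabilistic", "argmax"):
        raise ValueError(f"mode must be probabilistic|argmax, got {mode!r}")
    values = np.atleast_1d(np.asarray(values, float))
    true_bins = np.atleast_1d(np.asarray(true_bins, int))
    k = stats.n_bins
    P = _probability_matrix(values, stats, truncate, sd_floor)
    M = np.zeros((k, k))
    if mode == "probabilistic":
        np.add.at(M, true_bins, P)
    else:
        assigned = P.argmax(axis=1)  # argmax returns the first (younger) max
        np.add.at(M, (true_bins, assigned), 1.0)
    return M


@dataclass(frozen=True)
class ClassifierPerformance:
    """Replicate-averaged confusion matrix and accuracy summaries.

    ``confusion`` is row-normalised to percent; ``mean_accuracy`` is the
    assessment-weighted mean of the diagonal (an unweighted mean is in
    ``mean_accuracy_unweighted``); ``within_band`` is the per-bin percent
    within +-1 bin of the truth.
    """

    scenario: AgeBinScenario
    measure: str
    mode: str
    confusion: np.ndarray  # (k, k), row-normalised %
    bin_n: np.ndarray  # assessments per actual bin
    n_replicates: int
    assigned_proportions: np.ndarray = field(repr=False, default=None)  # (reps, k)

    @property
    def per_bin_accuracy(self) -> np.ndarray:
        return np.diag(self.confusion)

    @property
    def mean_accuracy(self) -> float:
        return float(np.average(self.per_bin_accuracy, weights=self.bin_n))

    @property
    def mean_accuracy_unweighted(self) -> float:
        return float(self.per_bin_accuracy.mean())

    @property
    def within_band(self) -> np.ndarray:
        return within_band_accuracy(self.confusion, k=1)

    def confusion_frame(self) -> pd.DataFrame:
        lab = self.scenario.labels
        return pd.DataFrame(self.confusion, index=lab, columns=lab)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.name,
            "bins": list(self.scenario.labels),
            "measure": self.measure,
            "mode": self.mode,
            "n_replicates": self.n_replicates,
            "bin_n": self.bin_n.tolist(),
            "confusion_pct": self.confusion.tolist(),
            "per_bin_accuracy_pct": self.per_bin_accuracy.tolist(),
            "mean_accuracy_pct": self.mean_accuracy,
            "mean_accuracy_unweighted_pct": self.mean_accuracy_unweighted,
            "within_band_1_pct": self.within_band.tolist(),
        }


def run_classifier_experiment(
    records: pd.DataFrame,
    scenario: AgeBinScenario,
    model: LengthModel,
    bhdf_noise: NoiseSpec,
    tl_noise: NoiseSpec,
    n_replicates: int = 1000,
    measure: str = "TL",
    mode: str = "probabilistic",
    seed: int | np.random.SeedSequence = 0,
    truncate: bool = False,
    sd_floor: float = 1e-6,
    two_stage: bool = True,
    holdout_animal: bool = False,
) -> ClassifierPerformance:
    """End-to-end Monte-Carlo scoring of one age classifier.

    Builds per-bin length distributions from the records (resubstitution:
    the same records are then classified, as when a long-term catalogue is
    both the reference and the test set; ``holdout_animal`` switches to
    leave-one-animal-out reference distributions), streams ``n_replicates``
    simulated datasets, and accumulates the confusion matrix.
    Reproducible given ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    known = records[records["age"].notna()]
    dropped = len(records) - len(known)
    if dropped:
        logger.warning("excluded %d assessment(s) with unknown age", dropped)
    true_bins = np.asarray(bin_index(known["age"].to_numpy(float), scenario))
    k = scenario.n_bins
    bin_n = np.bincount(true_bins, minlength=k)

    stats = compute_bin_stats(known, scenario, measure)

    total = np.zeros((k, k))
    proportions = np.empty((n_replicates, k))
    stream = simulate_dataset(known, model, bhdf_noise, tl_noise, n_replicates, seed, two_stage)
    for rep in stream:
        values = rep.tl_sim if measure == "TL" else rep.bhdf_sim
        if holdout_animal:
            M = np.zeros((k, k))
            for animal in np.unique(rep.animal_id):
                mask = rep.animal_id == animal
                s = compute_bin_stats(known[~mask], scenario, measure)
                M += score_replicate(values[mask], true_bins[mask], s, mode, truncate, sd_floor)
        else:
            M = score_replicate(values, true_bins, stats, mode, truncate, sd_floor)
        total += M
        proportions[rep.replicate_id] = M.sum(axis=0) / M.sum()

    rowsum = total.sum(axis=1, keepdims=True)
    confusion = 100.0 * total / rowsum
    return ClassifierPerformance(
        scenario=scenario,
        measure=measure,
        mode=mode,
        confusion=confusion,
        bin_n=bin_n,
        n_replicates=n_replicates,
        assigned_proportions=proportions,
    )


def within_band_accuracy(confusion: np.ndarray, k: int) -> np.ndarray:
    """Per-actual-bin mass assigned within +-k bins of the truth.

    ``k=0`` is the diagonal accuracy; ``k >= n_bins - 1`` always gives 100%
    for a row-normalised matrix.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    c = np.asarray(confusion, float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion must be square")
    nb = c.shape[0]
    out = np.empty(nb)
    for i in range(nb):
        lo, hi = max(0, i - k), min(nb, i + k + 1)
        out[i] = c[i, lo:hi].sum()
    return out


def population_age_structure(
    assigned_proportions: np.ndarray, scenario: AgeBinScenario
) -> pd.DataFrame:
    """Estimated proportion of the population in each age-class bin.

    Input is the (n_replicates, n_bins) matrix of per-replicate assigned
    proportions (rows sum to 1); output is the per-bin mean with a 2.5/97.5
    percentile Monte-Carlo interval.
    """
    p = np.atleast_2d(np.asarray(assigned_proportions, float))
    if p.shape[0] < 1:
        raise ValueError("at least one replicate required")
    lo, hi = np.percentile(p, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "bin": scenario.labels,
            "proportion": p.mean(axis=0),
            "lo_2.5": lo,
            "hi_97.5": hi,
        }
    )
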