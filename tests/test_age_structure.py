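import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from agelength.age_structure import (
    AgeBinScenario,
    BinLengthStats,
    assignment_probabilities,
    bin_index,
    builtin_scenarios,
    compute_bin_stats,
    population_age_structure,
    run_classifier_experiment,
    score_replicate,
    within_band_accuracy,
)
from agelength.length_models import LengthModel, fit_loglinear_model
from agelength.uas_simulator import NoiseSpec

UNIT_MODEL = LengthModel("loglinear", {"intercept": 0.0, "slope": 1.0}, n_fit=3)
ZERO = NoiseSpec(0.0, 0.0)


def make_stats(means, sds, mins=None, maxs=None, n=10):
    k = len(means)
    scenario = AgeBinScenario("T", tuple(range(0, 2 * k, 2)))
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    return BinLengthStats(
        scenario,
        "TL",
        means,
        sds,
        np.asarray(mins if mins is not None else means - 3 * sds, float),
        np.asarray(maxs if maxs is not None else means + 3 * sds, float),
        np.full(k, n),
    )


class TestScenarios:
    def test_builtin_bin_structure(self):
        s = builtin_scenarios()
        assert s["A"].n_bins == 7 and s["A"].edges == (0, 3, 7, 15, 25, 35, 40)
        assert s["B"].labels == ("0–2", "2–4", "4–6", "6–8", "8–10", "10+")
        assert s["C"].n_bins == 4
        assert s["D"].edges == (0, 2, 10)
        assert s["E"].edges == (0, 10) and s["E"].n_bins == 2

    def test_bin_index_half_open(self):
        d = builtin_scenarios()["D"]
        assert bin_index(10.0, d) == 2  # boundary is left-closed: 10 -> "10+"
        assert bin_index(1.99, d) == 0
        assert bin_index(0.0, d) == 0
        assert list(bin_index(np.array([0, 2, 9.99, 45]), d)) == [0, 1, 1, 2]

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            bin_index(-0.5, builtin_scenarios()["E"])

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            AgeBinScenario("x", (1, 5))  # first edge must be 0
        with pytest.raises(ValueError):
            AgeBinScenario("x", (0, 5, 5))
        with pytest.raises(ValueError):
            AgeBinScenario("x", (0,))


class TestBinStats:
    def test_underpopulated_bin_names_itself(self):
        df = pd.DataFrame({"age": [1.0, 1.5, 1.8], "tl": [60.0, 70.0, 80.0], "bhdf": [20.0, 21.0, 22.0]})
        with pytest.raises(ValueError, match="10\\+"):
            compute_bin_stats(df, builtin_scenarios()["E"], "TL")

    def test_summary_values(self):
        df = pd.DataFrame(
            {
                "age": [1.0, 1.5, 1.8, 20.0, 30.0],
                "tl": [60.0, 70.0, 80.0, 240.0, 250.0],
                "bhdf": [20.0, 21.0, 22.0, 70.0, 72.0],
            }
        )
        st = compute_bin_stats(df, builtin_scenarios()["E"], "TL")
        assert st.mean[0] == pytest.approx(70.0)
        assert st.sd[0] == pytest.approx(10.0)
        assert (st.min[0], st.max[0], st.n[0]) == (60.0, 80.0, 3)
        assert st.n[1] == 2

    def test_identical_records_give_zero_sd(self):
        df = pd.DataFrame({"age": [1, 1, 20, 20], "tl": [100.0] * 4, "bhdf": [30.0] * 4})
        st = compute_bin_stats(df, builtin_scenarios()["E"], "TL")
        assert np.all(st.sd == 0.0)

    def test_growth_makes_older_bins_longer(self, population):
        st = compute_bin_stats(population, builtin_scenarios()["E"], "TL")
        assert st.mean[1] > st.mean[0]


class TestAssignmentProbabilities:
    def test_symmetric_midpoint(self):
        st = make_stats([100, 120], [10, 10])
        p = assignment_probabilities(110.0, st).probabilities
        assert p == pytest.approx([0.5, 0.5])

    def test_density_ratio_two_sd(self):
        st = make_stats([100, 120], [10, 10])
        p = assignment_probabilities(100.0, st).probabilities
        expected = np.e**2 / (np.e**2 + 1)  # phi(0) / (phi(0) + phi(2))
        assert p[0] == pytest.approx(expected, abs=1e-12)

    def test_sums_to_one_everywhere(self, rng):
        st = make_stats([100, 150, 220], [5, 12, 20])
        for v in rng.uniform(10, 400, size=50):
            assert assignment_probabilities(v, st).probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_normal_densities(self, rng):
        # independent oracle: scipy normal pdf, naive normalization
        for _ in range(200):
            k = rng.integers(2, 6)
            st = make_stats(rng.uniform(50, 300, k), rng.uniform(2, 30, k))
            v = rng.uniform(40, 320)
            w = sps.norm.pdf(v, st.mean, st.sd)
            p = assignment_probabilities(v, st).probabilities
            assert np.max(np.abs(p - w / w.sum())) < 1e-12

    def test_truncation_zeroes_out_of_range_bins(self):
        st = make_stats([100, 120], [10, 10], mins=[95, 115], maxs=[105, 125])
        p = assignment_probabilities(110.0, st, truncate=True).probabilities
        # 110 is outside both ranges -> fallback to untruncated (0.5, 0.5)
        assert p == pytest.approx([0.5, 0.5])
        p2 = assignment_probabilities(104.0, st, truncate=True).probabilities
        assert p2 == pytest.approx([1.0, 0.0])

    def test_sd_floor_keeps_degenerate_bins_finite(self):
        st = make_stats([100, 120], [0.0, 10.0])
        p = assignment_probabilities(100.0, st).probabilities
        assert np.isfinite(p).all() and p[0] > 0.99

    def test_far_values_normalise_without_underflow(self):
        st = make_stats([100, 120], [1.0, 1.0])
        p = assignment_probabilities(5000.0, st).probabilities
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)


class TestScoreReplicate:
    def test_identical_bins_split_evenly(self):
        st = make_stats([100, 100], [10, 10])
        M = score_replicate([100.0, 100.0], [0, 1], st)
        assert np.allclose(M, [[0.5, 0.5], [0.5, 0.5]])

    def test_well_separated_bins_score_diagonal(self):
        st = make_stats([100, 300], [1.0, 1.0])
        M = score_replicate([100.0, 300.0], [0, 1], st)
        assert np.diag(M) == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_argmax_tie_goes_to_younger_bin(self):
        st = make_stats([100, 120], [10, 10])
        M = score_replicate([110.0], [1], st, mode="argmax")
        assert M[1, 0] == 1.0 and M[1, 1] == 0.0

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            score_replicate([1.0], [0], make_stats([1, 2], [1, 1]), mode="soft")


class TestWithinBand:
    CONF = np.array([[70.0, 30.0, 0.0], [10.0, 80.0, 10.0], [0.0, 25.0, 75.0]])

    def test_k0_equals_diagonal(self):
        assert within_band_accuracy(self.CONF, 0) == pytest.approx([70, 80, 75])

    def test_k1_sums_neighbors(self):
        assert within_band_accuracy(self.CONF, 1) == pytest.approx([100, 100, 100])

    def test_identity_confusion_is_100_for_any_k(self):
        eye = np.eye(4) * 100
        for k in range(4):
            assert within_band_accuracy(eye, k) == pytest.approx([100] * 4)

    def test_monotone_in_k(self, rng):
        M = rng.uniform(0, 1, (5, 5))
        M = 100 * M / M.sum(axis=1, keepdims=True)
        prev = within_band_accuracy(M, 0)
        for k in range(1, 5):
            cur = within_band_accuracy(M, k)
            assert np.all(cur >= prev - 1e-12)
            prev = cur
        assert within_band_accuracy(M, 4) == pytest.approx([100] * 5)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            within_band_accuracy(self.CONF, -1)


def separated_population():
    """Two age bins with disjoint, well-separated length distributions."""
    rng = np.random.default_rng(7)
    young = pd.DataFrame(
        {
            "animal_id": [f"y{i}" for i in range(40)],
            "age": rng.uniform(0, 9, 40),
            "tl": rng.uniform(95, 105, 40),
            "bhdf": rng.uniform(28, 32, 40),
        }
    )
    old = pd.DataFrame(
        {
            "animal_id": [f"o{i}" for i in range(40)],
            "age": rng.uniform(12, 40, 40),
            "tl": rng.uniform(395, 405, 40),
            "bhdf": rng.uniform(118, 122, 40),
        }
    )
    return pd.concat([young, old], ignore_index=True)


class TestClassifierExperiment:
    def test_perfect_separation_zero_noise(self):
        pop = separated_population()
        perf = run_classifier_experiment(
            pop,
            builtin_scenarios()["E"],
            fit_loglinear_model(pop),
            ZERO,
            ZERO,
            n_replicates=3,
            mode="argmax",
            seed=0,
        )
        assert perf.mean_accuracy == 100.0

    def test_determinism(self, population, loglinear_model, default_noise):
        b, t = default_noise
        args = (population, builtin_scenarios()["D"], loglinear_model, b, t)
        p1 = run_classifier_experiment(*args, n_replicates=20, seed=77)
        p2 = run_classifier_experiment(*args, n_replicates=20, seed=77)
        assert np.array_equal(p1.confusion, p2.confusion)
        assert p1.mean_accuracy == p2.mean_accuracy

    def test_confusion_rows_sum_to_100(self, population, loglinear_model, default_noise):
        b, t = default_noise
        perf = run_classifier_experiment(
            population, builtin_scenarios()["B"], loglinear_model, b, t, n_replicates=30, seed=5
        )
        assert perf.confusion.sum(axis=1) == pytest.approx([100.0] * 6, abs=1e-6)
        assert np.all(perf.within_band >= perf.per_bin_accuracy - 1e-9)

    def test_bhdf_measure_runs(self, population, loglinear_model, default_noise):
        b, t = default_noise
        perf = run_classifier_experiment(
            population, builtin_scenarios()["E"], loglinear_model, b, t,
            n_replicates=30, measure="BHDF", seed=5,
        )
        assert perf.measure == "BHDF" and 0 < perf.mean_accuracy <= 100

    def test_unknown_ages_excluded(self, loglinear_model, default_noise):
        b, t = default_noise
        df = separated_population()
        df.loc[0, "age"] = np.nan
        perf = run_classifier_experiment(
            df, builtin_scenarios()["E"], UNIT_MODEL, ZERO, ZERO, n_replicates=2, seed=0
        )
        assert int(perf.bin_n.sum()) == len(df) - 1


class TestPopulationAgeStructure:
    def test_zero_noise_recovers_true_occupancy(self):
        df = separated_population()
        perf = run_classifier_experiment(
            df, builtin_scenarios()["E"], fit_loglinear_model(df), ZERO, ZERO,
            n_replicates=5, mode="argmax", seed=0,
        )
        out = population_age_structure(perf.assigned_proportions, perf.scenario)
        assert out["proportion"].to_numpy() == pytest.approx([0.5, 0.5])
        assert out["proportion"].sum() == pytest.approx(1.0)

    def test_proportions_sum_to_one_each_replicate(self, population, loglinear_model, default_noise):
        b, t = default_noise
        perf = run_classifier_experiment(
            population, builtin_scenarios()["D"], loglinear_model, b, t, n_replicates=25, seed=3
        )
        assert perf.assigned_proportions.sum(axis=1) == pytest.approx(np.ones(25))

    def test_interval_widens_with_noise(self, population, loglinear_model):
        widths = []
        for sd in (0.01, 0.10):
            b, t = NoiseSpec(0.0, sd), NoiseSpec(0.0, sd, "TL")
            perf = run_classifier_experiment(
                population, builtin_scenarios()["E"], loglinear_model, b, t,
                n_replicates=100, seed=9,
            )
            out = population_age_structure(perf.assigned_proportions, perf.scenario)
            widths.append(float((out["hi_97.5"] - out["lo_2.5"]).iloc[0]))
        assert widths[1] > widths[0]
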