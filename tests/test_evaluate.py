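"""Performance statistics: repeatability, accuracy, agreement, prediction error."""

import numpy as np
import pandas as pd
import pytest

from methclock import quantify
from methclock.evaluate import (EvaluationError, accuracy_vs_expected,
                                clock_cross_correlation, mae_age,
                                method_correlation, per_level_sd, replicate_mad,
                                replicate_pairs, sensitivity_summary,
                                summarize_ages)
from methclock.simulate import (STANDARD_LEVELS, SimulationConfig,
                                simulate_sensitivity_series,
                                simulate_standard_series)


def _matrix(data, samples=None):
    m = pd.DataFrame(data)
    if samples is not None:
        m.index = samples
    m.index.name = "sample_id"
    return m


class TestReplicateMad:
    def test_identical_replicates_give_zero(self):
        m = _matrix({"cgA": [0.2, 0.2], "cgB": [0.9, 0.9]}, ["r1", "r2"])
        stat = replicate_mad(m, [("r1", "r2")])
        assert stat.mean == 0.0 and stat.sd == 0.0 and stat.n == 2

    def test_small_worked_example(self):
        m = _matrix({"cgA": [0.2, 0.3, 0.5, 0.5]}, ["a1", "a2", "b1", "b2"])
        stat = replicate_mad(m, [("a1", "a2"), ("b1", "b2")])
        assert stat.mean == pytest.approx(0.05)

    def test_missing_cells_dropped_pairwise(self):
        m = _matrix({"cgA": [0.2, np.nan], "cgB": [0.4, 0.5]}, ["r1", "r2"])
        stat = replicate_mad(m, [("r1", "r2")])
        assert stat.n == 1 and stat.mean == pytest.approx(0.1)

    def test_sample_in_two_pairs_rejected(self):
        m = _matrix({"cgA": [0.2, 0.3, 0.4]}, ["r1", "r2", "r3"])
        with pytest.raises(EvaluationError, match="more than one pair"):
            replicate_mad(m, [("r1", "r2"), ("r2", "r3")])

    def test_matches_double_loop_oracle(self, rng):
        samples = [f"s{i}" for i in range(6)]
        m = _matrix(rng.uniform(0, 1, (6, 9)), samples)
        m.columns = [f"cg{j}" for j in range(9)]
        pairs = [("s0", "s1"), ("s2", "s3"), ("s4", "s5")]
        diffs = [abs(m.loc[a, c] - m.loc[b, c]) for a, b in pairs for c in m.columns]
        stat = replicate_mad(m, pairs)
        assert stat.mean == pytest.approx(np.mean(diffs))
        assert stat.sd == pytest.approx(np.std(diffs, ddof=1))

    def test_invariant_under_marker_reordering_and_pair_relabeling(self, rng):
        samples = ["a1", "a2", "b1", "b2"]
        m = _matrix(rng.uniform(0, 1, (4, 5)), samples)
        m.columns = [f"cg{j}" for j in range(5)]
        pairs = [("a1", "a2"), ("b1", "b2")]
        base = replicate_mad(m, pairs)
        shuffled = m[list(m.columns[::-1])]
        assert replicate_mad(shuffled, pairs).mean == pytest.approx(base.mean)
        swapped = [("a2", "a1"), ("b2", "b1")]
        assert replicate_mad(m, swapped).mean == pytest.approx(base.mean)

    def test_pairs_derived_from_metadata(self):
        samples = pd.DataFrame({
            "sample_id": ["x_r1", "x_r2", "y_r1", "y_r2"],
            "source_id": ["x", "x", "y", "y"],
            "replicate": [1, 2, 1, 2]})
        assert replicate_pairs(samples) == [("x_r1", "x_r2"), ("y_r1", "y_r2")]


class TestAccuracy:
    def test_perfect_observation_gives_zero(self):
        m = _matrix({"cgA": [0.25], "cgB": [0.25]}, ["s1"])
        assert accuracy_vs_expected(m, {"s1": 0.25}).mean == 0.0

    def test_small_worked_example(self):
        m = _matrix({"cgA": [0.20], "cgB": [0.30]}, ["s1"])
        stat = accuracy_vs_expected(m, {"s1": 0.25})
        assert stat.mean == pytest.approx(0.05)

    def test_missing_truth_rejected(self):
        m = _matrix({"cgA": [0.2]}, ["s1"])
        with pytest.raises(EvaluationError):
            accuracy_vs_expected(m, {})

    def test_binomial_noise_regime_below_0p02(self, small_panel):
        cfg = SimulationConfig(seed=31, coverage_mu=np.log(10**4), coverage_sigma=0.2,
                               conversion_rate=1.0, inappropriate_conversion=0.0)
        counts, truth = simulate_standard_series(small_panel, config=cfg)
        matrix, _ = quantify.quantify(counts, small_panel)
        expected = dict(zip(truth.samples["sample_id"], truth.samples["expected_beta"]))
        assert accuracy_vs_expected(matrix, expected).mean < 0.02


class TestSensitivity:
    def test_group_means_match_hand_computation(self):
        m = _matrix({"cgA": [0.2, 0.4, 0.6, 0.8]}, ["lo1", "lo2", "hi1", "hi2"])
        meta = pd.DataFrame({
            "sample_id": ["lo1", "lo2", "hi1", "hi2"],
            "input_ng": [1.0, 1.0, 50.0, 50.0],
            "expected_beta": [0.25, 0.25, 0.25, 0.25]})
        out = sensitivity_summary(m, meta)
        lo = out[out["input_ng"] == 1.0].iloc[0]
        hi = out[out["input_ng"] == 50.0].iloc[0]
        assert lo["mean"] == pytest.approx(0.3) and hi["mean"] == pytest.approx(0.7)

    def test_single_group_yields_one_row(self):
        m = _matrix({"cgA": [0.2]}, ["s1"])
        meta = pd.DataFrame({"sample_id": ["s1"], "input_ng": [25.0],
                             "expected_beta": [0.25]})
        assert len(sensitivity_summary(m, meta)) == 1

    def test_variability_decreases_with_dna_input(self, small_panel):
        """Across seeds, the SD of observed beta shrinks as input grows."""
        sds = {1.0: [], 50.0: []}
        for seed in range(20):
            cfg = SimulationConfig(seed=400 + seed, coverage_mu=np.log(800),
                                   coverage_sigma=0.3)
            counts, truth = simulate_sensitivity_series(
                small_panel, levels=[0.5], inputs_ng=(50.0, 1.0), config=cfg)
            matrix, _ = quantify.quantify(counts, small_panel, min_reads=1)
            out = sensitivity_summary(matrix, truth.samples)
            for ng in (1.0, 50.0):
                sds[ng].append(float(out[out["input_ng"] == ng]["sd"].iloc[0]))
        assert np.mean(sds[1.0]) > np.mean(sds[50.0])


class TestMethodCorrelation:
    def test_identical_matrices(self):
        m = _matrix({"cgA": [0.1, 0.5], "cgB": [0.9, 0.3]}, ["s1", "s2"])
        corr, mad = method_correlation({"A": m, "B": m.copy()})
        assert corr.loc["A", "B"] == pytest.approx(1.0)
        assert mad.loc["A", "B"] == 0.0
        assert (np.diag(corr) == 1.0).all()

    def test_monotone_transform_preserves_rank_correlation(self):
        m = _matrix({"cgA": [0.1, 0.5], "cgB": [0.9, 0.3]}, ["s1", "s2"])
        warped = m ** 3  # strictly monotone
        corr, _ = method_correlation({"A": m, "B": warped})
        assert corr.loc["A", "B"] == pytest.approx(1.0)

    def test_matches_midrank_product_moment_oracle(self, rng):
        vals_a = rng.uniform(0, 1, (3, 4))
        vals_b = rng.uniform(0, 1, (3, 4))
        vals_b[0, 0] = vals_b[0, 1]  # force a tie
        cols = [f"cg{j}" for j in range(4)]
        A = _matrix(vals_a, ["s1", "s2", "s3"]); A.columns = cols
        B = _matrix(vals_b, ["s1", "s2", "s3"]); B.columns = cols
        corr, mad = method_correlation({"A": A, "B": B})
        from scipy.stats import rankdata
        ra = rankdata(vals_a.ravel())
        rb = rankdata(vals_b.ravel())
        expected = np.corrcoef(ra, rb)[0, 1]
        assert corr.loc["A", "B"] == pytest.approx(expected, abs=1e-12)
        assert mad.loc["A", "B"] == pytest.approx(np.mean(np.abs(vals_a - vals_b)))

    def test_single_technology_rejected(self):
        m = _matrix({"cgA": [0.1]}, ["s1"])
        with pytest.raises(EvaluationError):
            method_correlation({"A": m})


class TestAgeError:
    def test_perfect_prediction(self):
        assert mae_age([7, 28], [7, 28]).mean == 0.0

    def test_small_worked_example(self):
        stat = mae_age([40.0, 50.0], [44.0, 44.0])
        assert stat.mean == pytest.approx(5.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            mae_age([1.0], [1.0, 2.0])

    def test_matches_direct_oracle(self, rng):
        pred = rng.uniform(0, 90, 30)
        chrono = rng.uniform(0, 90, 30)
        stat = mae_age(pred, chrono)
        assert stat.mean == pytest.approx(np.mean(np.abs(pred - chrono)))
        assert stat.sd == pytest.approx(np.std(np.abs(pred - chrono), ddof=1))

    def test_cohort_age_summary_uses_sample_sd(self):
        ages = [7, 28, 46, 61, 78] * 2
        stat = summarize_ages(ages)
        assert round(stat.mean, 1) == 44.0
        assert round(stat.sd, 1) == 26.1  # n-1 denominator


class TestClockCorrelation:
    @staticmethod
    def _outputs(values_by_clock, samples):
        rows = [(s, c, v, "years", 0)
                for c, vals in values_by_clock.items() for s, v in zip(samples, vals)]
        return pd.DataFrame(rows, columns=["sample_id", "clock", "value",
                                           "units", "n_imputed"])

    def test_self_correlation_is_one_and_anticorrelation_minus_one(self):
        samples = [f"s{i}" for i in range(5)]
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = self._outputs({"a": v, "b": [-x for x in v]}, samples)
        with pytest.warns(UserWarning, match="only n=5"):
            corr = clock_cross_correlation(out)
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_constant_clock_yields_nan_not_error(self):
        samples = [f"s{i}" for i in range(12)]
        out = self._outputs({"a": list(range(12)), "b": [2.0] * 12}, samples)
        corr = clock_cross_correlation(out)
        assert np.isnan(corr.loc["a", "b"])

    def test_correlation_decays_with_independent_noise(self):
        """Two clocks driven by the same latent age decorrelate as noise grows."""
        latent = np.linspace(5, 80, 40)
        mean_r = []
        for noise in (1.0, 5.0, 25.0):
            rs = []
            for seed in range(10):
                rng = np.random.default_rng(900 + seed)
                a = latent + rng.normal(0, noise, latent.size)
                b = latent + rng.normal(0, noise, latent.size)
                out = self._outputs({"a": a, "b": b}, [f"s{i}" for i in range(40)])
                rs.append(clock_cross_correlation(out).loc["a", "b"])
            mean_r.append(np.mean(rs))
        assert mean_r[0] > mean_r[1] > mean_r[2]


class TestVariabilityProfile:
    def test_replicate_spread_peaks_at_intermediate_levels(self, small_panel):
        """Observed beta spread is maximal mid-scale, minimal at 0 and 1."""
        per_level = {lv: [] for lv in STANDARD_LEVELS}
        for seed in range(10):
            cfg = SimulationConfig(seed=600 + seed, coverage_mu=np.log(1500),
                                   coverage_sigma=0.5)
            counts, truth = simulate_standard_series(small_panel, config=cfg)
            matrix, _ = quantify.quantify(counts, small_panel, min_reads=1)
            expected = dict(zip(truth.samples["sample_id"],
                                truth.samples["expected_beta"]))
            sds = per_level_sd(matrix, expected)
            for lv in STANDARD_LEVELS:
                per_level[lv].append(float(sds[lv]))
        avg = {lv: np.mean(v) for lv, v in per_level.items()}
        mid = max(avg[0.25], avg[0.5], avg[0.75])
        assert mid > avg[0.0] and mid > avg[1.0]
        assert avg[0.5] > avg[0.0] and avg[0.5] > avg[1.0]
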