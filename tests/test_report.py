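

import numpy as np
import pytest

from mitosweep import (
    CombinationSummary,
    SVMConfig,
    SplitSpec,
    ToolSubset,
    compare_best_vs_full,
    contribution_binned,
    contribution_topk,
    evaluate_combination,
    generate_dataset,
    impute_missing,
    predict_with_subset,
    rank_combinations,
    run_sweep,
)
from mitosweep.report import best_sensitivity_by_size, mean_sensitivity_by_size


def _summary(mask, mean_sens=0.5, mean_spec=0.9, n_runs=10):
    return CombinationSummary(
        subset=ToolSubset(mask), n_runs=n_runs,
        mean_sens=mean_sens, sd_sens=0.05, mean_spec=mean_spec, sd_spec=0.01,
        mean_fdr=0.1, sd_fdr=0.01, mean_cfdr=0.2, sd_cfdr=0.02, n_overfit_runs=0,
    )


def _all_summaries(n_tools, value):
    """One summary per non-empty subset; metric value assigned by `value(mask)`."""
    return [
        _summary(mask, mean_sens=value(mask))
        for mask in range(1, 1 << n_tools)
    ]


class TestRanking:
    def test_distinct_means_strictly_ordered(self):
        summaries = [_summary(1, 0.2), _summary(2, 0.9), _summary(3, 0.5)]
        ranked = rank_combinations(summaries, "sensitivity")
        assert [s.subset.mask for s in ranked] == [2, 3, 1]

    def test_tie_broken_by_smaller_size_then_mask(self):
        summaries = [_summary(0b10011, 0.7), _summary(0b101, 0.7), _summary(0b110, 0.7)]
        ranked = rank_combinations(summaries, "sensitivity")
        assert [s.subset.mask for s in ranked] == [0b101, 0b110, 0b10011]

    def test_matches_brute_force_sort_oracle(self):
        rng = np.random.default_rng(0)
        summaries = [_summary(m, float(rng.random())) for m in rng.choice(
            np.arange(1, 256), size=100, replace=False)]
        ranked = rank_combinations(summaries, "sensitivity")
        oracle = sorted(summaries, key=lambda s: (-s.mean_sens, s.subset.size, s.subset.mask))
        assert [s.subset.mask for s in ranked] == [s.subset.mask for s in oracle]

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            rank_combinations([_summary(1)], "auc")


class TestContributionTopK:
    def test_tool_in_every_top_combination_has_probability_one(self):
        # tool 0 always present in the top: give mask-containing-0 high values
        summaries = _all_summaries(4, lambda m: 0.9 if m & 1 else 0.1)
        table = contribution_topk(summaries, "sensitivity", k=8, n_tools=4)
        assert table.probabilities[0, 0] == 1.0

    def test_k_equal_to_all_2047_subsets_gives_the_counting_identity(self):
        summaries = _all_summaries(11, lambda m: 0.5)
        table = contribution_topk(summaries, "sensitivity", k=2047, n_tools=11)
        np.testing.assert_allclose(table.probabilities[0], 1024 / 2047)

    def test_tool_absent_from_top_has_probability_zero(self):
        summaries = _all_summaries(4, lambda m: 0.1 if m & 0b1000 else 0.9)
        table = contribution_topk(summaries, "sensitivity", k=7, n_tools=4)
        assert table.probabilities[0, 3] == 0.0

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            contribution_topk([_summary(1)], "sensitivity", k=0)
        with pytest.raises(ValueError):
            contribution_topk([_summary(1)], "sensitivity", k=2)


class TestContributionBinned:
    def test_single_bin_equals_topk_with_all(self):
        rng = np.random.default_rng(1)
        summaries = _all_summaries(5, lambda m: float(rng.random()))
        binned = contribution_binned(summaries, "sensitivity", bin_edges=[0.0, 1.0], n_tools=5)
        topk = contribution_topk(summaries, "sensitivity", k=len(summaries), n_tools=5)
        np.testing.assert_allclose(binned.probabilities[0], topk.probabilities[0])

    def test_singleton_bins_give_membership_indicators(self):
        summaries = [_summary(0b01, 0.25), _summary(0b10, 0.75)]
        table = contribution_binned(summaries, "sensitivity",
                                    bin_edges=[0.0, 0.5, 1.0], n_tools=2)
        np.testing.assert_array_equal(table.probabilities, [[1.0, 0.0], [0.0, 1.0]])

    def test_row_sums_equal_mean_subset_size_per_bin(self):
        rng = np.random.default_rng(2)
        summaries = _all_summaries(6, lambda m: float(rng.random()))
        edges = np.linspace(0.0, 1.0, 6)
        table = contribution_binned(summaries, "sensitivity", bin_edges=edges, n_tools=6)
        # brute-force counting identity per bin
        values = np.array([s.mean_sens for s in summaries])
        which = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, 4)
        for b in range(5):
            members = [s for s, w in zip(summaries, which) if w == b]
            if not members:
                assert np.isnan(table.probabilities[b]).all()
                continue
            expected = np.mean([s.subset.size for s in members])
            assert np.nansum(table.probabilities[b]) == pytest.approx(expected, abs=1e-12)

    def test_empty_bins_are_nan_not_zero(self):
        summaries = [_summary(1, 0.9)]
        table = contribution_binned(summaries, "sensitivity",
                                    bin_edges=[0.0, 0.5, 1.0], n_tools=1)
        assert np.isnan(table.probabilities[0, 0])

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            contribution_binned([_summary(1)], "sensitivity", bin_edges=[0.5, 0.2, 1.0])

    def test_edges_must_cover_observed_range(self):
        with pytest.raises(ValueError, match="cover"):
            contribution_binned([_summary(1, 0.9)], "sensitivity", bin_edges=[0.0, 0.5])


@pytest.fixture(scope="module")
def sweep_output():
    from mitosweep import PredictorProfile, ScenarioConfig

    cfg = ScenarioConfig(
        profiles=(
            PredictorProfile("strong", tpr=0.9, fpr=0.01),
            PredictorProfile("ok", tpr=0.4, fpr=0.05),
            PredictorProfile("noise", tpr=0.3, fpr=0.3, noise_sd=0.4),
        ),
        n_pos=60, n_neg=240, seed=3,
    )
    table = impute_missing(generate_dataset(cfg))
    spec = SplitSpec(n_test_pos=15, n_test_neg=60, n_runs=5, base_seed=3)
    return run_sweep(table, spec, SVMConfig(), keep_runs=True)


class TestCompareBestVsFull:

    def test_degenerate_full_set_best_reports_no_paradox(self, sweep_output):
        summaries, runs = sweep_output
        record = compare_best_vs_full(summaries, runs, k_best_size=3)
        if record.best_mask == 0b111:
            assert not record.paradox and record.z is None
        else:
            assert record.z is not None

    def test_restricted_best_is_found_and_z_computed(self, sweep_output):
        summaries, runs = sweep_output
        record = compare_best_vs_full(summaries, runs, k_best_size=2)
        assert record.best_size <= 2
        assert record.z is not None
        assert record.difference == pytest.approx(
            record.best_mean_sens - record.full_mean_sens, abs=1e-9
        )

    def test_printed_study_values_feed_through_the_comparison_arithmetic(self):
        from mitosweep import welch_z

        diff, z, _ = welch_z(64.14, 5.22, 100, 52.51, 5.80, 100)
        assert diff == pytest.approx(11.63, abs=1e-12)

    def test_missing_full_set_rejected(self):
        with pytest.raises(ValueError, match="full tool set"):
            compare_best_vs_full([_summary(1)], {}, k_best_size=1, n_tools=2)


class TestSizeCurves:
    def test_mean_and_best_by_size_match_brute_force(self):
        rng = np.random.default_rng(4)
        summaries = _all_summaries(4, lambda m: float(rng.random()))
        mean_curve = mean_sensitivity_by_size(summaries)
        best_curve = best_sensitivity_by_size(summaries)
        for size in range(1, 5):
            vals = [s.mean_sens for s in summaries if s.subset.size == size]
            assert mean_curve[size] == pytest.approx(np.mean(vals))
            assert best_curve[size] == pytest.approx(max(vals))


class TestPredictWithSubset:
    def test_perfect_tool_reproduces_training_labels(self, separable_table):
        labels = predict_with_subset(
            separable_table, ToolSubset(1), separable_table, SVMConfig()
        )
        np.testing.assert_array_equal(labels, separable_table.labels)
        assert len(labels) == separable_table.n_proteins

    def test_matches_evaluate_combination_internal_predictions(self):
        from mitosweep import ConfusionCounts, stratified_split
        from mitosweep import PredictorProfile, ScenarioConfig

        cfg = ScenarioConfig(
            profiles=(PredictorProfile("a", tpr=0.7, fpr=0.05),
                      PredictorProfile("b", tpr=0.4, fpr=0.1)),
            n_pos=30, n_neg=120, seed=6,
        )
        table = impute_missing(generate_dataset(cfg))
        spec = SplitSpec(n_test_pos=8, n_test_neg=30, n_runs=1, base_seed=9)
        subset = ToolSubset(0b11)
        _, runs = evaluate_combination(table, subset, spec, SVMConfig())
        train_t, test_t = stratified_split(table.restrict(subset), spec, 0, salt=subset.mask)
        labels = predict_with_subset(test_t, ToolSubset(0b11, ), train_t, SVMConfig())
        counts = ConfusionCounts.from_predictions(test_t.labels, labels)
        assert counts == runs[0].counts
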