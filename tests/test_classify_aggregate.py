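"""Heuristic and trainable classification, bootstrap aggregation, and
sample-level calls."""

import numpy as np
import pytest
from scipy import stats

from interfish.classify_aggregate import (
    BootstrapConfig,
    CnnConfig,
    HeuristicThresholds,
    NucleusPrediction,
    SampleRule,
    bootstrap_sample_call,
    cnn_predict,
    cnn_train,
    combine_focal_gate,
    heterogeneity_chisq,
    heuristic_classify,
    merge_window_predictions,
    sample_rule_call,
    threshold_grid_search,
    _balanced_epoch_indices,
)


class TestHeuristic:
    @pytest.mark.parametrize(
        "stats_,expected",
        [
            ((5, 20), "HSR-like"),
            ((15, 100), "EC-like"),
            ((10, 20), "EC-like"),  # strict < on the mean cut
            ((5, 64), "EC-like"),  # strict < on the variance cut
            ((9.99, 63.99), "HSR-like"),
        ],
    )
    def test_rule_application(self, stats_, expected):
        assert heuristic_classify(stats_) == expected

    def test_grid_search_separable_data_reaches_perfect_accuracy(self):
        ec = [(20, 150), (30, 400), (18, 90)]
        hsr = [(4, 10), (6, 30), (8, 20)]
        stats_ = ec + hsr
        labels = ["EC-like"] * 3 + ["HSR-like"] * 3
        thr, acc = threshold_grid_search(stats_, labels, [5, 10, 15], [32, 64, 128])
        assert acc == 1.0

    def test_grid_search_single_cell_grid(self):
        stats_ = [(5, 10), (20, 100)]
        labels = ["HSR-like", "EC-like"]
        thr, acc = threshold_grid_search(stats_, labels, [10], [64])
        assert (thr.mean_cut, thr.var_cut) == (10, 64) and acc == 1.0

    def test_grid_search_accuracy_matches_naive_double_loop(self, rng):
        stats_ = [(float(m), float(v)) for m, v in rng.uniform(0, 30, size=(40, 2)) * (1, 10)]
        labels = [rng.choice(["EC-like", "HSR-like"]) for _ in range(40)]
        if len(set(labels)) < 2:
            labels[0] = "EC-like" if labels[1] == "HSR-like" else "HSR-like"
        mean_grid, var_grid = [5.0, 10.0, 20.0], [30.0, 64.0, 120.0]
        thr, acc = threshold_grid_search(stats_, labels, mean_grid, var_grid)
        best = 0.0
        for m in mean_grid:
            for v in var_grid:
                t = HeuristicThresholds(mean_cut=m, var_cut=v)
                correct = 0
                for s, lab in zip(stats_, labels):
                    correct += heuristic_classify(s, t) == lab
                best = max(best, correct / len(labels))
        assert acc == pytest.approx(best)

    def test_grid_search_requires_two_classes_and_a_grid(self):
        with pytest.raises(ValueError):
            threshold_grid_search([(1, 1)], ["EC-like"], [10], [64])
        with pytest.raises(ValueError):
            threshold_grid_search([(1, 1), (2, 2)], ["EC-like", "HSR-like"], [], [64])


def separable_toy_patches(n_per_class=10, seed=0):
    """Tiny 32x32 single-channel patches: bright-top vs bright-bottom."""
    rng = np.random.default_rng(seed)
    patches, labels = [], []
    for _ in range(n_per_class):
        a = rng.uniform(0, 0.2, (32, 32, 1))
        a[:16] += 0.7
        patches.append(a)
        labels.append("EC-amp")
        b = rng.uniform(0, 0.2, (32, 32, 1))
        b[16:] += 0.7
        patches.append(b)
        labels.append("HSR-amp")
    return patches, labels


class TestTrainingHarness:
    def test_tiny_config_overfits_separable_toy_set(self):
        patches, labels = separable_toy_patches(10)
        config = CnnConfig(
            n_classes=3, dense_blocks=(2, 2), growth_factor=8,
            learning_rate=5e-3, max_epochs=200, seed=0, feature_pool=8,
        )
        model = cnn_train(patches, labels, config)
        preds = cnn_predict(model, patches)
        assert [p.hard_label for p in preds] == labels

    def test_posteriors_sum_to_one_and_are_deterministic(self):
        patches, labels = separable_toy_patches(5)
        config = CnnConfig(
            n_classes=3, dense_blocks=(2,), growth_factor=4,
            learning_rate=5e-3, max_epochs=30, seed=1, feature_pool=8,
        )
        model = cnn_train(patches, labels, config)
        a = cnn_predict(model, patches[:3])
        b = cnn_predict(model, patches[:3])
        for pa, pb in zip(a, b):
            assert pa.posteriors.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_array_equal(pa.posteriors, pb.posteriors)
            assert pa.hard_label == ("EC-amp", "HSR-amp", "no-amp")[np.argmax(pa.posteriors)]

    def test_run_to_run_identical_losses_under_fixed_seed(self):
        patches, labels = separable_toy_patches(5)
        config = CnnConfig(
            n_classes=2, dense_blocks=(2,), growth_factor=4,
            max_epochs=20, seed=3, feature_pool=8,
        )
        m1 = cnn_train(patches, labels, config)
        m2 = cnn_train(patches, labels, config)
        for (W1, b1), (W2, b2) in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(W1, W2)
            np.testing.assert_array_equal(b1, b2)

    def test_single_class_data_rejected(self):
        patches, _ = separable_toy_patches(3)
        with pytest.raises(ValueError):
            cnn_train(patches, ["EC-amp"] * len(patches), CnnConfig())

    def test_balanced_sampler_equalizes_strata(self, rng):
        """Over many epochs, strata of sizes 100 and 10 receive equal
        expected draw mass per stratum."""
        strata = np.array(["big"] * 100 + ["small"] * 10)
        draws = np.concatenate(
            [_balanced_epoch_indices(strata, 110, rng) for _ in range(200)]
        )
        frac_small = (draws >= 100).mean()
        se = np.sqrt(0.25 / draws.size)
        assert abs(frac_small - 0.5) < 4 * se


class TestFocalGate:
    def _pred(self, ec, hsr, no):
        return NucleusPrediction(nucleus_id=1, posteriors=(ec, hsr, no))

    def test_no_focal_amp_forces_no_amp(self):
        out = combine_focal_gate(self._pred(0.7, 0.2, 0.1), "no-focal-amp")
        assert out.hard_label == "no-amp"

    def test_absent_gate_passes_through(self):
        pred = self._pred(0.5, 0.3, 0.2)
        assert combine_focal_gate(pred, None) is pred

    def test_focal_amp_picks_better_amplified_class(self):
        assert combine_focal_gate(self._pred(0.6, 0.3, 0.1), "focal-amp").hard_label == "EC-amp"
        assert combine_focal_gate(self._pred(0.2, 0.5, 0.3), "focal-amp").hard_label == "HSR-amp"

    def test_unknown_gate_value_rejected(self):
        with pytest.raises(ValueError):
            combine_focal_gate(self._pred(1, 0, 0), "maybe")

    def test_window_votes_merge_by_mean_posterior(self):
        preds = [
            NucleusPrediction(nucleus_id=1, posteriors=(0.8, 0.1, 0.1)),
            NucleusPrediction(nucleus_id=1, posteriors=(0.2, 0.7, 0.1)),
            NucleusPrediction(nucleus_id=2, posteriors=(0.1, 0.1, 0.8)),
        ]
        merged = merge_window_predictions(preds)
        assert len(merged) == 2
        np.testing.assert_allclose(merged[0].posteriors, (0.5, 0.4, 0.1))


class TestBootstrap:
    def test_homogeneous_input_invariant_to_seed(self):
        for seed in (0, 1, 99):
            dist = bootstrap_sample_call(
                ["EC-amp"] * 25, BootstrapConfig(seed=seed)
            )
            assert dist["EC-amp"] == 1.0
            assert dist["HSR-amp"] == 0.0 and dist["no-amp"] == 0.0

    def test_fixed_seed_reproducible(self):
        labels = ["EC-amp"] * 7 + ["HSR-amp"] * 3
        a = bootstrap_sample_call(labels, BootstrapConfig(seed=42))
        b = bootstrap_sample_call(labels, BootstrapConfig(seed=42))
        assert a == b

    def test_seventy_thirty_matches_binomial_oracle(self):
        """With 70% EC labels, the EC win fraction over 10-cell majority
        votes follows P(Bin(10,0.7) >= 6) + 0.5 P(= 5) under the uniform
        tie rule."""
        labels = ["EC-amp"] * 70 + ["HSR-amp"] * 30
        config = BootstrapConfig(n_iterations=10_000, seed=5)
        dist = bootstrap_sample_call(labels, config)
        oracle = stats.binom.sf(5, 10, 0.7) + 0.5 * stats.binom.pmf(5, 10, 0.7)
        se = np.sqrt(oracle * (1 - oracle) / config.n_iterations)
        assert abs(dist["EC-amp"] - oracle) < 3 * se

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_sample_call([])


class TestSampleRule:
    @pytest.mark.parametrize(
        "fractions,expected",
        [
            ({"no-amp": 1.0}, "no-amp"),
            ({"no-amp": 0.80, "EC-amp": 0.20}, "no-amp"),
            ({"no-amp": 0.79, "EC-amp": 0.21}, "heterogeneous"),
            ({"HSR-amp": 0.80, "EC-amp": 0.20}, "HSR-amp"),
            ({"HSR-amp": 0.79, "EC-amp": 0.21}, "heterogeneous"),
            ({"EC-amp": 0.50, "HSR-amp": 0.50}, "EC-amp"),
            ({"EC-amp": 0.49, "HSR-amp": 0.36, "no-amp": 0.15}, "heterogeneous"),
            ({"EC-amp": 0.45, "HSR-amp": 0.40, "no-amp": 0.15}, "heterogeneous"),
        ],
    )
    def test_threshold_order_and_boundaries(self, fractions, expected):
        assert sample_rule_call(fractions) == expected

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            sample_rule_call({"EC-amp": 0.5})

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            SampleRule(noamp_cut=0.0)


class TestHeterogeneityChisq:
    def test_identical_counts_give_zero_statistic(self):
        stat, df, p = heterogeneity_chisq([10, 20, 30], [10, 20, 30])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_by_two_table_hand_formula(self):
        # {{10,20},{20,10}}: expected 15 everywhere, statistic 4 * 25/15
        stat, df, p = heterogeneity_chisq([10, 20], [20, 10])
        assert df == 1
        assert stat == pytest.approx(4 * 25 / 15)

    def test_survival_function_reference_point(self):
        """A statistic of 2.7252 at df 3 corresponds to p = 0.4360."""
        assert stats.chi2.sf(2.7252, 3) == pytest.approx(0.4360, abs=5e-5)

    def test_zero_count_classes_dropped_pairwise(self):
        stat3, df3, _ = heterogeneity_chisq(
            {"EC-amp": 10, "HSR-amp": 20, "no-amp": 0},
            {"EC-amp": 12, "HSR-amp": 18, "no-amp": 0},
        )
        assert df3 == 1  # the both-zero class does not contribute df

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity_chisq([0, 0], [5, 5])

    def test_p_value_agrees_with_multinomial_monte_carlo(self, rng):
        """Pearson p-value within Monte-Carlo error of a permutation-style
        multinomial simulation on a small 2x3 table."""
        a = np.array([18, 12, 10])
        b = np.array([10, 15, 15])
        stat, df, p = heterogeneity_chisq(list(a), list(b))
        pooled = (a + b) / (a + b).sum()
        n_sim = 4000
        hits = 0
        for _ in range(n_sim):
            sa = rng.multinomial(a.sum(), pooled)
            sb = rng.multinomial(b.sum(), pooled)
            if (sa + sb).min() == 0:
                continue
            s, _, _ = heterogeneity_chisq(list(sa), list(sb))
            hits += s >= stat - 1e-12
        mc = hits / n_sim
        se = np.sqrt(mc * (1 - mc) / n_sim)
        assert abs(p - mc) < 3 * se + 0.01
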