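"""Tagging-accuracy likelihood: oracles, identities, and recovery."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from interfish.tagging_mle import (
    TaggingExperiment,
    estimate_untagged_count,
    expected_category_counts,
    fit_tagging_experiment,
    simulate_tagging_experiment,
    tag_nucleus,
    tagging_accuracy,
    tagging_fit_check,
    tagging_log_likelihood,
)

PAPER_LIKE = dict(ph=0.2642, pe=0.7358, qh=0.9763, qe=0.0237)


def brute_force_likelihood(x, Nh, ch, ph, pe, qh, qe):
    """Exhaustive oracle: enumerate which subset of the Nh untagged
    nuclei is truly EC (all size-x subsets equally arranged -> sum over
    labelings) and, for each labeling, every prediction assignment
    consistent with the observed (ch, ce) counts."""
    total = 0.0
    for ec_set in itertools.combinations(range(Nh), x):
        for preds in itertools.product("he", repeat=Nh):
            if sum(p == "h" for p in preds) != ch:
                continue
            prob = 1.0
            for i, p in enumerate(preds):
                if i in ec_set:
                    prob *= ph if p == "h" else pe
                else:
                    prob *= qh if p == "h" else qe
            total += prob
    # the model treats the x EC nuclei as exchangeable: the likelihood is
    # per-labeling, not summed over labelings
    return total / math.comb(Nh, x)


class TestTagNucleus:
    def test_all_zero_channel_untagged(self):
        assert tag_nucleus(np.zeros((8, 8), dtype=np.uint8)) == "untagged"

    def test_bright_interior_nucleus_tagged(self):
        channel = np.zeros((8, 8), dtype=np.uint8)
        channel[3, 3] = 255
        assert tag_nucleus(channel) == "tagged"

    def test_boundary_nucleus_excluded_even_if_bright(self):
        channel = np.full((8, 8), 255, dtype=np.uint8)
        assert tag_nucleus(channel, boundary_flag=True) == "excluded"

    @pytest.mark.parametrize("maximum,expected", [(10, "untagged"), (11, "tagged")])
    def test_threshold_is_strictly_exceeds(self, maximum, expected):
        channel = np.zeros((4, 4), dtype=np.uint8)
        channel[0, 0] = maximum
        assert tag_nucleus(channel) == expected


class TestLogLikelihood:
    def test_x_zero_collapses_to_single_binomial_term(self):
        exp = TaggingExperiment(Nh=10, Ne=5, ch=7, ce=3, **PAPER_LIKE)
        expected = (
            math.log(math.comb(10, 7))
            + 7 * math.log(exp.qh)
            + 3 * math.log(exp.qe)
        )
        assert tagging_log_likelihood(0, exp) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("ch", [0, 1, 2])
    def test_two_nucleus_exhaustive_enumeration(self, ch):
        Nh = 2
        exp = TaggingExperiment(Nh=Nh, Ne=3, ch=ch, ce=Nh - ch, **PAPER_LIKE)
        for x in range(Nh + 1):
            oracle = brute_force_likelihood(
                x, Nh, ch, exp.ph, exp.pe, exp.qh, exp.qe
            )
            ours = math.exp(tagging_log_likelihood(x, exp))
            assert ours == pytest.approx(oracle, rel=1e-9)

    def test_indistinguishable_classifiers_flatten_the_likelihood(self):
        """With ph = qh the sum collapses (Vandermonde) and no x is more
        likely than another."""
        exp = TaggingExperiment(
            Nh=12, Ne=4, ch=8, ce=4, ph=0.6, pe=0.4, qh=0.6, qe=0.4
        )
        values = [tagging_log_likelihood(x, exp) for x in range(13)]
        assert max(values) - min(values) < 1e-9

    def test_out_of_range_x_rejected(self):
        exp = TaggingExperiment(Nh=5, Ne=2, ch=3, ce=2, **PAPER_LIKE)
        with pytest.raises(ValueError):
            tagging_log_likelihood(-1, exp)
        with pytest.raises(ValueError):
            tagging_log_likelihood(6, exp)

    @pytest.mark.parametrize("Nh,x", [(8, 3), (14, 7), (20, 0), (20, 20)])
    def test_likelihood_normalizes_over_all_outcomes(self, Nh, x):
        """Summing exp(log L) over every (ch, ce) split of Nh equals 1."""
        total = sum(
            math.exp(
                tagging_log_likelihood(
                    x,
                    TaggingExperiment(
                        Nh=Nh, Ne=1, ch=ch, ce=Nh - ch, **PAPER_LIKE
                    ),
                )
            )
            for ch in range(Nh + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_log_space_matches_direct_space(self):
        """Direct-space evaluation (explicit binomials and powers) agrees
        with the log-space path for moderate Nh."""
        Nh, ch = 30, 22
        exp = TaggingExperiment(Nh=Nh, Ne=9, ch=ch, ce=Nh - ch, **PAPER_LIKE)
        for x in (0, 5, 17, 30):
            direct = 0.0
            for ah in range(x + 1):
                if ch - ah < 0 or ch - ah > Nh - x or (Nh - ch) + ah - x < 0:
                    continue
                direct += (
                    math.comb(x, ah)
                    * math.comb(Nh - x, ch - ah)
                    * exp.ph**ah
                    * exp.pe ** (x - ah)
                    * exp.qh ** (ch - ah)
                    * exp.qe ** ((Nh - ch) + ah - x)
                )
            ours = math.exp(tagging_log_likelihood(x, exp))
            assert ours == pytest.approx(direct, rel=1e-9)


class TestEstimator:
    def test_printed_worked_example(self):
        """The printed experiment (337 untagged nuclei, 309/28 HSR/EC
        predictions, pure-line probabilities) has its likelihood maximum
        at 28 untagged true-EC nuclei."""
        exp = TaggingExperiment(
            Nh=765 - 428, Ne=428, ch=309, ce=28, **PAPER_LIKE
        )
        assert estimate_untagged_count(exp) == 28

    def test_flat_likelihood_ties_resolve_to_smallest_x(self):
        exp = TaggingExperiment(
            Nh=12, Ne=4, ch=8, ce=4, ph=0.6, pe=0.4, qh=0.6, qe=0.4
        )
        assert estimate_untagged_count(exp) == 0

    def test_role_swap_equivariance(self):
        """Swapping (p <-> q, ch <-> ce) maps the maximizer x to Nh - x."""
        exp = TaggingExperiment(Nh=40, Ne=10, ch=31, ce=9, **PAPER_LIKE)
        swapped = TaggingExperiment(
            Nh=40, Ne=10, ch=9, ce=31,
            ph=exp.qe, pe=exp.qh, qh=exp.pe, qe=exp.ph,
        )
        # swapping roles of HSR/EC everywhere mirrors the estimate
        assert estimate_untagged_count(swapped) == 40 - estimate_untagged_count(exp)

    def test_parameter_recovery_from_simulated_experiments(self):
        """Simulated 500-nucleus experiments with 15 untagged true-EC
        nuclei recover the count with small bias across seeds."""
        estimates = [
            estimate_untagged_count(
                simulate_tagging_experiment(
                    500, 250, 15, seed=seed, **PAPER_LIKE
                )[0]
            )
            for seed in range(30)
        ]
        assert abs(np.mean(estimates) - 15) < 3


class TestAccuracyAndFit:
    def test_printed_percentages(self):
        exp = TaggingExperiment(Nh=337, Ne=428, ch=309, ce=28, **PAPER_LIKE)
        untagged, accuracy = tagging_accuracy(28, exp)
        assert untagged == 6.14
        assert accuracy == 93.86

    def test_zero_untagged_means_perfect_tagging(self):
        exp = TaggingExperiment(Nh=10, Ne=5, ch=10, ce=0, **PAPER_LIKE)
        assert tagging_accuracy(0, exp) == (0.0, 100.0)

    def test_observed_equal_expected_gives_zero_statistic(self):
        exp = TaggingExperiment(Nh=20, Ne=10, ch=16, ce=4, **PAPER_LIKE)
        x_hat = estimate_untagged_count(exp)
        expected = expected_category_counts(x_hat, exp)
        # round expected to integers that still total Nh + Ne
        observed = {k: round(v) for k, v in expected.items()}
        drift = sum(observed.values()) - (exp.Nh + exp.Ne)
        observed["tagged_ec"] -= drift
        stat, df, p = tagging_fit_check(x_hat, exp, observed)
        assert df == 3
        assert stat < 0.2 and p > 0.97

    def test_observed_total_validated(self):
        exp = TaggingExperiment(Nh=10, Ne=5, ch=8, ce=2, **PAPER_LIKE)
        with pytest.raises(ValueError):
            tagging_fit_check(
                2, exp,
                {"tagged_hsr": 1, "tagged_ec": 1, "untagged_hsr": 1, "untagged_ec": 1},
            )

    def test_fit_pipeline_returns_consistent_report(self):
        exp, observed = simulate_tagging_experiment(500, 250, 15, seed=3, **PAPER_LIKE)
        fit = fit_tagging_experiment(exp, observed)
        assert 0 <= fit.x_hat <= exp.Nh
        assert fit.untagged_fraction == pytest.approx(
            100 * fit.x_hat / (exp.Ne + fit.x_hat), abs=0.005
        )
        assert fit.p_value is not None and 0 <= fit.p_value <= 1

    def test_fit_check_calibrated_conservative_under_the_model(self):
        """Experiments generated under the model never over-reject: because
        x is fitted from the same counts, the df=3 chi-square p-values are
        stochastically at least uniform, so the empirical rejection rate at
        any level stays at or below that level (up to Monte-Carlo error)."""
        p_values = []
        for seed in range(200):
            exp, observed = simulate_tagging_experiment(
                120, 60, 6, seed=seed, **PAPER_LIKE
            )
            fit = fit_tagging_experiment(exp, observed)
            p_values.append(fit.p_value)
        p_values = np.array(p_values)
        grid = np.linspace(0.01, 0.99, 99)
        ecdf = np.array([(p_values <= g).mean() for g in grid])
        assert np.max(ecdf - grid) < 0.05  # one-sided: no excess rejection
        assert (p_values <= 0.05).mean() <= 0.05
        # and the p-values are not degenerate at 1
        assert p_values.std() > 0.05


class TestExperimentValidation:
    def test_count_invariants_enforced(self):
        with pytest.raises(ValueError):
            TaggingExperiment(Nh=10, Ne=2, ch=5, ce=4, **PAPER_LIKE)
        with pytest.raises(ValueError):
            TaggingExperiment(Nh=4, Ne=2, ch=2, ce=2, ph=0.5, pe=0.4, qh=0.5, qe=0.5)

    def test_simulation_consistency_checks(self):
        with pytest.raises(ValueError):
            simulate_tagging_experiment(10, 12, 1, seed=0, **PAPER_LIKE)
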