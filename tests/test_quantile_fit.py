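"""Quantile binning and multinomial estimation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from antddm.model_space import SCHEMES, SharingScheme
from antddm.quantile_fit import (
    ConditionDataset,
    FitConfig,
    empirical_quantiles,
    ez_init,
    fit_participant,
    neg2_log_multinomial,
    observed_bin_counts,
    pearson_chi2,
)


class TestEmpiricalQuantiles:
    def test_type7_interpolation_hand_example(self):
        # RTs 0.1 .. 1.0: h = (n-1) p gives edges by linear interpolation
        rts = np.arange(1, 11) / 10.0
        edges = empirical_quantiles(rts)
        np.testing.assert_allclose(edges, [0.19, 0.37, 0.55, 0.73, 0.91],
                                   atol=1e-12)

    def test_identical_rts_yield_tied_edges(self):
        edges = empirical_quantiles(np.full(20, 0.5))
        assert np.all(edges == 0.5)

    def test_converges_to_analytic_quantiles(self):
        from scipy.optimize import brentq

        from antddm.ddm import (DDMParams, SimOptions, choice_probability,
                                first_passage_cdf, simulate_trials)

        p = DDMParams.symmetric(a=0.2, v=0.79, ter=0.3, eta=0.05)
        res = simulate_trials(p, SimOptions(n_trials=60_000, rng_seed=21))
        emp = empirical_quantiles(res.rt[res.boundary == 1])
        pu = choice_probability(p, "upper")
        ana = [brentq(lambda t: first_passage_cdf(p, t, "upper") / pu - q,
                      0.301, 5.0) for q in (0.1, 0.3, 0.5, 0.7, 0.9)]
        np.testing.assert_allclose(emp, ana, atol=0.004)


class TestObservedBinCounts:
    def test_quantile_construction_gives_canonical_counts(self):
        rng = np.random.default_rng(0)
        data = ConditionDataset("c", rng.uniform(0.3, 0.9, 100), [])
        s = observed_bin_counts(data)
        np.testing.assert_array_equal(s.correct_counts, [10, 20, 20, 20, 20, 10])
        np.testing.assert_array_equal(s.error_counts, [0])
        assert s.error_edges is None

    def test_both_sides_binned_when_enough_errors(self):
        rng = np.random.default_rng(1)
        data = ConditionDataset("c", rng.uniform(0.3, 0.9, 50),
                                rng.uniform(0.3, 0.9, 50))
        s = observed_bin_counts(data)
        assert s.correct_counts.sum() + s.error_counts.sum() == 100
        assert len(s.error_counts) == 6

    def test_counts_match_independent_tabulation(self):
        rng = np.random.default_rng(2)
        rts = rng.lognormal(-0.8, 0.3, 437)
        data = ConditionDataset("c", rts, [])
        s = observed_bin_counts(data)
        # brute-force tabulation by sorting and counting
        order = np.sort(rts)
        brute = []
        prev = 0.0
        for e in list(s.correct_edges) + [np.inf]:
            brute.append(int(np.sum((order > prev) & (order <= e))))
            prev = e
        np.testing.assert_array_equal(s.correct_counts, brute)

    def test_degenerate_edges_collapse_with_flag(self):
        data = ConditionDataset("c", np.full(40, 0.5), [])
        s = observed_bin_counts(data)
        assert s.degenerate
        assert s.correct_edges is None
        np.testing.assert_array_equal(s.correct_counts, [40])

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            observed_bin_counts(ConditionDataset("c", [], []))

    @given(st.integers(12, 300), st.integers(0, 300))
    def test_bin_count_conservation(self, nc, ne):
        rng = np.random.default_rng(nc * 1000 + ne)
        data = ConditionDataset("c", rng.uniform(0.2, 1.0, nc),
                                rng.uniform(0.2, 1.0, ne))
        s = observed_bin_counts(data)
        assert s.n_trials == nc + ne


class TestObjective:
    def test_hand_arithmetic_toy_case(self):
        counts = np.array([3.0, 7.0])
        probs = np.array([0.3, 0.7])
        expect = -2.0 * (3 * np.log(0.3) + 7 * np.log(0.7))
        assert neg2_log_multinomial(counts, probs) == pytest.approx(expect)

    def test_observed_proportions_minimize(self):
        counts = np.array([10.0, 30.0, 60.0])
        mle = counts / counts.sum()
        base = neg2_log_multinomial(counts, mle)
        rng = np.random.default_rng(3)
        for _ in range(50):
            q = rng.dirichlet([1, 1, 1])
            assert neg2_log_multinomial(counts, q) >= base - 1e-9

    def test_single_full_bin_is_zero(self):
        assert neg2_log_multinomial([25.0], [1.0]) == 0.0

    def test_structure_mismatch_rejected(self):
        with pytest.raises(ValueError):
            neg2_log_multinomial([1.0, 2.0], [0.5, 0.3, 0.2])

    def test_pearson_variant_zero_at_perfect_fit(self):
        counts = np.array([20.0, 80.0])
        assert pearson_chi2(counts, counts / 100.0) == pytest.approx(0.0)


@pytest.fixture(scope="module")
def simulated_condition():
    from antddm.ddm import DDMParams, SimOptions, simulate_trials

    p = DDMParams.symmetric(a=0.23, v=0.79, ter=0.3, eta=0.07)
    res = simulate_trials(p, SimOptions(n_trials=2000, rng_seed=77))
    ok = ~res.censored
    return p, ConditionDataset("only", res.rt[ok & (res.boundary == 1)],
                               res.rt[ok & (res.boundary == 0)])


class TestFitParticipant:

    def test_all_shared_scheme_gives_identical_estimates(self, simulated_condition):
        _, data = simulated_condition
        twin = ConditionDataset("twin", data.correct_rt.copy(),
                                data.error_rt.copy())
        scheme = SharingScheme("shared", frozenset(), "all shared")
        fit = fit_participant([data, twin], scheme,
                              FitConfig(n_restarts=2, maxiter=400))
        p1, p2 = fit.params["only"], fit.params["twin"]
        assert (p1.a, p1.v, p1.eta, p1.ter) == (p2.a, p2.v, p2.eta, p2.ter)

    def test_estimate_fits_no_worse_than_truth(self, simulated_condition):
        truth, data = simulated_condition
        from antddm.ddm import predicted_bin_probabilities

        cfg = FitConfig(fix_ter=truth.ter)
        fit = fit_participant([data], SCHEMES[0], cfg)
        s = observed_bin_counts(data)
        counts = np.concatenate([s.correct_counts, s.error_counts])
        pc, pe = predicted_bin_probabilities(
            truth, s.correct_edges, s.error_edges)
        at_truth = neg2_log_multinomial(counts, np.concatenate([pc, pe]))
        assert fit.objective <= at_truth + 1e-9

    def test_estimates_invariant_to_trial_order(self, simulated_condition):
        _, data = simulated_condition
        rng = np.random.default_rng(5)
        shuffled = ConditionDataset(
            "only", rng.permutation(data.correct_rt),
            rng.permutation(data.error_rt))
        cfg = FitConfig(n_restarts=1, maxiter=120)
        f1 = fit_participant([data], SCHEMES[0], cfg)
        f2 = fit_participant([shuffled], SCHEMES[0], cfg)
        assert f1.objective == f2.objective
        assert f1.params["only"].a == f2.params["only"].a

    def test_shared_variability_parameters_estimable(self, simulated_condition):
        _, data = simulated_condition
        cfg = FitConfig(n_restarts=1, maxiter=250, estimate_sz_st=True)
        fit = fit_participant([data], SCHEMES[0], cfg)
        p = fit.params["only"]
        assert 0.0 <= p.sz < 0.5 * p.a
        assert 0.0 <= p.st <= p.ter
        assert fit.n_free_parameters == 4 + 2  # a, v, eta, Ter + sz, st

    def test_fixing_ter_while_scheme_varies_it_is_an_error(self, simulated_condition):
        _, data = simulated_condition
        with pytest.raises(ValueError):
            fit_participant([data], SCHEMES[2], FitConfig(fix_ter=0.3))

    def test_recovers_generating_parameters(self, congruency_recovery):
        """Median estimates near truth: a, v within 10%, eta within 0.03."""
        med = congruency_recovery["median"]
        truth = congruency_recovery["truth"]
        for lab in truth:
            assert med[lab]["a"] == pytest.approx(truth[lab]["a"], rel=0.10)
            assert med[lab]["v"] == pytest.approx(truth[lab]["v"], rel=0.10)
            assert med[lab]["eta"] == pytest.approx(truth[lab]["eta"], abs=0.03)


class TestEzInit:
    def test_moment_heuristic_is_in_plausible_range(self):
        rng = np.random.default_rng(8)
        correct = rng.normal(0.5, 0.08, 1500).clip(0.2)
        error = rng.normal(0.55, 0.1, 90).clip(0.2)
        a, v, ter = ez_init(correct, error)
        assert 0.05 < a < 0.5
        assert v > 0
        assert ter < correct.mean()
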