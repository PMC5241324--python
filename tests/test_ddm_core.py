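"""Analytic first-passage machinery: closed forms, series oracles, simulator."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from antddm import _fpt
from antddm.ddm import (
    DDMParams,
    ParameterError,
    SimOptions,
    choice_probability,
    first_passage_cdf,
    first_passage_density,
    mean_decision_time,
    predicted_bin_probabilities,
    simulate_trials,
)


def closed_form_p_upper(v, a, z, s):
    """Independent closed form for the absorption probability."""
    if v == 0:
        return z / a
    return (1 - math.exp(-2 * v * z / s**2)) / (1 - math.exp(-2 * v * a / s**2))


class TestChoiceProbability:
    def test_zero_drift_symmetric_start_is_half(self):
        p = DDMParams(a=0.2, v=0.0, z=0.1, ter=0.3)
        assert choice_probability(p, "upper") == pytest.approx(0.5, abs=1e-12)
        assert choice_probability(p, "lower") == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("a,v,z,s", [
        (0.1, 0.1, 0.05, 0.1),   # the canonical 0.7311 case
        (0.2, 0.58, 0.1, 0.1),
        (0.28, -0.3, 0.2, 0.1),
        (2.0, 1.0, 0.5, 1.0),
    ])
    def test_matches_closed_form(self, a, v, z, s):
        p = DDMParams(a=a, v=v, z=z, ter=0.3, s=s)
        expect = closed_form_p_upper(v, a, z, s)
        assert choice_probability(p, "upper") == pytest.approx(expect, abs=1e-10)
        assert choice_probability(p, "upper") + choice_probability(p, "lower") \
            == pytest.approx(1.0, abs=1e-10)

    def test_start_near_upper_boundary_gives_certainty(self):
        p = DDMParams(a=0.2, v=-0.5, z=0.2 - 1e-9, ter=0.3)
        assert choice_probability(p, "upper") > 0.999999

    def test_invalid_params_raise(self):
        with pytest.raises(ParameterError):
            DDMParams(a=-0.1, v=0.3, z=0.05, ter=0.3)
        with pytest.raises(ParameterError):
            DDMParams(a=0.2, v=0.3, z=0.25, ter=0.3)
        with pytest.raises(ParameterError):
            DDMParams(a=0.2, v=0.3, z=0.1, ter=0.1, st=0.2)


class TestDensity:
    def test_zero_before_minimal_nondecision_time(self):
        p = DDMParams.symmetric(a=0.2, v=0.3, ter=0.3, st=0.05)
        for t in (0.0, 0.1, 0.2499):
            assert first_passage_density(p, t, "upper") == 0.0

    def test_small_and_large_series_are_mutual_oracles(self):
        # unit-diffusion kernels, region where both series converge well
        for (v, a, z) in [(2.0, 2.3, 1.15), (0.0, 2.0, 1.0), (-1.5, 2.7, 1.0)]:
            for t in np.linspace(0.05, 1.2, 25):
                small = _fpt._dens_small(t, v, a, z)
                large = _fpt._dens_large(t, v, a, z)
                assert small == pytest.approx(large, abs=1e-8)

    @pytest.mark.parametrize("eta", [0.0, 0.08])
    def test_density_integrates_to_choice_probability(self, eta):
        p = DDMParams.symmetric(a=0.2, v=0.3, ter=0.3, eta=eta)
        for b in ("upper", "lower"):
            total, _ = quad(lambda t: first_passage_density(p, t, b),
                            p.ter, 40.0, limit=300)
            assert total == pytest.approx(choice_probability(p, b), abs=1e-6)

    def test_nonnegative(self):
        p = DDMParams.symmetric(a=0.25, v=0.7, ter=0.3, eta=0.07)
        ts = np.linspace(0.0, 3.0, 200)
        assert np.all(first_passage_density(p, ts, "upper") >= 0.0)
        assert np.all(first_passage_density(p, ts, "lower") >= 0.0)


class TestCdf:
    def test_zero_at_t_zero(self):
        p = DDMParams.symmetric(a=0.2, v=0.4, ter=0.3)
        assert first_passage_cdf(p, 0.0, "upper") == 0.0

    def test_symmetric_zero_drift_limit_is_half(self):
        p = DDMParams.symmetric(a=0.2, v=0.0, ter=0.3)
        assert first_passage_cdf(p, 60.0, "upper") == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("eta,st", [(0.0, 0.0), (0.07, 0.0), (0.05, 0.04)])
    def test_consistent_with_density_quadrature(self, eta, st):
        p = DDMParams.symmetric(a=0.23, v=0.79, ter=0.3, eta=eta, st=st)
        for t in (0.35, 0.45, 0.6, 1.0):
            num, _ = quad(lambda u: first_passage_density(p, u, "upper"),
                          0.0, t, limit=300)
            assert first_passage_cdf(p, t, "upper") == pytest.approx(num, abs=1e-6)

    def test_nondecreasing_and_limits_to_choice_probability(self):
        p = DDMParams.symmetric(a=0.27, v=0.58, ter=0.3, eta=0.05)
        ts = np.linspace(0.0, 8.0, 300)
        F = first_passage_cdf(p, ts, "upper")
        assert np.all(np.diff(F) >= -1e-12)
        assert F[-1] == pytest.approx(choice_probability(p, "upper"), abs=1e-8)


class TestMeanDecisionTime:
    def test_zero_drift_closed_form(self):
        # E[T] = z (a - z) / s^2 = 1.0 s
        p = DDMParams.symmetric(a=0.2, v=0.0, ter=0.3)
        assert mean_decision_time(p) == pytest.approx(1.0, abs=1e-9)

    def test_vanishes_for_large_drift(self):
        p = DDMParams.symmetric(a=0.2, v=50.0, ter=0.3)
        assert mean_decision_time(p) < 0.005

    def test_matches_simulator(self):
        p = DDMParams.symmetric(a=0.24, v=0.68, ter=0.3, eta=0.07)
        res = simulate_trials(p, SimOptions(n_trials=60_000, rng_seed=5))
        dec = res.rt[~res.censored] - p.ter
        se = dec.std() / math.sqrt(len(dec))
        assert mean_decision_time(p) == pytest.approx(dec.mean(), abs=3 * se)


class TestBinProbabilities:
    def test_edges_at_model_quantiles_give_canonical_masses(self):
        from scipy.optimize import brentq

        p = DDMParams.symmetric(a=0.2, v=0.3, ter=0.3, eta=0.05)
        pu = choice_probability(p, "upper")
        edges = [brentq(lambda t: first_passage_cdf(p, t, "upper") / pu - q,
                        0.301, 20.0) for q in (0.1, 0.3, 0.5, 0.7, 0.9)]
        pc, pe = predicted_bin_probabilities(p, edges, None)
        expect = np.array([0.1, 0.2, 0.2, 0.2, 0.2, 0.1]) * pu
        np.testing.assert_allclose(pc, expect, atol=1e-9)
        assert pe[0] == pytest.approx(1.0 - pu, abs=1e-9)

    def test_masses_are_cdf_differences_and_sum_to_one(self):
        p = DDMParams.symmetric(a=0.27, v=0.58, ter=0.3, eta=0.05)
        ce = [0.4, 0.5, 0.6, 0.7, 0.9]
        ee = [0.45, 0.55, 0.65, 0.8, 1.1]
        pc, pe = predicted_bin_probabilities(p, ce, ee)
        assert pc.sum() + pe.sum() == pytest.approx(1.0, abs=1e-8)
        Fc = first_passage_cdf(p, np.array(ce), "upper")
        assert pc[0] == pytest.approx(Fc[0], abs=1e-8)
        assert pc[2] == pytest.approx(Fc[2] - Fc[1], abs=1e-8)
        Fe = first_passage_cdf(p, np.array(ee), "lower")
        assert pe[3] == pytest.approx(Fe[3] - Fe[2], abs=1e-8)

    def test_degenerate_error_side_collapses_to_choice_probability(self):
        p = DDMParams.symmetric(a=0.23, v=0.79, ter=0.3)
        pc, pe = predicted_bin_probabilities(p, [0.4, 0.45, 0.5, 0.55, 0.65])
        assert len(pe) == 1
        assert pc.sum() == pytest.approx(choice_probability(p, "upper"), abs=1e-8)

    def test_non_monotone_edges_rejected(self):
        p = DDMParams.symmetric(a=0.2, v=0.3, ter=0.3)
        with pytest.raises(ValueError):
            predicted_bin_probabilities(p, [0.5, 0.4, 0.6, 0.7, 0.8])


class TestSimulator:
    def test_deterministic_under_seed(self):
        p = DDMParams.symmetric(a=0.2, v=0.5, ter=0.3)
        opts = SimOptions(n_trials=500, rng_seed=11)
        r1 = simulate_trials(p, opts)
        r2 = simulate_trials(p, opts)
        np.testing.assert_array_equal(r1.rt, r2.rt)
        np.testing.assert_array_equal(r1.boundary, r2.boundary)

    def test_upper_fraction_matches_choice_probability(self):
        p = DDMParams.symmetric(a=0.16, v=0.25, ter=0.3, eta=0.1)
        # long horizon: the analytic probability is uncensored
        res = simulate_trials(p, SimOptions(n_trials=100_000, rng_seed=3,
                                            max_time=60.0))
        pu = choice_probability(p, "upper")
        frac = (res.boundary == 1).mean()
        se = math.sqrt(pu * (1 - pu) / len(res.rt))
        assert frac == pytest.approx(pu, abs=3 * se)

    def test_coarse_dt_warns(self):
        p = DDMParams.symmetric(a=0.2, v=0.5, ter=0.3)
        with pytest.warns(UserWarning):
            simulate_trials(p, SimOptions(n_trials=10, rng_seed=0, dt=0.05))

    def test_censoring_flags_trials_beyond_horizon(self):
        p = DDMParams.symmetric(a=0.3, v=0.01, ter=0.3)  # slow decisions
        res = simulate_trials(p, SimOptions(n_trials=300, rng_seed=9,
                                            max_time=0.6))
        assert res.censored.any()
        assert np.all(res.rt[res.censored] == 0.6)
        assert np.all(res.boundary[res.censored] == -1)


class TestInvariants:
    @given(st.floats(0.12, 0.4), st.floats(-1.0, 1.0), st.floats(0.3, 0.7),
           st.floats(0.05, 1.5))
    def test_reflection_symmetry(self, a, v, zfrac, t):
        """Swapping v -> -v and z -> a - z exchanges the boundary roles."""
        z = zfrac * a
        p1 = DDMParams(a=a, v=v, z=z, ter=0.0)
        p2 = DDMParams(a=a, v=-v, z=a - z, ter=0.0)
        assert first_passage_density(p1, t, "upper") == pytest.approx(
            first_passage_density(p2, t, "lower"), rel=1e-9, abs=1e-12)
        assert choice_probability(p1, "upper") == pytest.approx(
            choice_probability(p2, "lower"), abs=1e-12)

    @given(st.floats(0.5, 20.0), st.floats(0.05, 1.0))
    def test_scaling_invariance(self, c, t):
        """Common rescaling of a, z, v, eta, s leaves predictions unchanged."""
        p1 = DDMParams.symmetric(a=0.24, v=0.6, ter=0.3, eta=0.07, s=0.1)
        p2 = DDMParams.symmetric(a=0.24 * c, v=0.6 * c, ter=0.3,
                                 eta=0.07 * c, s=0.1 * c)
        assert choice_probability(p1, "upper") == pytest.approx(
            choice_probability(p2, "upper"), abs=1e-10)
        assert first_passage_density(p1, 0.3 + t, "upper") == pytest.approx(
            first_passage_density(p2, 0.3 + t, "upper"), rel=1e-8, abs=1e-12)

    def test_mean_decision_time_increases_with_threshold(self):
        times = [mean_decision_time(DDMParams.symmetric(a=a, v=0.5, ter=0.3))
                 for a in np.linspace(0.12, 0.4, 8)]
        assert np.all(np.diff(times) > 0)

    def test_accuracy_increases_with_drift(self):
        ps = [choice_probability(DDMParams.symmetric(a=0.2, v=v, ter=0.3), "upper")
              for v in np.linspace(0.0, 1.5, 10)]
        assert np.all(np.diff(ps) > 0)

    def test_defective_densities_sum_to_unit_mass(self):
        p = DDMParams.symmetric(a=0.2, v=0.4, ter=0.3, eta=0.06)
        total = sum(quad(lambda t: first_passage_density(p, t, b),
                         p.ter, 40.0, limit=300)[0] for b in ("upper", "lower"))
        assert total == pytest.approx(1.0, abs=1e-6)
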