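"""The HOT comparative risk assessment: moments, mixtures, quantiles, PAF."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hot_equity.cra import (
    BaselinePA,
    ExposureResponse,
    LinearMoments,
    WeeklyMixture,
    compute_paf,
    deaths_equivalent,
    default_baseline_pa,
    default_exposure_response,
    evenly_spaced_quantiles,
    exposure_response_eval,
    lognormal_linear_moments,
    overall_travel_activity,
    round_half_up,
    run_cra,
    sample_travel_activity,
    shift_baseline,
    weekly_scale,
)
from hot_equity.models import SubgroupParams

TOY_ER = ExposureResponse(knots=((0.0, 1.0), (7.5, 0.8)))


def make_params(pi=0.65, mu=0.3, sigma0=0.8, f=0.3):
    return SubgroupParams(
        participation_pi=pi,
        prevalence_p=pi * f,
        mu_log_daily=mu,
        sigma0=sigma0,
        frequency_f=f,
    )


class TestLinearMoments:
    @pytest.mark.parametrize(
        "mu,sigma,mean,sd",
        [
            (0.0, 0.0, 1.0, 0.0),
            (1.0, 0.0, np.e, 0.0),
            (0.0, 1.0, 1.6487212707, 2.1611974159),
        ],
    )
    def test_closed_form(self, mu, sigma, mean, sd):
        m = lognormal_linear_moments(mu, sigma)
        assert m.mean_daily == pytest.approx(mean, abs=1e-9)
        assert m.sd_daily == pytest.approx(sd, abs=1e-9)

    def test_against_monte_carlo(self, rng):
        n = 2_000_000
        draws = rng.lognormal(0.0, 1.0, n)
        m = lognormal_linear_moments(0.0, 1.0)
        se_mean = draws.std() / np.sqrt(n)
        assert abs(draws.mean() - m.mean_daily) < 4 * se_mean
        assert abs(draws.std(ddof=1) - m.sd_daily) < 0.02

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            lognormal_linear_moments(0.0, -0.1)


class TestWeeklyScale:
    def test_seven_f_scaling(self):
        m = lognormal_linear_moments(0.0, 0.0)  # mean 1, sd 0
        mix = weekly_scale(m, 0.302, 0.65)
        assert mix.mean_weekly == pytest.approx(7 * 0.302)
        assert mix.sd_weekly == 0.0

    def test_zero_frequency_gives_zero_mixture(self):
        m = lognormal_linear_moments(0.5, 0.4)
        mix = weekly_scale(m, 0.0, 0.65)
        assert mix.mean_weekly == 0.0 and mix.sd_weekly == 0.0

    def test_round_trip_through_printed_reference_intensity(self):
        """A daily mean solved from weekly intensity 3.96 at f = 0.22
        scales back to 3.96 through the weekly transform."""
        f, weekly = 0.22, 3.96
        daily_mean = weekly / (7 * f)
        mix = weekly_scale(LinearMoments(daily_mean, 0.0), f, 0.65)
        assert mix.mean_weekly == pytest.approx(weekly, abs=1e-12)


class TestSampling:
    def test_zero_participation_all_zero(self):
        mix = WeeklyMixture(0.0, 3.0, 1.0)
        assert not sample_travel_activity(mix, 1000, 1).any()

    def test_point_mass_when_sd_zero(self):
        mix = WeeklyMixture(1.0, 4.0, 0.0)
        draws = sample_travel_activity(mix, 1000, 1)
        assert (draws == 4.0).all()

    def test_impossible_moment_match_rejected(self):
        with pytest.raises(ValueError, match="moment"):
            sample_travel_activity(WeeklyMixture(0.5, 0.0, 1.0), 10, 0)

    def test_mixture_moment_conservation(self):
        """Sample mean equals pi * mean_weekly within 4 MC standard errors
        at one million draws."""
        mix = WeeklyMixture(0.65, 3.96, 4.0)
        draws = sample_travel_activity(mix, 1_000_000, 123)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.65 * 3.96) < 4 * se
        active = draws[draws > 0]
        se_active = active.std(ddof=1) / np.sqrt(len(active))
        assert abs(active.mean() - 3.96) < 4 * se_active

    def test_reproducible_under_seed(self):
        mix = WeeklyMixture(0.65, 3.96, 4.0)
        a = sample_travel_activity(mix, 10_000, 7)
        b = sample_travel_activity(mix, 10_000, 7)
        np.testing.assert_array_equal(a, b)


class TestShiftAndQuantiles:
    def test_identity_when_groups_equal(self):
        pa0 = np.array([1.0, 2.0, 3.0])
        ta = np.array([0.5, 0.0, 2.0])
        np.testing.assert_array_equal(shift_baseline(pa0, ta, ta), pa0)

    def test_clamp_rule(self):
        out = shift_baseline([1.0, 1.0], [0.0, 3.0], [5.0, 1.0])
        np.testing.assert_array_equal(out, [0.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            shift_baseline([1.0], [1.0, 2.0], [0.0, 0.0])

    @given(seed=st.integers(0, 2**16))
    def test_clamp_never_reduces_mean(self, seed):
        rng = np.random.default_rng(seed)
        pa0 = rng.uniform(0, 5, 200)
        ta_s = rng.uniform(0, 5, 200)
        ta_r = rng.uniform(0, 5, 200)
        out = shift_baseline(pa0, ta_s, ta_r)
        delta = ta_s - ta_r
        clamped = (pa0 + delta) < 0
        if clamped.any():
            assert out.mean() > pa0.mean() + delta.mean() - 1e-12
        else:
            assert out.mean() == pytest.approx(pa0.mean() + delta.mean())

    def test_quantiles_of_constant_vector(self):
        q = evenly_spaced_quantiles(np.full(50, 2.5), 10)
        np.testing.assert_array_equal(q, np.full(10, 2.5))

    def test_quantiles_identity_on_own_grid(self):
        values = np.arange(1, 10_001, dtype=float)
        q = evenly_spaced_quantiles(values, 10_000)
        np.testing.assert_allclose(q, values)

    def test_quantiles_glivenko_cantelli(self, rng):
        u = rng.random(1_000_000)
        q = evenly_spaced_quantiles(u, 100)
        probs = (np.arange(1, 101) - 0.5) / 100
        assert np.max(np.abs(q - probs)) < 0.005

    def test_quantiles_monotone(self, rng):
        q = evenly_spaced_quantiles(rng.normal(size=5000), 97)
        assert (np.diff(q) >= 0).all()


class TestExposureResponse:
    def test_interpolation_and_extrapolation(self):
        assert exposure_response_eval(TOY_ER, 0.0) == 1.0
        assert exposure_response_eval(TOY_ER, 3.75) == pytest.approx(0.9)
        assert exposure_response_eval(TOY_ER, 100.0) == pytest.approx(0.8)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            ExposureResponse(knots=((0.0, 1.0), (5.0, 1.2)))  # increasing risk
        with pytest.raises(ValueError):
            ExposureResponse(knots=((1.0, 1.0), (5.0, 0.9)))  # not starting at 0
        with pytest.raises(ValueError):
            ExposureResponse(knots=((0.0, 0.9), (5.0, 0.8)))  # RR(0) != 1

    def test_packaged_default_curve_is_valid(self):
        er = default_exposure_response()
        assert er.knots[0] == (0.0, 1.0)
        rs = [r for _, r in er.knots]
        assert all(b <= a for a, b in zip(rs, rs[1:]))


class TestPaf:
    def test_identical_quantiles_give_zero(self):
        q = np.linspace(0, 10, 100)
        assert compute_paf(q, q, TOY_ER) == 0.0

    def test_constant_curve_gives_zero(self):
        er = ExposureResponse(knots=((0.0, 1.0), (10.0, 1.0)))
        assert compute_paf([0.0, 5.0], [3.0, 9.0], er) == pytest.approx(0.0)

    def test_hand_computed_two_point_example(self):
        er = ExposureResponse(knots=((0.0, 1.0), (10.0, 0.8)))
        paf = compute_paf([10.0, 10.0], [0.0, 10.0], er)
        assert paf == pytest.approx((0.8 + 0.8) / (1.0 + 0.8) - 1, abs=1e-12)
        assert paf == pytest.approx(-0.111111, abs=1e-6)


class TestScalars:
    def test_overall_travel_activity_product(self):
        assert overall_travel_activity(0.0, 5.0) == 0.0
        assert round_half_up(overall_travel_activity(0.650, 3.963)) == 2.58

    def test_deaths_equivalent(self):
        assert deaths_equivalent(0.0, 100000) == 0
        assert deaths_equivalent(0.01, 274313) == 2743

    def test_negative_deaths_rejected(self):
        with pytest.raises(ValueError):
            deaths_equivalent(0.01, -5)


class TestRunCra:
    def test_subgroup_equal_reference_paf_exactly_zero(self):
        p = make_params()
        res = run_cra(p, make_params(), TOY_ER, default_baseline_pa(), 50_000, 500, seed=5)
        assert res.paf == 0.0
        assert res.delta_ta_pct == 0.0

    def test_more_active_subgroup_reduces_mortality(self):
        ref = make_params(pi=0.6, mu=0.2)
        sub = make_params(pi=0.8, mu=0.8)
        res = run_cra(sub, ref, TOY_ER, default_baseline_pa(), 100_000, 1000, seed=5)
        assert res.paf < 0
        assert res.delta_ta_pct > 0

    def test_seed_stability_bit_identical(self):
        ref = make_params()
        sub = make_params(pi=0.62, mu=0.1)
        kwargs = dict(n_sim=50_000, m=500, seed=11)
        a = run_cra(sub, ref, TOY_ER, default_baseline_pa(), **kwargs)
        b = run_cra(sub, ref, TOY_ER, default_baseline_pa(), **kwargs)
        assert a == b

    def test_monotone_in_subgroup_activity(self):
        """PAF never increases as subgroup participation or log-intensity
        increases (non-increasing exposure-response curve)."""
        ref = make_params()
        baseline = default_baseline_pa()
        er = default_exposure_response()
        pafs_pi = [
            run_cra(make_params(pi=pi), ref, er, baseline, 200_000, 2000, seed=3).paf
            for pi in (0.35, 0.55, 0.75, 0.95)
        ]
        assert all(b <= a for a, b in zip(pafs_pi, pafs_pi[1:]))
        pafs_mu = [
            run_cra(make_params(mu=mu), ref, er, baseline, 200_000, 2000, seed=3).paf
            for mu in (-0.6, 0.0, 0.6, 1.2)
        ]
        assert all(b <= a for a, b in zip(pafs_mu, pafs_mu[1:]))

    def test_closed_form_limit_sigma_zero(self):
        """With sigma0 = 0, participation ~ 1 and a point-mass baseline, the
        simulated PAF equals R(pa + delta)/R(pa) - 1 exactly."""
        pi = 1.0 - 1e-12
        ref = make_params(pi=pi, mu=0.0, sigma0=0.0, f=0.2)
        sub = make_params(pi=pi, mu=0.5, sigma0=0.0, f=0.2)
        pa = 4.0
        baseline = BaselinePA.point_mass(pa)
        res = run_cra(sub, ref, TOY_ER, baseline, 10_000, 100, seed=2)
        delta = 7 * 0.2 * (np.exp(0.5) - np.exp(0.0))
        expected = exposure_response_eval(TOY_ER, pa + delta) / exposure_response_eval(
            TOY_ER, pa
        ) - 1
        assert res.paf == pytest.approx(expected, abs=1e-9)

    def test_common_random_numbers_reduce_variance(self):
        ref = make_params()
        sub = make_params(pi=0.62, mu=0.1)
        baseline = default_baseline_pa()
        crn = [
            run_cra(sub, ref, TOY_ER, baseline, 50_000, 500, seed=s,
                    common_random_numbers=True).paf
            for s in range(8)
        ]
        indep = [
            run_cra(sub, ref, TOY_ER, baseline, 50_000, 500, seed=s).paf
            for s in range(8)
        ]
        assert np.std(crn) <= np.std(indep) * 1.5  # loose sanity bound

    def test_paf_dispersion_across_seeds_small(self):
        """At one million draws the PAF varies by less than 0.002 across
        seeds for parameters on the scale of the study's subgroup table."""
        ref = make_params(pi=0.65, mu=0.033, sigma0=0.8, f=0.264)
        sub = make_params(pi=0.59, mu=0.033 - 0.4, sigma0=0.8, f=0.20)
        baseline = default_baseline_pa()
        er = default_exposure_response()
        pafs = [
            run_cra(sub, ref, er, baseline, 1_000_000, 10_000, seed=s).paf
            for s in range(20)
        ]
        assert np.std(pafs) < 0.002
        assert np.mean(pafs) > 0  # less active subgroup raises mortality
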