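"""Log-normal fitting, interval inversion, resampling comparison and
extrapolation tests, with analytic and sampling oracles, plus hypothesis
property checks of the summary identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tetrec import (FitSummary, LogNormalFit, compare_fits,
                    extrapolate_profile, fit_co_fraction_regression,
                    fit_extrapolation, fit_lognormal, lognormal_from_interval)
from tetrec import tables


class TestFitLognormal:
    def test_constant_lengths(self):
        fit = fit_lognormal([1000.0] * 10)
        assert fit.mu == pytest.approx(math.log(1000))
        assert fit.sigma == 0.0
        assert fit.ks_pvalue == 1.0

    def test_two_scales_log_symmetry(self):
        # {e, e^3}: mu = 2 and sigma = 1 under the MLE (population) convention
        fit = fit_lognormal([math.e, math.e**3])
        assert fit.mu == pytest.approx(2.0)
        assert fit.sigma == pytest.approx(1.0)
        with pytest.raises(ValueError):
            fit_lognormal([math.e])

    def test_log_symmetric_sample(self):
        fit = fit_lognormal([math.e, math.e**2, math.e**3])
        assert fit.mu == pytest.approx(2.0)
        assert fit.sigma == pytest.approx(np.std([1, 2, 3]))  # MLE convention

    def test_parameter_recovery_from_samples(self):
        rng = np.random.default_rng(21)
        x = rng.lognormal(7.55, 0.75, size=5000)
        fit = fit_lognormal(x)
        assert abs(fit.mu - 7.55) <= 3 * fit.sd_mean
        assert abs(fit.sigma - 0.75) / 0.75 <= 0.05
        assert fit.ks_pvalue > 0.05

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal([100.0, 0.5, 2000.0])


class TestIntervalInversion:
    @pytest.mark.parametrize("lower,upper,central", [
        (435, 8350, 1906),       # wild-type CO summary
        (334, 14775, 2222),      # low-activity CO summary
        (228, 10068, 1515),      # high-activity NCO summary
        (382, 7124, 1650),       # wild-type NCO summary (printed 1649)
    ])
    def test_printed_intervals_invert_to_central_lengths(self, lower, upper,
                                                         central):
        fit = lognormal_from_interval(lower, upper)
        assert round(fit.summary().central_length) == pytest.approx(central,
                                                                    abs=1)

    def test_degenerate_interval(self):
        fit = lognormal_from_interval(1000, 1000.0001)
        assert fit.sigma == pytest.approx(0.0, abs=1e-6)
        assert fit.summary().central_length == pytest.approx(1000, rel=1e-6)

    @pytest.mark.parametrize("lo,hi", [(100, 100), (200, 100), (0, 10), (-5, 5)])
    def test_invalid_bounds_rejected(self, lo, hi):
        with pytest.raises(ValueError):
            lognormal_from_interval(lo, hi)

    @given(mu=st.floats(2.0, 12.0), sigma=st.floats(0.01, 2.0))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip_interval_to_parameters(self, mu, sigma):
        fit = LogNormalFit(mu=mu, sigma=sigma)
        lo, hi = fit.summary().interval_95
        back = lognormal_from_interval(lo, hi)
        assert back.mu == pytest.approx(mu, rel=1e-6)
        assert back.sigma == pytest.approx(sigma, rel=1e-6)

    @given(mu=st.floats(2.0, 12.0), sigma=st.floats(0.0, 2.0))
    @settings(max_examples=50, derandomize=True)
    def test_central_length_is_geometric_mean_of_interval(self, mu, sigma):
        s = LogNormalFit(mu=mu, sigma=sigma).summary()
        lo, hi = s.interval_95
        assert s.central_length == pytest.approx(math.sqrt(lo * hi), rel=1e-9)

    def test_summary_must_bracket_central(self):
        with pytest.raises(ValueError):
            FitSummary(central_length=10.0, interval_95=(20.0, 30.0))


class TestCompareFits:
    def test_identical_fits_give_p_near_one(self):
        fit = LogNormalFit(mu=7.5, sigma=0.7, sd_mean=0.05, n=200)
        assert compare_fits(fit, fit, seed=1) > 0.9

    def test_widely_separated_fits(self):
        a = LogNormalFit(mu=7.5, sigma=0.7, sd_mean=0.05, n=200)
        b = LogNormalFit(mu=8.0, sigma=0.7, sd_mean=0.05, n=200)  # 10 sd apart
        assert compare_fits(a, b, seed=1) < 0.001

    @pytest.mark.parametrize("delta", [0.0, 0.05, 0.1, 0.2])
    def test_matches_analytic_normal_difference(self, delta):
        a = LogNormalFit(mu=7.5, sigma=0.7, sd_mean=0.06, n=150)
        b = LogNormalFit(mu=7.5 + delta, sigma=0.7, sd_mean=0.08, n=100)
        p = compare_fits(a, b, n_resamples=200_000, seed=3)
        z = delta / math.hypot(a.sd_mean, b.sd_mean)
        analytic = 2 * stats.norm.sf(z)
        assert p == pytest.approx(analytic, abs=0.02)

    def test_requires_sd_mean(self):
        a = LogNormalFit(mu=7.5, sigma=0.7)
        with pytest.raises(ValueError):
            compare_fits(a, a)

    def test_few_resamples_warn(self):
        fit = LogNormalFit(mu=7.5, sigma=0.7, sd_mean=0.05, n=200)
        with pytest.warns(UserWarning):
            compare_fits(fit, fit, n_resamples=100, seed=1)

    def test_hypomorph_mean_shifts_against_wild_type(self, tetrad_batch):
        # significance machinery on simulated data: two disjoint halves of
        # the same generative process should NOT differ
        from tetrec import fit_lognormal
        lengths = [t.length for _, truth in tetrad_batch
                   for e in truth.nco_events() if e.subtypes == {"simple"}
                   for t in e.tracts]
        half = len(lengths) // 2
        a = fit_lognormal(lengths[:half])
        b = fit_lognormal(lengths[half:])
        assert compare_fits(a, b, seed=5) > 0.05


class TestCoFractionRegression:
    def test_printed_tallies_predict_low_activity_ncos(self):
        model = fit_co_fraction_regression(tables.EVENT_TALLIES.values())
        assert round(model.predict_nco(10), 1) == 1.2
        assert round(model.predict_nco(3), 1) == 0.3

    def test_two_collinear_points_interpolate_exactly(self):
        model = fit_co_fraction_regression([(80, 20), (40, 10)])
        # both tetrads have CO fraction 0.8: flat line
        assert model.predict_fraction(60) == pytest.approx(0.8)
        assert model.predict_nco(60) == pytest.approx(15.0)

    def test_degenerate_co_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_co_fraction_regression([(50, 10), (50, 20)])

    def test_accepts_event_tally_objects(self):
        tallies = [tables.EVENT_TALLIES[k] for k in tables.EVENT_TALLIES]
        pairs = [(t.co_total, t.nco_total) for t in tallies]
        a = fit_co_fraction_regression(tallies)
        b = fit_co_fraction_regression(pairs)
        assert a == b


class TestExtrapolation:
    def test_linear_family_recovers_exact_line(self):
        # anchors on mean = 100 + 20 * co, sigma = 0.5 + 0.001 * co
        anchors = [(co, LogNormalFit(mu=math.log(100 + 20 * co),
                                     sigma=0.5 + 0.001 * co))
                   for co in (90, 60, 30)]
        model = fit_extrapolation(anchors, family="linear")
        fit = model.predict_fit(10)
        assert math.exp(fit.mu) == pytest.approx(300.0, rel=1e-9)
        assert fit.sigma == pytest.approx(0.51, rel=1e-9)

    def test_anchor_activity_returns_anchor_fit(self):
        anchors = [(co, LogNormalFit(mu=math.log(1000 + 5 * co), sigma=0.7))
                   for co in (92, 60, 30)]
        model = fit_extrapolation(anchors, family="linear")
        fit = model.predict_fit(60)
        assert math.exp(fit.mu) == pytest.approx(1300.0, rel=1e-9)

    def test_inverse_family_reproduces_printed_low_activity_mean(self):
        model = fit_extrapolation(tables.anchor_points("CO"), family="inverse")
        central = math.exp(model.predict_fit(10).mu)
        assert central == pytest.approx(5497, rel=0.05)

    def test_inverse_family_monotone_as_activity_falls(self):
        model = fit_extrapolation(tables.anchor_points("CO"), family="inverse")
        centrals = [math.exp(model.predict_fit(co).mu)
                    for co in (92, 54, 30, 10, 3)]
        assert centrals == sorted(centrals)

    def test_full_profile_with_event_mix(self):
        co_model = fit_co_fraction_regression(tables.EVENT_TALLIES.values())
        prof = extrapolate_profile(tables.anchor_points("CO"),
                                   tables.anchor_points("NCO"),
                                   target_co=10, family="inverse",
                                   co_fraction_model=co_model)
        assert round(prof.expected_nco, 1) == 1.2
        # NCO tracts shrink, CO tracts grow at low activity
        assert math.exp(prof.nco_fit.mu) < 1649
        assert math.exp(prof.co_fit.mu) > 2222

    @pytest.mark.parametrize("family", ["log", "inverse"])
    def test_nonpositive_target_rejected(self, family):
        with pytest.raises(ValueError):
            fit_extrapolation(tables.anchor_points("CO"),
                              family=family).predict_fit(0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            fit_extrapolation(tables.anchor_points("CO"), family="cubic")
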