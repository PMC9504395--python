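import datetime as dt
from fractions import Fraction

import numpy as np
import pytest

from opinionpulse.bayes import (
    DirichletNetSentiment,
    DirichletParams,
    PolarityCounts,
    build_prior,
    daily_pss_series,
    polarity_proportions,
    posterior,
    pss_credible_interval,
    pss_point,
    weekly_average,
)

D = dt.date(2020, 10, 1)


def pc(n_pos, n_neu, n_neg, day=D, stratum="US"):
    return PolarityCounts(day, stratum, n_pos, n_neu, n_neg)


class TestProportionsAndPoint:
    @pytest.mark.parametrize("counts,theta", [
        ((5, 3, 2), (0.5, 0.3, 0.2)),
        ((10, 0, 0), (1.0, 0.0, 0.0)),
        ((1, 1, 1), (1 / 3, 1 / 3, 1 / 3)),
    ])
    def test_proportions(self, counts, theta):
        np.testing.assert_allclose(polarity_proportions(pc(*counts)), theta)

    def test_zero_total_undefined(self):
        with pytest.raises(ValueError, match="N=0"):
            polarity_proportions(pc(0, 0, 0))

    @pytest.mark.parametrize("theta,expected", [
        ((0.5, 0.3, 0.2), 0.3),
        ((1 / 3, 1 / 3, 1 / 3), 0.0),
        ((0.0, 0.0, 1.0), -1.0),
    ])
    def test_pss_point(self, theta, expected):
        assert pss_point(theta) == pytest.approx(expected, abs=1e-15)

    def test_exact_on_all_small_count_triples(self):
        # rational-arithmetic oracle over every triple with N <= 30
        for N in range(1, 31):
            for a in range(N + 1):
                for b in range(N + 1 - a):
                    c = N - a - b
                    theta = polarity_proportions(pc(a, b, c))
                    exact = [Fraction(a, N), Fraction(b, N), Fraction(c, N)]
                    np.testing.assert_allclose(
                        theta, [float(x) for x in exact], rtol=1e-15)
                    assert pss_point(theta) == pytest.approx(
                        float(Fraction(a - c, N)), abs=1e-15)


class TestPrior:
    def test_empty_history_is_balanced(self):
        prior = build_prior([])
        np.testing.assert_allclose(prior.vector(), [1.0, 1.0, 1.0])

    def test_informative_prior_arithmetic(self):
        history = [pc(50, 11, 4), pc(20, 10, 5, D + dt.timedelta(1))]
        prior = build_prior(history, prior_weight=1 / 7, base=1.0)
        np.testing.assert_allclose(prior.vector(), [11.0, 4.0, 16 / 7])

    def test_zero_weight_annihilates_history(self):
        prior = build_prior([pc(100, 100, 100)], prior_weight=0.0, base=2.0)
        np.testing.assert_allclose(prior.vector(), [2.0, 2.0, 2.0])

    def test_conjugate_update(self):
        post = posterior(DirichletParams(1, 1, 1), pc(5, 3, 2))
        np.testing.assert_allclose(post.vector(), [6.0, 4.0, 3.0])
        np.testing.assert_allclose(
            posterior(DirichletParams(1, 1, 1), pc(0, 0, 0)).vector(),
            [1.0, 1.0, 1.0])

    def test_posterior_mean(self):
        assert DirichletParams(6, 4, 3).mean()[0] == pytest.approx(6 / 13)


class TestCredibleInterval:
    def test_symmetric_posterior_centred_on_zero(self):
        est = pss_credible_interval(DirichletParams(5, 5, 5), seed=0)
        assert est.pss_point == 0.0
        mc_tol = 3 / np.sqrt(est.n_mc)
        assert abs(est.ci_low + est.ci_high) < 3 * mc_tol
        assert est.ci_low < 0 < est.ci_high

    def test_concentrated_posterior(self):
        est = pss_credible_interval(DirichletParams(1001, 1, 1), seed=0)
        assert est.pss_point == pytest.approx(1000 / 1003)
        assert est.ci_low > 0.98

    def test_width_shrinks_with_evidence(self):
        # matched mean proportions, 100x the pseudo-counts: the interval
        # must be strictly narrower (volume reduces uncertainty)
        wide = pss_credible_interval(DirichletParams(15, 9, 6), seed=1)
        narrow = pss_credible_interval(DirichletParams(1500, 900, 600), seed=1)
        assert (narrow.ci_high - narrow.ci_low) < (wide.ci_high - wide.ci_low)

    def test_bounds_and_reproducibility(self):
        a = pss_credible_interval(DirichletParams(3, 2, 4), seed=42)
        b = pss_credible_interval(DirichletParams(3, 2, 4), seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert -1 <= a.ci_low <= a.ci_high <= 1
        assert -1 <= a.pss_point <= 1

    def test_rejects_tiny_mc(self):
        with pytest.raises(ValueError, match="n_mc"):
            pss_credible_interval(DirichletParams(1, 1, 1), n_mc=10)


class TestDailySeries:
    def test_single_day_composes_prior_and_update(self):
        est, = daily_pss_series([pc(5, 3, 2)], seed=0)
        assert est.pss_point == pytest.approx(3 / 13)
        assert not est.prior_only

    def test_stationary_counts_converge(self):
        days = [pc(50, 30, 20, D + dt.timedelta(i)) for i in range(30)]
        series = daily_pss_series(days, seed=0)
        points = [e.pss_point for e in series]
        # once the trailing window is saturated the point estimate is
        # constant: prior (1 + 100/7-weighted week) + day's counts
        assert len(set(points[-10:])) == 1
        assert points[-1] == pytest.approx(0.3, abs=0.01)

    def test_all_empty_days_are_prior_only(self):
        days = [pc(0, 0, 0, D + dt.timedelta(i)) for i in range(5)]
        series = daily_pss_series(days, seed=0)
        assert all(e.prior_only for e in series)
        assert all(e.pss_point == 0.0 for e in series)

    def test_large_sample_agreement_with_empirical_pss(self):
        est, = daily_pss_series([pc(50_000, 30_000, 20_000)], seed=0)
        empirical = pss_point(polarity_proportions(pc(50_000, 30_000, 20_000)))
        assert abs(est.pss_point - empirical) < 1e-3

    def test_prior_influence_decays_with_daily_volume(self):
        history = [pc(90, 5, 5, D - dt.timedelta(i)) for i in range(7, 0, -1)]
        gaps = []
        for n in (10, 1000, 100_000):
            day = pc(n, n, 2 * n, D)  # empirical pss = -0.25
            series = daily_pss_series(history + [day], seed=0)
            est = [e for e in series if e.date == D][0]
            gaps.append(abs(est.pss_point - (-0.25)))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[-1] < 1e-3

    def test_duplicate_dates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            daily_pss_series([pc(1, 1, 1), pc(2, 2, 2)], seed=0)

    def test_interval_bounds_always_in_range(self):
        rng = np.random.default_rng(3)
        days = [pc(*rng.integers(0, 50, size=3), D + dt.timedelta(int(i)))
                for i in range(20)]
        for est in daily_pss_series(days, n_mc=1000, seed=1):
            assert -1 <= est.ci_low <= est.ci_high <= 1
            assert -1 <= est.pss_point <= 1


class TestWeeklyAverage:
    def test_seven_days_average_to_one_block(self):
        ests = [e for i in range(7)
                for e in daily_pss_series([pc(1, 1, 1, D + dt.timedelta(i))],
                                          seed=0)]
        # overwrite points with 0.1..0.7 via dataclasses.replace
        import dataclasses
        ests = [dataclasses.replace(e, pss_point=(i + 1) / 10)
                for i, e in enumerate(ests)]
        weeks = weekly_average(ests)
        assert weeks == [(D, pytest.approx(0.4))]

    def test_partial_second_block(self):
        import dataclasses
        ests = [dataclasses.replace(
                    daily_pss_series([pc(1, 1, 1, D + dt.timedelta(i))],
                                     seed=0)[0], pss_point=1.0)
                for i in range(8)]
        weeks = weekly_average(ests)
        assert len(weeks) == 2
        assert weeks[1][0] == D + dt.timedelta(days=7)

    def test_gap_weeks_omitted(self):
        import dataclasses
        ests = [dataclasses.replace(
                    daily_pss_series([pc(1, 1, 1, day)], seed=0)[0],
                    pss_point=0.5)
                for day in (D, D + dt.timedelta(days=20))]
        weeks = weekly_average(ests)
        assert [w[0] for w in weeks] == [D, D + dt.timedelta(days=14)]


class TestTransformer:
    def test_frame_round_trip(self, tiny_corpus):
        from opinionpulse.engagement import tweets_to_frame

        frame = tweets_to_frame(tiny_corpus)
        out = DirichletNetSentiment(n_mc=1000, random_state=0).fit().transform(frame)
        assert set(out.columns) >= {"date", "stratum", "pss", "ci_low", "ci_high"}
        assert len(out) == 2  # two study days, national stratum
        assert ((out["ci_low"] <= out["pss"]) & (out["pss"] <= out["ci_high"])).all()
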