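import numpy as np
import pandas as pd
import pytest

from streamcom import (
    ASFEstimate,
    KSchedule,
    asf_api_relation,
    classify_wetness,
    compute_api,
    summarize_api_by_cluster,
)
from streamcom.som import ClusterPartition


def days(start, n):
    return pd.date_range(start, periods=n, freq="D")


class TestComputeAPI:
    def test_pulse_response_unrolls_the_recursion(self):
        d = days("2013-01-01", 5)
        p = np.array([10.0, 0, 0, 0, 0])
        api = compute_api(d, p, k=KSchedule.constant(0.9), api_init=0.0)
        np.testing.assert_allclose(api.api, [0.0, 10.0, 9.0, 8.1, 7.29])

    def test_geometric_decay_without_rain(self):
        d = days("2013-01-01", 20)
        api = compute_api(d, np.zeros(20), k=KSchedule.constant(0.9), api_init=100.0)
        np.testing.assert_allclose(api.api, 100.0 * 0.9 ** np.arange(20))

    def test_constant_rain_converges_to_fixed_point(self):
        d = days("2013-01-01", 600)
        api = compute_api(d, np.full(600, 2.0), k=KSchedule.constant(0.9))
        assert api.api[-1] == pytest.approx(2.0 / 0.1, rel=1e-6)

    def test_lumped_variant(self):
        d = days("2013-01-01", 3)
        api = compute_api(
            d, np.array([10.0, 0, 0]), k=KSchedule.constant(0.9), lumped=True
        )
        np.testing.assert_allclose(api.api, [0.0, 9.0, 8.1])

    def test_linearity_in_precipitation(self, rng):
        d = days("2013-03-01", 120)
        p1 = rng.gamma(0.7, 3.0, 120)
        p2 = rng.gamma(0.7, 1.0, 120)
        k = KSchedule()
        combo = compute_api(d, 2.0 * p1 + 3.0 * p2, k=k).api
        parts = 2.0 * compute_api(d, p1, k=k).api + 3.0 * compute_api(d, p2, k=k).api
        np.testing.assert_allclose(combo, parts, atol=1e-9)

    def test_shift_equivariance_with_constant_k(self, rng):
        p = rng.gamma(0.7, 3.0, 100)
        k = KSchedule.constant(0.9)
        a = compute_api(days("2013-01-01", 100), p, k=k).api
        shifted = compute_api(days("2013-01-02", 100), p, k=k).api
        np.testing.assert_allclose(shifted, a)  # same recursion, shifted calendar

    def test_errors(self):
        with pytest.raises(ValueError, match="negative"):
            compute_api(days("2013-01-01", 3), np.array([1.0, -1.0, 0.0]))
        gappy = pd.DatetimeIndex(["2013-01-01", "2013-01-02", "2013-01-04"])
        with pytest.raises(ValueError, match="gap"):
            compute_api(gappy, np.zeros(3))


class TestKSchedule:
    def test_out_of_range_rejected_by_default(self):
        with pytest.raises(ValueError, match="outside"):
            KSchedule(tuple([0.5] * 12))
        ks = KSchedule(tuple([0.5] * 12), allow_out_of_range=True)
        assert ks.k_by_month[0] == 0.5

    def test_monthly_lookup(self):
        ks = KSchedule()
        d = pd.DatetimeIndex(["2013-01-15", "2013-07-15"])
        assert ks.for_dates(d).tolist() == [ks.k_by_month[0], ks.k_by_month[6]]


class TestClassifyWetness:
    def test_literal_thresholds_mirror_quartile_rule(self):
        d = days("2013-01-01", 3)
        api = compute_api(d, np.zeros(3), k=KSchedule.constant(0.9), api_init=0.0)
        api.api[:] = [91.0, 15.5, 40.0]
        out = classify_wetness(api, thresholds=(15.5, 63.4))
        assert out.wetness.tolist() == ["high", "low", "moderate"]

    def test_boundary_value_at_q1_is_low(self):
        d = days("2013-01-01", 3)
        api = compute_api(d, np.zeros(3), k=KSchedule.constant(0.9))
        api.api[:] = [15.5, 63.4, 20.0]
        out = classify_wetness(api, thresholds=(15.5, 63.4))
        assert out.wetness[0] == "low" and out.wetness[1] == "high"

    def test_self_referenced_quartiles_partition_roughly_25_50_25(self, rng):
        n = 2000
        d = days("2010-01-01", n)
        api = compute_api(d, np.zeros(n), k=KSchedule.constant(0.9))
        api.api[:] = rng.uniform(0, 100, n)
        api.burn_in[:] = False
        out = classify_wetness(api)
        frac = pd.Series(out.wetness).value_counts(normalize=True)
        assert frac["low"] == pytest.approx(0.25, abs=0.03)
        assert frac["moderate"] == pytest.approx(0.50, abs=0.03)
        assert frac["high"] == pytest.approx(0.25, abs=0.03)

    def test_short_reference_rejected(self):
        d = days("2013-01-01", 100)
        api = compute_api(d, np.zeros(100), k=KSchedule.constant(0.9))
        with pytest.raises(ValueError, match="365"):
            classify_wetness(api, reference=api)


class TestSummaries:
    def test_cluster_means(self):
        d = days("2013-01-01", 3)
        api = compute_api(d, np.zeros(3), k=KSchedule.constant(0.9))
        api.api[:] = [10.0, 20.0, 30.0]
        labels = np.array([1, 1, 1])
        part = ClusterPartition(d, labels, labels.copy(), 1)
        out = summarize_api_by_cluster(api, part)
        assert out["mean_api"].iloc[0] == pytest.approx(20.0)

    def test_cluster_api_ordering_follows_rainfall_levels(self):
        # regimes built atop distinct precipitation levels keep their mean-API
        # ordering (constant k, equal-length regimes so equilibria dominate)
        from streamcom import RegimeSpec, SimulationConfig, generate_precipitation

        regimes = [
            RegimeSpec(1, "2013-01-01", "2013-06-30", 0.0, 1.0),
            RegimeSpec(2, "2013-07-01", "2013-12-31", 0.0, 4.0),
            RegimeSpec(3, "2014-01-01", "2014-06-30", 0.0, 10.0),
        ]
        cfg = SimulationConfig(regimes=regimes, n_missing=0, seed=6)
        dates, p = generate_precipitation(cfg)
        api = compute_api(dates, p, k=KSchedule.constant(0.9))
        labels = np.concatenate(
            [np.full(len(r.dates), r.regime_id) for r in regimes]
        )
        part = ClusterPartition(dates, labels, labels.copy(), 3)
        out = summarize_api_by_cluster(api, part).set_index("cluster")
        assert (
            out.loc[1, "mean_api"]
            < out.loc[2, "mean_api"]
            < out.loc[3, "mean_api"]
        )

    def test_missing_coverage_errors(self):
        d = days("2013-01-01", 3)
        api = compute_api(d, np.zeros(3), k=KSchedule.constant(0.9))
        other = days("2014-01-01", 3)
        labels = np.ones(3, dtype=int)
        part = ClusterPartition(other, labels, labels.copy(), 1)
        with pytest.raises(ValueError, match="2014"):
            summarize_api_by_cluster(api, part)


def est(cluster, asf_days=None, censoring="none"):
    return ASFEstimate(cluster, asf_days, censoring, 60.0, 30)


def api_means(pairs):
    return pd.DataFrame(
        {"cluster": [c for c, _ in pairs], "mean_api": [a for _, a in pairs]}
    )


class TestASFAPIRelation:
    def test_study_triples_yield_negative_correlation(self):
        # clusters at mean APIs 13.6, 43.1, 91.0 with ASFs 25 d, 13 d, < 1 d
        rel = asf_api_relation(
            [est(2, 25), est(5, 13), est(4, None, "below_one_day")],
            api_means([(2, 13.6), (5, 43.1), (4, 91.0)]),
        )
        assert rel["determined"] and rel["pearson_r"] < 0
        assert {p["asf"] for p in rel["points"]} == {25.0, 13.0, 0.5}

    def test_censored_above_excluded_but_reported(self):
        rel = asf_api_relation(
            [est(1, None, "above_horizon"), est(2, 25), est(5, 13),
             est(4, None, "below_one_day")],
            api_means([(1, 17.7), (2, 13.6), (5, 43.1), (4, 91.0)]),
        )
        assert len(rel["points"]) == 3
        assert rel["excluded_censored_above"][0]["cluster"] == 1

    def test_degenerate_duplicate_api_still_finite(self):
        rel = asf_api_relation(
            [est(1, 10), est(2, 20), est(3, 5)],
            api_means([(1, 50.0), (2, 50.0), (3, 80.0)]),
        )
        assert np.isfinite(rel["pearson_r"])

    def test_monotone_grid_strongly_negative(self):
        apis = np.linspace(5, 95, 8)
        ests = [est(i, int(40 - 0.4 * a)) for i, a in enumerate(apis)]
        rel = asf_api_relation(ests, api_means(list(zip(range(8), apis))))
        assert rel["pearson_r"] <= -0.9

    def test_too_few_points_undetermined(self):
        rel = asf_api_relation(
            [est(1, 10), est(2, 20)], api_means([(1, 10.0), (2, 20.0)])
        )
        assert rel["determined"] is False and rel["pearson_r"] is None
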