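import math

import numpy as np
import pandas as pd
import pytest

from pyrewash.evaluate import (
    SampleSeries,
    emc,
    eml,
    event_matrix,
    gof_report,
    kge,
    nse,
    pca,
    regress,
    rmse,
)


class TestEmcEml:
    def test_constant_concentration(self):
        s = SampleSeries(np.array([3.0, 3.0, 3.0]), np.array([10.0, 50.0, 40.0]))
        assert emc(s) == pytest.approx(3.0)

    def test_equal_volumes_average(self):
        s = SampleSeries(np.array([2.0, 4.0]), np.array([100.0, 100.0]))
        assert emc(s) == pytest.approx(3.0)

    def test_flow_weighting(self):
        s = SampleSeries(np.array([1.0, 5.0]), np.array([300.0, 100.0]))
        assert emc(s) == pytest.approx(2.0)

    def test_eml_both_routes_agree(self):
        s = SampleSeries(np.array([1.0, 5.0]), np.array([300.0, 100.0]))
        total_v = float(np.sum(s.volumes))
        direct = float(np.sum(s.concentrations * s.volumes))
        assert eml(emc(s), total_v) == pytest.approx(direct) == pytest.approx(800.0)

    def test_eml_arithmetic(self):
        assert eml(0.0, 100.0) == 0.0
        assert eml(3.0, 100.0) == pytest.approx(300.0)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            emc(SampleSeries(np.array([1.0]), np.array([0.0])))


class TestRmse:
    def test_identical_series(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_calculation(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(math.sqrt(12.5))

    def test_constant_offset(self):
        x = np.array([1.0, 5.0, 9.0])
        assert rmse(x, x + 2.5) == pytest.approx(2.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestNse:
    def test_perfect(self):
        assert nse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_mean_benchmark_is_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert nse(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_hand_calculation(self):
        assert nse([1.0, 2.0, 3.0], [1.0, 2.0, 5.0]) == pytest.approx(-1.0)

    def test_constant_observations_error(self):
        with pytest.raises(ValueError, match="constant"):
            nse([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_affine_invariance(self):
        obs = np.array([1.0, 4.0, 2.0, 8.0])
        sim = np.array([1.5, 3.0, 2.5, 7.0])
        assert nse(3.0 * obs + 7.0, 3.0 * sim + 7.0) == pytest.approx(nse(obs, sim))


class TestKge:
    def test_perfect(self):
        value, r, alpha, beta = kge([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (value, r, alpha, beta) == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_doubled_simulation_closed_form(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        value, r, alpha, beta = kge(obs, 2.0 * obs)
        assert r == pytest.approx(1.0)
        assert alpha == pytest.approx(2.0)
        assert beta == pytest.approx(2.0)
        assert value == pytest.approx(1.0 - math.sqrt(2.0))

    def test_scale_invariance_only(self):
        obs = np.array([1.0, 4.0, 2.0, 8.0])
        sim = np.array([1.5, 3.0, 2.5, 7.0])
        base = kge(obs, sim)[0]
        assert kge(5.0 * obs, 5.0 * sim)[0] == pytest.approx(base)
        # a common shift changes beta, hence KGE
        assert kge(obs + 10.0, sim + 10.0)[0] != pytest.approx(base)

    def test_zero_mean_error(self):
        with pytest.raises(ValueError, match="zero observed mean"):
            kge([-1.0, 1.0], [0.5, 0.5])

    def test_report_consistency(self):
        obs = np.array([1.0, 4.0, 2.0, 8.0])
        sim = np.array([1.5, 3.0, 2.5, 7.0])
        g = gof_report(obs, sim)
        assert g.kge == pytest.approx(
            1.0 - math.sqrt((g.r - 1) ** 2 + (g.alpha - 1) ** 2 + (g.beta - 1) ** 2)
        )
        assert g.alpha == pytest.approx(g.sigma_sim / g.sigma_obs)
        assert g.beta == pytest.approx(g.mu_sim / g.mu_obs)


ANALYTES = ("bifenthrin", "cyfluthrin", "cypermethrin")


def _events_frame(n=17, n_missing=3, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "site": rng.choice(["F1", "F2"], size=n),
            "adp_day": rng.exponential(10, n),
            "rain_mm": rng.lognormal(2, 0.5, n),
            "runoff_m3": rng.lognormal(4, 0.8, n),
            "eml_tss_mg": rng.lognormal(3, 1.0, n),
        },
        index=[f"E{i:03d}" for i in range(n)],
    )
    for a in ANALYTES:
        df[f"m_avail_{a}_g"] = rng.lognormal(0, 1, n)
        df[f"eml_{a}_ug"] = rng.lognormal(10, 1, n)
    for i in range(n_missing):
        df.loc[df.index[i], f"eml_{ANALYTES[i % 3]}_ug"] = np.nan
    return df


class TestEventMatrix:
    def test_eleven_variables(self):
        m = event_matrix(_events_frame(), ANALYTES)
        assert m.full.shape[1] == 11

    def test_complete_case_exclusion(self):
        m = event_matrix(_events_frame(n=17, n_missing=3), ANALYTES)
        assert len(m.complete) == 14
        assert len(m.complete_case_ids) == 14
        assert len(m.incomplete_case_ids) == 3

    def test_no_missing_all_complete(self):
        m = event_matrix(_events_frame(n_missing=0), ANALYTES)
        assert len(m.complete) == 17

    def test_site_encoded_binary(self):
        m = event_matrix(_events_frame(), ANALYTES)
        assert set(m.full["site"].unique()) <= {0, 1}

    def test_missing_column_reported(self):
        with pytest.raises(KeyError, match="adp_day"):
            event_matrix(_events_frame().drop(columns=["adp_day"]), ANALYTES)


FIXTURE_5X3 = np.array(
    [
        [2.1, -1.0, 0.5],
        [0.3, 0.2, 1.7],
        [-1.2, 0.9, -0.4],
        [3.4, -2.2, 0.1],
        [0.8, 1.1, 2.2],
    ]
)


class TestPca:
    def test_variance_fractions_match_eigendecomposition_oracle(self):
        # independent oracle: eigenvalues of the correlation matrix
        corr = np.corrcoef(FIXTURE_5X3, rowvar=False)
        eigvals = np.sort(np.linalg.eigh(corr)[0])[::-1]
        expected = eigvals / eigvals.sum()
        result = pca(FIXTURE_5X3, standardize=True)
        np.testing.assert_allclose(result.variance_fraction, expected, atol=1e-10)

    def test_variance_fractions_sum_to_one(self):
        result = pca(FIXTURE_5X3)
        assert result.variance_fraction.sum() == pytest.approx(1.0)

    def test_two_perfectly_correlated_variables(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        result = pca(np.column_stack([x, 3.0 * x + 1.0]), standardize=True)
        assert result.variance_fraction[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        result = pca(FIXTURE_5X3)
        gram = result.loadings.T @ result.loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_reconstruction(self):
        result = pca(FIXTURE_5X3, standardize=True)
        X = FIXTURE_5X3
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        np.testing.assert_allclose(
            result.scores @ result.loadings.T, Xs, atol=1e-10
        )

    def test_retained_count_by_cumulative_variance(self):
        result = pca(FIXTURE_5X3, retain_variance=0.99)
        cum = np.cumsum(result.variance_fraction)
        assert cum[result.retained_count - 1] >= 0.99 - 1e-12
        if result.retained_count > 1:
            assert cum[result.retained_count - 2] < 0.99

    def test_rejects_missing_values(self):
        bad = FIXTURE_5X3.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pca(bad)


class TestRegress:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        r = regress(x, 2.0 * x + 1.0)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        r = regress([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert r.slope == pytest.approx(0.0)
        assert r.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_three_point_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 3.0, 5.0])
        # closed-form OLS via normal equations
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        r2 = 1.0 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
        r = regress(x, y)
        assert r.slope == pytest.approx(slope) == pytest.approx(1.5)
        assert r.intercept == pytest.approx(intercept) == pytest.approx(1.0 / 3.0)
        assert r.r_squared == pytest.approx(r2)

    def test_degenerate_predictor(self):
        with pytest.raises(ValueError, match="degenerate"):
            regress([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
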