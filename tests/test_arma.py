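import numpy as np
import pytest

from speechtiming.arma import (
    ArmaError,
    ArmaFit,
    ArmaSpec,
    aicc,
    akaike_set,
    akaike_weights,
    d1_weight_share,
    enumerate_grid,
    fit_arma,
    grid_search,
    marginal_weights_by_p,
)
from speechtiming.series import extract_ini, log_ini
from speechtiming.synthetic import SyntheticConfig, generate_language


def make_fit(loglik, k, n_eff, spec=ArmaSpec(0, 0, 0)):
    f = ArmaFit(
        spec=spec, loglik=loglik, k=k, n_eff=n_eff, aicc=np.nan,
        coefficients={}, innovation_var=1.0, converged=True,
    )
    f.aicc = aicc(f)
    return f


class TestGrid:
    def test_72_variants(self):
        specs = enumerate_grid()
        assert len(specs) == 72
        assert len(set(specs)) == 72
        assert {s.d for s in specs} == {0, 1}
        assert max(s.p for s in specs) == 5 and max(s.q for s in specs) == 5

    def test_reduced_grid(self):
        assert len(enumerate_grid(max_p=2, max_q=2, max_d=1)) == 18

    def test_invalid_spec(self):
        with pytest.raises(ArmaError):
            ArmaSpec(p=-1, d=0, q=0)
        with pytest.raises(ArmaError):
            ArmaSpec(p=0, d=2, q=0)


class TestAicc:
    def test_hand_evaluation(self):
        f = make_fit(loglik=-100.0, k=2, n_eff=50)
        # AIC = 204; AICc = 204 + 2*2*3/47
        assert f.aicc == pytest.approx(204.0 + 12.0 / 47.0)

    def test_limit_equals_aic(self):
        f = make_fit(loglik=-100.0, k=3, n_eff=10**9)
        assert f.aicc == pytest.approx(-2 * -100.0 + 2 * 3, abs=1e-3)

    def test_monotone_in_k(self):
        vals = [make_fit(-50.0, k, 40).aicc for k in (1, 2, 3, 5)]
        assert vals == sorted(vals)
        assert len(set(vals)) == len(vals)

    def test_small_sample_infinite(self):
        f = make_fit(loglik=-10.0, k=10, n_eff=11)
        assert np.isinf(f.aicc)


class TestAkaikeWeights:
    def test_single_model(self):
        np.testing.assert_allclose(akaike_weights([123.4]), [1.0])

    def test_equal_scores_symmetric(self):
        w = akaike_weights([50.0] * 5)
        np.testing.assert_allclose(w, np.full(5, 0.2))

    def test_direct_formula(self):
        w = akaike_weights([100.0, 102.0])
        raw = np.array([1.0, np.exp(-1.0)])
        np.testing.assert_allclose(w, raw / raw.sum(), atol=1e-4)
        np.testing.assert_allclose(w, [0.7311, 0.2689], atol=1e-4)

    def test_shift_invariance(self):
        a = np.array([300.0, 301.5, 304.2])
        np.testing.assert_allclose(akaike_weights(a), akaike_weights(a + 77.7))

    def test_sum_to_one_with_infinite_entries(self):
        w = akaike_weights([100.0, np.inf, 101.0])
        assert w[1] == 0.0
        assert w.sum() == pytest.approx(1.0)

    def test_all_infinite_errors(self):
        with pytest.raises(ArmaError):
            akaike_weights([np.inf, np.inf])

    def test_brute_force_oracle(self, rng):
        a = rng.uniform(100, 120, size=30)
        expected = np.exp(-0.5 * (a - a.min()))
        expected /= expected.sum()
        np.testing.assert_allclose(akaike_weights(a), expected)


class TestAkaikeSet:
    def test_single_model(self):
        assert akaike_set([1.0]) == [0]

    def test_cumulative_prefix(self):
        members = akaike_set([0.5, 0.3, 0.16, 0.04])
        assert members == [0, 1, 2]  # cumulative 0.96

    def test_uniform_72(self):
        members = akaike_set(np.full(72, 1.0 / 72.0))
        assert len(members) == 69  # ceil to reach >= 0.95

    def test_brute_force_cumsum_oracle(self, rng):
        w = rng.dirichlet(np.ones(40))
        members = akaike_set(w)
        sorted_w = np.sort(w)[::-1]
        expected_size = int(np.argmax(np.cumsum(sorted_w) >= 0.95 - 1e-12)) + 1
        assert len(members) == expected_size
        assert w[members].sum() >= 0.95 - 1e-9

    def test_threshold_one_returns_everything(self):
        w = np.array([0.6, 0.25, 0.15])
        assert sorted(akaike_set(w, threshold=1.0)) == [0, 1, 2]


def _series(cfg):
    seq, _ = generate_language(cfg)
    s = extract_ini(seq)
    return log_ini(s), s.i


class TestFitArma:
    def test_mean_model_recovers_moments(self):
        y, x = _series(SyntheticConfig(n_nuclei=320, n_phrases=8, log_sd=0.3, seed=2))
        fit = fit_arma(y, None, ArmaSpec(0, 0, 0, with_exog=False))
        present = y[1:][np.isfinite(y[1:])]
        assert fit.coefficients["intercept"] == pytest.approx(present.mean(), abs=0.02)
        assert fit.innovation_var == pytest.approx(present.var(), rel=0.1)
        assert fit.k == 2  # intercept + innovation variance

    def test_ar1_parameter_recovery(self):
        cfg = SyntheticConfig(
            n_nuclei=312, n_phrases=8, process="arima", ar=(0.6,), d_order=0,
            innovation_sd=0.25, seed=10,
        )
        y, x = _series(cfg)
        fit = fit_arma(y, None, ArmaSpec(1, 0, 0, with_exog=False))
        phi = fit.coefficients["ar.L1"]
        se = np.sqrt((1 - 0.6**2) / fit.n_eff)
        assert abs(phi - 0.6) < 3 * se

    def test_k_counts_exog_and_variance(self):
        y, x = _series(SyntheticConfig(n_nuclei=120, n_phrases=6, seed=3))
        fit = fit_arma(y, x, ArmaSpec(1, 0, 1, with_exog=True))
        # intercept + exog + ar + ma + sigma2
        assert fit.k == 5

    def test_d1_drops_intercept_by_default(self):
        y, x = _series(SyntheticConfig(n_nuclei=120, n_phrases=6, seed=3))
        fit = fit_arma(y, x, ArmaSpec(0, 1, 0, with_exog=True))
        assert "intercept" not in fit.coefficients
        assert fit.k == 2  # exog + sigma2

    def test_masking_never_raises_n_eff(self):
        cfg_few = SyntheticConfig(n_nuclei=120, n_phrases=2, seed=4)
        cfg_many = SyntheticConfig(n_nuclei=120, n_phrases=20, seed=4)
        y1, x1 = _series(cfg_few)
        y2, x2 = _series(cfg_many)
        f1 = fit_arma(y1, x1, ArmaSpec(0, 0, 0))
        f2 = fit_arma(y2, x2, ArmaSpec(0, 0, 0))
        assert f2.n_eff < f1.n_eff

    def test_too_few_observations(self):
        y, x = _series(SyntheticConfig(n_nuclei=15, n_phrases=2, seed=5))
        with pytest.raises(ArmaError, match="too few"):
            fit_arma(y, x, ArmaSpec(0, 0, 0))

    def test_deterministic(self):
        y, x = _series(SyntheticConfig(n_nuclei=150, n_phrases=10, seed=6))
        a = fit_arma(y, x, ArmaSpec(1, 1, 1))
        b = fit_arma(y, x, ArmaSpec(1, 1, 1))
        assert a.loglik == b.loglik
        assert a.coefficients == b.coefficients


@pytest.fixture(scope="module")
def small_table():
    cfg = SyntheticConfig(
        n_nuclei=212, n_phrases=12, process="arima", ma=(0.5,), d_order=1,
        innovation_sd=0.3, seed=11,
    )
    seq, _ = generate_language(cfg)
    s = extract_ini(seq)
    return grid_search(log_ini(s), s.i, max_p=2, max_q=2)


class TestModelTableSummaries:
    def test_weights_sum_to_one(self, small_table):
        assert small_table.weights.sum() == pytest.approx(1.0)

    def test_d1_share_is_complement_of_d0(self, small_table):
        d1 = d1_weight_share(small_table)
        d0 = 100.0 * sum(
            w for f, w in zip(small_table.fits, small_table.weights) if f.spec.d == 0
        )
        assert d1 + d0 == pytest.approx(100.0)

    def test_d1_structure_recovered(self, small_table):
        assert d1_weight_share(small_table) > 90.0

    def test_marginal_weights_group_by_oracle(self, small_table):
        marg = marginal_weights_by_p(small_table, max_p=2)
        for p in range(3):
            expected = sum(
                w
                for f, w in zip(small_table.fits, small_table.weights)
                if f.spec.p == p
            )
            assert marg[p] == pytest.approx(expected)
        assert marg.sum() == pytest.approx(1.0)

    def test_akaike_set_minimal_prefix(self, small_table):
        w = small_table.weights
        members = small_table.akaike_set
        assert w[members].sum() >= 0.95 - 1e-9
        assert w[members].sum() - w[members[-1]] < 0.95

    def test_best_is_argmin_aicc(self, small_table):
        finite = [f for f in small_table.fits if f.converged and np.isfinite(f.aicc)]
        assert small_table.best.aicc == pytest.approx(min(f.aicc for f in finite))

    def test_best_beats_noise_baseline(self, small_table):
        y_fit_spec = ArmaSpec(0, 0, 0, with_exog=False)
        cfg = SyntheticConfig(
            n_nuclei=212, n_phrases=12, process="arima", ma=(0.5,), d_order=1,
            innovation_sd=0.3, seed=11,
        )
        seq, _ = generate_language(cfg)
        s = extract_ini(seq)
        baseline = fit_arma(log_ini(s), None, y_fit_spec)
        assert small_table.best.aicc <= baseline.aicc

    def test_tsv_serialization(self, small_table, tmp_path):
        p = tmp_path / "table.tsv"
        small_table.to_tsv(p)
        import pandas as pd

        df = pd.read_csv(p, sep="\t")
        assert len(df) == 18
        assert set(["p", "d", "q", "loglik", "k", "aicc", "weight", "in_akaike_set"]) <= set(
            df.columns
        )
        assert df["weight"].sum() == pytest.approx(1.0)
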