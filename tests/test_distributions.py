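"""Telegraph/limit pmfs, hyper-distributions and compound mixtures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from txnoise import (
    ConfigurationError,
    NoiseSpec,
    ParameterError,
    Pmf,
    TelegraphParams,
    compound_pmf,
    limit_pmf,
    noise_moments,
    sample_noise,
    telegraph_mean_var,
    telegraph_pmf,
)
from txnoise.distributions import truncation_support


class TestTelegraphPmf:
    def test_ground_state_closed_form(self):
        # p(0) = 1F1(1; 2; -2) = (1 - e^-2)/2 for lam=mu=1, K=2
        expected = (1.0 - math.exp(-2.0)) / 2.0
        assert telegraph_pmf(0, TelegraphParams(1, 1, 2)) == pytest.approx(expected, rel=1e-12)

    def test_constitutive_limit_is_poisson(self):
        # mu = 0 keeps the gene permanently active -> Poisson(K)
        n = np.arange(40)
        p = telegraph_pmf(n, TelegraphParams(3.0, 0.0, 5.0))
        assert np.allclose(p, stats.poisson.pmf(n, 5.0), rtol=1e-12, atol=1e-300)

    def test_bursty_limit_is_negative_binomial(self):
        # mu -> inf with burst size K/mu fixed -> NegBin(lam, K/mu)
        n = np.arange(51)
        p = telegraph_pmf(n, TelegraphParams(2.0, 1000.0, 1000.0))
        assert np.max(np.abs(p - limit_pmf(n, "negbin", 2.0, 1.0))) < 1e-3

    def test_degradation_rescaling_invariance(self):
        n = np.arange(30)
        a = telegraph_pmf(n, TelegraphParams(2.0, 3.0, 50.0, 1.0))
        b = telegraph_pmf(n, TelegraphParams(4.0, 6.0, 100.0, 2.0))
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("lam,mu,K", [
        (1.0, 1.0, 2.0), (2.0, 12.0, 100.0), (0.5, 8.0, 300.0),
        (2.0, 12.0, 1000.0), (10.0, 0.0, 50.0),
    ])
    def test_normalisation(self, lam, mu, K):
        # truncated mass reaches 1 within 1e-6 at mean + 10 sd (tail-extended)
        p = TelegraphParams(lam, mu, K)
        m, v = telegraph_mean_var(p)
        nmax = truncation_support(m, v, lambda n: telegraph_pmf(n, p))
        total = telegraph_pmf(np.arange(nmax + 1), p).sum()
        assert abs(total - 1.0) < 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(lam=st.floats(0.2, 20), mu=st.floats(0, 30), K=st.floats(0.5, 300))
    def test_probabilities_lie_in_unit_interval(self, lam, mu, K):
        p = telegraph_pmf(np.arange(0, 60, 7), TelegraphParams(lam, mu, K))
        assert np.all(p >= 0) and np.all(p <= 1 + 1e-12)

    def test_moment_formulas_match_pmf(self):
        p = TelegraphParams(2.0, 12.0, 100.0)
        m, v = telegraph_mean_var(p)
        nmax = truncation_support(m, v, lambda n: telegraph_pmf(n, p))
        n = np.arange(nmax + 1)
        w = telegraph_pmf(n, p)
        assert n @ w == pytest.approx(m, rel=1e-9)
        assert (n - m) ** 2 @ w == pytest.approx(v, rel=1e-8)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ParameterError):
            TelegraphParams(0.0, 1.0, 2.0)       # lam must be > 0
        with pytest.raises(ParameterError):
            TelegraphParams(1.0, -1.0, 2.0)
        with pytest.raises(ParameterError):
            TelegraphParams(1.0, 1.0, math.inf)
        with pytest.raises(ParameterError):
            telegraph_pmf(-1, TelegraphParams(1, 1, 2))


class TestLimitPmf:
    def test_degenerate_poisson_is_point_mass(self):
        assert limit_pmf(0, "poisson", 0.0) == 1.0
        assert limit_pmf(3, "poisson", 0.0) == 0.0

    def test_unit_negbin_is_geometric(self):
        # r=1, burst size 1 -> pmf(n) = 2^-(n+1)
        n = np.arange(20)
        np.testing.assert_allclose(limit_pmf(n, "negbin", 1.0, 1.0),
                                   0.5 ** (n + 1), rtol=1e-12)

    def test_negbin_mean_is_r_times_burst_size(self):
        r, beta = 3.0, 50.0 / 3.0  # lam, K/mu convention: mean lam*K/mu
        n = np.arange(2000)
        assert n @ limit_pmf(n, "negbin", r, beta) == pytest.approx(r * beta, rel=1e-8)

    def test_invalid_family_and_params(self):
        with pytest.raises(ParameterError):
            limit_pmf(0, "negbin", -1.0, 1.0)
        with pytest.raises(ParameterError):
            limit_pmf(0, "weibull", 1.0)


class TestNoiseSpec:
    @pytest.mark.parametrize("spec,mean,cv2", [
        (NoiseSpec.scaled_beta(300, 1.5, 7.5), 50.0, 0.5),
        (NoiseSpec.scaled_beta(400 / 3, 6, 10.5), 400 / 3 * 6 / 16.5, 0.1),
        (NoiseSpec.gamma(5, 10), 50.0, 0.2),
        (NoiseSpec.gamma(8, 1.25), 10.0, 0.125),
        (NoiseSpec.point(50), 50.0, 0.0),
        (NoiseSpec.scaled_beta_prime(2.0, 5.0, 10.0), 2.0 * 10 / 15, None),
    ])
    def test_exact_moments(self, spec, mean, cv2):
        m, c = noise_moments(spec)
        assert m == pytest.approx(mean, rel=1e-12)
        if cv2 is not None:
            assert c == pytest.approx(cv2, rel=1e-9)

    def test_point_sampling_is_constant(self):
        np.testing.assert_array_equal(sample_noise(NoiseSpec.point(50), 3, 0),
                                      [50.0, 50.0, 50.0])

    def test_gamma_sample_mean(self):
        x = sample_noise(NoiseSpec.gamma(5, 10), 100_000, 12345)
        se = math.sqrt(0.2) * 50 / math.sqrt(len(x))
        assert abs(x.mean() - 50.0) < 3 * se

    def test_truncated_normal_draws_nonnegative(self):
        x = sample_noise(NoiseSpec.truncated_normal(37, 10), 100_000, 7)
        assert np.all(x >= 0)
        # truncation at zero barely shifts a distribution 3.7 sd above it
        assert abs(x.mean() - 37.0) < 0.2

    def test_sampling_reproducible(self):
        a = sample_noise(NoiseSpec.gamma(5, 10), 100, 99)
        b = sample_noise(NoiseSpec.gamma(5, 10), 100, 99)
        np.testing.assert_array_equal(a, b)

    def test_bad_hyperparameters_raise(self):
        with pytest.raises(ParameterError):
            NoiseSpec("lognormal", (0, 1))
        with pytest.raises(ParameterError):
            NoiseSpec.gamma(-1, 1)
        with pytest.raises(ParameterError):
            NoiseSpec("scaled-beta", (100, 1.5))  # wrong arity


class TestCompoundPmf:
    def test_gamma_poisson_mixture_is_negative_binomial(self):
        # shape-1 gamma (exponential) mixing of Poisson -> geometric
        n = np.arange(25)
        q = compound_pmf(n, "poisson", "K", NoiseSpec.gamma(1.0, 1.0))
        assert np.max(np.abs(q - 0.5 ** (n + 1))) < 1e-8

    def test_point_mixing_reproduces_base_exactly(self):
        n = np.arange(30)
        q = compound_pmf(n, "telegraph", "K", NoiseSpec.point(60.0),
                         {"lam": 2.0, "mu": 4.0})
        np.testing.assert_array_equal(q, telegraph_pmf(n, TelegraphParams(2, 4, 60)))

    def test_beta_mixed_telegraph_presents_as_burstier_telegraph(self):
        # varying K on Telegraph(2, 3, .) reproduces Telegraph(2, 12, 100)
        n = np.arange(60)
        q = compound_pmf(n, "telegraph", "K", NoiseSpec.scaled_beta(100, 5, 9),
                         {"lam": 2.0, "mu": 3.0})
        assert np.max(np.abs(q - telegraph_pmf(n, TelegraphParams(2, 12, 100)))) < 1e-8

    def test_law_of_total_expectation(self):
        # E[compound] = E_f[E[base|K]] = E_f[K] for the Poisson base
        spec = NoiseSpec.gamma(5.0, 10.0)
        n = np.arange(300)
        q = compound_pmf(n, "poisson", "K", spec)
        assert n @ q == pytest.approx(spec.mean(), rel=1e-7)

    def test_configuration_errors(self):
        with pytest.raises(ConfigurationError):
            compound_pmf(0, "poisson", "rate", NoiseSpec.gamma(1, 1))
        with pytest.raises(ConfigurationError):
            compound_pmf(0, "telegraph", "K", NoiseSpec.gamma(1, 1), {"lam": 1.0})
        with pytest.raises(ConfigurationError):
            compound_pmf(0, "student", "K", NoiseSpec.gamma(1, 1))


class TestPmfTable:
    def test_validation_and_export(self, tmp_path):
        p = TelegraphParams(2, 4, 60)
        m, v = telegraph_mean_var(p)
        nmax = truncation_support(m, v, lambda n: telegraph_pmf(n, p))
        probs = telegraph_pmf(np.arange(nmax + 1), p)
        table = Pmf(probs)
        assert table.support_max == nmax
        out = tmp_path / "pmf.csv"
        table.write(out)
        import pandas as pd

        back = pd.read_csv(out)
        assert list(back.columns) == ["n", "probability"]
        np.testing.assert_allclose(back["probability"], probs)

    def test_rejects_unnormalised_table(self):
        with pytest.raises(ParameterError):
            Pmf(np.array([0.5, 0.2]))
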