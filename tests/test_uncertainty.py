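"""Sample-specific expected squared error: sigma^2, variance term, bias term."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pcrerr as pe
from pcrerr.exceptions import (
    ConfigurationError,
    DegreesOfFreedomError,
    DimensionError,
    RankError,
    ValidationError,
)


def toy_model(g_hat, A, N=100, mask=None, m_max_bias=None, sigma2_hat=None):
    """A score-space-only model carrier for formula tests."""
    g_hat = np.asarray(g_hat, dtype=float)
    M = g_hat.shape[0]
    return pe.PCRModel(
        x_mean=np.zeros(M), y_mean=0.0, loadings=np.eye(M),
        singular_values=np.ones(M), cal_scores=np.zeros((N, M)), g_hat=g_hat,
        A=A, N=N, K=M, M=M, sigma2_hat=sigma2_hat,
        significance_mask=None if mask is None else np.asarray(mask, dtype=bool),
        m_max_bias=m_max_bias,
    )


class TestEstimateSigma2:
    def test_noise_free_is_zero(self):
        # spectra of rank 8 with 5 informative components: any A_noise >= 5
        # leaves an exactly-zero residual on noise-free data
        truth = pe.strong_signal_truth(K=30, M=8, sigma2_y=0.0)
        ds = pe.simulate_dataset(truth, N=60, N_P=2, seed=1)
        assert pe.estimate_sigma2(ds.X_cal, ds.y_cal, A_noise=6) < 1e-10

    def test_recovers_noise_variance(self):
        # full-rank spectra (nonzero spectral noise) so all 50 components fit;
        # MSEC(50) ~ sigma^2 chi^2_149 / 149 concentrates within 25%
        truth = pe.strong_signal_truth(K=85, M=5, sigma2_y=0.25, sigma2_x=1e-6)
        ds = pe.simulate_dataset(truth, N=200, N_P=2, seed=7)
        est = pe.estimate_sigma2(ds.X_cal, ds.y_cal, A_noise=50)
        assert abs(est - 0.25) < 0.25 * 0.25

    def test_caps_at_rank(self, standard_dataset, standard_model):
        # 15 latent components, errorless spectra: cap at rank - 1 = 14
        est = pe.estimate_sigma2(standard_dataset.X_cal, standard_dataset.y_cal)
        assert est == pytest.approx(standard_model.sigma2_hat)
        assert 0.1 < est < 0.5  # near the generating 0.25

    def test_no_degrees_of_freedom(self, rng):
        X = rng.normal(size=(20, 30))
        with pytest.raises(DegreesOfFreedomError):
            pe.estimate_sigma2(X, rng.normal(size=20), A_noise=19)


class TestSignificantComponents:
    def test_exact_score_column_flags_only_itself(self, rng):
        X = rng.normal(size=(30, 10))
        base = pe.fit_pcr(X, rng.normal(size=30), A=2)
        y = 5.0 * base.cal_scores[:, 1]
        m = pe.fit_pcr(X, y, A=2)
        mask = pe.significant_components(m, y, alpha=0.01, m_max=5)
        expect = np.zeros(m.M, dtype=bool)
        expect[1] = True
        assert np.array_equal(mask, expect)

    def test_alpha_one_flags_all_tested(self, standard_model, standard_dataset):
        mask = pe.significant_components(
            standard_model, standard_dataset.y_cal, alpha=1.0, m_max=15
        )
        assert mask[:15].all()

    def test_null_response_rarely_flagged(self, standard_dataset):
        """Independent noise response: ~alpha * m_max false flags on average."""
        ds = standard_dataset
        rng = np.random.default_rng(202)
        flags = 0
        reps = 200
        for _ in range(reps):
            y = rng.standard_normal(100)
            m = pe.fit_pcr(ds.X_cal, y, A=5)
            flags += pe.significant_components(m, y, alpha=0.01, m_max=15).sum()
        assert flags / reps <= 0.5

    def test_m_max_exceeding_rank(self, standard_model, standard_dataset):
        with pytest.raises(DimensionError):
            pe.significant_components(standard_model, standard_dataset.y_cal, m_max=40)


class TestVarianceContribution:
    def test_centroid(self):
        assert pe.variance_contribution(np.zeros(5), 3, 1.0, 100) == pytest.approx(0.01)

    def test_direct_substitution(self):
        u = np.array([0.1, 0.2, 0.5])
        val = pe.variance_contribution(u, 2, 1.0, 100)
        assert val == pytest.approx(0.01 + 0.01 + 0.04)

    def test_monotone_in_A(self, rng):
        u = rng.normal(size=8)
        vals = [pe.variance_contribution(u, a, 0.3, 50) for a in range(1, 9)]
        assert np.all(np.diff(vals) >= 0)

    def test_invalid_rank(self):
        with pytest.raises(RankError):
            pe.variance_contribution(np.zeros(3), 4, 1.0, 10)


class TestBiasContribution:
    def test_direct_substitution_and_mask_gating(self):
        u = np.zeros(6)
        u[2], u[3] = 0.5, 0.1  # components 3 and 4, one-indexed
        g = np.zeros(6)
        g[2], g[3] = 2.0, 1.0
        both = toy_model(g, A=2, mask=[0, 0, 1, 1, 0, 0], m_max_bias=4)
        assert pe.bias_contribution(u, both) == pytest.approx(-1.1)
        gated = toy_model(g, A=2, mask=[0, 0, 1, 0, 0, 0], m_max_bias=4)
        assert pe.bias_contribution(u, gated) == pytest.approx(-1.0)

    def test_empty_bias_range(self):
        m = toy_model(np.ones(4), A=4, mask=[1, 1, 1, 1], m_max_bias=4)
        assert pe.bias_contribution(np.ones(4), m) == 0.0

    def test_missing_mask_raises(self):
        with pytest.raises(ConfigurationError):
            pe.bias_contribution(np.ones(4), toy_model(np.ones(4), A=2))


class TestExpectedSquaredError:
    def test_centroid_total(self):
        m = toy_model(np.zeros(5), A=2, mask=np.zeros(5), m_max_bias=5, sigma2_hat=1.0)
        bd = pe.expected_squared_error(np.zeros(5), m)
        assert bd.total == pytest.approx(1.01)
        assert bd.bias_signed == 0.0

    def test_assembled_example(self):
        g = np.zeros(6)
        g[2], g[3] = 2.0, 1.0
        m = toy_model(g, A=2, mask=[0, 0, 1, 1, 0, 0], m_max_bias=4, sigma2_hat=1.0)
        u = np.zeros(6)
        u[0], u[1], u[2], u[3] = 0.1, 0.2, 0.5, 0.1
        bd = pe.expected_squared_error(u, m)
        assert bd.variance_term == pytest.approx(0.06)
        assert bd.bias_signed == pytest.approx(-1.1)
        assert bd.total == pytest.approx(1.0 + 0.06 + 1.21)

    def test_missing_sigma2_raises(self):
        m = toy_model(np.zeros(3), A=1, mask=np.zeros(3), m_max_bias=3)
        with pytest.raises(ConfigurationError):
            pe.expected_squared_error(np.zeros(3), m)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_decomposition_identity(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(3, 12))
        A = int(rng.integers(1, M))
        m = toy_model(
            rng.normal(scale=3, size=M), A=A, mask=rng.integers(0, 2, M),
            m_max_bias=M, sigma2_hat=float(rng.uniform(0.01, 2.0)),
        )
        bd = pe.expected_squared_error(rng.normal(size=M), m)
        assert bd.total == pytest.approx(bd.sigma2 + bd.variance_term + bd.bias_signed**2, abs=1e-10)
        assert bd.variance_term >= bd.sigma2 / m.N


class TestOlsEquivalence:
    def test_centroid(self, small_full_rank):
        X, _ = small_full_rank
        Xc = X - X.mean(axis=0)
        val = pe.ols_expected_squared_error(np.zeros(5), Xc, 1.0, N=100)
        assert val == pytest.approx(1.01)

    def test_scales_linearly_in_sigma2(self, small_full_rank, rng):
        X, _ = small_full_rank
        Xc = X - X.mean(axis=0)
        x = rng.normal(size=5)
        assert pe.ols_expected_squared_error(x, Xc, 2.0) == pytest.approx(
            2.0 * pe.ols_expected_squared_error(x, Xc, 1.0)
        )

    def test_pcr_formula_reduces_to_ols_at_full_rank(self, small_full_rank, rng):
        X, y = small_full_rank
        m = pe.fit_pcr(X, y, A=5)
        assert m.M == 5
        m = dataclasses.replace(
            m, sigma2_hat=0.7,
            significance_mask=np.zeros(5, dtype=bool), m_max_bias=5,
        )
        Xc = X - m.x_mean
        for x in rng.normal(size=(4, 5)):
            total = pe.expected_squared_error(pe.project(m, x), m).total
            ols = pe.ols_expected_squared_error(x - m.x_mean, Xc, 0.7, N=m.N)
            assert total == pytest.approx(ols, abs=1e-8)

    def test_singular_design_raises(self):
        X = np.ones((10, 3))
        with pytest.raises(RankError):
            pe.ols_expected_squared_error(np.zeros(3), X, 1.0)


class TestSamePredictionDifferentUncertainty:
    def test_constructed_pair(self, standard_model):
        """Two score vectors with identical predictions can differ in expected
        squared error: move orthogonally to the coefficient vector inside the
        model space."""
        m = standard_model
        g = m.g_hat[: m.A]
        v = np.zeros(m.M)
        v[0], v[1] = g[1], -g[0]
        v *= 1.0 / np.linalg.norm(v[: m.A])
        u1 = np.zeros(m.M)
        u2 = v
        pred1 = m.y_mean + u1[: m.A] @ g
        pred2 = m.y_mean + u2[: m.A] @ g
        assert abs(pred1 - pred2) < 1e-12
        t1 = pe.expected_squared_error(u1, m).total
        t2 = pe.expected_squared_error(u2, m).total
        assert t2 / t1 >= 1.5


class TestCalibrateUncertainty:
    def test_attaches_state_without_mutation(self, standard_dataset):
        ds = standard_dataset
        m0 = pe.fit_pcr(ds.X_cal, ds.y_cal, A=5)
        m1 = pe.calibrate_uncertainty(m0, ds.X_cal, ds.y_cal)
        assert m0.sigma2_hat is None
        assert m1.sigma2_hat > 0
        assert m1.significance_mask.shape == (m1.M,)
        assert m1.m_max_bias == 15
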