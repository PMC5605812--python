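"""Unit and property tests for the four speckle densities and samplers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from hkspeckle.models import (
    DomainError,
    HKParams,
    KParams,
    ParameterError,
    RayleighParams,
    RicianParams,
    hk_intensity_snr,
    hk_log_pdf,
    hk_pdf,
    k_pdf,
    rayleigh_pdf,
    rician_pdf,
    sample,
)


def _hk_pdf_vec(a_grid, p):
    return np.exp(hk_log_pdf(np.asarray(a_grid, float), p))


class TestRayleighPdf:
    def test_direct_substitution(self):
        assert rayleigh_pdf(1.0, RayleighParams(1.0)) == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_zero_amplitude(self):
        assert rayleigh_pdf(0.0, RayleighParams(2.0)) == 0.0

    @pytest.mark.parametrize("d", [0.1, 1.0, 5.0])
    def test_normalization(self, d):
        total, _ = quad(lambda a: rayleigh_pdf(a, RayleighParams(d)), 0, 50 * d)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(DomainError):
            rayleigh_pdf(-0.1, RayleighParams(1.0))

    def test_invalid_scale_rejected(self):
        with pytest.raises(ParameterError):
            RayleighParams(0.0)


class TestRicianPdf:
    def test_reduces_to_rayleigh_at_zero_coherent(self):
        a = np.linspace(0, 4, 200)
        np.testing.assert_allclose(
            rician_pdf(a, RicianParams(0.0, 0.7)),
            rayleigh_pdf(a, RayleighParams(0.7)),
            atol=1e-14,
        )

    def test_value_at_unit(self):
        assert rician_pdf(1.0, RicianParams(0.0, 1.0)) == pytest.approx(0.606531, abs=1e-6)

    @pytest.mark.parametrize("l,g", [(0.5, 0.15), (0.6, 0.11)])
    def test_normalization(self, l, g):
        total, _ = quad(lambda a: float(rician_pdf(a, RicianParams(l, g))), 0, l + 30 * g)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_log_space_no_overflow(self):
        # a*l/g^2 ~ 4e4 would overflow a naive I0
        val = rician_pdf(2.0, RicianParams(2.0, 0.01))
        assert np.isfinite(val) and val > 0

    def test_negative_amplitude_rejected(self):
        with pytest.raises(DomainError):
            rician_pdf(-1.0, RicianParams(0.5, 0.2))


class TestKPdf:
    @pytest.mark.parametrize("m,a_scale", [(0.87, 7.48), (1.92, 7.50)])
    def test_normalization(self, m, a_scale):
        total, _ = quad(lambda a: float(k_pdf(a, KParams(m, a_scale))), 0, 60.0 / a_scale, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_second_moment_relation(self):
        # scale a = 2 sqrt(m / (2 sigma^2)) makes 2 sigma^2 the second moment
        m, sigma = 2.0, 0.2
        a_scale = 2.0 * math.sqrt(m / (2.0 * sigma**2))
        p = KParams(m, a_scale)
        m2, _ = quad(lambda a: a * a * float(k_pdf(a, p)), 0, 60.0 / a_scale, limit=200)
        assert m2 == pytest.approx(2.0 * sigma**2, rel=1e-6)

    def test_large_m_approaches_rayleigh(self):
        # matched second moment 2 d^2
        m, d = 500.0, 0.5
        a_scale = 2.0 * math.sqrt(m / (2.0 * d * d))
        grid = np.linspace(1e-3, 4 * d, 500)
        diff = np.abs(k_pdf(grid, KParams(m, a_scale)) - rayleigh_pdf(grid, RayleighParams(d)))
        assert diff.max() < 1e-2

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            KParams(-1.0, 2.0)
        with pytest.raises(ParameterError):
            KParams(1.0, 0.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(DomainError):
            k_pdf(-0.5, KParams(1.0, 2.0))


class TestHkPdf:
    def test_eps_zero_equals_k(self):
        sigma, c = 0.2, 2.0
        p_hk = HKParams(0.0, sigma, c)
        p_k = KParams(c, math.sqrt(2.0) / sigma)
        grid = np.linspace(1e-3, 2.0, 120)
        diff = max(abs(hk_pdf(a, p_hk) - float(k_pdf(a, p_k))) for a in grid)
        assert diff < 1e-6

    @pytest.mark.parametrize("eps,sigma,c", [(0.54, 0.16, 5.69), (0.01, 0.17, 1.0)])
    def test_normalization(self, eps, sigma, c):
        p = HKParams(eps, sigma, c)
        hi = eps + sigma * math.sqrt(2 * c) * 12 + 1
        # split at the a = eps cusp; modest epsabs keeps runtime sane
        i1, _ = quad(lambda a: hk_pdf(a, p), 0, eps, epsabs=1e-9, limit=80)
        i2, _ = quad(lambda a: hk_pdf(a, p), eps, hi, epsabs=1e-9, limit=160)
        assert i1 + i2 == pytest.approx(1.0, abs=1e-6)

    def test_large_c_approaches_rician(self):
        g, l, c = 0.15, 0.5, 200.0
        sigma = math.sqrt(g * g / c)
        p = HKParams(l, sigma, c)
        grid = np.linspace(1e-3, 1.5, 300)
        diff = np.abs(_hk_pdf_vec(grid, p) - rician_pdf(grid, RicianParams(l, g)))
        assert diff.max() < 1e-2

    def test_zero_amplitude(self):
        assert hk_pdf(0.0, HKParams(0.5, 0.2, 3.0)) == 0.0

    def test_negative_amplitude_rejected(self):
        with pytest.raises(DomainError):
            hk_pdf(-0.2, HKParams(0.5, 0.2, 3.0))

    def test_invalid_tol_rejected(self):
        with pytest.raises(ValueError):
            hk_pdf(0.5, HKParams(0.5, 0.2, 3.0), tol=0.0)

    def test_two_routes_agree(self, reference_hk_params):
        # Bessel-integral quadrature vs compound-representation mixture
        grid = np.array([0.05, 0.2, 0.5, 0.9, 1.4])
        for p in reference_hk_params:
            direct = np.array([hk_pdf(a, p) for a in grid])
            mixture = _hk_pdf_vec(grid, p)
            np.testing.assert_allclose(direct, mixture, atol=2e-6)


class TestNormalizationProperty:
    # one quadrature-based normalization check per model family over a
    # parameter sample (acceptance criterion: +-1e-6 at >= 10 parameter sets)
    @pytest.mark.parametrize(
        "eps,sigma,c",
        [
            (0.01, 0.17, 1.0),
            (0.36, 0.16, 5.61),
            (0.54, 0.16, 5.69),
            (0.69, 0.11, 14.02),
            (0.09, 0.20, 1.10),
            (0.24, 0.26, 100.0),
        ],
    )
    def test_hk_mixture_normalization(self, eps, sigma, c):
        p = HKParams(eps, sigma, c)
        hi = eps + sigma * math.sqrt(2 * c) * 12 + 1
        total, _ = quad(
            lambda a: float(_hk_pdf_vec([a], p)[0]), 0, hi, limit=200, points=[eps]
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("d", [0.11, 0.29, 2.4])
    def test_rayleigh(self, d):
        total, _ = quad(lambda a: rayleigh_pdf(a, RayleighParams(d)), 0, 40 * d)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("l,g", [(0.33, 0.15), (0.69, 0.11), (2.0, 0.5)])
    def test_rician(self, l, g):
        total, _ = quad(lambda a: float(rician_pdf(a, RicianParams(l, g))), 0, l + 30 * g)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("m,a_scale", [(0.87, 7.48), (5.41, 14.89), (2.14, 11.46)])
    def test_k(self, m, a_scale):
        total, _ = quad(lambda a: float(k_pdf(a, KParams(m, a_scale))), 0, 80.0 / a_scale, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestIntensitySnr:
    def test_reference_triples(self):
        assert round(hk_intensity_snr(HKParams(0.01, 0.17, 1.00)), 2) == 0.58
        assert round(hk_intensity_snr(HKParams(0.36, 0.16, 5.61)), 2) == 0.97

    def test_all_reference_cells_two_decimals(self, reference_cells):
        for alpha, rho, eps, sigma, c, snr in reference_cells:
            got = round(hk_intensity_snr(HKParams(eps, sigma, c)), 2)
            assert got == pytest.approx(snr, abs=1e-9), (alpha, rho)

    def test_rayleigh_limit_is_one(self):
        # eps = 0, c -> inf: (2 s^2 c) / (2 s^2 sqrt(2c + c^2)) -> 1
        vals = [hk_intensity_snr(HKParams(0.0, 0.2, c)) for c in (10.0, 1e3, 1e6)]
        assert vals == sorted(vals)
        assert vals[-1] == pytest.approx(1.0, abs=1e-3)

    @given(
        eps=st.floats(0.0, 2.0),
        sigma=st.floats(0.01, 2.0),
        c=st.floats(0.5, 200.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_positive(self, eps, sigma, c):
        assert hk_intensity_snr(HKParams(eps, sigma, c)) > 0


class TestSamplers:
    def test_coherent_dominated_mean(self):
        a = sample("hk", HKParams(10.0, 0.01, 1.0), 1000, seed=11)
        assert abs(a.mean() - 10.0) < 0.01

    def test_mean_intensity_identity(self):
        p = HKParams(0.5, 0.2, 3.0)
        a = sample("hk", p, 20000, seed=12)
        i = a**2
        expect = p.epsilon**2 + 2 * p.sigma**2 * p.c  # = 0.49
        assert abs(i.mean() - expect) < 3 * i.std() / math.sqrt(i.size)

    def test_deterministic_under_seed(self):
        a1 = sample("hk", HKParams(0.5, 0.2, 3.0), 100, seed=5)
        a2 = sample("hk", HKParams(0.5, 0.2, 3.0), 100, seed=5)
        np.testing.assert_array_equal(a1, a2)

    def test_wrong_param_type_rejected(self):
        with pytest.raises(ParameterError):
            sample("hk", RayleighParams(1.0), 10, seed=0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            sample("nakagami", RayleighParams(1.0), 10, seed=0)

    @staticmethod
    def _ks_against_numeric_cdf(a, grid, pdf_vals):
        cdf = np.concatenate([[0.0], np.cumsum(np.diff(grid) * 0.5 * (pdf_vals[1:] + pdf_vals[:-1]))])
        cdf /= cdf[-1]
        return stats.kstest(a, lambda x: np.interp(x, grid, cdf))

    def test_hk_sampler_matches_pdf(self):
        p = HKParams(0.36, 0.16, 5.61)
        a = sample("hk", p, 5000, seed=13)
        grid = np.linspace(0, a.max() * 1.2, 4000)
        res = self._ks_against_numeric_cdf(a, grid, np.exp(hk_log_pdf(grid, p)))
        assert res.pvalue > 0.01

    @pytest.mark.parametrize(
        "model,params",
        [
            ("rayleigh", RayleighParams(0.29)),
            ("rician", RicianParams(0.6, 0.11)),
            ("k", KParams(2.0, 7.5)),
            ("hk", HKParams(0.54, 0.16, 5.69)),
        ],
    )
    def test_sampler_pdf_consistency_all_models(self, model, params):
        a = sample(model, params, 5000, seed=29)
        grid = np.linspace(0, a.max() * 1.2, 4000)
        if model == "rayleigh":
            pdf_vals = rayleigh_pdf(grid, params)
        elif model == "rician":
            pdf_vals = rician_pdf(grid, params)
        elif model == "k":
            pdf_vals = k_pdf(grid, params)
            pdf_vals[0] = 0.0
        else:
            pdf_vals = np.exp(hk_log_pdf(grid, params))
        res = self._ks_against_numeric_cdf(a, grid, np.nan_to_num(pdf_vals))
        assert res.pvalue > 0.01

    def test_monte_carlo_snr_matches_closed_form(self, reference_hk_params):
        # empirical mean(A^2)/std(A^2) vs the closed form, 5+ reference triples
        picked = [reference_hk_params[i] for i in (0, 5, 6, 11, 15, 19)]
        for p in picked:
            a = sample("hk", p, 100_000, seed=hash((p.epsilon, p.c)) % 2**31)
            i = a**2
            emp = i.mean() / i.std()
            assert emp == pytest.approx(hk_intensity_snr(p), rel=0.03), p
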