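"""Closed-form, limit and duality checks of the viscoelastic model library."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfc, gamma

from conftest import gaver_stehfest
from timsom.models import (ViscoModel, derived_params,
                           mittag_leffler, model_G, model_chi, model_creep,
                           model_relaxation)

W = np.logspace(-2, 5, 29)  # rad/s test grid

ALL_MODELS = [
    ViscoModel("newtonian", eta=1e-3),
    ViscoModel("springpot", C_alpha=2.0, alpha=0.4),
    ViscoModel("kelvin_voigt", E=10.0, eta=0.5),
    ViscoModel("maxwell", E=10.0, eta=0.5),
    ViscoModel("fractional_kv", C_alpha=5.0, alpha=0.2, C_beta=0.01,
               beta=0.9),
    ViscoModel("fractional_maxwell", C_alpha=10.0, alpha=0.1, C_beta=1.0,
               beta=0.9),
]


class TestComplexModulus:
    def test_newtonian_closed_form(self):
        m = ViscoModel("newtonian", eta=1e-3)
        G = model_G(m, 2 * math.pi * 625)
        assert G.real == pytest.approx(0.0, abs=1e-15)
        assert G.imag == pytest.approx(1e-3 * 2 * math.pi * 625, rel=1e-12)

    def test_springpot_alpha0_is_spring(self):
        m = ViscoModel("springpot", C_alpha=7.5, alpha=0.0)
        assert np.allclose(m.complex_modulus(W), 7.5)

    def test_fractional_maxwell_limit_matches_classic(self):
        fm = ViscoModel("fractional_maxwell", C_alpha=10.0, alpha=0.0,
                        C_beta=0.5, beta=1.0)
        tau = 0.5 / 10.0
        ref = 10.0 * 1j * W * tau / (1 + 1j * W * tau)
        assert np.allclose(fm.complex_modulus(W), ref, rtol=1e-12)
        # at the crossover frequency G' = G'' = E/2
        G = fm.complex_modulus(1.0 / tau)
        assert G.real == pytest.approx(5.0, rel=1e-12)
        assert G.imag == pytest.approx(5.0, rel=1e-12)

    def test_fractional_kv_limit_matches_classic(self):
        fkv = ViscoModel("fractional_kv", C_alpha=10.0, alpha=0.0,
                         C_beta=0.5, beta=1.0)
        kv = ViscoModel("kelvin_voigt", E=10.0, eta=0.5)
        assert np.allclose(fkv.complex_modulus(W), kv.complex_modulus(W),
                           rtol=1e-12)

    @pytest.mark.parametrize("m", ALL_MODELS, ids=lambda m: m.family)
    def test_passivity(self, m):
        G = m.complex_modulus(W)
        assert np.all(G.real >= -1e-15 * np.abs(G))
        assert np.all(G.imag >= -1e-15 * np.abs(G))

    @pytest.mark.parametrize("m", ALL_MODELS, ids=lambda m: m.family)
    def test_hermitian_symmetry_of_springpot_terms(self, m):
        # chi(-w) = chi*(w) via (i w)^a conjugation; equivalently G' even,
        # G'' odd: conj(G(w)) must equal the modulus built from (-i w)^a
        G = m.complex_modulus(W)
        terms = [c * (-1j * W) ** a for c, a in m.springpots()]
        if m.is_series:
            ref = terms[0] * terms[1] / (terms[0] + terms[1])
        else:
            ref = sum(terms)
        assert np.allclose(np.conj(G), ref, rtol=1e-12)

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(ValueError):
            ALL_MODELS[0].complex_modulus(0.0)


class TestResponse:
    def test_definition(self):
        m = ViscoModel("springpot", C_alpha=1.0, alpha=0.0)  # G = 1 Pa
        chi = model_chi(m, 1.0, 0.5)
        assert chi == pytest.approx(1.0 / (3.0 * math.pi), rel=1e-12)

    @pytest.mark.parametrize("m", ALL_MODELS, ids=lambda m: m.family)
    def test_inverse_of_modulus(self, m):
        chi = m.response(W, 0.5)
        assert np.allclose(chi * m.complex_modulus(W) * 6 * math.pi * 0.5,
                           1.0, rtol=1e-12)

    def test_newtonian_closed_form(self):
        m = ViscoModel("newtonian", eta=1e-3)
        w = 2 * math.pi * 100
        assert m.response(w, 0.5) == pytest.approx(
            -1j / (6 * math.pi * 0.5 * 1e-3 * w), rel=1e-12)


class TestTimeDomain:
    def test_springpot_creep_closed_form(self):
        m = ViscoModel("springpot", C_alpha=1.0, alpha=0.5)
        assert model_creep(m, 1.0) == pytest.approx(1 / gamma(1.5), rel=1e-12)

    def test_newtonian_creep(self):
        m = ViscoModel("newtonian", eta=2.0)
        t = np.array([0.1, 1.0, 7.0])
        assert np.allclose(model_creep(m, t), t / 2.0, rtol=1e-12)

    def test_springpot_creep_relaxation_product(self):
        a = 0.3
        m = ViscoModel("springpot", C_alpha=4.0, alpha=a)
        t = np.logspace(-2, 2, 9)
        prod = model_creep(m, t) * model_relaxation(m, t)
        assert np.allclose(prod, 1.0 / (gamma(1 + a) * gamma(1 - a)),
                           rtol=1e-12)

    def test_fractional_maxwell_creep_is_sum_of_springpots(self):
        fm = ViscoModel("fractional_maxwell", C_alpha=3.0, alpha=0.2,
                        C_beta=0.7, beta=0.8)
        t = np.logspace(-2, 2, 9)
        ref = (t ** 0.2 / (3.0 * gamma(1.2))
               + t ** 0.8 / (0.7 * gamma(1.8)))
        assert np.allclose(fm.creep(t), ref, rtol=1e-12)

    def test_kelvin_voigt_creep_closed_form(self):
        kv = ViscoModel("kelvin_voigt", E=2.0, eta=1.0)
        t = np.linspace(0.05, 3.0, 12)
        assert np.allclose(kv.creep(t), (1 - np.exp(-2.0 * t)) / 2.0,
                           rtol=1e-10)

    def test_fkv_creep_vs_laplace_inversion(self, fkv_cell):
        """J(t) of the fractional KV against an independent numerical
        inversion of 1/(s^2 G(s)) (Gaver-Stehfest), <= 0.5% relative."""
        (ca, al), (cb, be) = fkv_cell.springpots()

        def Jhat(s):
            return 1.0 / (s * (ca * s ** al + cb * s ** be))

        t = np.logspace(-3, 2, 20)
        ours = fkv_cell.creep(t)
        ref = np.array([gaver_stehfest(Jhat, ti) for ti in t])
        assert np.max(np.abs(ours - ref) / np.abs(ref)) < 5e-3

    def test_fm_relaxation_vs_laplace_inversion(self, fm_condensate):
        (ca, al), (cb, be) = fm_condensate.springpots()

        def Ghat(s):
            ga, gb = ca * s ** al, cb * s ** be
            return ga * gb / (ga + gb) / s

        t = np.logspace(-3, 1, 15)
        ours = fm_condensate.relaxation(t)
        ref = np.array([gaver_stehfest(Ghat, ti) for ti in t])
        assert np.max(np.abs(ours - ref) / np.abs(ref)) < 5e-3

    def test_singular_relaxation_rejected(self):
        with pytest.raises(ValueError):
            model_relaxation(ViscoModel("newtonian", eta=1.0), 1.0)

    def test_domain_errors(self):
        m = ViscoModel("springpot", C_alpha=1.0, alpha=0.5)
        with pytest.raises(ValueError):
            model_creep(m, 0.0)
        with pytest.raises(ValueError):
            model_relaxation(m, -1.0)


class TestMittagLeffler:
    def test_exponential_identity(self):
        # E_{1,2}(-x) = (1 - e^-x)/x
        for x in (0.3, 3.0, 30.0, 300.0):
            assert mittag_leffler(1.0, 2.0, -x) == pytest.approx(
                (1 - math.exp(-x)) / x, rel=1e-8)

    def test_erfc_identity(self):
        # E_{1/2,1}(-x) = exp(x^2) erfc(x)
        for x in (0.5, 2.0, 8.0, 25.0):
            ref = math.exp(x * x) * erfc(x)
            assert mittag_leffler(0.5, 1.0, -x) == pytest.approx(
                ref, rel=1e-7)

    def test_positive_argument_rejected(self):
        with pytest.raises(ValueError):
            mittag_leffler(0.5, 1.0, 1.0)


class TestDerivedParams:
    def test_maxwell_exact(self):
        d = derived_params(ViscoModel("maxwell", eta=1.0, E=10.0))
        assert d.tau == pytest.approx(0.1, rel=1e-14)
        assert d.omega_c_rad_s == pytest.approx(10.0, rel=1e-14)
        assert d.omega_c_hz == pytest.approx(10 / (2 * math.pi), rel=1e-14)
        assert d.plateau == pytest.approx(10.0)

    def test_fkv_equal_exponents_no_crossover(self):
        m = ViscoModel("fractional_kv", C_alpha=1.0, alpha=0.4,
                       C_beta=2.0, beta=0.4)
        d = derived_params(m)
        assert not d.has_crossover

    def test_springpot_half_no_crossover(self):
        d = derived_params(ViscoModel("springpot", C_alpha=1.0, alpha=0.5))
        assert not d.has_crossover

    def test_fm_crossover_vs_grid_scan(self):
        m = ViscoModel("fractional_maxwell", C_alpha=1.0, alpha=0.2,
                       C_beta=1.0, beta=0.8)
        d = derived_params(m)
        grid = np.logspace(-6, 9, 2_000_001)
        G = m.complex_modulus(grid)
        i = np.argmin(np.abs(G.real - G.imag) / np.abs(G))
        assert d.omega_c_rad_s == pytest.approx(grid[i], rel=1e-5)


class TestValidationAndSerialization:
    @pytest.mark.parametrize("kwargs", [
        dict(family="fractional_kv", C_alpha=1.0, alpha=0.9, C_beta=1.0,
             beta=0.2),                                   # alpha > beta
        dict(family="springpot", C_alpha=-1.0, alpha=0.5),  # C <= 0
        dict(family="springpot", C_alpha=1.0, alpha=1.5),   # exponent > 1
        dict(family="nonsense", eta=1.0),
    ])
    def test_invalid_models_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ViscoModel(**kwargs)

    @pytest.mark.parametrize("m", ALL_MODELS, ids=lambda m: m.family)
    def test_json_roundtrip(self, m):
        d = m.to_dict()
        assert d["units"] == "pN-um-s"
        assert ViscoModel.from_dict(d) == m


@settings(deadline=None, max_examples=25, derandomize=True)
@given(c=st.floats(1e-3, 1e3), a=st.floats(0.0, 1.0),
       w=st.floats(1e-3, 1e6))
def test_springpot_modulus_polar_form(c, a, w):
    """|G| = C w^a and arg G = pi a / 2 for any springpot."""
    G = ViscoModel("springpot", C_alpha=c, alpha=a).complex_modulus(w)
    assert abs(G) == pytest.approx(c * w ** a, rel=1e-10)
    assert math.atan2(G.imag, G.real) == pytest.approx(
        math.pi * a / 2, abs=1e-10)
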