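"""Fundamental extraction, the first-harmonic map and its inversion."""

import math

import numpy as np
import pytest

from timsom.models import ViscoModel
from timsom.spectra import (ResponseSpectrum, chi_active_passive,
                            chi_t_from_signals, extract_fundamental,
                            fha_compensate, fha_forward, peak_snr)
from timsom.tsim import InterleavedTrace

WT = 2 * math.pi * 12_500.0


def make_trace(cfg, f, V1_fn, V2_fn, n_cycles=400):
    n = np.arange(n_cycles)
    t1 = n * cfg.cycle + cfg.sample_offset
    t2 = t1 + cfg.cycle / 2
    return InterleavedTrace(drive_freq=f, t1=t1, V1=V1_fn(t1),
                            t2=t2, V2=V2_fn(t2), config=cfg)


def grid_below_nyquist(n=21):
    w = 2 * math.pi * np.logspace(-1, math.log10(6249.0), n)
    return w


class TestExtractFundamental:
    @pytest.mark.parametrize("method", ["regression", "projection"])
    def test_pure_cosine(self, cfg, method):
        f = 125.0
        w = 2 * math.pi * f
        tr = make_trace(cfg, f, lambda t: np.cos(w * t),
                        lambda t: np.zeros_like(t))
        v1, v2 = extract_fundamental(tr, method=method)
        assert v1 == pytest.approx(1.0 + 0j, abs=1e-9)
        assert abs(v2) < 1e-9

    @pytest.mark.parametrize("method", ["regression", "projection"])
    def test_phase_shift_rotates_output(self, cfg, method):
        f, phi = 125.0, 0.7
        w = 2 * math.pi * f
        tr0 = make_trace(cfg, f, lambda t: np.cos(w * t),
                         lambda t: np.zeros_like(t))
        tr1 = make_trace(cfg, f, lambda t: np.cos(w * t + phi),
                         lambda t: np.zeros_like(t))
        v0, _ = extract_fundamental(tr0, method=method)
        v1, _ = extract_fundamental(tr1, method=method)
        assert v1 / v0 == pytest.approx(np.exp(1j * phi), abs=1e-9)

    def test_immobile_bead_ratio_is_zero(self, cfg):
        f = 125.0
        w = 2 * math.pi * f
        tr = make_trace(cfg, f, lambda t: cfg.k * 0.1 * np.sin(w * t),
                        lambda t: np.zeros_like(t))
        v1, v2 = extract_fundamental(tr)
        assert chi_t_from_signals(v1, v2, cfg.k) == pytest.approx(0, abs=1e-12)

    def test_too_short_trace_raises(self, cfg):
        tr = make_trace(cfg, 10.0, np.cos, np.sin, n_cycles=20)
        with pytest.raises(ValueError, match="shorter"):
            extract_fundamental(tr)

    def test_non_integer_periods_rejected_without_trim(self, cfg):
        tr = make_trace(cfg, 110.0, np.cos, np.sin, n_cycles=400)
        with pytest.raises(ValueError, match="trim"):
            extract_fundamental(tr, trim=False)

    def test_regression_removes_harmonic_leakage(self, cfg):
        # strongly non-sinusoidal periodic signal at an incommensurate
        # frequency: regression must beat the plain projection
        f = 15.85
        w = 2 * math.pi * f

        def v(t):
            return np.cos(w * t) + 0.5 * np.sin(2 * w * t) \
                + 0.3 * np.cos(3 * w * t)

        tr = make_trace(cfg, f, v, lambda t: np.zeros_like(t),
                        n_cycles=3200)
        vr, _ = extract_fundamental(tr, method="regression")
        vp, _ = extract_fundamental(tr, method="projection")
        assert abs(vr - 1.0) < 1e-6
        assert abs(vr - 1.0) < abs(vp - 1.0)


class TestChiTAlgebra:
    def test_zero_v2(self):
        assert chi_t_from_signals(1.0 + 0j, 0j, 50.0) == 0

    def test_v1_minus_two_v2(self):
        # V1 = -2 V2  =>  chi_t = 2/k
        assert chi_t_from_signals(-2.0 + 0j, 1.0 + 0j, 50.0) == \
            pytest.approx(2 / 50.0)

    def test_singular_denominator(self):
        with pytest.raises(ZeroDivisionError):
            chi_t_from_signals(1.0 + 0j, -1.0 + 0j, 50.0)


class TestChiActivePassive:
    def test_zero_stiffness_identity(self):
        chi = 0.3 - 0.1j
        assert chi_active_passive(chi, 0.0) == chi

    def test_direct_substitution(self):
        k = 50.0
        chi = (1 - 1j) / k
        assert chi_active_passive(chi, k) == pytest.approx(
            (1 - 1j) / (k * (2 - 1j)))

    def test_stiff_material_limit(self):
        k = 50.0
        assert chi_active_passive(1e9 / k, k) == pytest.approx(1 / k,
                                                               rel=1e-8)


class TestFhaForward:
    def test_constant_real_chi_gives_zero(self):
        w = grid_below_nyquist()
        chit = fha_forward(lambda v: np.full_like(np.asarray(v, float),
                                                  0.02, dtype=complex),
                           w, WT, 50.0)
        assert np.max(np.abs(chit)) < 1e-10 * 0.02

    def test_weak_trap_limit(self, water):
        w = 2 * math.pi * 100.0
        chi_fn = lambda v: water.response(v, 0.5)
        chit = fha_forward(chi_fn, w, WT, 1e-6)
        chi1 = 0.5 * (chi_fn(WT + w) + np.conj(chi_fn(WT - w)))
        assert chit == pytest.approx(chi_fn(w) - chi1, rel=1e-6)

    def test_hermitian_negative_frequency_handling(self, fkv_cell):
        # chi_-* must equal chi evaluated at -(w_t - w) by conjugation
        w = 2 * math.pi * 400.0
        chi_fn = lambda v: fkv_cell.response(v, 0.5)
        chit = fha_forward(chi_fn, w, WT, 50.0)
        chi, chip = chi_fn(w), chi_fn(WT + w)
        chim = np.conj(chi_fn(WT - w))
        chi1, P = 0.5 * (chip + chim), chip * chim
        k = 50.0
        ref = (chi - chi1 + k * (chi * chi1 - P)) / (1 + 2 * k * chi1
                                                     + k * k * P)
        assert chit == pytest.approx(ref, rel=1e-12)


class TestCompensation:
    def test_round_trip_solid_hint(self, fkv_cell):
        k = 50.0
        w = 2 * math.pi * np.logspace(-1, math.log10(1250), 15)
        chi_fn = lambda v: fkv_cell.response(v, 0.5)
        dev = ResponseSpectrum(omega=w, chi=fha_forward(chi_fn, w, WT, k),
                               k=k, a=0.5, omega_t=WT, stage="deviated")
        comp, diag = fha_compensate(dev, "viscoelastic_solid")
        assert diag["converged"]
        err = np.abs(comp.chi - chi_fn(w)) / np.abs(chi_fn(w))
        assert np.max(err) < 0.01

    def test_weak_trap_near_identity(self):
        # k|chi| << 1 and chi decaying at high frequency: the deviation is
        # negligible and compensation barely changes the spectrum
        visc = ViscoModel("newtonian", eta=10.0)
        w = 2 * math.pi * np.logspace(0, 2, 12)
        chi_fn = lambda v: visc.response(v, 0.5)
        assert np.max(50.0 * np.abs(chi_fn(w))) < 0.1
        chit = fha_forward(chi_fn, w, WT, 50.0)
        assert np.max(np.abs(chit / chi_fn(w) - 1)) < 1e-3
        dev = ResponseSpectrum(omega=w, chi=chit, k=50.0, a=0.5,
                               omega_t=WT)
        comp, _ = fha_compensate(dev, "viscoelastic_liquid")
        assert np.max(np.abs(comp.chi / chit - 1)) < 1e-3

    def test_idempotence(self, fkv_cell):
        k = 50.0
        w = 2 * math.pi * np.logspace(-1, 3, 15)
        chi_fn = lambda v: fkv_cell.response(v, 0.5)
        dev = ResponseSpectrum(omega=w, chi=fha_forward(chi_fn, w, WT, k),
                               k=k, a=0.5, omega_t=WT)
        once, _ = fha_compensate(dev, "viscoelastic_solid")
        twice, _ = fha_compensate(once, "viscoelastic_solid")
        assert np.max(np.abs(twice.chi - once.chi)
                      / np.abs(once.chi)) < 1e-4

    def test_elastic_dominance_deviation_monotone(self):
        """For a nearly elastic solid in a stiff trap the time-shared
        measurement underestimates |chi| at high frequency, increasingly
        so over the upper decade."""
        m = ViscoModel("fractional_kv", C_alpha=2.0, alpha=0.02,
                       C_beta=1e-5, beta=0.9)
        w = 2 * math.pi * np.logspace(math.log10(125), math.log10(1250), 8)
        chi_fn = lambda v: m.response(v, 0.5)
        chit = fha_forward(chi_fn, w, WT, 50.0)
        ratio = np.abs(chit) / np.abs(chi_fn(w))
        assert np.all(ratio < 1.0)
        assert np.all(np.diff(ratio) < 0)

    def test_unknown_hint_propagates(self, fkv_cell):
        w = 2 * math.pi * np.logspace(0, 3, 10)
        dev = ResponseSpectrum(omega=w,
                               chi=fkv_cell.response(w, 0.5),
                               k=50.0, a=0.5, omega_t=WT)
        with pytest.raises(ValueError, match="nonsense"):
            fha_compensate(dev, "nonsense")


class TestPeakSnr:
    def test_noiseless_trace_far_above_floor(self, cfg):
        f = 125.0
        w = 2 * math.pi * f
        tr = make_trace(cfg, f, lambda t: np.cos(w * t),
                        lambda t: 2.0 * np.cos(w * t + 0.3))
        assert peak_snr(tr, w) > 100.0

    def test_amplitude_scaling_with_fixed_noise(self, cfg):
        f = 125.0
        w = 2 * math.pi * f
        rng = np.random.default_rng(7)
        noise = rng.normal(0, 0.1, 400)
        r = []
        for amp in (1.0, 10.0):
            tr = make_trace(cfg, f, lambda t: np.cos(w * t),
                            lambda t: amp * np.cos(w * t) + noise)
            r.append(peak_snr(tr, w))
        assert r[1] / r[0] == pytest.approx(10.0, rel=0.05)

    def test_white_noise_ratio_near_unity(self, cfg):
        f = 125.0
        w = 2 * math.pi * f
        ratios = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tr = make_trace(cfg, f, lambda t: np.zeros_like(t),
                            lambda t: rng.normal(0, 1, len(t)))
            ratios.append(peak_snr(tr, w))
        assert 0.5 < np.median(ratios) < 2.0

    def test_short_trace_rejected(self, cfg):
        tr = make_trace(cfg, 125.0, np.cos, np.sin, n_cycles=8)
        with pytest.raises(ValueError):
            peak_snr(tr, 2 * math.pi * 125.0)


class TestResponseSpectrum:
    def test_chi_G_consistency(self, fkv_cell):
        w = 2 * math.pi * np.logspace(0, 3, 10)
        spec = ResponseSpectrum(omega=w, chi=fkv_cell.response(w, 0.5),
                                k=50.0, a=0.5, omega_t=WT)
        assert np.allclose(spec.G, fkv_cell.complex_modulus(w), rtol=1e-12)
        assert np.allclose(1 / (6 * math.pi * 0.5 * spec.chi), spec.G)

    def test_decreasing_omega_rejected(self):
        with pytest.raises(ValueError):
            ResponseSpectrum(omega=np.array([2.0, 1.0]),
                             chi=np.array([1 + 0j, 1 + 0j]),
                             k=50.0, a=0.5, omega_t=WT)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ResponseSpectrum(omega=np.array([WT]),
                             chi=np.array([1 + 0j]),
                             k=50.0, a=0.5, omega_t=WT)
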