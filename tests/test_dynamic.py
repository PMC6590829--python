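"""Quasielastic models: analytic widths, sum rules and the FT bridge."""

import numpy as np
import pytest

from scatterfit.dynamic import (bin_channels, confined_w, convolve_w, hwhm,
                                intermediate_scattering, lorentzian_w,
                                rotational_diffusion_w, sphere_eigenvalues,
                                time_to_frequency)


def wgrid(wmax, n=4001):
    return np.linspace(-wmax, wmax, n)


class TestTimeDomain:
    def test_normalization_at_t0(self):
        for model in ("diffusion", "stretched", "jumpdiffusion"):
            c = intermediate_scattering(model, [0.0, 1.0], q=1.0, D=0.5)
            assert c.Y[0] == 1.0

    def test_stretched_beta1_is_exponential(self):
        t = np.linspace(0, 10, 50)
        a = intermediate_scattering("stretched", t, q=1.2, D=0.3, beta=1.0)
        b = intermediate_scattering("diffusion", t, q=1.2, D=0.3)
        np.testing.assert_allclose(a.Y, b.Y, rtol=1e-14)

    def test_jump_diffusion_free_limit(self):
        t = np.linspace(0, 5, 20)
        a = intermediate_scattering("jumpdiffusion", t, q=1.0, D=0.4, tau=1e-12)
        b = intermediate_scattering("diffusion", t, q=1.0, D=0.4)
        np.testing.assert_allclose(a.Y, b.Y, atol=1e-10)

    def test_monotone_decay_and_validation(self):
        t = np.linspace(0, 20, 200)
        c = intermediate_scattering("stretched", t, q=1.0, D=0.2, beta=0.6)
        assert np.all(np.diff(c.Y) <= 0)
        with pytest.raises(ValueError):
            intermediate_scattering("stretched", t, 1.0, beta=2.5)


class TestLorentzian:
    def test_transdiff_hwhm_exact(self):
        q, D = 1.3, 0.7
        s = lorentzian_w("transdiff", wgrid(60, 40001), q, D)
        G = D * q**2
        assert s.attributes["hwhm"] == G
        assert hwhm(s) == pytest.approx(G, abs=2 * 60 / 40000)

    def test_jumpdiff_saturates(self):
        D, tau = 1.0, 0.5
        q = np.sqrt(100.0 / (D * tau))  # D q^2 tau = 100
        s = lorentzian_w("jumpdiff", wgrid(20, 2001), q, D, tau)
        sat = 1.0 / tau
        assert abs(s.attributes["hwhm"] - sat) / sat < 1.5e-2

    def test_unit_area(self):
        s = lorentzian_w("transdiff", wgrid(100.0, 200001), q=1.0, D=1.0)
        area = np.trapezoid(s.Y, s.X)
        assert area == pytest.approx(1.0, abs=1e-2)
        # +-100 Gamma leaves ~2/(pi*100) in the wings
        assert area == pytest.approx(1 - 2 / (np.pi * 100), abs=1e-3)


class TestConfined:
    def test_eigenvalues_match_known_roots(self):
        x = sphere_eigenvalues(2, 3)
        # l=0: roots of j0' = -j1: tan x = x
        np.testing.assert_allclose(x[0, :2], [4.493409, 7.725252], atol=1e-5)
        # l=1: first root 2.081576 (lowest confinement mode)
        assert x[1, 0] == pytest.approx(2.081576, abs=1e-5)

    def test_eisf_limits(self):
        w = wgrid(50, 2001)
        s = confined_w("sphere", w, q=1e-6, D=1.0, R=1.0)
        assert s.attributes["eisf"] == pytest.approx(1.0, abs=1e-9)
        h = confined_w("harmonic", w, q=1e-6, u2=0.3, tau=1.0)
        assert h.attributes["eisf"] == pytest.approx(1.0, abs=1e-9)

    def test_sphere_amplitude_completeness(self):
        from scatterfit.dynamic import _sphere_amplitudes
        from scipy import special
        y = 3.0
        eisf = (3 * special.spherical_jn(1, y) / y) ** 2
        _, A = _sphere_amplitudes(y, 7, 7)
        assert eisf + A.sum() == pytest.approx(1.0, abs=1e-3)

    def test_sphere_low_q_plateau(self):
        D, R = 1.0, 1.0
        w = wgrid(40, 160001)
        s = confined_w("sphere", w, q=0.1 / R, D=D, R=R, l_max=5, n_max=5)
        width = hwhm(s, exclude_elastic=True)
        assert width == pytest.approx(4.33296 * D / R**2, rel=0.02)

    def test_harmonic_area_and_eisf(self):
        q, u2 = 1.5, 0.2
        w = wgrid(400, 80001)
        s = confined_w("harmonic", w, q=q, u2=u2, tau=0.5)
        assert s.attributes["eisf"] == pytest.approx(np.exp(-q**2 * u2))
        assert np.trapezoid(s.Y, s.X) == pytest.approx(1.0, abs=1e-2)

    def test_cutoff_validation(self):
        with pytest.raises(ValueError):
            confined_w("sphere", wgrid(10), q=1.0, l_max=2)


class TestRotational:
    def test_truncated_sum_rule(self):
        s = rotational_diffusion_w(wgrid(100, 2001), q=2.0, R=1.0, Dr=1.0,
                                   l_max=10)
        assert s.attributes["sum_rule"] >= 0.999

    def test_pure_elastic_at_low_q(self):
        w = wgrid(10, 2001)
        s = rotational_diffusion_w(w, q=1e-8, R=1.0, Dr=1.0)
        ic = np.argmin(np.abs(w))
        off = np.delete(s.Y, ic)
        assert s.attributes["eisf"] == pytest.approx(1.0)
        assert np.max(off) < 1e-10

    def test_small_qr_width_twice_dr(self):
        Dr = 0.8
        w = wgrid(20, 80001)
        s = rotational_diffusion_w(w, q=0.3, R=1.0, Dr=Dr, l_max=12)
        width = hwhm(s, exclude_elastic=True)
        assert width == pytest.approx(2 * Dr, rel=0.05)


class TestFTBridge:
    def test_exponential_gives_lorentzian_width(self):
        G = 2.0
        w = wgrid(60, 12001)
        s = time_to_frequency(lambda t: np.exp(-G * t), w, resolution=0.0)
        assert hwhm(s) == pytest.approx(G, abs=2 * (w[1] - w[0]))

    def test_constant_gives_resolution_function(self):
        sig = 1.5
        w = wgrid(12, 4001)
        s = time_to_frequency(lambda t: np.ones_like(t), w, resolution=sig)
        gauss = np.exp(-0.5 * (w / sig) ** 2) / (sig * np.sqrt(2 * np.pi))
        np.testing.assert_allclose(s.Y, gauss, atol=1e-6)

    def test_area_preserved(self):
        G, W = 1.7, 80.0
        w = wgrid(W, 20001)
        s = time_to_frequency(lambda t: np.exp(-G * t), w, resolution=0.5)
        # the analytic in-window mass of the Lorentzian line
        expected = 2 / np.pi * np.arctan(W / G)
        assert np.trapezoid(s.Y, w) == pytest.approx(expected, abs=2e-3)

    @pytest.mark.parametrize("model,params", [
        ("transdiff", {"D": 0.5, "tau": 0.0}),
        ("jumpdiff", {"D": 0.5, "tau": 0.8}),
    ])
    def test_time_vs_frequency_hwhm_over_q_scan(self, model, params):
        """Fourier-transformed time-domain diffusion models agree with the
        frequency-domain Lorentzians across a q scan."""
        D, tau = params["D"], params["tau"]
        for q in (0.2, 0.7, 1.2, 2.0):
            G = D * q**2 / (1 + D * q**2 * tau) if model == "jumpdiff" else D * q**2
            w = np.linspace(-30 * G, 30 * G, 8001)
            tmodel = "jumpdiffusion" if model == "jumpdiff" else "diffusion"
            def I(t):
                return intermediate_scattering(tmodel, t, q=q, D=D, tau=tau).Y
            ft = time_to_frequency(I, w, resolution=0.0)
            direct = lorentzian_w(model, w, q, D, tau)
            assert hwhm(ft) == pytest.approx(hwhm(direct), rel=0.02)

    def test_accepts_timecurve_dataset(self):
        t = np.linspace(0, 40, 4000)
        ds = intermediate_scattering("diffusion", t, q=1.0, D=1.0)
        w = wgrid(30, 4001)
        s = time_to_frequency(ds, w, resolution=0.0, t_max=40.0)
        assert s.attributes["q"] == 1.0
        assert hwhm(s) == pytest.approx(1.0, rel=0.05)

    def test_leak_warning(self):
        w = wgrid(5, 801)
        with pytest.warns(UserWarning, match="leak"):
            time_to_frequency(lambda t: np.exp(-1e-4 * t), w, resolution=0.0,
                              t_max=10.0)


class TestSpectralAlgebra:
    def test_convolution_with_center_spike_is_identity(self):
        w = wgrid(30, 3001)
        dw = w[1] - w[0]
        a = lorentzian_w("transdiff", w, q=1.0, D=1.0)
        spike = a.copy()
        spike.data[:, 1] = 0.0
        spike.data[np.argmin(np.abs(w)), 1] = 1.0 / dw
        out = convolve_w(a, spike)
        np.testing.assert_allclose(out.Y, a.Y, rtol=1e-12)

    def test_lorentzian_widths_add(self):
        w = wgrid(150, 30001)
        a = lorentzian_w("transdiff", w, q=1.0, D=1.0)     # G = 1
        b = lorentzian_w("transdiff", w, q=1.0, D=2.5)     # G = 2.5
        out = convolve_w(a, b)
        assert hwhm(out) == pytest.approx(3.5, rel=0.01)

    def test_areas_multiply(self):
        w = wgrid(200, 20001)
        a = lorentzian_w("transdiff", w, q=1.0, D=1.0)
        b = lorentzian_w("transdiff", w, q=1.0, D=0.5)
        area = np.trapezoid(convolve_w(a, b).Y, w)
        aa = np.trapezoid(a.Y, w) * np.trapezoid(b.Y, w)
        assert area == pytest.approx(aa, abs=1e-3)

    def test_associative(self):
        w = wgrid(100, 8001)
        a = lorentzian_w("transdiff", w, 1.0, 1.0)
        b = lorentzian_w("transdiff", w, 1.0, 0.6)
        c = lorentzian_w("transdiff", w, 1.0, 0.3)
        left = convolve_w(convolve_w(a, b), c).Y
        right = convolve_w(a, convolve_w(b, c)).Y
        # edge bins feel the finite window; the physical center does not
        mid = slice(len(left) // 4, 3 * len(left) // 4)
        np.testing.assert_allclose(left[mid], right[mid], atol=1e-6)

    def test_composite_with_zero_fraction_reduces(self):
        """trans x rot x [(1-f) + f harmonic] collapses to trans x rot at f=0."""
        w = wgrid(60, 6001)
        dw = w[1] - w[0]
        trans = lorentzian_w("transdiff", w, q=1.0, D=0.8)
        rot = rotational_diffusion_w(w, q=1.0, R=1.0, Dr=0.5)
        harm = confined_w("harmonic", w, q=1.0, u2=0.2, tau=0.4)
        f = 0.0
        mix = harm.copy()
        mix.data[:, 1] = f * harm.Y
        mix.data[np.argmin(np.abs(w)), 1] += (1 - f) / dw
        total = convolve_w(convolve_w(trans, rot), mix)
        plain = convolve_w(trans, rot)
        np.testing.assert_allclose(total.Y, plain.Y, rtol=1e-10)

    def test_grid_mismatch_rejected(self):
        a = lorentzian_w("transdiff", wgrid(10, 101), 1.0, 1.0)
        b = lorentzian_w("transdiff", wgrid(12, 101), 1.0, 1.0)
        with pytest.raises(ValueError):
            convolve_w(a, b)


class TestBinning:
    def test_grid_matching_edges_identity(self):
        w = wgrid(10, 201)
        s = lorentzian_w("transdiff", w, 1.0, 1.0)
        dw = w[1] - w[0]
        edges = np.concatenate([w - dw / 2, [w[-1] + dw / 2]])
        out = bin_channels(s, edges)
        np.testing.assert_allclose(out.Y, s.Y)
        np.testing.assert_allclose(out.X, s.X, atol=1e-12)

    def test_constant_spectrum_unchanged(self):
        w = wgrid(5, 101)
        from scatterfit.datacore import DataSet
        s = DataSet(np.column_stack([w, np.full_like(w, 3.3)]))
        out = bin_channels(s, np.linspace(-5, 5, 11))
        np.testing.assert_allclose(out.Y, 3.3)

    def test_downbinning_conserves_integral(self):
        w = wgrid(40, 4001)
        s = lorentzian_w("transdiff", w, 1.0, 1.0)
        edges = w[::2]
        out = bin_channels(s, edges)
        assert len(out.X) == pytest.approx(len(w) // 2, abs=2)
        i1 = np.trapezoid(s.Y, s.X)
        i2 = np.trapezoid(out.Y, out.X)
        assert i2 == pytest.approx(i1, abs=1e-3)

    def test_empty_channel_warning(self):
        w = wgrid(5, 101)
        s = lorentzian_w("transdiff", w, 1.0, 1.0)
        with pytest.warns(UserWarning, match="empty"):
            bin_channels(s, [-20.0, -10.0, 0.0, 10.0])


class TestHWHM:
    def test_exact_lorentzian(self):
        w = wgrid(30, 60001)
        s = lorentzian_w("transdiff", w, 1.0, 1.0)
        assert hwhm(s) == pytest.approx(1.0, abs=w[1] - w[0])

    def test_gaussian_width(self):
        sig = 2.0
        w = wgrid(15, 30001)
        from scatterfit.datacore import DataSet
        s = DataSet(np.column_stack([w, np.exp(-0.5 * (w / sig) ** 2)]))
        assert hwhm(s) == pytest.approx(np.sqrt(2 * np.log(2)) * sig, rel=5e-3)

    def test_first_order_grid_convergence(self):
        from scatterfit.datacore import DataSet
        def err(n):
            w = wgrid(9.73, n)
            s = DataSet(np.column_stack([w, 1.0 / (1.0 + w**2)]))
            return abs(hwhm(s) - 1.0)
        # linear interpolation of the crossing: error drops with the step
        assert err(8001) < err(201)

    def test_no_crossing_error(self):
        from scatterfit.datacore import DataSet
        w = wgrid(0.1, 101)
        s = DataSet(np.column_stack([w, 1.0 / (1.0 + w**2)]))
        with pytest.raises(ValueError, match="crossing"):
            hwhm(s)
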