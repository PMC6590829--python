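"""Fluid and crystal structure factors against closed forms and limits."""

import numpy as np
import pytest

from scatterfit.cloudscattering import build_lattice_cloud, cloud_intensity, \
    fibonacci_sphere
from scatterfit.structurefactor import (lattice_sf, py_hard_sphere,
                                        reciprocal_peaks, rmsa, rmsa_roots,
                                        sq_to_gr, sticky_hard_sphere,
                                        tau_critical)


def wertheim_sq(q, R, eta):
    """Independent oracle: Wertheim direct-correlation closed form."""
    x = np.asarray(q) * 2 * R
    al = (1 + 2 * eta) ** 2 / (1 - eta) ** 4
    be = -6 * eta * (1 + eta / 2) ** 2 / (1 - eta) ** 4
    ga = eta * al / 2
    f1 = (np.sin(x) - x * np.cos(x)) / x**3
    f2 = (2 * x * np.sin(x) + (2 - x**2) * np.cos(x) - 2) / x**4
    f3 = (-(x**4) * np.cos(x)
          + 4 * ((3 * x**2 - 6) * np.cos(x) + (x**3 - 6 * x) * np.sin(x) + 6)) / x**6
    nc = -24 * eta * (al * f1 + be * f2 + ga * f3)
    return 1.0 / (1.0 - nc)


class TestPercusYevick:
    @pytest.mark.parametrize("phi", [0.1, 0.2, 0.3, 0.4])
    def test_compressibility_limit(self, phi):
        S0 = py_hard_sphere(np.array([1e-7]), R=1.0, phi=phi).Y[0]
        assert S0 == pytest.approx((1 - phi) ** 4 / (1 + 2 * phi) ** 2, abs=1e-4)

    def test_ideal_gas_limit(self):
        q = np.linspace(0.1, 10, 50)
        np.testing.assert_array_equal(py_hard_sphere(q, 1.0, 0.0).Y, 1.0)

    def test_matches_wertheim_closed_form(self):
        q = np.linspace(0.2, 20, 400)
        for phi in (0.15, 0.35):
            np.testing.assert_allclose(py_hard_sphere(q, 1.2, phi).Y,
                                       wertheim_sq(q, 1.2, phi), atol=1e-12)

    def test_peak_above_one_at_phi_04(self):
        R = 1.0
        q = np.linspace(0.05, 8.0, 2000)
        S = py_hard_sphere(q, R, 0.4).Y
        i = np.argmax(S)
        assert S[i] > 1.0
        assert 2.5 < q[i] * 2 * R < 2 * np.pi + 1.0

    def test_large_q_limit(self):
        S = py_hard_sphere(np.linspace(150, 200, 300), 1.0, 0.4).Y
        assert np.max(np.abs(S - 1)) < 1e-3

    def test_phi_out_of_range(self):
        with pytest.raises(ValueError):
            py_hard_sphere([0.1], 1.0, 0.8)


class TestStickyHardSphere:
    def test_tau_infinity_reduces_to_py(self):
        q = np.linspace(0.05, 15, 300)
        a = sticky_hard_sphere(q, 1.0, 0.25, tau=1e9).Y
        b = py_hard_sphere(q, 1.0, 0.25).Y
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_stickiness_raises_compressibility(self):
        q0 = np.array([1e-7])
        vals = [sticky_hard_sphere(q0, 1.0, 0.2, tau=t).Y[0]
                for t in (10.0, 2.0, 1.0, 0.5)]
        assert np.all(np.diff(vals) > 0)

    def test_low_density_virial_oracle(self):
        # S(0) ~ 1 - 8 phi + 2 phi / tau from the adhesive second virial
        phi, tau = 0.005, 0.7
        S0 = sticky_hard_sphere(np.array([1e-7]), 1.0, phi, tau).Y[0]
        assert S0 == pytest.approx(1 - 8 * phi + 2 * phi / tau, abs=5e-4)

    def test_large_q_limit(self):
        # the adhesive surface shell makes S-1 ring with a 1/q envelope,
        # so the asymptote needs a much larger q than plain hard spheres
        S = sticky_hard_sphere(np.linspace(1500, 1600, 300), 1.0, 0.3, 5.0).Y
        assert np.max(np.abs(S - 1)) < 1e-3

    def test_two_phase_region_rejected(self):
        tc = tau_critical(0.3)
        with pytest.raises(ValueError, match="two-phase"):
            sticky_hard_sphere([0.1], 1.0, 0.3, tau=0.9 * tc)


class TestRMSA:
    def test_uncharged_limit_is_py(self):
        q = np.linspace(0.05, 12, 200)
        a = rmsa(q, R=1.0, phi=0.3, gamma=0.0, ak=2.0).Y
        b = py_hard_sphere(q, 1.0, 0.3).Y
        np.testing.assert_allclose(a, b, atol=1e-4)

    def test_tiny_gamma_continuous_with_py(self):
        q = np.linspace(0.05, 12, 200)
        a = rmsa(q, R=1.0, phi=0.3, gamma=1e-7, ak=2.0).Y
        b = py_hard_sphere(q, 1.0, 0.3).Y
        np.testing.assert_allclose(a, b, atol=1e-4)

    def test_fully_screened_limit_near_py(self):
        q = np.linspace(0.05, 12, 150)
        a = rmsa(q, R=1.0, phi=0.35, gamma=0.05, ak=50.0).Y
        b = py_hard_sphere(q, 1.0, 0.35).Y
        assert np.max(np.abs(a - b)) < 0.01

    @pytest.mark.parametrize("ak", [0.1, 1.0, 8.0, 30.0, 58.0])
    def test_headline_sweep_physical_solution(self, ak):
        """Contact potential 3 kT, phi=0.4, R=3.1: a physical solution with
        a clean hard core must come back across the whole screening range."""
        R = 3.1
        curve = rmsa(np.linspace(0.01, 3.0, 50), R=R, phi=0.4, gamma=3.0, ak=ak)
        assert curve.attributes["n_real_roots"] >= 1
        # evaluate the core violation through the public g(r) transform
        q = np.linspace(1e-3, 2000.0 / (2 * R), 100000)
        S = rmsa(q, R=R, phi=0.4, gamma=3.0, ak=ak)
        n = 0.4 / (4 / 3 * np.pi * R**3)
        r = np.linspace(0.1 * R, 0.9 * 2 * R, 60)
        g = sq_to_gr(S, n, r)
        assert np.max(np.abs(g.Y)) < 0.02

    def test_selected_root_beats_rejected_roots(self):
        rng = np.random.default_rng(42)
        for _ in range(6):
            eta = rng.uniform(0.1, 0.45)
            gamma = rng.uniform(0.5, 8.0)
            z = rng.uniform(0.3, 30.0)
            cands = rmsa_roots(eta, gamma, z)
            best = cands[0]["score"]
            for other in cands[1:]:
                assert best <= other["score"] + 1e-12

    def test_repulsion_lowers_compressibility(self):
        q0 = np.array([1e-6])
        vals = [rmsa(q0, 1.0, 0.3, gamma=g, ak=2.0).Y[0]
                for g in (0.0, 1.0, 3.0, 8.0)]
        assert np.all(np.diff(vals) < 0)

    def test_rescaling_reported_and_contact_fixed(self):
        c = rmsa(np.linspace(0.1, 5, 20), R=1.0, phi=0.08, gamma=6.0, ak=1.5)
        assert c.attributes["rescaled"] == 1.0
        assert c.attributes["phi_effective"] > 0.08
        assert c.attributes["contact"] >= -1e-3
        assert np.all(c.Y > 0)

    def test_large_q_limit(self):
        S = rmsa(np.linspace(150, 200, 200), 1.0, 0.3, 3.0, 2.0).Y
        assert np.max(np.abs(S - 1)) < 1e-3

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            rmsa([0.1], 1.0, 0.6, 1.0, 1.0)
        with pytest.raises(ValueError):
            rmsa([0.1], 1.0, 0.3, -1.0, 1.0)


class TestSqToGr:
    def test_ideal_gas_identity(self):
        from scatterfit.datacore import DataSet
        q = np.linspace(1e-3, 50, 5000)
        S = DataSet(np.column_stack([q, np.ones_like(q)]))
        g = sq_to_gr(S, n=0.5, r_grid=np.linspace(0.5, 5, 20))
        np.testing.assert_allclose(g.Y, 1.0, atol=1e-12)

    def test_py_hard_core_and_asymptote(self):
        R, phi = 1.0, 0.3
        q = np.linspace(1e-3, 700.0, 140000)
        S = py_hard_sphere(q, R, phi)
        n = phi / (4 / 3 * np.pi * R**3)
        r_in = np.linspace(0.2, 1.8 * R, 40)
        g_in = sq_to_gr(S, n, r_in)
        assert np.max(np.abs(g_in.Y)) < 0.05
        r_far = np.linspace(9.5 * R, 10.5 * R, 11)
        g_far = sq_to_gr(S, n, r_far)
        assert np.max(np.abs(g_far.Y - 1)) < 0.02

    def test_qmax_refinement_converges(self):
        R, phi = 1.0, 0.25
        n = phi / (4 / 3 * np.pi * R**3)
        r = np.linspace(3.0, 6.0, 30)
        g1 = sq_to_gr(py_hard_sphere(np.linspace(1e-3, 300, 60000), R, phi), n, r)
        g2 = sq_to_gr(py_hard_sphere(np.linspace(1e-3, 600, 120000), R, phi), n, r)
        assert np.max(np.abs(g1.Y - g2.Y)) < 0.01

    def test_truncation_warning(self):
        q = np.linspace(1e-3, 3.0, 500)
        S = py_hard_sphere(q, 1.0, 0.4)
        with pytest.warns(UserWarning, match="qmax"):
            sq_to_gr(S, 0.1, [1.0, 2.0])


class TestLattice:
    def test_sc_peak_sequence(self):
        a = 5.0
        qh, mF2 = reciprocal_peaks("sc", a, 3.0)
        base = 2 * np.pi / a
        np.testing.assert_allclose(qh[:3], base * np.sqrt([1, 2, 3]), rtol=1e-9)
        # multiplicities 6, 12, 8 for (100), (110), (111)
        np.testing.assert_allclose(mF2[:3], [6, 12, 8])

    def test_bcc_fcc_extinction_rules(self):
        a = 4.0
        base = 2 * np.pi / a
        qh, mF2 = reciprocal_peaks("bcc", a, 4.0)
        # (100) absent, first peak is (110)
        assert np.min(qh) == pytest.approx(base * np.sqrt(2), rel=1e-9)
        qh, mF2 = reciprocal_peaks("fcc", a, 4.0)
        # first peaks (111), (200); mixed parity absent
        np.testing.assert_allclose(qh[:2], base * np.array([np.sqrt(3), 2.0]),
                                   rtol=1e-9)

    def test_first_peak_positions_in_curve(self):
        a = 5.0
        q = np.linspace(0.5, 3.5, 4000)
        for lat, s in (("sc", 1.0), ("bcc", np.sqrt(2)), ("fcc", np.sqrt(3))):
            S = lattice_sf(q, lat, a=a, domainsize=300.0).Y
            i = np.argmax(S)
            assert q[i] == pytest.approx(2 * np.pi / a * s, abs=3e-3)

    def test_isolated_peak_integral_recovers_weight(self):
        a, L = 5.0, 2000.0
        lat = "sc"
        q0 = 2 * np.pi / a
        q = np.linspace(q0 - 0.15, q0 + 0.15, 40001)
        S = lattice_sf(q, lat, a=a, domainsize=L, u2=0.0)
        c = 2 * np.pi**2 / a**3
        # with u2 = 0 and beta = 1 the curve IS the lattice part Z, and
        # Int Z q^2 dq / c across an isolated peak recovers m |F|^2
        integral = np.trapezoid(S.Y * q**2, q) / c
        mF2 = 6.0  # (100) multiplicity, |F|^2 = 1
        # Lorentzian tails outside +-0.15 carry a few permille
        assert integral == pytest.approx(mF2, rel=0.02)

    def test_gaussian_peak_integral(self):
        a, L = 5.0, 2000.0
        q0 = 2 * np.pi / a
        q = np.linspace(q0 - 0.05, q0 + 0.05, 20001)
        S = lattice_sf(q, "sc", a=a, domainsize=L, u2=0.0, peak_shape="gaussian")
        integral = np.trapezoid(S.Y * q**2, q) / (2 * np.pi**2 / a**3)
        assert integral == pytest.approx(6.0, rel=0.01)

    def test_debye_waller_suppresses_peaks(self):
        q = np.linspace(0.8, 3.5, 1500)
        s0 = lattice_sf(q, "bcc", a=4.0, domainsize=100.0, u2=0.0).Y
        s1 = lattice_sf(q, "bcc", a=4.0, domainsize=100.0, u2=0.05).Y
        assert s1.max() < s0.max()

    def test_hkl_budget_guard(self):
        with pytest.raises(ValueError, match="1e5"):
            reciprocal_peaks("sc", 50.0, 50.0)

    def test_cluster_cross_check_bcc(self):
        """Explicit bcc cluster shows the analytic peak positions, plus
        low-q shape scattering and weak forbidden features."""
        a = 2.0
        cloud = build_lattice_cloud("bcc", a=a, shape="cube", size=5 * a)
        q = np.linspace(1.5, 6.5, 240)
        I = cloud_intensity(cloud, q, fibonacci_sphere(500)).Y / cloud.n
        base = 2 * np.pi / a
        # strongest features near the allowed (110) and (200) positions
        i110 = np.argmax(I * ((q > base * 1.2) & (q < base * 1.6)))
        assert q[i110] == pytest.approx(base * np.sqrt(2), abs=0.1)
        S = lattice_sf(q, "bcc", a=a, domainsize=10 * a).Y
        ia = np.argmax(S)
        assert abs(q[i110] - q[ia]) < 0.1
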