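"""Interparticle structure factors for particle suspensions and crystals.

Fluid models
------------
* :func:`py_hard_sphere` -- Percus-Yevick hard spheres, evaluated through
  the analytic Baxter factor function (identical to the Wertheim
  direct-correlation closed form, which the test suite uses as the
  independent oracle).
* :func:`sticky_hard_sphere` -- Baxter's adhesive hard spheres; the
  coefficient relations (quadratic for the stickiness parameter lambda,
  alpha/beta/E of the factor function) are re-derived from the Baxter
  boundary conditions in this package.
* :func:`rmsa` -- screened-Coulomb (hard core + Yukawa) spheres in the
  rescaled mean spherical approximation.  The MSA closure reduces, through
  the Baxter Wiener-Hopf factorization, to a closing quartic in the Yukawa
  tail amplitude of the factor function; *all* roots are obtained as
  eigenvalues of the companion matrix, g(r) is computed for every real
  root by sine transform, and the root with the smallest hard-core
  violation near r = sigma/2 is selected.  If the contact value g(sigma+)
  of that solution is negative, the Hansen-Hayter rescaling to a larger
  effective hard-sphere diameter is applied until the contact condition
  holds.

Crystals
--------
:func:`lattice_sf` builds powder-averaged structure factors of sc/bcc/fcc
lattices from an explicit reciprocal-lattice enumeration, with finite
domain-size peak broadening, Debye-Waller attenuation with complementary
diffuse scattering, and an optional particle-asymmetry factor beta(q).

All momentum transfers are in inverse length units of the radii passed in
(nm^-1 for nm); S(q) is dimensionless.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np

from . import _msa_generated as _gen
from .datacore import DataSet
from .formfactor import register_model

__all__ = [
    "py_hard_sphere",
    "sticky_hard_sphere",
    "rmsa",
    "rmsa_roots",
    "sq_to_gr",
    "lattice_sf",
    "tau_critical",
]


def _sq_curve(q, S, **attrs) -> DataSet:
    return DataSet(np.column_stack([q, S]), attrs, [], {"X": 0, "Y": 1})


# ---------------------------------------------------------------------------
# Baxter factor-function machinery (dimensionless units, sigma = 1)
# ---------------------------------------------------------------------------

def _qtilde(k, A, B, E, Ci=0.0, Co=0.0, z=1.0):
    """Fourier transform Int_0^inf q(r) e^{ikr} dr of the factor function

    q(r) = A r^2/2 + B r + E + Ci e^{-zr} on (0,1), Co e^{-zr} beyond.
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    out = np.empty(k.shape, dtype=complex)
    big = np.abs(k) > 1e-3
    ik = 1j * k
    if np.any(big):
        kb = ik[big]
        e = np.exp(kb)
        P0 = (e - 1.0) / kb
        P1 = (e - P0) / kb
        P2 = (e - 2.0 * P1) / kb
        w = kb - z
        out[big] = (A / 2 * P2 + B * P1 + E * P0
                    + Ci * (np.exp(w) - 1.0) / w - Co * np.exp(w) / w)
    if np.any(~big):
        ks = ik[~big]
        j = np.arange(8)
        fac = np.cumprod(np.concatenate([[1.0], np.arange(1.0, 8.0)]))
        pw = ks[:, None] ** j[None, :] / fac[None, :]
        w = ks - z
        out[~big] = (A / 2 * (pw / (j + 3)).sum(1) + B * (pw / (j + 2)).sum(1)
                     + E * (pw / (j + 1)).sum(1)
                     + Ci * (np.exp(w) - 1.0) / w - Co * np.exp(w) / w)
    return out


def _sq_factor(k, eta, A, B, E, Ci=0.0, Co=0.0, z=1.0):
    """S(k) = |1 - 12 eta qtilde(k)|^-2 from the Baxter factorization."""
    Q = 1.0 - 12.0 * eta * _qtilde(k, A, B, E, Ci, Co, z)
    return 1.0 / np.abs(Q) ** 2


def _py_coefficients(eta):
    a = (1.0 + 2.0 * eta) / (1.0 - eta) ** 2
    b = -1.5 * eta / (1.0 - eta) ** 2
    return a, b, -a / 2.0 - b


# ---------------------------------------------------------------------------
# Percus-Yevick hard spheres
# ---------------------------------------------------------------------------

@register_model("py_hard_sphere")
def py_hard_sphere(q, R: float = 3.0, phi: float = 0.2) -> DataSet:
    """Hard-sphere structure factor in the Percus-Yevick approximation.

    R is the particle radius and phi the volume fraction; the hard-core
    diameter is sigma = 2R.  S(q -> 0) = (1-phi)^4/(1+2*phi)^2.
    """
    if not 0.0 <= phi < 0.74:
        raise ValueError("phi must lie in [0, 0.74)")
    if R <= 0:
        raise ValueError("R must be > 0")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if phi == 0.0:
        return _sq_curve(q, np.ones_like(q), R=R, phi=phi)
    a, b, e0 = _py_coefficients(phi)
    S = _sq_factor(q * 2.0 * R, phi, a, b, e0)
    return _sq_curve(q, S, R=R, phi=phi)


# ---------------------------------------------------------------------------
# Baxter sticky (adhesive) hard spheres
# ---------------------------------------------------------------------------

def tau_critical(phi: float) -> float:
    """Smallest stickiness tau with a real Baxter solution (one-phase edge)."""
    # discriminant of (phi/12) l^2 - (tau + phi/(1-phi)) l + (1+phi/2)/(1-phi)^2
    from math import sqrt
    c = (1.0 + phi / 2.0) / (1.0 - phi) ** 2
    return sqrt(phi * c / 3.0) - phi / (1.0 - phi)


@register_model("sticky_hard_sphere")
def sticky_hard_sphere(q, R: float = 3.0, phi: float = 0.2, tau: float = 1.0,
                       width: float = 0.01) -> DataSet:
    """Adhesive hard spheres (Baxter's sticky limit of a narrow well).

    tau is the dimensionless stickiness (tau -> inf recovers plain hard
    spheres, small tau means strong adhesion); `width` is the relative
    well width of the finite-range picture the sticky limit idealizes and
    is kept as metadata only -- the limiting structure factor does not
    depend on it.  The physical (smaller) root of the quadratic for the
    sticky parameter lambda is used.
    """
    if not 0.0 < phi < 0.6:
        raise ValueError("phi must lie in (0, 0.6)")
    if R <= 0:
        raise ValueError("R must be > 0")
    tc = tau_critical(phi)
    if tau <= tc:
        raise ValueError(
            f"tau={tau} is inside the two-phase region; need tau > {tc:.6g} at phi={phi}"
        )
    q = np.atleast_1d(np.asarray(q, dtype=float))
    # (phi/12) l^2 - (tau + phi/(1-phi)) l + (1+phi/2)/(1-phi)^2 = 0
    p2 = phi / 12.0
    p1 = -(tau + phi / (1.0 - phi))
    p0 = (1.0 + phi / 2.0) / (1.0 - phi) ** 2
    disc = p1 * p1 - 4.0 * p2 * p0
    lam = (-p1 - np.sqrt(disc)) / (2.0 * p2)   # smaller root
    mu = lam * phi * (1.0 - phi)
    alpha = (1.0 + 2.0 * phi - mu) / (1.0 - phi) ** 2
    beta = (mu - 3.0 * phi) / (2.0 * (1.0 - phi) ** 2)
    e0 = lam / 12.0 - alpha / 2.0 - beta
    S = _sq_factor(q * 2.0 * R, phi, alpha, beta, e0)
    return _sq_curve(q, S, R=R, phi=phi, tau=tau, width=width, lam=lam)


# ---------------------------------------------------------------------------
# RMSA (hard core + screened Coulomb)
# ---------------------------------------------------------------------------

def _closing_roots(eta, gamma, z, nsamp=32):
    """All roots of the closing polynomial in the Yukawa tail amplitude Co.

    det(M) * E4 is polynomial in Co; its values on a circle in the complex
    plane give the coefficients exactly by FFT, and the roots follow from
    the companion matrix of the polynomial.
    """
    radius = max(1.0, gamma * np.exp(min(z, 500.0)) / z)
    vals = np.empty(nsamp, dtype=complex)
    for i, y in enumerate(np.exp(2j * np.pi * np.arange(nsamp) / nsamp)):
        Co = radius * y
        M, b = _gen.linear_system(Co, eta, gamma, z)
        vals[i] = np.linalg.det(M) * _gen.tail_residual(
            Co, *np.linalg.solve(M, b), eta, gamma, z)
    cy = np.fft.fft(vals) / nsamp           # coefficients in Co/radius
    mags = np.abs(cy)
    deg = int(np.max(np.nonzero(mags > 1e-11 * mags.max())[0]))
    if deg >= nsamp - 2:
        raise RuntimeError("closing polynomial degree out of range")
    roots = np.roots(cy[: deg + 1][::-1]) * radius
    return roots


def _gr_from_sq(r, kgrid, S, eta):
    """g(r) by sine transform, dimensionless sigma = 1 units."""
    rho = 6.0 * eta / np.pi
    integ = kgrid * (S - 1.0)
    out = np.empty(len(r))
    for i in range(0, len(r), 64):
        rr = np.asarray(r[i:i + 64])
        out[i:i + 64] = np.trapezoid(
            integ[None, :] * np.sin(rr[:, None] * kgrid[None, :]), kgrid, axis=1)
    return 1.0 + out / (2.0 * np.pi**2 * rho * np.asarray(r))


def rmsa_roots(eta: float, gamma: float, z: float,
               kmax: float = 400.0, nk: int = 20000):
    """Solve the MSA and score every real quartic root on physicality.

    Returns a list of candidate dicts sorted by the hard-core score
    (mean |g| over r in [0.4, 0.6] sigma), best first.  Each dict carries
    the factor-function coefficients, the analytic contact value g(sigma+)
    and S(0).
    """
    roots = _closing_roots(eta, gamma, z)
    real = np.unique(roots[np.abs(roots.imag) < 1e-7 * (np.abs(roots.real) + 1.0)].real)
    if real.size == 0:
        raise RuntimeError(f"no real root of the MSA closing quartic at "
                           f"eta={eta}, gamma={gamma}, z={z}")
    kgrid = np.linspace(1e-4, kmax, nk)
    rwin = np.linspace(0.4, 0.6, 11)
    scale = max(1.0, gamma * np.exp(min(z, 500.0)))
    cands = []
    for Co in real:
        M, b = _gen.linear_system(Co + 0j, eta, gamma, z)
        sol = np.linalg.solve(M, b).real
        if abs(_gen.tail_residual(Co, *sol, eta, gamma, z)) > 1e-5 * scale:
            continue  # spurious root of the det factor
        A, B, E, Ci, J = sol
        S = _sq_factor(kgrid, eta, A, B, E, Ci, Co, z)
        if not np.all(np.isfinite(S)):
            continue
        score = float(np.mean(np.abs(_gr_from_sq(rwin, kgrid, S, eta))))
        cands.append({
            "Co": float(Co), "A": A, "B": B, "E": E, "Ci": Ci, "J": J,
            "score": score,
            "contact": float(_gen.contact_value(Co, *sol, eta, gamma, z)),
            "S0": float(_sq_factor(np.array([1e-8]), eta, A, B, E, Ci, Co, z)[0]),
        })
    if not cands:
        raise RuntimeError(f"no physical MSA solution at eta={eta}, "
                           f"gamma={gamma}, z={z}")
    cands.sort(key=lambda c: c["score"])
    return cands


def _msa_best(eta, gamma, z):
    if gamma < 1e-14:
        a, b, e0 = _py_coefficients(eta)
        contact = (1.0 + eta / 2.0) / (1.0 - eta) ** 2
        return {"Co": 0.0, "A": a, "B": b, "E": e0, "Ci": 0.0, "J": 0.0,
                "score": 0.0, "contact": contact,
                "S0": (1.0 - eta) ** 4 / (1.0 + 2.0 * eta) ** 2}, 0, 1
    cands = rmsa_roots(eta, gamma, z)
    return cands[0], 0, len(cands)


@register_model("rmsa")
def rmsa(q, R: float = 3.1, phi: float = 0.2, gamma: float = 3.0,
         ak: float = 2.0, contact_tol: float = 1e-3,
         max_rescale_iter: int = 50) -> DataSet:
    """Screened-Coulomb structure factor (rescaled MSA).

    Parameters
    ----------
    q : array
        Momentum transfer, inverse length of R.
    R : float
        Hard-core radius (sigma = 2R).
    phi : float
        Volume fraction, 0 < phi <= 0.5.
    gamma : float
        Contact potential in units of kT (gamma = 0 is plain PY).
    ak : float
        Dimensionless screening constant kappa*sigma of the Yukawa tail
        beta*u(x) = gamma exp(-ak (x-1))/x, x = r/sigma.
    contact_tol : float
        Hansen-Hayter rescaling is applied while g(sigma_eff+) < -contact_tol.

    The returned curve carries the selected root index, number of real
    roots, rescaling flag, effective volume fraction and contact value as
    attributes.
    """
    if not 0.0 < phi <= 0.5:
        raise ValueError("phi must lie in (0, 0.5]")
    if gamma < 0 or ak <= 0 or R <= 0:
        raise ValueError("need gamma >= 0, ak > 0, R > 0")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    sigma = 2.0 * R

    def solve_scaled(s):
        eta_s = phi * s**3
        z_s = ak * s
        gamma_s = gamma * np.exp(-ak * (s - 1.0)) / s
        best, idx, nreal = _msa_best(eta_s, gamma_s, z_s)
        return best, eta_s, z_s, gamma_s, nreal

    best, eta_e, z_e, gamma_e, nreal = solve_scaled(1.0)
    s = 1.0
    rescaled = False
    if best["contact"] < -contact_tol:
        rescaled = True
        s_max = (0.72 / phi) ** (1.0 / 3.0)
        if s_max <= 1.0:
            raise RuntimeError("cannot rescale: packing already at the cap")
        # bracket the zero-contact scale, then bisect
        lo, hi = 1.0, None
        step = min(1.1, s_max)
        for _ in range(max_rescale_iter):
            cand, *_ = solve_scaled(step)
            if cand["contact"] >= -contact_tol:
                hi = step
                break
            lo = step
            if step >= s_max:
                break
            step = min(step * 1.1, s_max)
        if hi is None:
            raise RuntimeError(
                f"RMSA rescaling failed to reach g(contact) >= -{contact_tol} "
                f"within the packing cap (phi_eff <= 0.72); last contact "
                f"{cand['contact']:.4g}")
        for _ in range(max_rescale_iter):
            mid = 0.5 * (lo + hi)
            cand, *_ = solve_scaled(mid)
            if cand["contact"] >= -contact_tol:
                hi = mid
            else:
                lo = mid
            if hi - lo < 1e-6:
                break
        s = hi
        best, eta_e, z_e, gamma_e, nreal = solve_scaled(s)

    S = _sq_factor(q * sigma * s, eta_e, best["A"], best["B"], best["E"],
                   best["Ci"], best["Co"], z_e)
    return _sq_curve(
        q, S, R=R, phi=phi, gamma=gamma, ak=ak,
        selected_root=float(best["Co"]), n_real_roots=nreal,
        root_score=best["score"], rescaled=float(rescaled),
        scale_factor=s, phi_effective=eta_e, contact=best["contact"],
    )


# ---------------------------------------------------------------------------
# S(q) -> g(r)
# ---------------------------------------------------------------------------

def sq_to_gr(S: DataSet, n: float, r_grid: Sequence[float]) -> DataSet:
    """Radial distribution function from a structure factor curve.

    g(r) = 1 + 1/(2 pi^2 n r) Int_0^qmax q (S(q)-1) sin(qr) dq, trapezoid
    rule on the curve's own q grid; *n* is the particle number density in
    the inverse cubed length unit of r.
    """
    r = np.atleast_1d(np.asarray(r_grid, dtype=float))
    if np.any(r <= 0):
        raise ValueError("r_grid must be positive")
    qv, Sv = S.X, S.Y
    trunc = float(np.abs(Sv[-1] - 1.0))
    attrs = {"n": n, "qmax": float(qv[-1]), "truncation": trunc}
    if trunc > 0.01:
        warnings.warn(
            f"S(q) has not reached 1 at qmax ({trunc:.3g} away); g(r) will ring",
            stacklevel=2)
    integ = qv * (Sv - 1.0)
    g = np.empty(len(r))
    for i in range(0, len(r), 64):
        rr = r[i:i + 64]
        g[i:i + 64] = np.trapezoid(
            integ[None, :] * np.sin(rr[:, None] * qv[None, :]), qv, axis=1)
    g = 1.0 + g / (2.0 * np.pi**2 * n * r)
    for key in ("R", "phi"):
        if key in S.attributes:
            attrs[key] = S.attributes[key]
    return DataSet(np.column_stack([r, g]), attrs, [], {"X": 0, "Y": 1})


# ---------------------------------------------------------------------------
# lattice structure factors
# ---------------------------------------------------------------------------

_LATTICE_BASIS = {
    "sc": np.array([[0.0, 0.0, 0.0]]),
    "bcc": np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.5]]),
    "fcc": np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.0],
                     [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]),
}


def reciprocal_peaks(lattice: str, a: float, qmax: float):
    """(q_hkl, m |F_hkl|^2) of the powder pattern up to qmax.

    hkl run over the conventional-cell reciprocal lattice; extinction
    rules emerge from the unit-cell structure factor, and shells with the
    same |q| are merged with their multiplicity.
    """
    basis = _LATTICE_BASIS[lattice]
    hmax = int(np.ceil(qmax * a / (2.0 * np.pi))) + 1
    if (2 * hmax + 1) ** 3 > 1e5:
        raise ValueError("qmax enumerates more than 1e5 hkl points; reduce qmax")
    hs = np.arange(-hmax, hmax + 1)
    H = np.array(np.meshgrid(hs, hs, hs, indexing="ij")).reshape(3, -1).T
    H = H[np.any(H != 0, axis=1)]
    qh = 2.0 * np.pi / a * np.linalg.norm(H, axis=1)
    F2 = np.abs(np.exp(2j * np.pi * (H @ basis.T)).sum(axis=1)) ** 2
    keep = (qh <= qmax) & (F2 > 1e-9)
    qh, F2 = qh[keep], F2[keep]
    # merge shells of equal |q|
    order = np.argsort(qh)
    qh, F2 = qh[order], F2[order]
    uq, inv = np.unique(np.round(qh, 9), return_inverse=True)
    mF2 = np.zeros_like(uq)
    np.add.at(mF2, inv, F2)
    return uq, mF2


def _peak_shape(x, delta, kind):
    if kind == "lorentzian":
        return (delta / np.pi) / (x**2 + delta**2)
    if kind == "gaussian":
        s = delta / np.sqrt(2.0 * np.log(2.0))
        return np.exp(-0.5 * (x / s) ** 2) / (s * np.sqrt(2.0 * np.pi))
    raise ValueError(f"unknown peak shape {kind!r}")


@register_model("lattice_sf")
def lattice_sf(q, lattice: str = "fcc", a: float = 5.0,
               domainsize: float = 50.0, u2: float = 0.0,
               beta: Callable[[np.ndarray], np.ndarray] | None = None,
               peak_shape: str = "lorentzian") -> DataSet:
    """Powder structure factor of an sc/bcc/fcc crystal.

    The lattice part is Z(q) = c/q^2 sum_hkl m |F_hkl|^2 P(q - q_hkl) with
    unit-area peaks of half width delta = 2 pi / domainsize and the
    normalization c = 2 pi^2/(v_cell n_basis), which makes Z -> 1 on
    average at large q.  Assembled with Debye-Waller attenuation
    (u2 = <u^2>, 3D mean-square displacement) and particle asymmetry as

        S(q) = 1 + beta(q) [Z(q) exp(-q^2 u2 / 3) - 1] ,

    so the diffuse term complements the attenuated Bragg peaks.
    """
    if lattice not in _LATTICE_BASIS:
        raise ValueError(f"unknown lattice {lattice!r}")
    if a <= 0 or domainsize <= 0 or u2 < 0:
        raise ValueError("need a > 0, domainsize > 0, u2 >= 0")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q <= 0):
        raise ValueError("lattice_sf requires q > 0")
    delta = 2.0 * np.pi / domainsize
    qenum = q.max() + 10.0 * delta + 2.0 * np.pi / a
    qh, mF2 = reciprocal_peaks(lattice, a, qenum)
    nb = len(_LATTICE_BASIS[lattice])
    c = 2.0 * np.pi**2 / (a**3 * nb)
    Z = np.zeros_like(q)
    for qk, w in zip(qh, mF2):
        Z += w * _peak_shape(q - qk, delta, peak_shape)
    Z *= c / q**2
    bq = np.ones_like(q) if beta is None else np.asarray(beta(q), dtype=float)
    dw = np.exp(-q**2 * u2 / 3.0)
    S = 1.0 + bq * (Z * dw - 1.0)
    return _sq_curve(q, S, lattice_a=a, domainsize=domainsize, u2=u2,
                     delta=delta, n_peaks=len(qh))
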