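"""Quasielastic neutron-scattering models in time and frequency domain.

Time-domain models give the intermediate scattering function I(q,t)
(dimensionless, I(q,0) = 1 for the normalized models here); frequency-
domain models give the dynamic structure factor S(q, omega) on a
symmetric omega grid, classical (symmetric) and unit-area so that
Int S domega = I(q, t=0).  The Fourier bridge
:func:`time_to_frequency` multiplies I(q,t) by the time-domain Gaussian
corresponding to an omega-resolution width and cosine-transforms, so a
chain of processes can be composed by multiplication in time or by
:func:`convolve_w` in frequency.

Elastic components (the EISF of confined motions) are represented as a
unit-area single-bin spike at omega = 0: value EISF/d_omega in the center
bin.  Convolution, binning and the HWHM extraction treat that
representation consistently (a unit-area spike is the exact convolution
identity on the grid).

Units: t and 1/omega share one time unit (e.g. ns and ns^-1), q and the
lengths in D, R are reciprocal (nm^-1, nm); so D is in nm^2/ns.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special

from .datacore import DataSet

__all__ = [
    "intermediate_scattering",
    "lorentzian_w",
    "confined_w",
    "rotational_diffusion_w",
    "time_to_frequency",
    "convolve_w",
    "bin_channels",
    "hwhm",
    "sphere_eigenvalues",
]


def _tcurve(t, I, **attrs) -> DataSet:
    return DataSet(np.column_stack([t, I]), attrs, [], {"X": 0, "Y": 1})


def _spectrum(w, S, **attrs) -> DataSet:
    w = np.asarray(w, dtype=float)
    attrs.setdefault("grid_step", float(w[1] - w[0]) if len(w) > 1 else 0.0)
    return DataSet(np.column_stack([w, S]), attrs, [], {"X": 0, "Y": 1})


def _check_symmetric(w):
    w = np.atleast_1d(np.asarray(w, dtype=float))
    if len(w) < 3:
        raise ValueError("omega grid too short")
    dw = np.diff(w)
    if np.max(np.abs(dw - dw[0])) > 1e-9 * abs(dw[0]):
        raise ValueError("omega grid must be uniform")
    if abs(w[0] + w[-1]) > 1e-9 * max(abs(w[0]), 1.0):
        raise ValueError("omega grid must be symmetric about 0")
    return w, float(dw[0])


def _center_index(w):
    i = int(np.argmin(np.abs(w)))
    if abs(w[i]) > 1e-9 * max(1.0, abs(w[-1])):
        raise ValueError("omega grid has no bin at 0 for the elastic spike")
    return i


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def intermediate_scattering(model: str, t, q: float, D: float = 1.0,
                            beta: float = 1.0, tau: float = 1.0,
                            gamma: float | None = None) -> DataSet:
    """I(q,t) for simple diffusion, stretched exponential or jump diffusion.

    * 'diffusion':      exp(-q^2 D t)
    * 'stretched':      exp(-(Gamma t)^beta), Gamma = gamma or q^2 D
    * 'jumpdiffusion':  exp(-Gamma_j t), Gamma_j = D q^2/(1 + D q^2 tau)
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if model == "diffusion":
        I = np.exp(-q**2 * D * t)
        attrs = {"q": q, "D": D}
    elif model == "stretched":
        if not 0.0 < beta <= 2.0:
            raise ValueError("beta must lie in (0, 2]")
        G = gamma if gamma is not None else q**2 * D
        I = np.exp(-((G * t) ** beta))
        attrs = {"q": q, "beta": beta, "Gamma": G}
    elif model == "jumpdiffusion":
        G = D * q**2 / (1.0 + D * q**2 * tau)
        I = np.exp(-G * t)
        attrs = {"q": q, "D": D, "tau": tau, "Gamma": G}
    else:
        raise ValueError(f"unknown model {model!r}")
    return _tcurve(t, I, **attrs)


# ---------------------------------------------------------------------------
# frequency domain: Lorentzian models
# ---------------------------------------------------------------------------

def _lorentz(w, G):
    return (G / np.pi) / (G * G + w * w)


def lorentzian_w(model: str, w, q: float, D: float = 1.0,
                 tau: float = 1.0) -> DataSet:
    """Unit-area Lorentzian spectra of free and jump translational diffusion.

    HWHM Gamma = D q^2 ('transdiff') or D q^2/(1 + D q^2 tau) ('jumpdiff',
    saturating at 1/tau for large q).
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    w, _ = _check_symmetric(w)
    if model == "transdiff":
        G = D * q**2
    elif model == "jumpdiff":
        G = D * q**2 / (1.0 + D * q**2 * tau)
    else:
        raise ValueError(f"unknown model {model!r}")
    return _spectrum(w, _lorentz(w, G), q=q, D=D, hwhm=G)


# ---------------------------------------------------------------------------
# frequency domain: confined motions
# ---------------------------------------------------------------------------

_eig_cache: dict = {}


def sphere_eigenvalues(l_max: int, n_max: int) -> np.ndarray:
    """Positive roots x_{l,n} of j_l'(x) = 0 (reflecting sphere boundary).

    Row l holds the n_max smallest nonzero roots for angular momentum l;
    computed once by bracketed root finding on the spherical Bessel
    derivative and cached.
    """
    key = (l_max, n_max)
    if key in _eig_cache:
        return _eig_cache[key]
    roots = np.empty((l_max + 1, n_max))
    xmax = 3.2 * (n_max + l_max + 2)
    xs = np.linspace(1e-3, xmax, int(40 * xmax))
    for l in range(l_max + 1):
        f = special.spherical_jn(l, xs, derivative=True)
        sign = np.sign(f)
        idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        found = []
        for i in idx:
            sol = optimize.brentq(
                lambda x: special.spherical_jn(l, x, derivative=True),
                xs[i], xs[i + 1], xtol=1e-13)
            if sol > 1e-6:
                found.append(sol)
            if len(found) == n_max:
                break
        if len(found) < n_max:
            raise RuntimeError(f"could not bracket {n_max} roots for l={l}")
        roots[l] = found
    _eig_cache[key] = roots
    return roots


def _sphere_amplitudes(y: float, l_max: int, n_max: int):
    """(x_{l,n}, A_n^l(y)) of diffusion in a reflecting sphere, qR = y."""
    x = sphere_eigenvalues(l_max, n_max)
    ls = np.arange(l_max + 1)[:, None]
    jl_prime = np.empty_like(x)
    num = np.empty_like(x)
    for l in range(l_max + 1):
        # y j_l'(y) / (y^2 - x^2), with the removable singularity at y = x
        dif = y**2 - x[l] ** 2
        val = y * special.spherical_jn(l, y, derivative=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = val / dif
        close = np.abs(dif) < 1e-8 * (y**2 + x[l] ** 2)
        if np.any(close):
            # l'Hopital: d/dy [y j_l'(y)] / (2y) at y = x (j_l'(x) = 0)
            xc = x[l][close]
            h = 1e-6
            d = (xc + h) * special.spherical_jn(l, xc + h, derivative=True) \
                - (xc - h) * special.spherical_jn(l, xc - h, derivative=True)
            frac[close] = d / (2 * h) / (2 * xc)
        num[l] = frac
    A = (2 * ls + 1) * 6.0 * x**2 / (x**2 - ls * (ls + 1)) * num**2
    return x, A


def confined_w(model: str, w, q: float, D: float = 1.0, R: float = 1.0,
               u2: float = 0.1, tau: float = 1.0, l_max: int = 7,
               n_max: int = 7) -> DataSet:
    """Spectra of spatially restricted motion: diffusion in a sphere or in
    a harmonic potential (both with an elastic EISF line).

    'sphere' (reflecting sphere of radius R, diffusion coefficient D):
    S = EISF delta(w) + sum_{l,n} A_n^l(qR) Lorentz(w; x_{l,n}^2 D/R^2),
    EISF = [3 j_1(qR)/(qR)]^2; the amplitudes use the eigenvalues x_{l,n}
    of j_l'(x) = 0.

    'harmonic' (overdamped oscillator, msd u2, relaxation time tau):
    S = e^{-q^2 u2} [delta(w) + sum_n (q^2 u2)^n/n! Lorentz(w; n/tau)],
    EISF = exp(-q^2 u2).

    If the truncated amplitudes miss more than 1 % of the sum rule a
    'truncation' warning attribute is attached.
    """
    if l_max < 3 or n_max < 3:
        raise ValueError("cutoffs must be >= 3")
    w, dw = _check_symmetric(w)
    ic = _center_index(w)
    S = np.zeros_like(w)
    if model == "sphere":
        if R <= 0 or D <= 0:
            raise ValueError("R and D must be > 0")
        y = q * R
        if y < 1e-8:
            eisf, total = 1.0, 1.0
        else:
            eisf = float((3.0 * special.spherical_jn(1, y) / y) ** 2)
            x, A = _sphere_amplitudes(y, l_max, n_max)
            for l in range(l_max + 1):
                for n in range(n_max):
                    S += A[l, n] * _lorentz(w, x[l, n] ** 2 * D / R**2)
            total = eisf + float(A.sum())
        attrs = {"q": q, "D": D, "R": R, "eisf": eisf}
    elif model == "harmonic":
        if u2 < 0 or tau <= 0:
            raise ValueError("u2 >= 0 and tau > 0 required")
        x = q**2 * u2
        eisf = float(np.exp(-x))
        n = np.arange(1, max(n_max, int(x + 10 * np.sqrt(x + 1))) + 1)
        weights = eisf * np.exp(n * np.log(x) - special.gammaln(n + 1)) if x > 0 \
            else np.zeros_like(n, dtype=float)
        for ni, wi in zip(n, weights):
            if wi > 1e-12:
                S += wi * _lorentz(w, ni / tau)
        total = eisf + float(weights.sum())
        attrs = {"q": q, "u2": u2, "tau": tau, "eisf": eisf}
    else:
        raise ValueError(f"unknown model {model!r}")
    S[ic] += eisf / dw
    if 1.0 - total > 0.01:
        warnings.warn(f"amplitude sum rule misses {1 - total:.3g}; raise cutoffs",
                      stacklevel=2)
        attrs["truncation"] = 1.0 - total
    return _spectrum(w, S, **attrs)


def rotational_diffusion_w(w, q: float, R: float = 1.0, Dr: float = 1.0,
                           l_max: int = 10) -> DataSet:
    """Sears expansion for isotropic rotational diffusion on a sphere of
    radius R: j_0^2(qR) delta(w) + sum_l (2l+1) j_l^2(qR) L(w; l(l+1) Dr)."""
    if l_max < 3:
        raise ValueError("l_max must be >= 3")
    w, dw = _check_symmetric(w)
    ic = _center_index(w)
    y = q * R
    eisf = float(special.spherical_jn(0, y) ** 2)
    S = np.zeros_like(w)
    total = eisf
    for l in range(1, l_max + 1):
        amp = (2 * l + 1) * special.spherical_jn(l, y) ** 2
        S += amp * _lorentz(w, l * (l + 1) * Dr)
        total += amp
    S[ic] += eisf / dw
    attrs = {"q": q, "R": R, "Dr": Dr, "eisf": eisf, "sum_rule": total}
    if 1.0 - total > 0.01:
        warnings.warn(f"Sears sum rule misses {1 - total:.3g}; raise l_max",
                      stacklevel=2)
        attrs["truncation"] = 1.0 - total
    return _spectrum(w, S, **attrs)


# ---------------------------------------------------------------------------
# time <-> frequency bridge
# ---------------------------------------------------------------------------

def time_to_frequency(model: Callable[[np.ndarray], np.ndarray] | DataSet,
                      w_grid, resolution: float = 0.0,
                      t_max: float | None = None, nt: int = 2**14) -> DataSet:
    """S(q,omega) from a time-domain correlation function by cosine
    transform, with a Gaussian omega-resolution of width *resolution*
    applied as the corresponding Gaussian factor exp(-resolution^2 t^2/2)
    in time (it doubles as the transform window).

    *model* is either a callable I(t) or a TimeCurve DataSet (interpolated
    onto the transform grid).  The time grid extends until the windowed
    I(t) has decayed to 0.5 % of I(0) (warning attribute otherwise).
    """
    w, dw = _check_symmetric(w_grid)
    if isinstance(model, DataSet):
        ds = model
        def func(t):
            return np.interp(t, ds.X, ds.Y)
        attrs = dict(ds.attributes)
    else:
        func = model
        attrs = {}

    def windowed(t):
        I = np.asarray(func(t), dtype=float)
        if resolution > 0:
            I = I * np.exp(-0.5 * (resolution * t) ** 2)
        return I

    if t_max is None:
        t_max = 5.0 / resolution if resolution > 0 else 1.0
        I0 = abs(windowed(np.array([0.0]))[0])
        for _ in range(60):
            if abs(windowed(np.array([t_max]))[0]) < 5e-3 * I0:
                break
            t_max *= 1.6
    t = np.linspace(0.0, t_max, nt)
    I = windowed(t)
    leak = abs(I[-1]) / max(abs(I[0]), 1e-300)
    if leak > 0.01:
        warnings.warn(f"I(t_max)/I(0) = {leak:.3g}: transform may leak",
                      stacklevel=2)
        attrs["truncation_leak"] = leak
    # S(w) = (1/pi) Int_0^inf I(t) cos(w t) dt   (I even in t)
    S = np.empty_like(w)
    wt = np.abs(w)
    for i in range(0, len(w), 128):
        S[i:i + 128] = np.trapezoid(
            I[None, :] * np.cos(wt[i:i + 128, None] * t[None, :]), t, axis=1)
    S /= np.pi
    S = np.clip(S, 0.0, None)
    attrs.update(resolution=resolution, t_max=t_max)
    if leak > 0.01:
        attrs["truncation_leak"] = leak
    return _spectrum(w, S, **attrs)


# ---------------------------------------------------------------------------
# spectral algebra
# ---------------------------------------------------------------------------

def convolve_w(a: DataSet, b: DataSet) -> DataSet:
    """Discrete convolution of two spectra on a common uniform grid.

    (a (*) b)(w_i) = sum_j a(w_j) b(w_i - w_j) d_omega; areas multiply and
    a unit-area center spike is the exact identity.
    """
    wa, dwa = _check_symmetric(a.X)
    wb, dwb = _check_symmetric(b.X)
    if len(wa) != len(wb) or abs(dwa - dwb) > 1e-9 * dwa \
            or np.max(np.abs(wa - wb)) > 1e-9 * max(abs(wa[-1]), 1.0):
        raise ValueError("spectra must share one uniform omega grid")
    conv = np.convolve(a.Y, b.Y, mode="full")[len(wa) - 1 - _center_index(wa):]
    conv = conv[: len(wa)] * dwa
    attrs = {k: v for k, v in a.attributes.items() if k in ("q", "grid_step")}
    return _spectrum(wa, conv, **attrs)


def bin_channels(s: DataSet, channel_edges: Sequence[float]) -> DataSet:
    """Average a spectrum into frequency channels.

    The channel value is the mean of the points inside each channel and
    the channel position the mean of their omegas; empty channels are
    dropped with a warning.
    """
    edges = np.asarray(channel_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("channel_edges must be increasing, length >= 2")
    w, S = s.X, s.Y
    idx = np.searchsorted(edges, w, side="right") - 1
    ok = (idx >= 0) & (idx < len(edges) - 1)
    out_w, out_S = [], []
    empty = 0
    for b in range(len(edges) - 1):
        sel = ok & (idx == b)
        if not np.any(sel):
            empty += 1
            continue
        out_w.append(w[sel].mean())
        out_S.append(S[sel].mean())
    if empty:
        warnings.warn(f"{empty} empty channels dropped", stacklevel=2)
    return DataSet(np.column_stack([out_w, out_S]), dict(s.attributes),
                   list(s.comments), {"X": 0, "Y": 1})


def hwhm(s: DataSet, exclude_elastic: bool = False) -> float:
    """Half width at half maximum of a spectrum peaked at omega = 0.

    Linear interpolation of the half-maximum crossing on the omega > 0
    side; with ``exclude_elastic`` the center-bin spike is replaced by the
    interpolation of its neighbours first.
    """
    w, S = s.X.copy(), s.Y.copy()
    ic = int(np.argmin(np.abs(w)))
    if exclude_elastic:
        S[ic] = 0.5 * (S[ic - 1] + S[ic + 1])
    peak = S[ic]
    if peak < np.max(S) * (1 - 1e-9):
        raise ValueError("spectrum is not peaked at omega = 0")
    half = peak / 2.0
    right_w, right_S = w[ic:], S[ic:]
    below = np.nonzero(right_S <= half)[0]
    if len(below) == 0:
        raise ValueError("no half-maximum crossing inside the grid; widen it")
    j = below[0]
    if j == 0:
        return 0.0
    w1, w2 = right_w[j - 1], right_w[j]
    s1, s2 = right_S[j - 1], right_S[j]
    return float(w1 + (s1 - half) / (s1 - s2) * (w2 - w1))
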