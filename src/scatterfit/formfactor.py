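"""Analytic small-angle form factors and polydispersity averaging.

Conventions
-----------
Lengths are nm, momentum transfer q is nm^-1 and scattering length
densities (SLD) are nm^-2; *contrast* always means the particle-solvent
SLD difference.  Models with an explicit material contrast report absolute
intensity per particle with forward scattering ``I0 = (V_p rho)^2``;
models without one (Gaussian chain, Beaucage, Teubner-Strey) are
normalized to I(0) = 1 (Beaucage: to the Guinier prefactor G).

Every model returns a :class:`~scatterfit.datacore.DataSet` with columns
``[q, I]`` and the defining parameters (plus I0 and Rg where meaningful)
stored as attributes, so curves feed directly into the fitting machinery.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
from scipy import special, stats

from .datacore import DataSet

__all__ = [
    "sphere",
    "multishell_sphere",
    "gaussian_chain",
    "beaucage",
    "teubner_strey",
    "distributed_average",
    "sphere_amplitude",
    "register_model",
    "get_model",
    "MODEL_REGISTRY",
]

MODEL_REGISTRY: dict[str, Callable] = {}


def register_model(name: str, func: Callable | None = None):
    """Register a model for lookup by the fitting CLI; usable as decorator."""
    def deco(f):
        MODEL_REGISTRY[name] = f
        return f
    return deco(func) if func is not None else deco


def get_model(name: str) -> Callable:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None


def _curve(q, I, **attributes) -> DataSet:
    return DataSet(np.column_stack([q, I]), attributes, [], {"X": 0, "Y": 1})


def sphere_amplitude(x: np.ndarray) -> np.ndarray:
    """Normalized sphere amplitude kernel 3(sin x - x cos x)/x^3, Phi(0)=1."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    out = np.where(small, 1.0 - x * x / 10.0, 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3)
    return out


@register_model("sphere")
def sphere(q, R: float = 1.0, contrast: float = 1.0) -> DataSet:
    """Homogeneous sphere of radius R.

    I(q) = (V rho)^2 [3(sin qR - qR cos qR)/(qR)^3]^2 with V = 4 pi R^3/3.
    """
    if R <= 0:
        raise ValueError("R must be > 0")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    V = 4.0 / 3.0 * np.pi * R**3
    I = (V * contrast * sphere_amplitude(q * R)) ** 2
    return _curve(q, I, R=R, contrast=contrast,
                  I0=(V * contrast) ** 2, Rg=np.sqrt(3.0 / 5.0) * R)


@register_model("multishell_sphere")
def multishell_sphere(q, radii, contrasts) -> DataSet:
    """Concentric shells with piecewise-constant SLD contrast.

    ``radii`` are the strictly increasing outer radii of the shells and
    ``contrasts[k]`` the SLD contrast of the material between
    ``radii[k-1]`` and ``radii[k]`` (the innermost shell is the core).
    The amplitude telescopes over the sphere kernel:

        F_a(q) = sum_k rho_k [V_k Phi(q r_k) - V_{k-1} Phi(q r_{k-1})]

    so a hollow core is contrast 0 and a single shell reduces exactly to
    :func:`sphere`.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    radii = np.asarray(radii, dtype=float)
    contrasts = np.asarray(contrasts, dtype=float)
    if radii.ndim != 1 or len(radii) != len(contrasts):
        raise ValueError("radii and contrasts must be 1-d of equal length")
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    V = 4.0 / 3.0 * np.pi * radii**3
    amp = np.zeros_like(q)
    total_b = 0.0
    prev_V = 0.0
    prev_kernel = np.zeros_like(q)
    for rk, Vk, rho in zip(radii, V, contrasts):
        kern = Vk * sphere_amplitude(q * rk)
        amp += rho * (kern - prev_kernel)
        total_b += rho * (Vk - prev_V)
        prev_kernel, prev_V = kern, Vk
    return _curve(q, amp**2, radii=radii, contrasts=contrasts, I0=total_b**2)


@register_model("gaussian_chain")
def gaussian_chain(q, Rg: float = 3.0) -> DataSet:
    """Debye function for an ideal Gaussian polymer coil, P(0)=1.

    P(x) = 2 (exp(-x) + x - 1)/x^2 with x = q^2 Rg^2.
    """
    if Rg <= 0:
        raise ValueError("Rg must be > 0")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    x = (q * Rg) ** 2
    small = x < 1e-6
    xs = np.where(small, 1.0, x)
    P = np.where(small, 1.0 - x / 3.0, 2.0 * (np.expm1(-xs) + xs) / xs**2)
    return _curve(q, P, Rg=Rg, I0=1.0)


@register_model("beaucage")
def beaucage(q, Rg: float = 3.0, d: float = 2.0, G: float = 1.0) -> DataSet:
    """Unified Guinier/power-law model (exponent d between 1 and 4).

    I(q) = G exp(-q^2 Rg^2/3) + B [ (erf(q Rg/sqrt(6)))^3 / q ]^d with the
    matched prefactor B = G d / Rg^d [6 d^2/((2+d)(2+2d))]^{d/2} Gamma(d/2),
    giving a curve that is continuous, positive, Guinier-limited to G at
    low q and a clean q^-d power law at high q.
    """
    if Rg <= 0:
        raise ValueError("Rg must be > 0")
    if not 1.0 <= d <= 4.0:
        raise ValueError("power-law exponent d must lie in [1, 4]")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    B = G * d / Rg**d * (6.0 * d**2 / ((2.0 + d) * (2.0 + 2.0 * d))) ** (d / 2.0) \
        * special.gamma(d / 2.0)
    qs = np.where(q > 0, q, 1.0)
    qstar = qs / special.erf(qs * Rg / np.sqrt(6.0)) ** 3
    I = G * np.exp(-(q * Rg) ** 2 / 3.0) + B / qstar**d
    I = np.where(q > 0, I, G)
    return _curve(q, I, Rg=Rg, d=d, G=G, I0=G)


@register_model("teubner_strey")
def teubner_strey(q, xi: float = 5.0, d: float = 15.0) -> DataSet:
    """Bicontinuous microemulsion scattering (correlation length xi,
    domain repeat distance d).

    I(q) = (8 pi / xi) / (a2 + c1 q^2 + c2 q^4) with the standard
    coefficient map  k = 2 pi/d:

        a2 = (k^2 + xi^-2)^2,  c1 = -2 (k^2 - xi^-2),  c2 = 1.

    c1 < 0 (a peak near q = 2 pi/d) whenever k xi > 1.
    """
    if xi <= 0 or d <= 0:
        raise ValueError("xi and d must be > 0")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    k = 2.0 * np.pi / d
    b = 1.0 / xi**2
    a2 = (k**2 + b) ** 2
    c1 = -2.0 * (k**2 - b)
    I = (8.0 * np.pi / xi) / (a2 + c1 * q**2 + q**4)
    return _curve(q, I, xi=xi, d=d, I0=float(8.0 * np.pi / xi / a2))


# ---------------------------------------------------------------------------
# polydispersity averaging
# ---------------------------------------------------------------------------

# truncation of continuous weight functions, in units of `width`
_TRUNC = {"normal": 5.0, "lognorm": 5.0, "gamma": 5.0, "uniform": 1.0, "lorentz": 20.0}


def _weight_dist(distribution: str, mean: float, width: float):
    """scipy frozen distribution for the named parameter distribution.

    `width` is the standard deviation for normal/lognorm/gamma, the
    half-width for uniform/duniform and the HWHM for lorentz; poisson
    ignores it (variance = mean).
    """
    if distribution == "normal":
        return stats.norm(mean, width)
    if distribution == "lognorm":
        s = np.sqrt(np.log1p((width / mean) ** 2))
        return stats.lognorm(s, scale=mean * np.exp(-0.5 * s * s))
    if distribution == "gamma":
        k = (mean / width) ** 2
        return stats.gamma(k, scale=width**2 / mean)
    if distribution == "lorentz":
        return stats.cauchy(mean, width)
    if distribution == "uniform":
        return stats.uniform(mean - width, 2.0 * width)
    raise ValueError(f"unsupported distribution {distribution!r}")


def distributed_average(
    model: Callable[..., DataSet],
    param: str,
    distribution: str,
    mean: float,
    width: float,
    n_points: int = 41,
    model_kwargs: Mapping | None = None,
    q=None,
) -> DataSet:
    """Average a one-parameter model family over a parameter distribution.

    Continuous distributions ('normal', 'lognorm', 'gamma', 'lorentz',
    'uniform') are integrated by fixed Gauss-Legendre quadrature on the
    truncated support (+-5 widths; lorentz +-20, uniform exactly its
    support), with weights renormalized to unit mass on the truncation
    window; discrete ones ('poisson', 'duniform') are exact sums.  The
    parameter grid is clipped to positive values where the distribution
    support requires it.
    """
    if width < 0:
        raise ValueError("width must be >= 0")
    kwargs = dict(model_kwargs or {})

    def eval_at(p):
        return model(q, **{param: p}, **kwargs) if q is not None else model(**{param: p}, **kwargs)

    if width == 0 or (distribution == "poisson" and width == 0):
        out = eval_at(mean)
        out.attributes.update(dist_param=param, distribution=distribution,
                              dist_mean=mean, dist_width=0.0)
        return out

    if distribution == "poisson":
        ks = np.arange(max(0, int(mean - 5 * np.sqrt(mean) - 1)),
                       int(mean + 5 * np.sqrt(mean) + 2))
        w = stats.poisson(mean).pmf(ks)
        pts = ks.astype(float)
    elif distribution == "duniform":
        pts = np.arange(mean - width, mean + width + 1)
        w = np.ones_like(pts)
    elif distribution in _TRUNC:
        dist = _weight_dist(distribution, mean, width)
        lo = mean - _TRUNC[distribution] * width
        hi = mean + _TRUNC[distribution] * width
        if distribution in ("lognorm", "gamma"):
            lo = max(lo, 1e-12)
        nodes, gw = np.polynomial.legendre.leggauss(n_points)
        pts = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
        w = gw * 0.5 * (hi - lo) * dist.pdf(pts)
    else:
        raise ValueError(f"unsupported distribution {distribution!r}")

    keep = w > 0
    pts, w = pts[keep], w[keep]
    if pts.size == 0:
        raise ValueError("distribution support does not overlap parameter domain")
    w = w / w.sum()

    first = eval_at(pts[0])
    acc = w[0] * first.Y
    for p, wi in zip(pts[1:], w[1:]):
        acc = acc + wi * eval_at(p).Y
    out = DataSet(np.column_stack([first.X, acc]), dict(first.attributes), [],
                  {"X": 0, "Y": 1})
    out.attributes.update(dist_param=param, distribution=distribution,
                          dist_mean=mean, dist_width=width)
    out.attributes.pop(param, None)
    return out
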