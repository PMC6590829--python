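"""Instrument resolution smearing and iterative Lake desmearing.

Two kernel geometries are supported: per-point Gaussian q-resolution
(pinhole SANS, Pedersen-style) and an infinite-slit/Kratky geometry.  The
forward operator is

    I_s(q) = Int K(q, q') I(q') dq'

evaluated by quadrature on an oversampled grid with every kernel row
normalized to unit mass; outside the measured range the curve is
continued by a fitted Porod power law so the kernel support is covered.

Desmearing inverts the operator with the Lake iteration in its
multiplicative (positivity-preserving) form,

    I_{n+1} = I_n * [ I_meas / smear(I_n) ] ,

with a centered moving-average smoothing of odd width applied to the
update ratio each iteration and an automatic chi-square convergence
criterion: stop when
the chi-square between smear(I_n) and the measurement stops improving by
more than 0.1 % or drops to the number of degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .datacore import DataSet

__all__ = ["ResolutionKernel", "smear", "desmear_lake"]


@dataclass
class ResolutionKernel:
    """Gaussian or slit resolution description.

    kind='gaussian': *sigma* is a scalar, an array matching the data grid,
    or a callable sigma(q) giving the per-point Gaussian width.
    kind='slit': *slit_length* is the half-length L of the (infinite)
    slit in q units; the smeared intensity is
    I_s(q) = (1/L) Int_0^L I(sqrt(q^2 + u^2)) du.
    """

    kind: str = "gaussian"
    sigma: float | Sequence[float] | Callable = 0.0
    slit_length: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "slit"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")

    def sigma_at(self, q: np.ndarray) -> np.ndarray:
        if callable(self.sigma):
            return np.broadcast_to(np.asarray(self.sigma(q), float), q.shape)
        return np.broadcast_to(np.asarray(self.sigma, dtype=float), q.shape)


def _porod_extension(q, I, qext):
    """Continue a curve beyond its last points by a fitted A q^-4 tail.

    The amplitude estimate is linear in I, which keeps the whole smearing
    operator exactly linear; points within a kernel width of the upper
    edge therefore inherit a Porod assumption.
    """
    n = max(3, len(q) // 10)
    A = np.mean(I[-n:] * q[-n:] ** 4)
    return A / qext**4


def _interp_extend(qgrid, q, I):
    """I on qgrid: interpolation inside, Porod tail above, flat below."""
    out = np.interp(qgrid, q, I, left=I[0], right=np.nan)
    high = qgrid > q[-1]
    if np.any(high):
        out[high] = _porod_extension(q, I, qgrid[high])
    return out


def _smear_values(q, I, kernel: ResolutionKernel, oversample: int = 4):
    q = np.asarray(q, dtype=float)
    I = np.asarray(I, dtype=float)
    if kernel.kind == "gaussian":
        sig = kernel.sigma_at(q)
        if np.all(sig <= 0):
            return I.copy()
        out = I.copy()
        act = sig > 0
        smax = sig.max()
        span = 5.0 * smax
        if q[-1] - q[0] < 2 * span and q[-1] < span:
            raise ValueError("kernel wider than the data range")
        # oversampled quadrature grid covering the kernel support
        dq = min(np.diff(q).min() / oversample, smax / 6.0)
        qq = np.arange(max(q[0] - span, dq / 2), q[-1] + span, dq)
        II = _interp_extend(qq, q, I)
        for i in np.nonzero(act)[0]:
            w = np.exp(-0.5 * ((qq - q[i]) / sig[i]) ** 2)
            w /= w.sum()
            out[i] = np.dot(w, II)
        return out
    # slit geometry
    L = kernel.slit_length
    if L <= 0:
        return I.copy()
    nu = 64
    u = (np.arange(nu) + 0.5) / nu * L
    qeff = np.sqrt(q[:, None] ** 2 + u[None, :] ** 2)
    flat = _interp_extend(np.sort(np.unique(qeff.ravel())), q, I)
    vals = np.interp(qeff, np.sort(np.unique(qeff.ravel())), flat)
    return vals.mean(axis=1)


def smear(curve: DataSet, kernel: ResolutionKernel) -> DataSet:
    """Apply the resolution kernel to a [q, I] curve."""
    Is = _smear_values(curve.X, curve.Y, kernel)
    attrs = dict(curve.attributes)
    attrs["smeared"] = 1.0
    return DataSet(np.column_stack([curve.X, Is]), attrs, list(curve.comments),
                   {"X": 0, "Y": 1})


def _moving_average(y, width):
    if width <= 1:
        return y
    if width % 2 == 0:
        width += 1
    pad = width // 2
    yp = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    kern = np.ones(width) / width
    return np.convolve(yp, kern, mode="valid")


def desmear_lake(measured: DataSet, kernel: ResolutionKernel,
                 smoothing_window: int = 5, max_iter: int = 50) -> DataSet:
    """Iterative Lake desmearing with smoothing and automatic stopping.

    The measured curve must be positive; eY (where present) weights the
    convergence chi-square.  Returns the desmeared curve with the
    iteration count and final reduced chi-square as attributes.  If the
    chi-square rises three iterations in a row the best iterate found so
    far is returned inside a RuntimeError's ``args[1]``.
    """
    q, Imeas = measured.X, measured.Y
    if np.any(Imeas <= 0):
        raise ValueError("measured intensities must be positive")
    eY = measured.eY
    wgt = 1.0 / np.where(eY > 0, eY, 1.0) if eY is not None else np.ones_like(Imeas)
    dof = len(q)

    def chi2_of(candidate):
        return float(np.sum(((smear_vals(candidate) - Imeas) * wgt) ** 2))

    def smear_vals(candidate):
        return _smear_values(q, candidate, kernel)

    I = Imeas.copy()
    best = I.copy()
    best_chi2 = chi2_of(I)
    if best_chi2 <= dof:
        # the measurement already explains itself (e.g. identity kernel)
        return _result(measured, best, 0, best_chi2 / dof)
    prev_chi2 = best_chi2
    rising = 0
    niter = 0
    for niter in range(1, max_iter + 1):
        ratio = Imeas / np.clip(smear_vals(I), 1e-300, None)
        # smoothing the update ratio (close to 1 + noise) suppresses the
        # noise amplification without flattening sharp features of I
        I = I * _moving_average(ratio, smoothing_window)
        if np.any(I <= 0):
            warnings.warn("nonpositive intermediate values floored", stacklevel=2)
            I = np.clip(I, 1e-12, None)
        chi2 = chi2_of(I)
        if chi2 < best_chi2:
            best, best_chi2 = I.copy(), chi2
        if chi2 > prev_chi2:
            rising += 1
            if rising >= 3:
                raise RuntimeError(
                    "Lake iteration diverging (chi-square rose 3 times); "
                    "best iterate attached", _result(measured, best, niter,
                                                     best_chi2 / dof))
        else:
            rising = 0
        if chi2 <= dof or (prev_chi2 - chi2) < 1e-3 * prev_chi2:
            prev_chi2 = chi2
            break
        prev_chi2 = chi2
    return _result(measured, best, niter, best_chi2 / dof)


def _result(measured, I, niter, chi2_red):
    attrs = dict(measured.attributes)
    attrs.update(iterations=float(niter), chi2_reduced=float(chi2_red))
    cols = [measured.X, I]
    roles = {"X": 0, "Y": 1}
    if measured.eY is not None:
        cols.append(measured.eY)
        roles["eY"] = 2
    return DataSet(np.column_stack(cols), attrs, list(measured.comments), roles)
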