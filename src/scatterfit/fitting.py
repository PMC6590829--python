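"""Simultaneous chi-square fitting of a model against a DataCollection.

The central idea is *attribute binding*: a model is an ordinary Python
function ``model(x, a, D, q, ...)``; any parameter whose name matches a
dataset attribute is bound per-dataset as a fixed value, so one model fits a
whole multi-condition measurement series at once.  Remaining parameters are
either *common* (one value shared by all datasets; scalar start) or
*independent* (one value per dataset; list start).

Usage follows the statsmodels shape::

    model = MultiDataModel(collection, func, fixed={"R": 3.0})
    result = model.fit(free={"D": 0.1}, algorithm="leastsquare")
    print(result.summary())

``result`` carries best-fit values, 1-sigma errors from the covariance
scaled by the reduced chi-square, the per-dataset model curves and a
``simulate`` method for what-if parameter variation.
"""

from __future__ import annotations

import inspect
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .datacore import DataCollection, DataSet, write_ascii

__all__ = [
    "ParameterBinding",
    "MultiDataModel",
    "FitResult",
    "resolve_parameters",
    "fit",
    "simulate",
]

_SOURCES = ("free-common", "free-independent", "fixed-user", "fixed-attribute", "model-default")


@dataclass
class ParameterBinding:
    """How one model parameter is supplied during the fit."""

    name: str
    source: str  # one of _SOURCES
    values: object  # scalar, or per-dataset array for independent/attribute
    bounds: tuple | None = None

    def __post_init__(self) -> None:
        if self.source not in _SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    def per_dataset(self, i: int):
        if self.source in ("free-independent", "fixed-attribute"):
            return self.values[i]
        return self.values


def _model_signature(model: Callable) -> tuple[str, list, dict]:
    """(x-name, parameter names, defaults) from the model's signature."""
    sig = inspect.signature(model)
    names = list(sig.parameters)
    if not names:
        raise ValueError("model must accept at least the abscissa argument")
    defaults = {
        n: p.default
        for n, p in sig.parameters.items()
        if p.default is not inspect.Parameter.empty
    }
    return names[0], names[1:], defaults


def resolve_parameters(
    model_signature: Sequence[str],
    collection: DataCollection,
    free: Mapping[str, object] | None = None,
    fixed: Mapping[str, object] | None = None,
    defaults: Mapping[str, object] | None = None,
    bounds: Mapping[str, tuple] | None = None,
) -> list[ParameterBinding]:
    """Bind every model parameter to exactly one source.

    Priority: user-fixed value > free start > dataset attribute > model
    default.  A scalar free start makes the parameter common; a list start
    (length = collection size) makes it independent per dataset.
    """
    free = dict(free or {})
    fixed = dict(fixed or {})
    defaults = dict(defaults or {})
    bounds = dict(bounds or {})
    for name in list(free) + list(fixed):
        if name not in model_signature:
            raise ValueError(f"parameter {name!r} not in model signature {list(model_signature)}")

    n = len(collection)
    bindings = []
    for name in model_signature:
        bnd = bounds.get(name)
        if name in fixed:
            bindings.append(ParameterBinding(name, "fixed-user", fixed[name], bnd))
        elif name in free:
            start = free[name]
            if np.ndim(start) > 0:
                start = np.asarray(start, dtype=float)
                if len(start) != n:
                    raise ValueError(
                        f"independent start for {name!r} has length {len(start)}, "
                        f"collection has {n} items"
                    )
                bindings.append(ParameterBinding(name, "free-independent", start, bnd))
            else:
                bindings.append(ParameterBinding(name, "free-common", float(start), bnd))
        elif all(name in ds.attributes for ds in collection):
            vals = [ds.attributes[name] for ds in collection]
            bindings.append(ParameterBinding(name, "fixed-attribute", vals, bnd))
        elif name in defaults:
            bindings.append(ParameterBinding(name, "model-default", defaults[name], bnd))
        else:
            raise ValueError(
                f"parameter {name!r} has no source: not free, not fixed, not a "
                "dataset attribute and no model default"
            )
    return bindings


class _Pack:
    """Maps between the optimizer vector and named per-dataset parameters.

    Independent parameters occupy contiguous slices, one slice per name.
    """

    def __init__(self, bindings: list[ParameterBinding], n_datasets: int) -> None:
        self.bindings = bindings
        self.n = n_datasets
        self.slices: dict[str, slice] = {}
        pos = 0
        for b in bindings:
            if b.source == "free-common":
                self.slices[b.name] = slice(pos, pos + 1)
                pos += 1
            elif b.source == "free-independent":
                self.slices[b.name] = slice(pos, pos + n_datasets)
                pos += n_datasets
        self.size = pos

    def start_vector(self) -> np.ndarray:
        v = np.empty(self.size)
        for b in self.bindings:
            if b.name in self.slices:
                v[self.slices[b.name]] = b.values
        return v

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray] | None:
        lo = np.full(self.size, -np.inf)
        hi = np.full(self.size, np.inf)
        any_bound = False
        for b in self.bindings:
            if b.name in self.slices and b.bounds is not None:
                lo[self.slices[b.name]] = b.bounds[0]
                hi[self.slices[b.name]] = b.bounds[1]
                any_bound = True
        return (lo, hi) if any_bound else None

    def kwargs_for(self, theta: np.ndarray, i: int) -> dict:
        kw = {}
        for b in self.bindings:
            if b.source == "free-common":
                kw[b.name] = theta[self.slices[b.name]][0]
            elif b.source == "free-independent":
                kw[b.name] = theta[self.slices[b.name]][i]
            else:
                kw[b.name] = b.per_dataset(i)
        return kw

    def named(self, theta: np.ndarray) -> dict:
        out = {}
        for name, sl in self.slices.items():
            vals = theta[sl]
            out[name] = float(vals[0]) if vals.size == 1 else np.asarray(vals)
        return out


def _eval_model(model, x, kwargs):
    out = model(x, **kwargs)
    extra = {}
    if isinstance(out, DataSet):
        extra = dict(out.attributes)
        out = out.Y
    y = np.asarray(out, dtype=float)
    return y, extra


class FitResult:
    """Best-fit parameters, uncertainties and diagnostics of one fit.

    Attributes
    ----------
    parameters : dict
        name -> scalar (common) or per-dataset array (independent).
    errors : dict
        1-sigma uncertainties on the same layout (NaN when the covariance
        is singular).
    covariance : ndarray
        Covariance over the packed free-parameter vector, scaled by the
        reduced chi-square.
    chi2_reduced : float
    model_curves : DataCollection
        One model curve per input dataset; each carries all bound parameter
        values (and any attributes the model computed) as attributes.
    """

    def __init__(self, model, pack, theta, cov, chi2, dof, collection, curves,
                 model_name, algorithm, extra_attributes):
        self._model = model
        self._pack = pack
        self.theta = theta
        self.parameters = pack.named(theta)
        self.covariance = cov
        self.chi2 = chi2
        self.dof = dof
        self.chi2_reduced = chi2 / dof if dof > 0 else math.nan
        self.model_curves = curves
        self.model_name = model_name
        self.algorithm = algorithm
        self.collection = collection
        self.extra_attributes = extra_attributes
        self.errors = self._errors_from_cov(cov)

    def _errors_from_cov(self, cov):
        errors = {}
        if cov is None:
            return {k: (math.nan if np.ndim(v) == 0 else np.full(np.shape(v), np.nan))
                    for k, v in self.parameters.items()}
        diag = np.sqrt(np.clip(np.diag(cov), 0, None))
        for name, sl in self._pack.slices.items():
            vals = diag[sl]
            errors[name] = float(vals[0]) if vals.size == 1 else vals
        return errors

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"Model: {self.model_name}    algorithm: {self.algorithm}",
            f"datasets: {len(self.collection)}   chi2_red = {self.chi2_reduced:.6g}",
            f"{'parameter':<16}{'estimate':>16}{'1-sigma':>16}  source",
        ]
        for b in self._pack.bindings:
            if b.name in self.parameters:
                est, err = self.parameters[b.name], self.errors[b.name]
                if np.ndim(est) == 0:
                    lines.append(f"{b.name:<16}{est:>16.6g}{err:>16.3g}  {b.source}")
                else:
                    for i, (e, s) in enumerate(zip(est, np.atleast_1d(err))):
                        lines.append(f"{b.name + f'[{i}]':<16}{e:>16.6g}{s:>16.3g}  {b.source}")
            else:
                lines.append(f"{b.name:<16}{'(bound)':>16}{'-':>16}  {b.source}")
        return "\n".join(lines)

    def save(self, sink) -> str:
        """Serialize the fit (parameters as attributes on the model curves)."""
        return write_ascii(self.model_curves, sink)

    def simulate(self, overrides: Mapping[str, object] | None = None,
                 x_grid: Sequence[float] | None = None) -> DataCollection:
        return simulate(self._model, self, overrides or {}, x_grid)


class MultiDataModel:
    """A model function bound to a DataCollection, ready to fit.

    Parameters
    ----------
    collection : DataCollection or DataSet
        The data; eY columns (where present) weight the residuals as
        1-sigma errors.
    model : callable
        ``model(x, **parameters) -> ndarray`` (or a DataSet whose Y is
        used and whose attributes are propagated into the result).
    fixed : mapping, optional
        User-fixed parameter values (highest priority, overriding dataset
        attributes of the same name).
    bounds : mapping, optional
        name -> (lo, hi) applied to free parameters.
    """

    def __init__(self, collection, model: Callable, fixed=None, bounds=None,
                 constraints=None, penalty_weight: float = 1e6) -> None:
        if isinstance(collection, DataSet):
            collection = DataCollection([collection])
        if len(collection) == 0:
            raise ValueError("empty collection")
        self.collection = collection
        self.model = model
        self.fixed = dict(fixed or {})
        self.bounds = dict(bounds or {})
        self.constraints = list(constraints or [])
        self.penalty_weight = penalty_weight
        self.xname, self.param_names, self.defaults = _model_signature(model)

    # -- internals -------------------------------------------------------
    def _residuals(self, theta, pack):
        res = []
        for i, ds in enumerate(self.collection):
            y, _ = _eval_model(self.model, ds.X, pack.kwargs_for(theta, i))
            if not np.all(np.isfinite(y)):
                raise FloatingPointError(
                    f"model returned non-finite values at {pack.named(theta)}"
                )
            w = ds.eY
            r = (ds.Y - y) / np.where(np.asarray(w) > 0, w, 1.0) if w is not None else ds.Y - y
            res.append(r)
        r = np.concatenate(res)
        if self.constraints:
            pen = [math.sqrt(self.penalty_weight) * max(0.0, -c(**pack.named(theta)))
                   for c in self.constraints]
            r = np.concatenate([r, pen])
        return r

    def _chi2(self, theta, pack) -> float:
        return float(np.sum(self._residuals(theta, pack) ** 2))

    def fit(self, free: Mapping[str, object], algorithm: str = "leastsquare",
            seed: int = 12345, **options) -> FitResult:
        """Minimize chi-square over the free parameters.

        algorithm : 'leastsquare' (Levenberg-Marquardt / trust-region),
        'neldermead', 'bfgs' or 'diffev' (differential evolution; *seed*
        makes it reproducible).
        """
        bindings = resolve_parameters(
            self.param_names, self.collection, free, self.fixed, self.defaults, self.bounds
        )
        pack = _Pack(bindings, len(self.collection))
        if pack.size == 0:
            raise ValueError("no free parameters")
        theta0 = pack.start_vector()
        barr = pack.bounds_arrays()

        if algorithm == "leastsquare":
            method = "trf" if barr is not None else "lm"
            sol = optimize.least_squares(
                self._residuals, theta0, args=(pack,), method=method,
                bounds=barr if barr is not None else (-np.inf, np.inf),
                xtol=options.pop("xtol", 1e-12), ftol=options.pop("ftol", 1e-12),
                gtol=options.pop("gtol", 1e-12),
            )
            theta = sol.x
        elif algorithm in ("neldermead", "bfgs"):
            meth = {"neldermead": "Nelder-Mead", "bfgs": "BFGS"}[algorithm]
            sol = optimize.minimize(
                self._chi2, theta0, args=(pack,), method=meth,
                options={"maxiter": options.pop("maxiter", 20000),
                         "xatol": 1e-10, "fatol": 1e-12} if meth == "Nelder-Mead"
                else {"maxiter": options.pop("maxiter", 20000)},
            )
            theta = sol.x
        elif algorithm == "diffev":
            if barr is None:
                span = np.maximum(np.abs(theta0), 1.0)
                lo, hi = theta0 - 10 * span, theta0 + 10 * span
            else:
                lo, hi = barr
            sol = optimize.differential_evolution(
                self._chi2, bounds=list(zip(lo, hi)), args=(pack,),
                seed=seed, tol=options.pop("tol", 1e-10), polish=True,
                maxiter=options.pop("maxiter", 2000), init="latinhypercube",
            )
            theta = sol.x
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")

        return self._build_result(theta, pack, algorithm)

    def _build_result(self, theta, pack, algorithm) -> FitResult:
        chi2 = self._chi2(theta, pack)
        npoints = sum(ds.nrows for ds in self.collection)
        dof = max(npoints - pack.size, 1)
        cov = self._covariance(theta, pack, chi2 / dof)

        curves = DataCollection()
        extra_attributes = []
        for i, ds in enumerate(self.collection):
            kw = pack.kwargs_for(theta, i)
            y, extra = _eval_model(self.model, ds.X, kw)
            attrs = {k: v for k, v in kw.items() if np.ndim(v) <= 1 and not isinstance(v, str)}
            attrs.update(extra)
            curves.append(DataSet(np.column_stack([ds.X, y]), attrs, [], {"X": 0, "Y": 1}))
            extra_attributes.append(extra)
        name = getattr(self.model, "__name__", "model")
        return FitResult(self.model, pack, theta, cov, chi2, dof,
                         self.collection, curves, name, algorithm, extra_attributes)

    def _covariance(self, theta, pack, scale):
        # numeric Jacobian of the residual vector at the optimum
        f0 = self._residuals(theta, pack)
        jac = np.empty((f0.size, theta.size))
        for j in range(theta.size):
            h = 1e-7 * max(abs(theta[j]), 1e-3)
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            jac[:, j] = (self._residuals(tp, pack) - self._residuals(tm, pack)) / (2 * h)
        jtj = jac.T @ jac
        try:
            cov = np.linalg.inv(jtj) * scale
        except np.linalg.LinAlgError:
            warnings.warn("singular covariance; parameter errors unavailable", stacklevel=2)
            return None
        if not np.all(np.isfinite(cov)):
            warnings.warn("non-finite covariance; parameter errors unavailable", stacklevel=2)
            return None
        return 0.5 * (cov + cov.T)


def fit(collection, model, free, fixed=None, bounds=None,
        algorithm: str = "leastsquare", seed: int = 12345, **options) -> FitResult:
    """Functional one-shot interface over :class:`MultiDataModel`."""
    return MultiDataModel(collection, model, fixed=fixed, bounds=bounds).fit(
        free, algorithm=algorithm, seed=seed, **options
    )


def simulate(model, result: FitResult, overrides: Mapping[str, object],
             x_grid: Sequence[float] | None = None) -> DataCollection:
    """Re-evaluate a fitted model with selected parameters overridden.

    Override values may be scalars or per-dataset lists; unknown names are
    rejected.  Output DataSets carry every bound parameter as an attribute.
    """
    names = set(result._pack.slices) | {b.name for b in result._pack.bindings}
    for name in overrides:
        if name not in names:
            raise ValueError(f"unknown override {name!r}")
    out = DataCollection()
    for i, ds in enumerate(result.collection):
        kw = result._pack.kwargs_for(result.theta, i)
        for name, val in overrides.items():
            kw[name] = val[i] if np.ndim(val) > 0 else val
        x = ds.X if x_grid is None else np.asarray(x_grid, dtype=float)
        y, extra = _eval_model(model, x, kw)
        attrs = {k: v for k, v in kw.items() if np.ndim(v) <= 1 and not isinstance(v, str)}
        attrs.update(extra)
        out.append(DataSet(np.column_stack([x, y]), attrs, [], {"X": 0, "Y": 1}))
    return out
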