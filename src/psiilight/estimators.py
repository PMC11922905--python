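"""Scikit-learn style estimators for light-response curve fitting.

Each estimator wraps one model family, follows the sklearn contract
(``fit``/``predict``, ``get_params``/``set_params``, fitted attributes with
a trailing underscore) and therefore composes with sklearn pipelines and
model selection.  ``X`` is the incident light intensity, accepted as a 1-D
array or a single-column 2-D array; ``y`` is the measured response (ETR,
Phi_PSII or NPQ according to ``curve_kind``).

Fitted attributes
-----------------
params_      dict of fitted parameter values
params_obj_  the validated parameter dataclass
derived_     :class:`~psiilight.curves.DerivedLightParams` (None for NPQ)
gof_         :class:`~psiilight.evaluation.GOFStats`
result_      the full :class:`~psiilight.fitting.FitResult`

Example
-------
>>> import numpy as np
>>> from psiilight.estimators import YeLightResponse
>>> from psiilight.synth import PROTOCOL_GRID
>>> from psiilight.curves import YeParams, eval_ye
>>> I = np.asarray(PROTOCOL_GRID)
>>> y = eval_ye(YeParams(0.294, 2.2e-4, 4.2e-4), kind="etr", I=I)
>>> est = YeLightResponse(curve_kind="etr", random_state=0).fit(I, y)
>>> round(est.derived_.i_sat)
1683
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import curves
from .curves import (
    DerivedLightParams,
    ExpParams,
    NRHParams,
    NegExpParams,
    YeParams,
)
from .errors import DegenerateDataError, DomainError, UnderdeterminedError
from .evaluation import gof
from .fitting import FitConfig, FitResult, SASchedule, anneal_least_squares
from .fluorescence import OpticalConstants
from .pigments import NPQCurveParams, npq_curve

__all__ = [
    "YeLightResponse",
    "NegExpLightResponse",
    "ExpLightResponse",
    "NRHLightResponse",
    "NPQLightResponse",
    "make_estimator",
    "DEFAULT_BOUNDS",
]

#: physically admissible default bounds, spanning reported crop values with
#: an order of magnitude to spare
DEFAULT_BOUNDS = {
    "alpha_e": (1e-6, 2.0),
    "phi_psii_max": (1e-6, 1.0),
    "beta_e": (0.0, 1e-2),
    "gamma_e": (1e-7, 1e-1),
    "k_w": (1e-6, 1e-1),
    "fv_fm": (1e-6, 1.0),
    "i_sat": (1.0, 5000.0),
    "alpha_prime": (1e-6, 2.0),
    "theta": (1e-6, 1.0),
    "etr_max": (1e-3, 1000.0),
    "A": (0.0, 0.1),
    "b": (1e-7, 1e-1),
    "NPQ0": (0.0, 5.0),
}

_BOUND_HIT_RTOL = 1e-6


class _LightResponseBase(RegressorMixin, BaseEstimator):
    """Shared machinery: validation, global+local search, bookkeeping."""

    _model_kind: str = ""

    def __init__(
        self,
        curve_kind: str = "etr",
        alpha: float = 0.5,
        beta: float = 0.84,
        n_starts: int = 20,
        sa_t_init: Optional[float] = None,
        sa_cooling: float = 0.92,
        sa_iters_per_temp: int = 60,
        sa_n_temps: int = 50,
        local_tol: float = 1e-10,
        bounds: Optional[dict] = None,
        k_aic: Optional[int] = None,
        random_state: int = 0,
    ):
        self.curve_kind = curve_kind
        self.alpha = alpha
        self.beta = beta
        self.n_starts = n_starts
        self.sa_t_init = sa_t_init
        self.sa_cooling = sa_cooling
        self.sa_iters_per_temp = sa_iters_per_temp
        self.sa_n_temps = sa_n_temps
        self.local_tol = local_tol
        self.bounds = bounds
        self.k_aic = k_aic
        self.random_state = random_state

    # --- model-family hooks (overridden per subclass) ---
    def _param_names(self) -> tuple:
        raise NotImplementedError

    def _curve(self, x: np.ndarray, I: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _to_params(self, x: np.ndarray):
        raise NotImplementedError

    def _derived(self, params) -> Optional[DerivedLightParams]:
        raise NotImplementedError

    def _tiebreak(self) -> tuple:
        return tuple(range(len(self._param_names())))

    # --- public API ---
    @property
    def consts_(self) -> OpticalConstants:
        return OpticalConstants(self.alpha, self.beta)

    def _validate(self, X, y=None):
        I = np.asarray(X, dtype=float)
        if I.ndim == 2:
            if I.shape[1] != 1:
                raise DomainError(
                    "X must be the light intensity: 1-D or a single column"
                )
            I = I[:, 0]
        elif I.ndim != 1:
            raise DomainError("X must be 1-D or 2-D with one column")
        if not np.all(np.isfinite(I)) or np.any(I < 0):
            raise DomainError("light intensities must be finite and >= 0")
        if y is None:
            return I
        y = np.asarray(y, dtype=float)
        if y.shape != I.shape:
            raise DomainError("X and y must have the same length")
        if not np.all(np.isfinite(y)):
            raise DomainError("response values must be finite")
        return I, y

    def fit(self, X, y):
        I, y = self._validate(X, y)
        names = self._param_names()
        d = len(names)
        if np.unique(I).size < d + 1:
            raise UnderdeterminedError(
                f"{self._model_kind} ({d} parameters) requires at least "
                f"{d + 1} distinct light intensities, got {np.unique(I).size}"
            )
        if np.ptp(y) == 0.0:
            raise DegenerateDataError("all response values identical")

        bounds = dict(DEFAULT_BOUNDS)
        if self.bounds:
            bounds.update(self.bounds)
        lo = np.array([bounds[n][0] for n in names])
        hi = np.array([bounds[n][1] for n in names])

        rng = np.random.default_rng(self.random_state)
        residuals = lambda x: self._curve(x, I) - y  # noqa: E731
        schedule = SASchedule(
            t_init=self.sa_t_init,
            cooling=self.sa_cooling,
            iters_per_temp=self.sa_iters_per_temp,
            n_temps=self.sa_n_temps,
        )
        x, ssr, info = anneal_least_squares(
            residuals,
            lo,
            hi,
            rng,
            n_starts=self.n_starts,
            schedule=schedule,
            local_tol=self.local_tol,
            tiebreak=self._tiebreak(),
        )

        hits = [
            n
            for n, xi, l, h in zip(names, x, lo, hi)
            if min(xi - l, h - xi) <= _BOUND_HIT_RTOL * (h - l)
        ]
        self.params_ = {n: float(v) for n, v in zip(names, x)}
        self.params_obj_ = self._to_params(x)
        self.derived_ = self._derived(self.params_obj_)
        k = self.k_aic if self.k_aic is not None else d
        self.gof_ = gof(y, self._curve(x, I), k)
        diagnostics = {
            "converged": info["converged"],
            "n_fev": info["n_fev"],
            "boundary_hits": hits,
            "best_start_ssr": info["best_start_ssr"],
            "seed": self.random_state,
        }
        self.result_ = FitResult(
            model_kind=self._model_kind,
            curve_kind=self.curve_kind,
            params=dict(self.params_),
            derived=self.derived_,
            gof=self.gof_,
            diagnostics=diagnostics,
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "params_"):
            raise DomainError("estimator is not fitted")
        I = self._validate(X)
        x = np.array([self.params_[n] for n in self._param_names()])
        return self._curve(x, I)


class YeLightResponse(_LightResponseBase):
    """Mechanistic light-response model.

    ``curve_kind='etr'`` fits (alpha_e, beta_e, gamma_e);
    ``curve_kind='phi'`` fits (phi_psii_max, beta_e, gamma_e).  With
    ``linked=True`` the other kind's leading coefficient is implied through
    phi_psii_max = alpha_e / (alpha*beta); the two curves are otherwise
    fitted with independent leading coefficients, as the two response kinds
    are measured and fitted separately in practice.
    """

    _model_kind = "ye"

    def __init__(
        self,
        curve_kind: str = "etr",
        alpha: float = 0.5,
        beta: float = 0.84,
        n_starts: int = 20,
        sa_t_init: Optional[float] = None,
        sa_cooling: float = 0.92,
        sa_iters_per_temp: int = 60,
        sa_n_temps: int = 50,
        local_tol: float = 1e-10,
        bounds: Optional[dict] = None,
        k_aic: Optional[int] = None,
        random_state: int = 0,
        linked: bool = True,
    ):
        super().__init__(
            curve_kind=curve_kind,
            alpha=alpha,
            beta=beta,
            n_starts=n_starts,
            sa_t_init=sa_t_init,
            sa_cooling=sa_cooling,
            sa_iters_per_temp=sa_iters_per_temp,
            sa_n_temps=sa_n_temps,
            local_tol=local_tol,
            bounds=bounds,
            k_aic=k_aic,
            random_state=random_state,
        )
        self.linked = linked

    def _param_names(self):
        if self.curve_kind == "etr":
            return ("alpha_e", "beta_e", "gamma_e")
        return ("phi_psii_max", "beta_e", "gamma_e")

    def _tiebreak(self):
        return (1, 2, 0)  # smallest beta_e, then gamma_e

    def _curve(self, x, I):
        shape = (1.0 - x[1] * I) / (1.0 + x[2] * I)
        if self.curve_kind == "etr":
            return x[0] * I * shape
        return x[0] * shape

    def _to_params(self, x):
        ab = self.consts_.ab
        if self.curve_kind == "etr":
            phi_max = x[0] / ab if self.linked else None
            if phi_max is not None and not (0 < phi_max <= 1):
                phi_max = None  # link leaves the admissible range; report unlinked
            return YeParams(x[0], x[1], x[2], phi_psii_max=phi_max)
        return YeParams(ab * x[0], x[1], x[2], phi_psii_max=x[0])

    def _derived(self, params):
        return curves.derived_ye(params)


class NegExpLightResponse(_LightResponseBase):
    """Negative-exponential quantum-yield decline; 2 parameters."""

    _model_kind = "negexp"

    def _param_names(self):
        return ("phi_psii_max", "k_w")

    def _curve(self, x, I):
        phi = x[0] * np.exp(-x[1] * I)
        if self.curve_kind == "etr":
            return self.consts_.ab * I * phi
        return phi

    def _to_params(self, x):
        return NegExpParams(x[0], x[1])

    def _derived(self, params):
        return curves.derived_negexp(params, self.consts_)


class ExpLightResponse(_LightResponseBase):
    """Saturating exponential; fits (fv_fm, i_sat)."""

    _model_kind = "exp"

    def _param_names(self):
        return ("fv_fm", "i_sat")

    def _curve(self, x, I):
        ab = self.consts_.ab
        z = I / x[1]
        if self.curve_kind == "etr":
            return -ab * x[0] * x[1] * np.expm1(-z)
        with np.errstate(invalid="ignore", divide="ignore"):
            return x[0] * np.where(z > 0, -np.expm1(-z) / np.where(z > 0, z, 1.0), 1.0)

    def _to_params(self, x):
        return ExpParams(x[0], x[1])

    def _derived(self, params):
        return curves.derived_exp(params, self.consts_)


class NRHLightResponse(_LightResponseBase):
    """Non-rectangular hyperbola; fits (alpha_prime, theta, etr_max)."""

    _model_kind = "nrh"

    def _param_names(self):
        return ("alpha_prime", "theta", "etr_max")

    def _curve(self, x, I):
        ap, th, em = x
        s = ap * I + em
        if th < 1e-12:
            etr = ap * I * em / s
        else:
            disc = s * s - 4.0 * th * ap * I * em
            etr = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * th)
        if self.curve_kind == "etr":
            return etr
        ab = self.consts_.ab
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(I > 0, etr / (ab * np.where(I > 0, I, 1.0)), ap / ab)

    def _to_params(self, x):
        return NRHParams(x[0], x[1], x[2])

    def _derived(self, params):
        return curves.derived_nrh(params)


class NPQLightResponse(_LightResponseBase):
    """Saturating NPQ light response, NPQ(I) = A*I/(1+b*I) + NPQ0."""

    _model_kind = "npq"

    def __init__(self, curve_kind: str = "npq", **kw):
        super().__init__(curve_kind=curve_kind, **kw)

    def _param_names(self):
        return ("A", "b", "NPQ0")

    def _curve(self, x, I):
        return x[0] * I / (1.0 + x[1] * I) + x[2]

    def _to_params(self, x):
        return NPQCurveParams(x[0], x[1], x[2])

    def _derived(self, params):
        return None

    def predict_asymptote(self) -> float:
        """High-light NPQ limit A/b + NPQ0 of the fitted curve."""
        p = self.params_obj_
        return p.A / p.b + p.NPQ0


_CLASSES = {
    "ye": YeLightResponse,
    "negexp": NegExpLightResponse,
    "exp": ExpLightResponse,
    "nrh": NRHLightResponse,
    "npq": NPQLightResponse,
}


def make_estimator(config: FitConfig, consts: OpticalConstants) -> _LightResponseBase:
    """Build the estimator matching a :class:`~psiilight.fitting.FitConfig`."""
    try:
        cls = _CLASSES[config.model_kind]
    except KeyError:
        raise DomainError(f"unknown model kind {config.model_kind!r}") from None
    kw = dict(
        curve_kind=config.curve_kind,
        alpha=consts.alpha,
        beta=consts.beta,
        n_starts=config.n_starts,
        sa_t_init=config.sa.t_init,
        sa_cooling=config.sa.cooling,
        sa_iters_per_temp=config.sa.iters_per_temp,
        sa_n_temps=config.sa.n_temps,
        local_tol=config.local_tol,
        bounds=config.bounds,
        k_aic=config.k_aic,
        random_state=config.seed,
    )
    if cls is YeLightResponse:
        kw["linked"] = config.linked
    return cls(**kw)
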