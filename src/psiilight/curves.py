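"""The four light-response model families.

Each model describes both the ETR-I curve and the Phi_PSII-I curve, linked
through ETR = alpha * beta * Phi_PSII * I.  The response kind is always an
explicit argument: the same family fitted to ETR data and to Phi_PSII data
yields different parameter estimates, so a model instance never infers the
kind silently.

Families
--------
ye
    Mechanistic model of the light reactions built on the photophysics of
    light-harvesting pigments.  ETR(I) = alpha_e * I * (1 - beta_e*I) /
    (1 + gamma_e*I); the aggregate parameters are the initial slope alpha_e,
    the dynamic down-regulation (photoinhibition) term beta_e and the
    saturation term gamma_e.  Closed forms exist for the saturation
    intensity I_sat and the maximum rate ETR_max.
negexp
    Negative exponential decline of the quantum yield,
    Phi_PSII(I) = phi_max * exp(-k_w * I); I_sat = 1/k_w.
exp
    Saturating exponential, ETR(I) = ab * Fv/Fm * I_sat * (1 - exp(-I/I_sat)).
    Its ETR_max convention is the curve evaluated at I = I_sat (a factor
    1 - 1/e below the asymptote), not the asymptote itself.
nrh
    Non-rectangular hyperbola with initial slope alpha_prime, curvature
    theta and asymptote etr_max.  Strictly increasing, so it defines no
    saturation intensity.

Values of the ye curves beyond I = 1/beta_e are negative and returned
as-is (not clipped): the declining branch is the photoinhibition regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .errors import DomainError
from .fluorescence import DEFAULT_CONSTANTS, OpticalConstants

__all__ = [
    "ETR",
    "PHI",
    "NPQ",
    "MODEL_KINDS",
    "YeParams",
    "NegExpParams",
    "ExpParams",
    "NRHParams",
    "DerivedLightParams",
    "eval_ye",
    "eval_negexp",
    "eval_exp",
    "eval_nrh",
    "derived_ye",
    "derived_negexp",
    "derived_exp",
    "derived_nrh",
    "eval_model",
    "derived_params",
]

# canonical curve-kind tokens
ETR = "etr"
PHI = "phi"
NPQ = "npq"

MODEL_KINDS = ("ye", "negexp", "exp", "nrh")

# flags used by DerivedLightParams.i_sat_flag
NOT_FINITE = "not_finite"
NOT_DEFINED = "not_defined_by_model"


def _check_I(I) -> np.ndarray:
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise DomainError("light intensities must be >= 0")
    return I


@dataclass(frozen=True)
class YeParams:
    """Aggregate parameters of the mechanistic model.

    alpha_e : initial slope of ETR-I, umol electrons (umol photons)^-1
    beta_e  : dynamic down-regulation term, m^2 s (umol photons)^-1
    gamma_e : saturation term, m^2 s (umol photons)^-1
    phi_psii_max : maximum effective quantum efficiency; equals
        alpha_e / (alpha*beta) when the two curve kinds are linked, but is
        kept as an independent free parameter otherwise.
    """

    alpha_e: float
    beta_e: float
    gamma_e: float
    phi_psii_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.alpha_e <= 0:
            raise DomainError(f"alpha_e must be > 0, got {self.alpha_e}")
        if self.gamma_e <= 0:
            raise DomainError(f"gamma_e must be > 0, got {self.gamma_e}")
        if self.beta_e < 0:
            raise DomainError(f"beta_e must be >= 0, got {self.beta_e}")
        if self.phi_psii_max is not None and not (0 < self.phi_psii_max <= 1):
            raise DomainError(
                f"phi_psii_max must be in (0, 1], got {self.phi_psii_max}"
            )

    @classmethod
    def linked(
        cls,
        alpha_e: float,
        beta_e: float,
        gamma_e: float,
        consts: OpticalConstants = DEFAULT_CONSTANTS,
    ) -> "YeParams":
        """Construct with phi_psii_max = alpha_e / (alpha*beta)."""
        return cls(alpha_e, beta_e, gamma_e, phi_psii_max=alpha_e / consts.ab)


@dataclass(frozen=True)
class NegExpParams:
    """phi_psii_max in (0, 1]; k_w > 0 in (umol photons m^-2 s^-1)^-1."""

    phi_psii_max: float
    k_w: float

    def __post_init__(self) -> None:
        if not (0 < self.phi_psii_max <= 1):
            raise DomainError(
                f"phi_psii_max must be in (0, 1], got {self.phi_psii_max}"
            )
        if self.k_w <= 0:
            raise DomainError(f"k_w must be > 0, got {self.k_w}")


@dataclass(frozen=True)
class ExpParams:
    """fv_fm in (0, 1]; i_sat > 0 in umol photons m^-2 s^-1."""

    fv_fm: float
    i_sat: float

    def __post_init__(self) -> None:
        if not (0 < self.fv_fm <= 1):
            raise DomainError(f"fv_fm must be in (0, 1], got {self.fv_fm}")
        if self.i_sat <= 0:
            raise DomainError(f"i_sat must be > 0, got {self.i_sat}")


@dataclass(frozen=True)
class NRHParams:
    """Non-rectangular hyperbola parameters.

    alpha_prime > 0 (initial slope); theta in [0, 1] (curvature; theta = 0
    degenerates to the rectangular hyperbola, handled analytically);
    etr_max > 0 (asymptote).
    """

    alpha_prime: float
    theta: float
    etr_max: float

    def __post_init__(self) -> None:
        if self.alpha_prime <= 0:
            raise DomainError(f"alpha_prime must be > 0, got {self.alpha_prime}")
        if not (0 <= self.theta <= 1):
            raise DomainError(f"theta must be in [0, 1], got {self.theta}")
        if self.etr_max <= 0:
            raise DomainError(f"etr_max must be > 0, got {self.etr_max}")


@dataclass(frozen=True)
class DerivedLightParams:
    """Derived saturation traits of a light-response curve.

    i_sat may be NaN with a flag: ``not_finite`` when the curve increases
    monotonically (ye with beta_e = 0) or ``not_defined_by_model`` when the
    family has no saturation intensity (nrh).  etr_max is then the supremum
    (ye, beta_e = 0) or the fitted asymptote (nrh).
    """

    i_sat: float
    etr_max: float
    i_sat_flag: Optional[str] = None

    @property
    def i_sat_finite(self) -> bool:
        return self.i_sat_flag is None and math.isfinite(self.i_sat)


# --- mechanistic (ye) model -------------------------------------------------

def eval_ye(
    params: YeParams,
    consts: OpticalConstants = DEFAULT_CONSTANTS,
    kind: str = ETR,
    I=0.0,
) -> np.ndarray:
    """ETR(I) = alpha_e*I*(1-beta_e*I)/(1+gamma_e*I);
    Phi(I) = phi_psii_max*(1-beta_e*I)/(1+gamma_e*I)."""
    I = _check_I(I)
    shape = (1.0 - params.beta_e * I) / (1.0 + params.gamma_e * I)
    if kind == ETR:
        return params.alpha_e * I * shape
    if kind == PHI:
        if params.phi_psii_max is None:
            raise DomainError("phi_psii_max must be set to evaluate a Phi curve")
        return params.phi_psii_max * shape
    raise DomainError(f"unknown curve kind {kind!r}")


def derived_ye(params: YeParams) -> DerivedLightParams:
    """Closed-form saturation intensity and maximum rate.

    I_sat = (sqrt((beta_e+gamma_e)/beta_e) - 1) / gamma_e
    ETR_max = alpha_e * ((sqrt(beta_e+gamma_e) - sqrt(beta_e)) / gamma_e)^2

    With beta_e = 0 the curve rises monotonically towards the supremum
    alpha_e/gamma_e and I_sat is flagged not finite.
    """
    a, b, g = params.alpha_e, params.beta_e, params.gamma_e
    if b == 0.0:
        return DerivedLightParams(math.inf, a / g, i_sat_flag=NOT_FINITE)
    i_sat = (math.sqrt((b + g) / b) - 1.0) / g
    etr_max = a * ((math.sqrt(b + g) - math.sqrt(b)) / g) ** 2
    return DerivedLightParams(i_sat, etr_max)


# --- negative exponential ---------------------------------------------------

def eval_negexp(
    params: NegExpParams,
    consts: OpticalConstants = DEFAULT_CONSTANTS,
    kind: str = PHI,
    I=0.0,
) -> np.ndarray:
    I = _check_I(I)
    phi = params.phi_psii_max * np.exp(-params.k_w * I)
    if kind == PHI:
        return phi
    if kind == ETR:
        return consts.ab * I * phi
    raise DomainError(f"unknown curve kind {kind!r}")


def derived_negexp(
    params: NegExpParams, consts: OpticalConstants = DEFAULT_CONSTANTS
) -> DerivedLightParams:
    """I_sat = 1/k_w; ETR_max = ab * I_sat * phi_max / e."""
    i_sat = 1.0 / params.k_w
    etr_max = consts.ab * i_sat * params.phi_psii_max * math.exp(-1.0)
    return DerivedLightParams(i_sat, etr_max)


# --- saturating exponential -------------------------------------------------

def eval_exp(
    params: ExpParams,
    consts: OpticalConstants = DEFAULT_CONSTANTS,
    kind: str = PHI,
    I=0.0,
) -> np.ndarray:
    """Phi(I) = fv_fm * (I_sat/I) * (1 - exp(-I/I_sat)), with the analytic
    I -> 0 limit fv_fm used at I = 0."""
    I = _check_I(I)
    x = I / params.i_sat
    if kind == ETR:
        return -consts.ab * params.fv_fm * params.i_sat * np.expm1(-x)
    if kind == PHI:
        # -expm1(-x)/x -> 1 as x -> 0
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(x > 0, -np.expm1(-x) / np.where(x > 0, x, 1.0), 1.0)
        return params.fv_fm * ratio
    raise DomainError(f"unknown curve kind {kind!r}")


def derived_exp(
    params: ExpParams, consts: OpticalConstants = DEFAULT_CONSTANTS
) -> DerivedLightParams:
    """ETR_max = ab * fv_fm * I_sat * (1 - 1/e); I_sat is the fitted
    parameter itself.

    Note this ETR_max is the ETR curve evaluated at I = I_sat, a factor
    (1 - 1/e) below the asymptote ab * fv_fm * I_sat — the family's own
    convention, since the curve saturates only asymptotically.
    """
    etr_max = consts.ab * params.fv_fm * params.i_sat * (1.0 - math.exp(-1.0))
    return DerivedLightParams(params.i_sat, etr_max)


# --- non-rectangular hyperbola ----------------------------------------------

_THETA_EPS = 1e-12


def eval_nrh(
    params: NRHParams,
    consts: OpticalConstants = DEFAULT_CONSTANTS,
    kind: str = ETR,
    I=0.0,
) -> np.ndarray:
    """ETR(I) = [a' I + ETRmax - sqrt((a' I + ETRmax)^2 - 4 theta a' I ETRmax)]
    / (2 theta); theta -> 0 reduces to the rectangular hyperbola.

    Phi(I) = ETR(I)/(ab*I) with the analytic limit alpha_prime/ab at I = 0.
    """
    I = _check_I(I)
    ap, th, em = params.alpha_prime, params.theta, params.etr_max
    s = ap * I + em
    if th < _THETA_EPS:
        etr = ap * I * em / s
    else:
        disc = s * s - 4.0 * th * ap * I * em
        etr = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * th)
    if kind == ETR:
        return etr
    if kind == PHI:
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(I > 0, etr / (consts.ab * np.where(I > 0, I, 1.0)),
                           ap / consts.ab)
        return phi
    raise DomainError(f"unknown curve kind {kind!r}")


def derived_nrh(params: NRHParams) -> DerivedLightParams:
    """The curve increases strictly towards its asymptote, so no saturation
    intensity exists; etr_max is the fitted asymptote parameter."""
    return DerivedLightParams(math.nan, params.etr_max, i_sat_flag=NOT_DEFINED)


# --- generic dispatch -------------------------------------------------------

_EVAL: dict[str, Callable] = {
    "ye": eval_ye,
    "negexp": eval_negexp,
    "exp": eval_exp,
    "nrh": eval_nrh,
}


def eval_model(model_kind, params, consts=DEFAULT_CONSTANTS, kind=ETR, I=0.0):
    """Evaluate any model family by its kind token."""
    try:
        f = _EVAL[model_kind]
    except KeyError:
        raise DomainError(f"unknown model kind {model_kind!r}") from None
    return f(params, consts, kind, I)


def derived_params(model_kind, params, consts=DEFAULT_CONSTANTS) -> DerivedLightParams:
    """Derived saturation traits for any model family."""
    if model_kind == "ye":
        return derived_ye(params)
    if model_kind == "negexp":
        return derived_negexp(params, consts)
    if model_kind == "exp":
        return derived_exp(params, consts)
    if model_kind == "nrh":
        return derived_nrh(params)
    raise DomainError(f"unknown model kind {model_kind!r}")
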