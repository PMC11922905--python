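"""Pigment-level photophysics behind the mechanistic model.

The aggregate curve parameters (alpha_e, beta_e, gamma_e) decompose into
microscopic quantities of the light-harvesting antenna: the eigen-absorption
cross-section sigma_ik of a pigment molecule (ground state i -> excited
state k), the excited-state lifetime tau, the occupation probabilities of
photochemistry / heat loss / fluorescence (xi1, xi2, xi3), the photochemical
and heat-loss rate constants (k_P, k_D), the degeneracy ratio g_i/g_k of the
two energy levels, the total pigment pool N0, the exciton-use efficiency
phi and the leaf area S.  Writing

    D = xi3 + (xi1*k_P + xi2*k_D) * tau        (de-excitation denominator)
    u = sigma_ik * tau / D

the aggregation reads

    alpha_e = alpha * beta * N0 * sigma_ik * phi / S
    beta_e  = (1 - g_i/g_k) * u
    gamma_e = (1 + g_i/g_k) * u

so gamma_e - beta_e = 2*(g_i/g_k)*u > 0 whenever 0 < g_i/g_k < 1.

Light-dependent responses derived from the same algebra:

    sigma'_ik(I) = sigma_ik * (1 - beta_e*I) / (1 + gamma_e*I)
    Phi_PSII(I)  = phi_max * sigma'_ik(I) / sigma_ik
    N_k/N0 (I)   = [1/(1 - g_i/g_k)] * beta_e*I / (1 + gamma_e*I)
    NPQ(I)       = A*I / (1 + b*I) + NPQ0

NPQ mirrors the excited-state fraction N_k/N0 (both are saturating in I up
to an affine transform).  The NPQ amplitude A lumps the product
NPQ_max * a, which is not separately identifiable from an NPQ-I fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .curves import YeParams
from .errors import DomainError
from .fluorescence import DEFAULT_CONSTANTS, OpticalConstants

__all__ = [
    "MicroscopicParams",
    "NPQCurveParams",
    "aggregate_from_microscopic",
    "sigma_eff",
    "phi_from_sigma",
    "nk_fraction",
    "npq_curve",
    "sigma_ik_from_alpha_e",
]

#: exciton-use efficiency and leaf area used throughout the study
DEFAULT_PHI_EXCITON = 0.95
DEFAULT_LEAF_AREA = 6e-4  # m^2


@dataclass(frozen=True)
class MicroscopicParams:
    """Pigment-level parameters for forward simulation and decomposition.

    ``g_ratio`` is g_i/g_k and must lie in [0, 1) so the down-regulation
    term stays non-negative.  ``R_ki`` (spontaneous k -> i transition rate)
    is carried as documentation only; it enters no displayed computation.
    ``n0_unit`` records whether N0 is a molecule count or an amount of
    substance — the algebra is unit-agnostic and no conversion is implied.
    """

    sigma_ik: float          # m^2
    tau: float               # s
    xi1: float
    xi2: float
    xi3: float
    k_P: float               # s^-1
    k_D: float               # s^-1
    g_ratio: float           # g_i / g_k
    N0: float
    phi_exciton: float = DEFAULT_PHI_EXCITON
    S: float = DEFAULT_LEAF_AREA
    R_ki: Optional[float] = None
    n0_unit: str = "molecules"

    def __post_init__(self) -> None:
        for name in ("sigma_ik", "tau", "k_P", "k_D", "N0", "S"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        for name in ("xi1", "xi2", "xi3"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if not (0.0 <= self.g_ratio < 1.0):
            raise DomainError(f"g_ratio must be in [0, 1), got {self.g_ratio}")
        if not (0.0 < self.phi_exciton <= 1.0):
            raise DomainError(
                f"phi_exciton must be in (0, 1], got {self.phi_exciton}"
            )


@dataclass(frozen=True)
class NPQCurveParams:
    """Saturating NPQ light response: NPQ(I) = A*I/(1 + b*I) + NPQ0."""

    A: float
    b: float
    NPQ0: float

    def __post_init__(self) -> None:
        if self.A < 0:
            raise DomainError(f"A must be >= 0, got {self.A}")
        if self.b <= 0:
            raise DomainError(f"b must be > 0, got {self.b}")
        if self.NPQ0 < 0:
            raise DomainError(f"NPQ0 must be >= 0, got {self.NPQ0}")


def aggregate_from_microscopic(
    micro: MicroscopicParams, consts: OpticalConstants = DEFAULT_CONSTANTS
) -> YeParams:
    """Collapse pigment-level parameters into the aggregate curve parameters."""
    D = micro.xi3 + (micro.xi1 * micro.k_P + micro.xi2 * micro.k_D) * micro.tau
    if D == 0:
        raise DomainError(
            "degenerate parameters: de-excitation denominator "
            "xi3 + (xi1*k_P + xi2*k_D)*tau is zero"
        )
    u = micro.sigma_ik * micro.tau / D
    alpha_e = consts.ab * micro.N0 * micro.sigma_ik * micro.phi_exciton / micro.S
    beta_e = (1.0 - micro.g_ratio) * u
    gamma_e = (1.0 + micro.g_ratio) * u
    return YeParams(alpha_e, beta_e, gamma_e, phi_psii_max=None)


def sigma_eff(sigma_ik: float, beta_e: float, gamma_e: float, I) -> np.ndarray:
    """Effective absorption cross-section sigma'_ik(I).

    Equals sigma_ik at I = 0 and declines with I, crossing zero at
    I = 1/beta_e (complete loss of effective absorption under strong light).
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise DomainError("light intensities must be >= 0")
    return sigma_ik * (1.0 - beta_e * I) / (1.0 + gamma_e * I)


def phi_from_sigma(phi_psii_max: float, sigma_eff_value, sigma_ik: float):
    """Phi_PSII is proportional to the effective cross-section:
    Phi = phi_max * sigma'_ik / sigma_ik."""
    if sigma_ik <= 0:
        raise DomainError(f"sigma_ik must be > 0, got {sigma_ik}")
    return phi_psii_max * np.asarray(sigma_eff_value, dtype=float) / sigma_ik


def nk_fraction(beta_e: float, gamma_e: float, g_ratio: float, I) -> np.ndarray:
    """Excited-state pigment fraction N_k/N0 as a function of I.

    Zero in darkness, saturating towards beta_e / ((1-g_ratio)*gamma_e).
    """
    if not (0.0 <= g_ratio < 1.0):
        raise DomainError(f"g_ratio must be in [0, 1), got {g_ratio}")
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise DomainError("light intensities must be >= 0")
    return (beta_e * I / (1.0 + gamma_e * I)) / (1.0 - g_ratio)


def npq_curve(params: NPQCurveParams, I) -> np.ndarray:
    """Saturating NPQ light response, NPQ(I) = A*I/(1+b*I) + NPQ0."""
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise DomainError("light intensities must be >= 0")
    return params.A * I / (1.0 + params.b * I) + params.NPQ0


def sigma_ik_from_alpha_e(
    alpha_e: float,
    consts: OpticalConstants = DEFAULT_CONSTANTS,
    phi_exciton: float = DEFAULT_PHI_EXCITON,
    S: float = DEFAULT_LEAF_AREA,
    N0: Optional[float] = None,
) -> float:
    """Invert the initial-slope aggregation for the eigen cross-section:

        sigma_ik = alpha_e * S / (alpha * beta * phi_exciton * N0)

    N0 has no universal default (it is estimated from chlorophyll content
    per leaf), so it must be supplied explicitly.
    """
    if N0 is None:
        raise DomainError(
            "N0 required: the total pigment pool must be supplied to recover "
            "sigma_ik from the initial slope"
        )
    if alpha_e <= 0 or phi_exciton <= 0 or S <= 0 or N0 <= 0:
        raise DomainError("all inputs to sigma_ik_from_alpha_e must be > 0")
    return alpha_e * S / (consts.ab * phi_exciton * N0)
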