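"""Standard chlorophyll-fluorescence photochemistry quantities.

Pulse-amplitude-modulated (PAM) fluorometry yields four basic fluorescence
levels per light step: F0 and Fm from a dark-adapted leaf, F' (steady state)
and Fm' (saturating-flash maximum) under actinic light.  From these the
conventional PSII quantities follow:

* effective quantum efficiency  Phi_PSII = (Fm' - F') / Fm'
* maximum quantum efficiency    Fv/Fm    = (Fm - F0) / Fm
* non-photochemical quenching   NPQ      = (Fm - Fm') / Fm'
* electron transport rate       ETR      = alpha * beta * Phi_PSII * I

where ``alpha`` partitions absorbed light between PSII and PSI and ``beta``
is the leaf absorptance.  Both are assumptions of the ETR calculation, so
they are injected via :class:`OpticalConstants` rather than hard-coded.

Fluorescence yields are dimensionless positive reals; no instrument-count
scaling is imposed.  Records that violate the ordering preconditions are
rejected individually with :class:`~psiilight.errors.InvalidMeasurementError`
so one bad step never voids a whole curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import DomainError, InvalidMeasurementError

__all__ = [
    "OpticalConstants",
    "FluorescenceRecord",
    "DEFAULT_CONSTANTS",
    "phi_psii",
    "fv_fm",
    "npq_from_fluorescence",
    "etr_from_phi",
]


@dataclass(frozen=True)
class OpticalConstants:
    """Optical constants entering the ETR calculation.

    Parameters
    ----------
    alpha : float
        PSII/PSI light-distribution coefficient (dimensionless, in (0, 1]).
        Default 0.5: absorbed photons split evenly between photosystems.
    beta : float
        Leaf absorptance (dimensionless, in (0, 1]).  Default 0.84.
    """

    alpha: float = 0.5
    beta: float = 0.84

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise DomainError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0.0 < self.beta <= 1.0):
            raise DomainError(f"beta must be in (0, 1], got {self.beta}")

    @property
    def ab(self) -> float:
        """Product alpha * beta, the photon-to-PSII conversion factor."""
        return self.alpha * self.beta


DEFAULT_CONSTANTS = OpticalConstants()


@dataclass(frozen=True)
class FluorescenceRecord:
    """One light step of raw fluorescence yields.

    Any subset of the four yields may be present; only ordering constraints
    between yields that are both present are enforced.
    """

    I: float
    F0: Optional[float] = None
    Fm: Optional[float] = None
    Fprime: Optional[float] = None
    Fmprime: Optional[float] = None

    def __post_init__(self) -> None:
        if self.I < 0:
            raise InvalidMeasurementError(f"negative light intensity in {self!r}")
        for name in ("F0", "Fm", "Fprime", "Fmprime"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidMeasurementError(
                    f"non-positive fluorescence yield {name}={v} in {self!r}"
                )
        if self.F0 is not None and self.Fm is not None and self.F0 > self.Fm:
            raise InvalidMeasurementError(f"F0 > Fm in {self!r}")
        if (
            self.Fprime is not None
            and self.Fmprime is not None
            and self.Fprime > self.Fmprime
        ):
            raise InvalidMeasurementError(f"Fprime > Fmprime in {self!r}")


def phi_psii(Fmprime: float, Fprime: float) -> float:
    """Effective PSII quantum efficiency, (Fm' - F') / Fm'.

    Raises
    ------
    InvalidMeasurementError
        If a yield is non-positive or F' exceeds Fm'.
    """
    if Fmprime <= 0 or Fprime <= 0:
        raise InvalidMeasurementError(
            f"non-positive yields Fmprime={Fmprime}, Fprime={Fprime}"
        )
    if Fprime > Fmprime:
        raise InvalidMeasurementError(
            f"Fprime={Fprime} exceeds Fmprime={Fmprime}"
        )
    return (Fmprime - Fprime) / Fmprime


def fv_fm(F0: float, Fm: float) -> float:
    """Maximum (dark-adapted) PSII quantum efficiency, (Fm - F0) / Fm."""
    if Fm <= 0 or F0 <= 0:
        raise InvalidMeasurementError(f"non-positive yields F0={F0}, Fm={Fm}")
    if F0 > Fm:
        raise InvalidMeasurementError(f"F0={F0} exceeds Fm={Fm}")
    return (Fm - F0) / Fm


def npq_from_fluorescence(Fm: float, Fmprime: float) -> float:
    """Non-photochemical quenching, (Fm - Fm') / Fm'.

    Negative quenching is impossible under this definition, so Fm' > Fm is
    rejected as an invalid measurement.
    """
    if Fm <= 0 or Fmprime <= 0:
        raise InvalidMeasurementError(
            f"non-positive yields Fm={Fm}, Fmprime={Fmprime}"
        )
    if Fmprime > Fm:
        raise InvalidMeasurementError(f"Fmprime={Fmprime} exceeds Fm={Fm}")
    return (Fm - Fmprime) / Fmprime


def etr_from_phi(
    phi: float, I: float, consts: OpticalConstants = DEFAULT_CONSTANTS
) -> float:
    """Linear electron transport rate, alpha * beta * Phi_PSII * I.

    Units: umol electrons m^-2 s^-1 for I in umol photons m^-2 s^-1.
    """
    if not (0.0 <= phi <= 1.0):
        raise DomainError(f"phi must be in [0, 1], got {phi}")
    if I < 0:
        raise DomainError(f"light intensity must be >= 0, got {I}")
    return consts.ab * phi * I
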