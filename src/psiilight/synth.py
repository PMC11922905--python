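"""Synthetic light-curve generation.

The generator emulates the measurement protocol of a leaf-chamber
fluorometer light curve: 16 actinic steps from darkness to 2000
umol photons m^-2 s^-1, five replicate leaves, and additive Gaussian
measurement noise.  The default noise scale is 2% of the curve maximum,
roughly the replicate scatter seen in field measurements of healthy
crop leaves.

All randomness flows from a single seed through
``numpy.random.SeedSequence.spawn``, so replicates are mutually
independent yet the whole data set is reproducible bit-for-bit from the
metadata each curve carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .curves import ExpParams, NRHParams, NegExpParams, YeParams, eval_model
from .errors import DomainError
from .fluorescence import DEFAULT_CONSTANTS, OpticalConstants
from .io import LightCurve
from .pigments import NPQCurveParams, npq_curve

__all__ = [
    "PROTOCOL_GRID",
    "SyntheticTruth",
    "generate_synthetic",
    "default_truth",
]

#: the 16-step actinic light protocol, umol photons m^-2 s^-1
PROTOCOL_GRID = (
    0.0, 25.0, 50.0, 100.0, 200.0, 300.0, 400.0, 600.0,
    800.0, 1000.0, 1200.0, 1400.0, 1600.0, 1800.0, 1900.0, 2000.0,
)

_PARAM_CLASSES = {
    "ye": YeParams,
    "negexp": NegExpParams,
    "exp": ExpParams,
    "nrh": NRHParams,
    "npq": NPQCurveParams,
}

#: generating truths typical of healthy C3 crop leaves (I_sat ~ 1.6-1.7
#: mmol, ETR_max ~ 180, Phi_PSIImax ~ 0.70, moderate NPQ)
_DEFAULT_TRUTHS = {
    "ye": YeParams(0.294, 2.2e-4, 4.2e-4, phi_psii_max=0.70),
    "negexp": NegExpParams(0.70, 1.0 / 1600.0),
    "exp": ExpParams(0.72, 600.0),
    "nrh": NRHParams(0.3, 0.7, 180.0),
    "npq": NPQCurveParams(1.5e-3, 5e-4, 0.05),
}


def default_truth(model_kind: str):
    """The package's reference generating parameters for a model family."""
    try:
        return _DEFAULT_TRUTHS[model_kind]
    except KeyError:
        raise DomainError(f"unknown model kind {model_kind!r}") from None


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating configuration for synthetic replicate curves.

    noise_sd is interpreted as a fraction of max|curve| when
    ``noise_relative`` (the default), otherwise as an absolute sd in the
    units of the response.
    """

    model_kind: str
    params: object
    curve_kind: str = "etr"
    noise_sd: float = 0.02
    noise_relative: bool = True
    grid: tuple = PROTOCOL_GRID
    n_reps: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in _PARAM_CLASSES:
            raise DomainError(f"unknown model kind {self.model_kind!r}")
        if not isinstance(self.params, _PARAM_CLASSES[self.model_kind]):
            raise DomainError(
                f"params must be {_PARAM_CLASSES[self.model_kind].__name__} "
                f"for model {self.model_kind!r}"
            )
        if len(self.grid) == 0:
            raise DomainError("grid must be non-empty")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.n_reps < 1:
            raise DomainError("n_reps must be >= 1")
        if self.seed is None:
            raise DomainError("seed is mandatory")


def _truth_curve(truth: SyntheticTruth, consts: OpticalConstants) -> np.ndarray:
    I = np.asarray(truth.grid, dtype=float)
    if truth.model_kind == "npq":
        return npq_curve(truth.params, I)
    return eval_model(truth.model_kind, truth.params, consts, truth.curve_kind, I)


def generate_synthetic(
    truth: SyntheticTruth,
    consts: OpticalConstants = DEFAULT_CONSTANTS,
) -> list:
    """Generate ``truth.n_reps`` replicate curves with seeded Gaussian noise.

    Each curve's metadata records the full generating truth, the constants
    and the replicate's position in the seed-spawning order, which is
    sufficient to regenerate it bit-identically.
    """
    clean = _truth_curve(truth, consts)
    sd = truth.noise_sd
    if truth.noise_relative:
        sd = truth.noise_sd * float(np.max(np.abs(clean)))
    streams = np.random.SeedSequence(truth.seed).spawn(truth.n_reps)
    I = np.asarray(truth.grid, dtype=float)
    kind = "npq" if truth.model_kind == "npq" else truth.curve_kind
    meta_common = {
        "provenance": "synthetic",
        "seed": truth.seed,
        "model_kind": truth.model_kind,
        "curve_kind": kind,
        "params": asdict(truth.params),
        "noise_sd": truth.noise_sd,
        "noise_relative": truth.noise_relative,
        "alpha": consts.alpha,
        "beta": consts.beta,
        "n_reps": truth.n_reps,
    }
    curves = []
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        y = clean + rng.normal(0.0, sd, size=I.size) if sd > 0 else clean.copy()
        meta = dict(meta_common, replicate_index=r)
        curves.append(
            LightCurve.from_arrays(f"rep{r + 1}", I, y, kind, metadata=meta)
        )
    return curves
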