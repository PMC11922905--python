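"""Goodness of fit, model selection and the four-model comparison table.

The statistics are the ones conventionally used to rank light-response
models:

* SSR, sum of squared residuals
* MAE, mean absolute error
* R^2 = 1 - SSR / SStot (SStot about the observed mean)
* AIC = 2k + n * ln(SSR / n)

``k`` defaults to the number of free fitted parameters but the counting
convention is configurable: ``with_constants`` counts every symbol in the
fitted equation including the optical constants alpha and beta where they
appear explicitly (so the ETR equations of the exponential families count
4, while the mechanistic ETR equation, whose constants are absorbed into
alpha_e, counts 3).  The comparison table records which k each AIC used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError
from .fluorescence import DEFAULT_CONSTANTS, OpticalConstants

__all__ = [
    "GOFStats",
    "gof",
    "aic_param_count",
    "ObservedSummary",
    "observed_summary",
    "ComparisonTable",
    "build_comparison_table",
]

#: flag token for non-estimable cells, serialized as "NA(<flag>)"
NOT_ESTIMABLE = "not_estimable"

#: parameter count per (curve_kind, model_kind) when optical constants that
#: appear explicitly in the fitted equation are counted as parameters
_K_WITH_CONSTANTS = {
    ("etr", "ye"): 3,
    ("etr", "negexp"): 4,
    ("etr", "exp"): 4,
    ("etr", "nrh"): 3,
    ("phi", "ye"): 3,
    ("phi", "negexp"): 2,
    ("phi", "exp"): 2,
    ("phi", "nrh"): 5,
}

_K_FREE = {
    "ye": 3,
    "negexp": 2,
    "exp": 2,
    "nrh": 3,
    "npq": 3,
}


def aic_param_count(
    model_kind: str, curve_kind: str, convention: str = "free"
) -> int:
    """Parameter count k for the AIC under a named counting convention."""
    if convention == "free":
        return _K_FREE[model_kind]
    if convention == "with_constants":
        try:
            return _K_WITH_CONSTANTS[(curve_kind, model_kind)]
        except KeyError:
            return _K_FREE[model_kind]
    raise DomainError(f"unknown k convention {convention!r}")


@dataclass(frozen=True)
class GOFStats:
    """Goodness-of-fit block for one fitted curve.

    ``aic`` is -inf when SSR = 0 (a perfect fit degenerates the log);
    ``r2`` is NaN with ``r2_flag`` set when the observations carry no
    variance.
    """

    n: int
    k: int
    ssr: float
    r2: float
    mae: float
    aic: float
    r2_flag: Optional[str] = None

    @property
    def aic_degenerate(self) -> bool:
        return not math.isfinite(self.aic)


def gof(observed, predicted, k: int) -> GOFStats:
    """Compute SSR, MAE, R^2 and AIC = 2k + n*ln(SSR/n)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise DomainError("observed and predicted must be 1-D of equal length")
    n = obs.size
    if n < 1:
        raise DomainError("at least one observation required")
    if k < 1:
        raise DomainError("k must be >= 1")
    resid = obs - pred
    ssr = float(np.dot(resid, resid))
    mae = float(np.abs(resid).mean())
    sstot = float(np.dot(obs - obs.mean(), obs - obs.mean()))
    if sstot == 0.0:
        r2, r2_flag = math.nan, "zero_variance"
    else:
        r2, r2_flag = 1.0 - ssr / sstot, None
    aic = -math.inf if ssr == 0.0 else 2.0 * k + n * math.log(ssr / n)
    return GOFStats(n=n, k=k, ssr=ssr, r2=r2, mae=mae, aic=aic, r2_flag=r2_flag)


# --- observed summaries -----------------------------------------------------

@dataclass(frozen=True)
class ObservedSummary:
    """Model-free summary of measured replicate curves.

    phi_psii_max : mean Phi_PSII at I = 0 (NaN + flag when no dark step).
    etr_max      : mean of per-replicate ETR maxima over the measured grid.
    i_sat        : mean of per-replicate argmax intensities (grid values,
                   no interpolation).
    SEs are sd/sqrt(n); NaN at n = 1.
    """

    phi_psii_max: float
    phi_psii_max_se: float
    etr_max: float
    etr_max_se: float
    i_sat: float
    i_sat_se: float
    n: int
    flags: tuple = ()


def _mean_se(vals: list) -> tuple[float, float]:
    arr = np.asarray(vals, dtype=float)
    if arr.size == 0:
        return math.nan, math.nan
    m = float(arr.mean())
    s = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else math.nan
    return m, s


def observed_summary(curves) -> ObservedSummary:
    """Summarise measured curves: Phi_PSII at I = 0, per-replicate ETR
    maxima and their argmax intensities."""
    phi0, emax, isat = [], [], []
    flags = []
    for c in curves:
        try:
            I, phi = c.series("phi")
            dark = np.flatnonzero(I == 0.0)
            if dark.size:
                phi0.append(float(phi[dark[0]]))
        except KeyError:
            pass
        try:
            I, etr = c.series("etr")
            j = int(np.argmax(etr))
            emax.append(float(etr[j]))
            isat.append(float(I[j]))
        except KeyError:
            pass
    if not phi0:
        flags.append("phi_psii_max_unavailable")
    if not emax:
        flags.append("etr_unavailable")
    pm, ps = _mean_se(phi0)
    em, es = _mean_se(emax)
    im, isd = _mean_se(isat)
    return ObservedSummary(
        phi_psii_max=pm,
        phi_psii_max_se=ps,
        etr_max=em,
        etr_max_se=es,
        i_sat=im,
        i_sat_se=isd,
        n=max(len(phi0), len(emax)),
        flags=tuple(flags),
    )


# --- comparison table -------------------------------------------------------

#: which derived quantities each model reports for each curve kind,
#: following the conventional presentation of four-model comparisons
_AVAILABLE = {
    ("etr", "ye"): {"i_sat", "etr_max"},
    ("etr", "negexp"): {"phi_psii_max", "i_sat", "etr_max"},
    ("etr", "exp"): {"i_sat", "fv_fm", "etr_max"},
    ("etr", "nrh"): {"etr_max"},
    ("phi", "ye"): {"phi_psii_max"},
    ("phi", "negexp"): {"phi_psii_max"},
    ("phi", "exp"): {"i_sat", "fv_fm"},
    ("phi", "nrh"): {"etr_max"},
}

_ROWS = ("phi_psii_max", "i_sat", "fv_fm", "etr_max", "r2", "mae", "k", "aic")


@dataclass(frozen=True)
class ComparisonTable:
    """Four-model comparison with an observed column.

    ``values``/``ses`` are nested dicts row -> column -> float (NaN where
    flagged); ``flags`` carries the per-cell not-estimable markers; the
    lowest-AIC model is named in ``best_model``.  ``to_frame`` renders a
    mean +/- SE DataFrame in the documented row and column order.
    """

    curve_kind: str
    columns: tuple
    values: dict
    ses: dict
    flags: dict
    best_model: Optional[str]
    k_convention: str = "free"

    def to_frame(self) -> pd.DataFrame:
        def cell(row, col):
            if self.flags.get(row, {}).get(col):
                return f"NA({self.flags[row][col]})"
            v = self.values[row].get(col, math.nan)
            if isinstance(v, float) and math.isnan(v):
                return f"NA({NOT_ESTIMABLE})"
            s = self.ses.get(row, {}).get(col, math.nan)
            if row in ("k",):
                return f"{v:.0f}"
            if isinstance(s, float) and math.isnan(s):
                return f"{v:.6g}"
            return f"{v:.6g} ± {s:.3g}"

        data = {c: [cell(r, c) for r in _ROWS] for c in self.columns}
        return pd.DataFrame(data, index=list(_ROWS))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="parameter")

    def to_dict(self) -> dict:
        return {
            "curve_kind": self.curve_kind,
            "columns": list(self.columns),
            "values": self.values,
            "ses": self.ses,
            "flags": self.flags,
            "best_model": self.best_model,
            "k_convention": self.k_convention,
        }


def build_comparison_table(
    fits: dict,
    observed: Optional[ObservedSummary] = None,
    curve_kind: str = "etr",
    k_convention: str = "free",
) -> ComparisonTable:
    """Assemble the per-model comparison.

    Parameters
    ----------
    fits : dict mapping model kind -> AggregateFitResult
    observed : optional model-free summary appended as the ``obs`` column
    k_convention : counting convention recorded with each AIC; the AIC is
        recomputed from each replicate's SSR under this convention and
        averaged.
    """
    if not fits:
        raise DomainError("at least one fitted model required")
    models = [m for m in ("ye", "negexp", "exp", "nrh") if m in fits]
    models += [m for m in fits if m not in models]
    columns = tuple(models) + (("obs",) if observed is not None else ())

    values: dict = {r: {} for r in _ROWS}
    ses: dict = {r: {} for r in _ROWS}
    flags: dict = {r: {} for r in _ROWS}

    aic_means = {}
    for m in models:
        agg = fits[m]
        avail = _AVAILABLE.get((curve_kind, m), set())
        k = aic_param_count(m, curve_kind, k_convention)
        # AIC under the requested convention, from per-replicate SSR
        aics = []
        for r in agg.per_replicate:
            g = r.gof
            if g.ssr > 0:
                aics.append(2.0 * k + g.n * math.log(g.ssr / g.n))
        aic_m, aic_s = _mean_se(aics)
        aic_means[m] = aic_m

        for row in ("phi_psii_max", "i_sat", "fv_fm", "etr_max"):
            if row in avail and row in agg.mean and math.isfinite(agg.mean[row]):
                values[row][m] = agg.mean[row]
                ses[row][m] = agg.se.get(row, math.nan)
            else:
                flags[row][m] = NOT_ESTIMABLE
        values["r2"][m], ses["r2"][m] = agg.mean.get("r2", math.nan), agg.se.get(
            "r2", math.nan
        )
        values["mae"][m], ses["mae"][m] = agg.mean.get("mae", math.nan), agg.se.get(
            "mae", math.nan
        )
        values["k"][m] = float(k)
        values["aic"][m], ses["aic"][m] = aic_m, aic_s

    if observed is not None:
        values["phi_psii_max"]["obs"] = observed.phi_psii_max
        ses["phi_psii_max"]["obs"] = observed.phi_psii_max_se
        values["i_sat"]["obs"] = observed.i_sat
        ses["i_sat"]["obs"] = observed.i_sat_se
        values["etr_max"]["obs"] = observed.etr_max
        ses["etr_max"]["obs"] = observed.etr_max_se
        for row in ("fv_fm", "r2", "mae", "k", "aic"):
            flags[row]["obs"] = NOT_ESTIMABLE

    finite = {m: a for m, a in aic_means.items() if math.isfinite(a)}
    best = min(finite, key=finite.get) if finite else None
    return ComparisonTable(
        curve_kind=curve_kind,
        columns=columns,
        values=values,
        ses=ses,
        flags=flags,
        best_model=best,
        k_convention=k_convention,
    )
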