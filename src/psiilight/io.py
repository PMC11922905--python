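"""Reading and writing light-curve data and fit results.

Canonical on-disk format is a long CSV, one row per observation::

    replicate_id,I,quantity,value
    leaf1,0,phi,0.71
    leaf1,25,phi,0.695
    ...

``quantity`` is one of ``etr``, ``phi``, ``npq``.  A wide raw-fluorescence
variant is also accepted, with columns ``replicate_id,I,F0,Fm,Fprime,Fmprime``
(F0/Fm optional per row); each row is converted to phi/etr (and npq when
both maxima are present) with the configured optical constants.  Malformed
rows are reported with their line number and skipped, so one bad step never
voids a curve.

Results (FitResult, AggregateFitResult, ComparisonTable) serialize to JSON
losslessly; flagged or non-finite cells become the literal token
``"NA(<flag>)"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, is_dataclass, asdict
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidMeasurementError
from .evaluation import ComparisonTable
from .fitting import AggregateFitResult, FitResult
from .fluorescence import (
    DEFAULT_CONSTANTS,
    OpticalConstants,
    etr_from_phi,
    npq_from_fluorescence,
    phi_psii,
)

__all__ = [
    "LightCurve",
    "ReadResult",
    "read_lightcurve_csv",
    "curves_to_csv",
    "write_results",
]

_LONG_COLS = ("replicate_id", "I", "quantity", "value")
_WIDE_COLS = ("replicate_id", "I")
_QUANTITIES = ("etr", "phi", "npq")


@dataclass
class LightCurve:
    """One replicate's light-response series.

    ``data`` holds columns I, quantity, value in measurement order;
    (I, quantity) pairs are unique within a replicate.  ``metadata``
    records species label, constants and provenance (measured vs
    synthetic + seed + generating truth).
    """

    replicate_id: str
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {"I", "quantity", "value"} - set(self.data.columns)
        if missing:
            raise FormatError(f"LightCurve data lacks columns {sorted(missing)}")
        if (self.data["I"] < 0).any():
            raise FormatError("negative light intensity in curve")
        dup = self.data.duplicated(subset=["I", "quantity"])
        if dup.any():
            raise FormatError(
                f"duplicate (I, quantity) pairs in replicate {self.replicate_id!r}"
            )

    def series(self, quantity: str) -> tuple[np.ndarray, np.ndarray]:
        """(I, value) arrays for one quantity, in stored order."""
        sub = self.data[self.data["quantity"] == quantity]
        if sub.empty:
            raise KeyError(f"no {quantity!r} records in replicate {self.replicate_id!r}")
        return sub["I"].to_numpy(float), sub["value"].to_numpy(float)

    @property
    def quantities(self) -> tuple:
        return tuple(self.data["quantity"].unique())

    @classmethod
    def from_arrays(cls, replicate_id, I, values, quantity, metadata=None):
        df = pd.DataFrame(
            {"I": np.asarray(I, float), "quantity": quantity,
             "value": np.asarray(values, float)}
        )
        return cls(replicate_id=str(replicate_id), data=df, metadata=metadata or {})


class ReadResult(NamedTuple):
    curves: list
    issues: list


def _wide_row_to_records(row, line_no: int, consts: OpticalConstants):
    """Convert one raw-fluorescence row to (quantity, value) pairs."""
    records = []
    I = float(row["I"])
    fp = row.get("Fprime")
    fmp = row.get("Fmprime")
    fm = row.get("Fm")
    if fp is not None and fmp is not None:
        phi = phi_psii(fmp, fp)
        records.append(("phi", phi))
        records.append(("etr", etr_from_phi(phi, I, consts)))
    if fm is not None and fmp is not None:
        records.append(("npq", npq_from_fluorescence(fm, fmp)))
    if not records:
        raise InvalidMeasurementError(
            f"line {line_no}: no usable fluorescence yields"
        )
    return records


def read_lightcurve_csv(
    path,
    consts: OpticalConstants = DEFAULT_CONSTANTS,
    species: Optional[str] = None,
) -> ReadResult:
    """Read light curves from a long or wide (raw-fluorescence) CSV.

    Returns a :class:`ReadResult` of validated curves and a list of
    row-level issues (each naming the line number and the problem).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty input file: {path}") from None
    if df.empty:
        raise FormatError(f"no data rows in {path}")

    cols = set(df.columns)
    issues: list[str] = []
    rows: list[dict] = []
    # header line is line 1; data rows start at 2
    if set(_LONG_COLS) <= cols:
        for idx, row in df.iterrows():
            line = idx + 2
            try:
                I = float(row["I"])
                value = float(row["value"])
                if not (math.isfinite(I) and math.isfinite(value)):
                    raise ValueError("non-finite")
                q = str(row["quantity"]).strip().lower()
                if q not in _QUANTITIES:
                    raise ValueError(f"unknown quantity {q!r}")
                if I < 0:
                    raise ValueError("negative I")
            except (TypeError, ValueError) as exc:
                issues.append(f"line {line}: {exc}")
                continue
            rows.append(
                {"replicate_id": str(row["replicate_id"]), "I": I,
                 "quantity": q, "value": value}
            )
    elif set(_WIDE_COLS) <= cols and cols & {"Fprime", "Fmprime", "F0", "Fm"}:
        for idx, row in df.iterrows():
            line = idx + 2
            try:
                I = float(row["I"])
                if not math.isfinite(I) or I < 0:
                    raise ValueError("invalid I")
                yields = {
                    k: (float(row[k]) if k in cols and pd.notna(row[k]) else None)
                    for k in ("F0", "Fm", "Fprime", "Fmprime")
                }
                recs = _wide_row_to_records({"I": I, **yields}, line, consts)
            except (TypeError, ValueError, InvalidMeasurementError) as exc:
                issues.append(f"line {line}: {exc}")
                continue
            for q, v in recs:
                rows.append(
                    {"replicate_id": str(row["replicate_id"]), "I": I,
                     "quantity": q, "value": v}
                )
    else:
        raise FormatError(
            f"unrecognised header {sorted(cols)}: expected the long columns "
            f"{_LONG_COLS} or the wide fluorescence columns "
            f"(replicate_id, I, F0, Fm, Fprime, Fmprime)"
        )

    if not rows:
        raise FormatError(f"no valid rows in {path}: {issues}")
    full = pd.DataFrame(rows)
    curves = []
    meta = {"provenance": "measured", "source": str(path),
            "alpha": consts.alpha, "beta": consts.beta}
    if species:
        meta["species"] = species
    for rid, grp in full.groupby("replicate_id", sort=False):
        curves.append(
            LightCurve(
                replicate_id=str(rid),
                data=grp[["I", "quantity", "value"]].reset_index(drop=True),
                metadata=dict(meta),
            )
        )
    return ReadResult(curves=curves, issues=issues)


def curves_to_csv(curves, path) -> None:
    """Write curves in the canonical long format."""
    frames = []
    for c in curves:
        df = c.data.copy()
        df.insert(0, "replicate_id", c.replicate_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# --- result serialization ---------------------------------------------------

def _jsonify(obj):
    """Recursively convert results to JSON-safe structures.

    Non-finite floats become "NA(<flag>)" tokens so flagged quantities are
    never silently coerced to null.
    """
    if isinstance(obj, float):
        if math.isnan(obj):
            return "NA(undefined)"
        if obj == math.inf:
            return "NA(not_finite)"
        if obj == -math.inf:
            return "NA(degenerate)"
        return obj
    if isinstance(obj, (np.floating, np.integer)):
        return _jsonify(float(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (FitResult, AggregateFitResult, ComparisonTable)):
        return _jsonify(obj.to_dict())
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(asdict(obj))
    return obj


def write_results(results, path, fmt: str = "json") -> None:
    """Write a FitResult, AggregateFitResult or ComparisonTable.

    JSON round-trips losslessly (floats at full precision); CSV is only
    defined for ComparisonTable and follows the documented column order.
    """
    path = Path(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_jsonify(results), fh, indent=2)
            fh.write("\n")
    elif fmt == "csv":
        if not isinstance(results, ComparisonTable):
            raise FormatError("CSV output is defined for ComparisonTable only")
        results.to_csv(path)
    else:
        raise FormatError(f"unknown output format {fmt!r}")
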