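"""Parameter estimation for light-response curves.

The global stage is multistart simulated annealing with Metropolis
acceptance: starts are Latin-hypercube draws within the parameter bounds,
the initial temperature defaults to the inter-quartile range of the starts'
SSR values, and the proposal scale shrinks with the geometric cooling
schedule.  The winner of the global stage is polished by a bounded
trust-region least-squares pass (finite-difference Jacobian).  All
randomness flows from the single seed in :class:`FitConfig`, so a fit is
bit-reproducible.

Ties between multistart optima (SSR within 1e-12 relative) are broken by
the lexicographically smallest value of the designated tie-break parameters
(for the mechanistic model: beta_e, then gamma_e).

Replicates are fitted independently and aggregated as mean +/- SE
(sd/sqrt(n)), the convention used for reporting five-leaf measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .curves import DerivedLightParams
from .errors import DegenerateDataError, DomainError, UnderdeterminedError
from .fluorescence import DEFAULT_CONSTANTS, OpticalConstants

__all__ = [
    "SASchedule",
    "FitConfig",
    "FitResult",
    "AggregateFitResult",
    "anneal_least_squares",
    "numeric_extrema_oracle",
    "OracleExtremum",
    "fit_single",
    "fit_replicates",
]

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class SASchedule:
    """Annealing schedule.

    t_init : initial temperature; None -> inter-quartile range of the
        multistart SSR values (scale-free default).
    cooling : geometric cooling factor per temperature level.
    iters_per_temp : Metropolis proposals per temperature level.
    n_temps : number of temperature levels (the stopping rule).
    """

    t_init: Optional[float] = None
    cooling: float = 0.92
    iters_per_temp: int = 60
    n_temps: int = 50

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling < 1.0):
            raise DomainError(f"cooling must be in (0, 1), got {self.cooling}")
        if self.iters_per_temp < 1 or self.n_temps < 1:
            raise DomainError("iters_per_temp and n_temps must be >= 1")


@dataclass(frozen=True)
class FitConfig:
    """Everything a fit needs besides the data.

    ``bounds`` maps parameter names to closed intervals and overrides the
    per-model defaults; ``k_aic`` overrides the AIC parameter count
    (default: number of free fitted parameters).
    """

    model_kind: str
    curve_kind: str
    seed: int
    bounds: Optional[dict] = None
    n_starts: int = 20
    sa: SASchedule = field(default_factory=SASchedule)
    local_tol: float = 1e-10
    k_aic: Optional[int] = None
    linked: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise DomainError("a seed is required for reproducible fitting")
        if self.n_starts < 1:
            raise DomainError("n_starts must be >= 1")
        if self.local_tol <= 0:
            raise DomainError("local_tol must be > 0")

    def to_file(self, path) -> None:
        """Write as a plain key = value config file (all fields)."""
        lines = [
            f"model_kind = {self.model_kind}",
            f"curve_kind = {self.curve_kind}",
            f"seed = {self.seed}",
            f"n_starts = {self.n_starts}",
            f"local_tol = {self.local_tol!r}",
            f"linked = {str(self.linked).lower()}",
            f"sa_cooling = {self.sa.cooling!r}",
            f"sa_iters_per_temp = {self.sa.iters_per_temp}",
            f"sa_n_temps = {self.sa.n_temps}",
        ]
        if self.sa.t_init is not None:
            lines.append(f"sa_t_init = {self.sa.t_init!r}")
        if self.k_aic is not None:
            lines.append(f"k_aic = {self.k_aic}")
        for name, (lo, hi) in (self.bounds or {}).items():
            lines.append(f"bounds.{name} = {lo!r}, {hi!r}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "FitConfig":
        """Read a key = value config file; unknown keys are rejected."""
        kv: dict = {}
        bounds: dict = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                key, sep, val = (s.strip() for s in line.partition("="))
                if not sep:
                    raise DomainError(f"malformed config line: {raw.rstrip()!r}")
                if key.startswith("bounds."):
                    lo, _, hi = val.partition(",")
                    bounds[key[len("bounds."):]] = (float(lo), float(hi))
                else:
                    kv[key] = val
        sa = SASchedule(
            t_init=float(kv.pop("sa_t_init")) if "sa_t_init" in kv else None,
            cooling=float(kv.pop("sa_cooling", 0.92)),
            iters_per_temp=int(kv.pop("sa_iters_per_temp", 60)),
            n_temps=int(kv.pop("sa_n_temps", 50)),
        )
        k_aic = int(kv.pop("k_aic")) if "k_aic" in kv else None
        try:
            cfg = cls(
                model_kind=kv.pop("model_kind"),
                curve_kind=kv.pop("curve_kind"),
                seed=int(kv.pop("seed")),
                bounds=bounds or None,
                n_starts=int(kv.pop("n_starts", 20)),
                sa=sa,
                local_tol=float(kv.pop("local_tol", 1e-10)),
                k_aic=k_aic,
                linked=kv.pop("linked", "true").lower() in ("true", "1", "yes"),
            )
        except KeyError as exc:
            raise DomainError(f"config file missing required key: {exc}") from None
        if kv:
            raise DomainError(f"unknown config keys: {sorted(kv)}")
        return cfg

    @classmethod
    def fast(cls, model_kind: str, curve_kind: str, seed: int, **kw) -> "FitConfig":
        """A lighter search for Monte-Carlo studies: fewer starts and a
        shorter schedule.  The local least-squares stage still polishes to
        full precision, so accuracy on well-conditioned curves is unchanged."""
        kw.setdefault("n_starts", 6)
        kw.setdefault("sa", SASchedule(cooling=0.85, iters_per_temp=20, n_temps=20))
        return cls(model_kind, curve_kind, seed, **kw)


@dataclass(frozen=True)
class FitResult:
    """One replicate's fit: parameters, derived traits, goodness of fit."""

    model_kind: str
    curve_kind: str
    params: dict
    derived: Optional[DerivedLightParams]
    gof: "GOFStats"  # noqa: F821 - forward ref, evaluation imports this module
    diagnostics: dict

    def to_dict(self) -> dict:
        d = {
            "model_kind": self.model_kind,
            "curve_kind": self.curve_kind,
            "params": dict(self.params),
            "derived": asdict(self.derived) if self.derived is not None else None,
            "gof": asdict(self.gof),
            "diagnostics": dict(self.diagnostics),
        }
        return d


@dataclass(frozen=True)
class AggregateFitResult:
    """Independent per-replicate fits summarised as mean +/- SE.

    ``se`` values are NaN when only one replicate succeeded (sample SE is
    undefined at n = 1).  Failures are recorded per replicate and excluded
    from the aggregate; ``n_success`` reports how many fits the means cover.
    """

    per_replicate: tuple
    mean: dict
    se: dict
    n_success: int
    failures: tuple = ()

    def to_dict(self) -> dict:
        return {
            "per_replicate": [r.to_dict() for r in self.per_replicate],
            "mean": dict(self.mean),
            "se": dict(self.se),
            "n_success": self.n_success,
            "failures": [dict(f) for f in self.failures],
        }


# --- global + local minimisation -------------------------------------------

def anneal_least_squares(
    residuals: Callable[[np.ndarray], np.ndarray],
    lower: Sequence[float],
    upper: Sequence[float],
    rng: np.random.Generator,
    n_starts: int = 20,
    schedule: SASchedule = SASchedule(),
    local_tol: float = 1e-10,
    tiebreak: Sequence[int] = (),
) -> tuple[np.ndarray, float, dict]:
    """Minimise sum(residuals(x)^2) over the box [lower, upper].

    Returns ``(x_best, ssr_best, info)`` with info carrying the function
    evaluation count, the best multistart initial SSR (the reported SSR
    never exceeds it) and a convergence flag for the local stage.
    """
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    d = lo.size
    width = hi - lo
    nfev = 0

    def ssr(x: np.ndarray) -> float:
        nonlocal nfev
        nfev += 1
        r = residuals(x)
        return float(np.dot(r, r))

    sampler = qmc.LatinHypercube(d=d, seed=rng)
    starts = lo + sampler.random(n_starts) * width
    start_ssr = np.array([ssr(x) for x in starts])
    best_start_ssr = float(start_ssr.min())

    t0 = schedule.t_init
    if t0 is None:
        q75, q25 = np.percentile(start_ssr, [75, 25])
        t0 = float(q75 - q25)
    if t0 <= 0:  # degenerate spread (e.g. flat objective): fall back to scale
        t0 = max(1e-12, 1e-3 * (1.0 + float(np.median(start_ssr))))

    candidates: list[tuple[float, np.ndarray]] = []
    for s in range(n_starts):
        x = starts[s].copy()
        fx = float(start_ssr[s])
        bx, bf = x.copy(), fx
        T = t0
        sigma = 0.2 * width
        for _ in range(schedule.n_temps):
            steps = rng.normal(size=(schedule.iters_per_temp, d))
            us = rng.random(schedule.iters_per_temp)
            for i in range(schedule.iters_per_temp):
                prop = np.clip(x + steps[i] * sigma, lo, hi)
                fp = ssr(prop)
                if fp <= fx or us[i] < math.exp(max(-(fp - fx) / T, -700.0)):
                    x, fx = prop, fp
                    if fx < bf:
                        bx, bf = x.copy(), fx
            T *= schedule.cooling
            sigma *= schedule.cooling
        candidates.append((bf, bx))

    # local polish of the most promising annealed points
    candidates.sort(key=lambda c: c[0])
    refined: list[tuple[float, np.ndarray]] = []
    converged = False
    for bf, bx in candidates[: min(3, len(candidates))]:
        try:
            sol = optimize.least_squares(
                residuals,
                np.clip(bx, lo, hi),
                bounds=(lo, hi),
                method="trf",
                xtol=local_tol,
                ftol=local_tol,
                gtol=None,
            )
            nfev += sol.nfev
            f_loc = float(2.0 * sol.cost)
            if f_loc <= bf:
                refined.append((f_loc, sol.x))
                converged = converged or bool(sol.success)
            else:
                refined.append((bf, bx))
        except Exception:
            refined.append((bf, bx))
    refined.extend(candidates[3:])

    best_f = min(f for f, _ in refined)
    tol = _TIE_RTOL * (1.0 + abs(best_f))
    tied = [x for f, x in refined if f - best_f <= tol]
    if len(tied) > 1 and tiebreak:
        tied.sort(key=lambda x: tuple(x[i] for i in tiebreak))
    x_best = tied[0]
    ssr_best = ssr(x_best)
    nfev -= 1  # final bookkeeping evaluation
    info = {
        "n_fev": nfev,
        "converged": converged,
        "best_start_ssr": best_start_ssr,
    }
    return x_best, min(ssr_best, best_f), info


# --- numeric extremum oracle ------------------------------------------------

@dataclass(frozen=True)
class OracleExtremum:
    """Result of the grid + golden-section maximiser."""

    i_opt: float
    value: float
    at_boundary: bool


def numeric_extrema_oracle(
    curve: Callable[[np.ndarray], np.ndarray],
    i_max: float,
    n_grid: int = 4001,
) -> OracleExtremum:
    """Locate the maximum of an ETR curve on [0, i_max] numerically.

    A uniform grid scan followed by bounded golden-section refinement
    between the neighbouring grid points.  When the grid maximum sits on
    the range boundary the curve is monotone over the range and the result
    is flagged ``at_boundary`` (no interior maximum).
    """
    grid = np.linspace(0.0, i_max, n_grid)
    vals = np.asarray(curve(grid), dtype=float)
    j = int(np.argmax(vals))
    if j == 0 or j == n_grid - 1:
        return OracleExtremum(float(grid[j]), float(vals[j]), at_boundary=True)
    res = optimize.minimize_scalar(
        lambda i: -float(curve(np.asarray([i]))[0]),
        bounds=(grid[j - 1], grid[j + 1]),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return OracleExtremum(float(res.x), float(-res.fun), at_boundary=False)


# --- curve-level fitting API -------------------------------------------------

def fit_single(
    curve,
    config: FitConfig,
    consts: OpticalConstants = DEFAULT_CONSTANTS,
) -> FitResult:
    """Fit one replicate :class:`~psiilight.io.LightCurve`.

    Thin wrapper over the estimator classes in :mod:`psiilight.estimators`.
    """
    from .estimators import make_estimator  # local import: estimators builds on this module

    I, y = curve.series(config.curve_kind)
    est = make_estimator(config, consts)
    est.fit(I, y)
    return est.result_


def fit_replicates(
    curves,
    config: FitConfig,
    consts: OpticalConstants = DEFAULT_CONSTANTS,
) -> AggregateFitResult:
    """Fit each replicate independently and aggregate mean +/- SE.

    A failing replicate is recorded (replicate id + message) and skipped;
    the aggregate covers the successes.  Raises only when every replicate
    fails.
    """
    if len(curves) < 1:
        raise DomainError("at least one replicate required")
    results: list[FitResult] = []
    failures: list[dict] = []
    for i, c in enumerate(curves):
        try:
            results.append(fit_single(c, config, consts))
        except (UnderdeterminedError, DegenerateDataError, DomainError) as exc:
            failures.append(
                {"replicate": getattr(c, "replicate_id", str(i)), "error": str(exc)}
            )
    if not results:
        raise DegenerateDataError(
            f"all {len(curves)} replicates failed to fit: {failures}"
        )
    mean, se = _aggregate(results)
    return AggregateFitResult(
        per_replicate=tuple(results),
        mean=mean,
        se=se,
        n_success=len(results),
        failures=tuple(failures),
    )


def _scalar_fields(r: FitResult) -> dict:
    out = dict(r.params)
    if r.derived is not None:
        if r.derived.i_sat_flag is None:
            out["i_sat"] = r.derived.i_sat
        out["etr_max"] = r.derived.etr_max
    g = r.gof
    out.update({"ssr": g.ssr, "r2": g.r2, "mae": g.mae, "aic": g.aic})
    return out


def _aggregate(results: list[FitResult]) -> tuple[dict, dict]:
    keys = list(_scalar_fields(results[0]).keys())
    mean: dict = {}
    se: dict = {}
    n = len(results)
    for k in keys:
        vals = np.array([_scalar_fields(r).get(k, math.nan) for r in results])
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            mean[k], se[k] = math.nan, math.nan
            continue
        mean[k] = float(vals.mean())
        se[k] = (
            float(vals.std(ddof=1) / math.sqrt(vals.size))
            if vals.size > 1
            else math.nan
        )
    return mean, se
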