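"""Parameter estimation: recovery, determinism, oracle, aggregation."""

import json
import math

import numpy as np
import pytest

from psiilight.curves import (
    NRHParams,
    NegExpParams,
    YeParams,
    derived_ye,
    eval_model,
)
from psiilight.errors import DegenerateDataError, UnderdeterminedError
from psiilight.evaluation import GOFStats
from psiilight.fitting import (
    AggregateFitResult,
    FitConfig,
    FitResult,
    fit_replicates,
    fit_single,
    numeric_extrema_oracle,
)
from psiilight.fitting import _aggregate
from psiilight.io import LightCurve, _jsonify
from psiilight.synth import SyntheticTruth, default_truth, generate_synthetic


def _noiseless(model, curve_kind, seed=0, n_reps=1):
    truth = default_truth(model)
    t = SyntheticTruth(model, truth, curve_kind=curve_kind, noise_sd=0.0,
                       seed=seed, n_reps=n_reps)
    return truth, generate_synthetic(t)


@pytest.mark.parametrize(
    "model, curve_kind",
    [("ye", "etr"), ("negexp", "phi"), ("exp", "etr"), ("nrh", "etr"),
     ("npq", "npq")],
)
def test_noiseless_recovery(model, curve_kind):
    """Fitting noiseless self-generated data recovers the generating
    parameters to high relative accuracy."""
    truth, curves = _noiseless(model, curve_kind)
    res = fit_single(curves[0], FitConfig.fast(model, curve_kind, seed=11))
    for name, value in res.params.items():
        true = getattr(truth, name)
        assert value == pytest.approx(true, rel=1e-4), (model, name)


def test_underdetermined_curve_rejected():
    c = LightCurve.from_arrays("r1", [0.0, 100.0], [0.0, 10.0], "etr")
    with pytest.raises(UnderdeterminedError):
        fit_single(c, FitConfig.fast("ye", "etr", seed=0))


def test_constant_response_rejected():
    I = np.linspace(0, 2000, 10)
    c = LightCurve.from_arrays("r1", I, np.full(10, 5.0), "etr")
    with pytest.raises(DegenerateDataError):
        fit_single(c, FitConfig.fast("ye", "etr", seed=0))


def test_seeded_determinism_bitwise():
    _, curves = _noiseless("ye", "etr")
    cfg = FitConfig.fast("ye", "etr", seed=99)
    a = fit_single(curves[0], cfg)
    b = fit_single(curves[0], cfg)
    assert json.dumps(_jsonify(a), sort_keys=True) == json.dumps(
        _jsonify(b), sort_keys=True
    )


def test_reported_ssr_never_exceeds_best_start():
    truth = default_truth("ye")
    t = SyntheticTruth("ye", truth, curve_kind="etr", noise_sd=0.02, seed=8)
    curves = generate_synthetic(t)
    for i, c in enumerate(curves):
        res = fit_single(c, FitConfig.fast("ye", "etr", seed=i))
        assert res.gof.ssr <= res.diagnostics["best_start_ssr"] + 1e-12


def test_replicate_aggregation_zero_variance():
    """Identical noiseless replicates fit to identical parameters: SE = 0."""
    _, curves = _noiseless("negexp", "phi", n_reps=5)
    agg = fit_replicates(curves, FitConfig.fast("negexp", "phi", seed=4))
    assert agg.n_success == 5
    for name in ("phi_psii_max", "k_w"):
        assert agg.se[name] == pytest.approx(0.0, abs=1e-10)


def test_single_replicate_se_unavailable():
    _, curves = _noiseless("negexp", "phi", n_reps=1)
    agg = fit_replicates(curves, FitConfig.fast("negexp", "phi", seed=4))
    assert agg.n_success == 1
    assert math.isnan(agg.se["phi_psii_max"])


def test_failed_replicates_recorded_not_fatal():
    _, good = _noiseless("ye", "etr", n_reps=2)
    bad = LightCurve.from_arrays("flat", np.linspace(0, 2000, 16),
                                 np.full(16, 3.0), "etr")
    agg = fit_replicates(good + [bad], FitConfig.fast("ye", "etr", seed=1))
    assert agg.n_success == 2
    assert len(agg.failures) == 1
    assert agg.failures[0]["replicate"] == "flat"


def test_mean_se_arithmetic():
    """mean 3, SE = sd/sqrt(5) ~ 0.7071 for fitted values 1..5."""
    gof = GOFStats(n=16, k=2, ssr=1.0, r2=0.99, mae=0.1, aic=-40.0)
    results = [
        FitResult("negexp", "phi", {"p": float(v)}, None, gof, {})
        for v in (1, 2, 3, 4, 5)
    ]
    mean, se = _aggregate(results)
    assert mean["p"] == pytest.approx(3.0)
    assert se["p"] == pytest.approx(math.sqrt(2.5) / math.sqrt(5), rel=1e-12)
    assert se["p"] == pytest.approx(0.7071, abs=1e-4)


def test_config_file_round_trip(tmp_path):
    """FitConfig round-trips through the key = value config format."""
    cfg = FitConfig(
        "ye", "phi", seed=42, n_starts=7, local_tol=1e-9, k_aic=4,
        bounds={"beta_e": (0.0, 5e-3)}, linked=False,
    )
    path = tmp_path / "fit.cfg"
    cfg.to_file(path)
    assert FitConfig.from_file(path) == cfg
    # defaults apply for omitted keys; unknown keys are rejected
    minimal = tmp_path / "min.cfg"
    minimal.write_text("model_kind = negexp\ncurve_kind = etr\nseed = 1\n")
    assert FitConfig.from_file(minimal) == FitConfig("negexp", "etr", seed=1)
    bad = tmp_path / "bad.cfg"
    bad.write_text("model_kind = ye\ncurve_kind = etr\nseed = 1\nbogus = 2\n")
    with pytest.raises(Exception, match="unknown config keys"):
        FitConfig.from_file(bad)


# --- numeric extremum oracle -------------------------------------------------

def test_oracle_agrees_with_ye_closed_form():
    p = YeParams(0.3, 1e-4, 5e-4)
    d = derived_ye(p)
    ext = numeric_extrema_oracle(
        lambda I: eval_model("ye", p, kind="etr", I=I), i_max=4 * d.i_sat
    )
    assert not ext.at_boundary
    assert ext.i_opt == pytest.approx(d.i_sat, rel=1e-6)
    assert ext.value == pytest.approx(d.etr_max, rel=1e-6)


def test_oracle_flags_monotone_nrh():
    p = NRHParams(0.3, 0.7, 200.0)
    ext = numeric_extrema_oracle(
        lambda I: eval_model("nrh", p, kind="etr", I=I), i_max=3000.0
    )
    assert ext.at_boundary
    assert ext.i_opt == pytest.approx(3000.0)


def test_oracle_negexp_argmax():
    p = NegExpParams(0.7, 1.0 / 1600.0)
    ext = numeric_extrema_oracle(
        lambda I: eval_model("negexp", p, kind="etr", I=I), i_max=6400.0
    )
    assert ext.i_opt == pytest.approx(1600.0, rel=1e-6)


# --- cross-curve consistency -------------------------------------------------

def test_linked_cross_curve_consistency():
    """Fitting ETR and Phi curves generated from the same linked truth
    returns alpha_e ~ alpha*beta*phi_psii_max."""
    truth = default_truth("ye")
    ab = 0.42
    etr_curves = generate_synthetic(
        SyntheticTruth("ye", truth, curve_kind="etr", noise_sd=0.01, seed=21)
    )
    phi_curves = generate_synthetic(
        SyntheticTruth("ye", truth, curve_kind="phi", noise_sd=0.01, seed=22)
    )
    a = fit_replicates(etr_curves, FitConfig.fast("ye", "etr", seed=1))
    p = fit_replicates(phi_curves, FitConfig.fast("ye", "phi", seed=2))
    assert a.mean["alpha_e"] == pytest.approx(
        ab * p.mean["phi_psii_max"], rel=0.05
    )
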