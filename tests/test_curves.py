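"""The four light-response model families and their derived traits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psiilight.curves import (
    ExpParams,
    NRHParams,
    NegExpParams,
    YeParams,
    derived_exp,
    derived_negexp,
    derived_nrh,
    derived_ye,
    eval_exp,
    eval_model,
    eval_negexp,
    eval_nrh,
    eval_ye,
)
from psiilight.errors import DomainError
from psiilight.fluorescence import OpticalConstants

CONSTS = OpticalConstants()


# --- mechanistic model -------------------------------------------------------

def test_ye_etr_values():
    p = YeParams(0.3, 1e-4, 5e-4)
    assert eval_ye(p, CONSTS, "etr", [1000.0])[0] == pytest.approx(180.0)
    assert eval_ye(p, CONSTS, "etr", [0.0])[0] == 0.0


def test_ye_phi_values():
    p = YeParams(0.3, 1e-4, 5e-4, phi_psii_max=0.719)
    assert eval_ye(p, CONSTS, "phi", [0.0])[0] == pytest.approx(0.719)
    assert eval_ye(p, CONSTS, "phi", [1000.0])[0] == pytest.approx(0.719 * 0.9 / 1.5)


def test_ye_phi_requires_phi_max():
    with pytest.raises(DomainError):
        eval_ye(YeParams(0.3, 1e-4, 5e-4), CONSTS, "phi", [0.0])


def test_ye_derived_closed_forms():
    d = derived_ye(YeParams(0.3, 1e-4, 5e-4))
    assert d.i_sat == pytest.approx(2898.979485566356, rel=1e-12)
    assert d.etr_max == pytest.approx(252.1224617320373, rel=1e-12)
    assert d.i_sat_flag is None


def test_ye_derived_symmetric_case():
    d = derived_ye(YeParams(0.5, 1e-3, 1e-3))
    assert d.i_sat == pytest.approx((math.sqrt(2) - 1) / 1e-3, rel=1e-12)


def test_ye_derived_no_downregulation():
    d = derived_ye(YeParams(0.3, 0.0, 5e-4))
    assert not d.i_sat_finite and d.i_sat_flag == "not_finite"
    assert d.etr_max == pytest.approx(0.3 / 5e-4)  # supremum


def test_ye_negative_branch_not_clipped():
    # ETR crosses zero exactly at I = 1/beta_e and goes negative beyond
    p = YeParams(0.3, 1e-3, 5e-4)
    at_zero = eval_ye(p, CONSTS, "etr", [1.0 / 1e-3])[0]
    assert at_zero == pytest.approx(0.0, abs=1e-12)
    assert eval_ye(p, CONSTS, "etr", [1500.0])[0] < 0


# --- negative exponential ----------------------------------------------------

def test_negexp_values():
    p = NegExpParams(0.7, 1.0 / 1600.0)
    assert eval_negexp(p, CONSTS, "phi", [0.0])[0] == pytest.approx(0.7)
    assert eval_negexp(p, CONSTS, "phi", [1600.0])[0] == pytest.approx(
        0.7 * math.exp(-1), rel=1e-12
    )
    assert eval_negexp(p, CONSTS, "etr", [1600.0])[0] == pytest.approx(
        0.42 * 1600 * 0.7 * math.exp(-1), rel=1e-12
    )


def test_negexp_derived():
    d = derived_negexp(NegExpParams(0.7, 1.0 / 1600.0), CONSTS)
    assert d.i_sat == pytest.approx(1600.0)
    assert d.etr_max == pytest.approx(0.42 * 1600 * 0.7 * math.exp(-1), rel=1e-12)
    d2 = derived_negexp(NegExpParams(0.656, 1e-3), CONSTS)
    assert d2.i_sat == pytest.approx(1000.0)
    assert d2.etr_max == pytest.approx(0.42 * 1000 * 0.656 * math.exp(-1), rel=1e-12)
    assert derived_negexp(NegExpParams(0.5, 1.0), CONSTS).i_sat == pytest.approx(1.0)


# --- saturating exponential --------------------------------------------------

def test_exp_values():
    p = ExpParams(0.72, 600.0)
    assert eval_exp(p, CONSTS, "phi", [0.0])[0] == pytest.approx(0.72)
    assert eval_exp(p, CONSTS, "phi", [600.0])[0] == pytest.approx(
        0.72 * (1 - math.exp(-1)), rel=1e-12
    )
    # ETR asymptote ab * fv_fm * i_sat
    far = eval_exp(p, CONSTS, "etr", [1e7])[0]
    assert far == pytest.approx(0.42 * 0.72 * 600, rel=1e-9)


def test_exp_derived_is_curve_at_i_sat():
    d = derived_exp(ExpParams(0.72, 600.0), CONSTS)
    assert d.etr_max == pytest.approx(0.42 * 0.72 * 600 * (1 - math.exp(-1)), rel=1e-12)
    unit = derived_exp(ExpParams(1.0, 1.0), OpticalConstants(1.0, 1.0))
    assert unit.etr_max == pytest.approx(1 - math.exp(-1), rel=1e-12)


@settings(derandomize=True, max_examples=100)
@given(fv=st.floats(0.1, 1.0), isat=st.floats(10, 4000))
def test_exp_etr_max_identity(fv, isat):
    """Definitional identity: derived ETR_max equals the ETR curve at I_sat."""
    p = ExpParams(fv, isat)
    d = derived_exp(p, CONSTS)
    assert d.etr_max == pytest.approx(
        eval_exp(p, CONSTS, "etr", [isat])[0], rel=1e-12
    )


# --- non-rectangular hyperbola ----------------------------------------------

def test_nrh_values():
    assert eval_nrh(NRHParams(0.3, 0.5, 200.0), CONSTS, "etr", [500.0])[0] == (
        pytest.approx(100.0)
    )
    # Blackman limit at theta = 1
    assert eval_nrh(NRHParams(0.3, 1.0, 200.0), CONSTS, "etr", [500.0])[0] == (
        pytest.approx(150.0)
    )
    # Phi at I = 0 is the analytic limit alpha_prime / (alpha*beta)
    assert eval_nrh(NRHParams(0.336, 0.9, 150.0), CONSTS, "phi", [0.0])[0] == (
        pytest.approx(0.8)
    )


def test_nrh_theta_zero_is_rectangular_hyperbola():
    p0 = NRHParams(0.3, 0.0, 200.0)
    I = np.array([100.0, 500.0, 2000.0])
    expected = 0.3 * I * 200.0 / (0.3 * I + 200.0)
    np.testing.assert_allclose(eval_nrh(p0, CONSTS, "etr", I), expected, rtol=1e-12)
    # continuity: tiny theta agrees with the limit
    tiny = eval_nrh(NRHParams(0.3, 1e-9, 200.0), CONSTS, "etr", I)
    np.testing.assert_allclose(tiny, expected, rtol=1e-6)


def test_nrh_derived_flags():
    d = derived_nrh(NRHParams(0.3, 0.5, 200.0))
    assert d.i_sat_flag == "not_defined_by_model"
    assert math.isnan(d.i_sat)
    assert d.etr_max == 200.0
    # the curve stays strictly below its asymptote at any finite I
    vals = eval_nrh(NRHParams(0.3, 0.5, 200.0), CONSTS, "etr",
                    np.linspace(0, 1e6, 2000))
    assert np.all(vals < 200.0)


# --- cross-model properties --------------------------------------------------

def _random_params(rng):
    return {
        "ye": YeParams.linked(
            float(rng.uniform(0.1, 0.4)),
            float(rng.uniform(1e-5, 5e-4)),
            float(rng.uniform(2e-4, 2e-3)),
            CONSTS,
        ),
        "negexp": NegExpParams(float(rng.uniform(0.3, 0.8)),
                               float(rng.uniform(1e-4, 2e-3))),
        "exp": ExpParams(float(rng.uniform(0.3, 0.8)),
                         float(rng.uniform(100, 2000))),
        "nrh": NRHParams(float(rng.uniform(0.1, 0.42)),
                         float(rng.uniform(0.05, 1.0)),
                         float(rng.uniform(50, 400))),
    }


def test_bridging_identity_all_models():
    """ETR(I) == alpha*beta*Phi(I)*I for every family with linked parameters."""
    rng = np.random.default_rng(42)
    I = np.linspace(1.0, 2500.0, 64)
    for _ in range(50):
        for kind, p in _random_params(rng).items():
            etr = eval_model(kind, p, CONSTS, "etr", I)
            phi = eval_model(kind, p, CONSTS, "phi", I)
            np.testing.assert_allclose(etr, CONSTS.ab * phi * I, rtol=1e-12)


def test_phi_monotonicity():
    """Every family's quantum-yield curve is non-increasing in I."""
    rng = np.random.default_rng(7)
    I = np.linspace(0.0, 2000.0, 400)
    for _ in range(20):
        for kind, p in _random_params(rng).items():
            phi = eval_model(kind, p, CONSTS, "phi", I)
            assert np.all(np.diff(phi) <= 1e-12), kind


def test_nrh_etr_increasing_concave():
    rng = np.random.default_rng(11)
    I = np.linspace(0.0, 3000.0, 500)
    for _ in range(20):
        p = _random_params(rng)["nrh"]
        etr = eval_nrh(p, CONSTS, "etr", I)
        d1 = np.diff(etr)
        assert np.all(d1 > -1e-9)
        assert np.all(np.diff(d1) <= 1e-9)


def test_negative_intensity_rejected():
    for kind, p in [
        ("ye", YeParams(0.3, 1e-4, 5e-4)),
        ("negexp", NegExpParams(0.7, 1e-3)),
        ("exp", ExpParams(0.7, 600)),
        ("nrh", NRHParams(0.3, 0.5, 200)),
    ]:
        with pytest.raises(DomainError):
            eval_model(kind, p, CONSTS, "etr", [-1.0])


def test_param_invariants_enforced():
    with pytest.raises(DomainError):
        YeParams(-0.1, 1e-4, 5e-4)
    with pytest.raises(DomainError):
        YeParams(0.3, -1e-4, 5e-4)
    with pytest.raises(DomainError):
        NegExpParams(1.5, 1e-3)
    with pytest.raises(DomainError):
        ExpParams(0.7, -5)
    with pytest.raises(DomainError):
        NRHParams(0.3, 1.5, 200)
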