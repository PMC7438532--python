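"""Joliot and LMF yield relations and induction kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from excilat.meanfield import (
    KineticTrace,
    ModelParams,
    complementary_area,
    gk_lmf,
    joliot_kinetics,
    kinetics_from_phi,
    lmf_phi_coeffs,
    phi_joliot,
    phi_lmf,
    phi_series,
    t_implicit_n3,
    time_of_x_quadrature,
    x_closed_n1,
    x_closed_n2,
)

X = np.linspace(0.0, 1.0, 101)


def test_model_params_validation():
    for bad in (dict(p=1.0, n=2), dict(p=-0.1, n=2), dict(p=0.5, n=0),
                dict(p=0.5, n=2, k_I=0.0)):
        with pytest.raises(ValueError):
            ModelParams(**bad)
    assert ModelParams(p=0.5, n=2).J == pytest.approx(1.0)


def test_phi_series_limits_and_expansion():
    x = 0.37
    # n=1: the single visit decides everything, phi = G_1 = x
    assert phi_series([x], p=0.9) == pytest.approx(x)
    # p=0: no hopping, phi = G_1 regardless of n
    assert phi_series([x, 0.9, 0.8], p=0.0) == pytest.approx(x)
    # n=3 term-by-term expansion with G_3 = x2/4 + 3 x3/4
    p, x2, x3 = 0.6, 0.11, 0.05
    expect = (1 - p) * x + (1 - p) * p * x2 + p**2 * (0.25 * x2 + 0.75 * x3)
    assert phi_series([x, x2, 0.25 * x2 + 0.75 * x3], p) == pytest.approx(expect)
    with pytest.raises(ValueError):
        phi_series([], p=0.5)


def test_phi_joliot_values():
    assert phi_joliot(1.0, 0.77) == pytest.approx(1.0)
    assert np.allclose(phi_joliot(X, 0.0), X)
    assert phi_joliot(0.5, 0.5) == pytest.approx(1.0 / 3.0)
    # reciprocal form: 1/phi = 1/((1-p)x) - p/(1-p)
    x, p = 0.3, 0.8
    assert 1.0 / phi_joliot(x, p) == pytest.approx(1 / ((1 - p) * x) - p / (1 - p))


def test_gk_lmf_polynomials(weights10):
    assert np.allclose(gk_lmf(X, weights10, 2), X**2)
    assert np.allclose(gk_lmf(X, weights10, 3), 0.25 * X**2 + 0.75 * X**3)
    for k in range(2, 11):
        assert gk_lmf(1.0, weights10, k) == pytest.approx(1.0, abs=1e-12)
    assert gk_lmf(0.4, weights10, 0) == 1.0
    assert gk_lmf(0.4, weights10, 1) == 0.4
    with pytest.raises(ValueError):
        gk_lmf(0.4, weights10, 11)


def test_phi_lmf_small_n_forms():
    p = 0.35
    assert np.allclose(phi_lmf(X, ModelParams(p=p, n=1)), X)
    assert np.allclose(phi_lmf(X, ModelParams(p=p, n=2)), (1 - p) * X + p * X**2)
    assert phi_lmf(0.0, ModelParams(p=p, n=4)) == pytest.approx(0.0)


@given(p=st.floats(0.0, 0.95), n=st.integers(1, 6))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_phi_lmf_is_yield_like(p, n):
    """phi is nondecreasing with phi(0)=0, phi(1)=1 for every p, n."""
    phi = np.asarray(phi_lmf(X, ModelParams(p=p, n=n)))
    assert phi[0] == pytest.approx(0.0, abs=1e-12)
    assert phi[-1] == pytest.approx(1.0, abs=1e-12)
    assert np.all(np.diff(phi) >= -1e-12)
    assert np.all((phi >= -1e-12) & (phi <= 1 + 1e-12))


@pytest.mark.parametrize("p", [0.0, 0.5, 0.9])
@pytest.mark.parametrize("n", [1, 2])
def test_kinetics_match_closed_forms(p, n):
    params = ModelParams(p=p, n=n)
    trace = kinetics_from_phi(
        lambda x: float(phi_lmf(x, params)), params, t_max=5.0, n_points=60
    )
    expect = x_closed_n1(trace.t) if n == 1 else x_closed_n2(trace.t, p)
    assert np.max(np.abs(trace.x - expect)) <= 1e-8


def test_kinetics_n3_implicit_relation():
    p = 0.9
    params = ModelParams(p=p, n=3)
    trace = kinetics_from_phi(
        lambda x: float(phi_lmf(x, params)), params, t_max=4.0, n_points=50
    )
    inner = slice(1, -1)
    assert np.max(np.abs(t_implicit_n3(trace.x[inner], p) - trace.t[inner])) <= 1e-6


def test_kinetics_quadrature_route_agrees():
    params = ModelParams(p=0.7, n=4)
    trace = kinetics_from_phi(
        lambda x: float(phi_lmf(x, params)), params, t_max=3.0, n_points=31
    )
    i = 15
    t_quad = time_of_x_quadrature(lambda x: float(phi_lmf(x, params)), params,
                                  float(trace.x[i]))
    assert t_quad == pytest.approx(float(trace.t[i]), abs=1e-8)


def test_kinetics_rejects_singular_yield():
    params = ModelParams(p=0.5, n=2)
    with pytest.raises(ValueError):
        kinetics_from_phi(lambda x: 1.2 * x, params, t_max=1.0)


def test_joliot_kinetics_against_ode():
    params = ModelParams(p=0.9, n=1)
    t = np.linspace(0.0, 8.0, 60)
    implicit = joliot_kinetics(params, t)
    ode = kinetics_from_phi(lambda x: float(phi_joliot(x, 0.9)), params,
                            t_max=8.0, t_grid=t)
    assert np.max(np.abs(implicit.x - ode.x)) <= 1e-8
    # p=0 reduces to simple exponential closure
    p0 = joliot_kinetics(ModelParams(p=0.0, n=1), t)
    assert np.allclose(p0.x, x_closed_n1(t), atol=1e-10)


def test_joliot_limit_of_series():
    """G_k = x^k with long lifetime converges geometrically to the hyperbola."""
    x = np.linspace(0.0, 1.0, 21)
    G = [x**k for k in range(1, 201)]
    assert np.max(np.abs(phi_series(G, 0.5) - phi_joliot(x, 0.5))) <= 1e-10


def test_complementary_area_limits():
    t = np.linspace(0.0, 3.0, 301)
    dark = KineticTrace(t=t, x=t * 0, phi=np.zeros_like(t))
    lit = KineticTrace(t=t, x=t * 0, phi=np.ones_like(t))
    assert np.allclose(complementary_area(dark), t)
    assert np.allclose(complementary_area(lit), 0.0)
    bad = KineticTrace(t=t[::-1], x=t * 0, phi=np.zeros_like(t))
    with pytest.raises(ValueError):
        complementary_area(bad)


def test_complementary_area_joliot_line():
    """1/phi vs 1/C is the Joliot straight line: slope 1/(1-p), intercept -p/(1-p)."""
    params = ModelParams(p=0.5, n=1)
    trace = joliot_kinetics(params, np.linspace(0.0, 6.0, 4001))
    C = trace.x / params.k_I  # x = k_I C (verified separately to 1e-8)
    sel = trace.phi > 1e-3
    slope, intercept = np.polyfit(1.0 / C[sel], 1.0 / trace.phi[sel], 1)
    resid = 1.0 / trace.phi[sel] - (slope / C[sel] + intercept)
    ss_tot = np.sum((1.0 / trace.phi[sel] - np.mean(1.0 / trace.phi[sel])) ** 2)
    assert slope == pytest.approx(2.0, abs=1e-6)
    assert intercept == pytest.approx(-1.0, abs=1e-4)
    assert 1.0 - np.sum(resid**2) / ss_tot >= 1.0 - 1e-6


def test_closure_rate_integrates_to_x():
    """x(t) = k_I C(t): quadrature of 1 - phi along the closed-form n=2 path."""
    p = 0.8
    params = ModelParams(p=p, n=2, k_I=1.0)

    def phi_of_t(t):
        x = x_closed_n2(t, p)
        return float(phi_lmf(x, params))

    for t_end in (0.5, 1.5, 3.0):
        C, _ = quad(lambda t: 1.0 - phi_of_t(t), 0.0, t_end, limit=200,
                    epsabs=1e-12, epsrel=1e-12)
        assert params.k_I * C == pytest.approx(float(x_closed_n2(t_end, p)), abs=1e-8)


@pytest.mark.parametrize("n", [2, 3, 5])
def test_induction_sigmoidicity(n):
    """phi(t) has exactly one inflection for n >= 2 (convex then concave)."""
    params = ModelParams(p=0.9, n=n)
    trace = kinetics_from_phi(
        lambda x: float(phi_lmf(x, params)), params, t_max=6.0, n_points=600
    )
    curve = np.diff(trace.phi, 2)
    signs = np.sign(curve[np.abs(curve) > 1e-12])
    assert np.count_nonzero(np.diff(signs)) == 1


def test_lmf_coeffs_sum_to_one():
    for p, n in [(0.3, 2), (0.9, 5), (0.0, 3)]:
        assert lmf_phi_coeffs(ModelParams(p=p, n=n)).sum() == pytest.approx(1.0)
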