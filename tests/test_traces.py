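"""Trace normalisation, time elimination, Joliot fitting and synthesis."""

import numpy as np
import pytest

from excilat.cmf import induction_trace_cmf
from excilat.meanfield import ModelParams, joliot_kinetics, phi_joliot, phi_lmf
from excilat.traces import (
    NoiseModel,
    RawTrace,
    eliminate_time,
    fit_joliot,
    normalize_absorption,
    normalize_fluorescence,
    read_trace_csv,
    reciprocal_diagnostics,
    synth_traces,
    write_trace_csv,
)

TRUTH = ModelParams(p=0.9, n=3, k_I=1000.0)


def ideal_fluorescence(phase="induction"):
    """Piecewise trace with exactly flat head and tail segments."""
    t = np.linspace(0.0, 1.0, 400)
    if phase == "relaxation":
        v = np.clip((0.9 - t) / 0.6, 0.0, 1.0)
    else:
        v = np.clip((t - 0.05) / 0.6, 0.0, 1.0)
    return t, v


def test_normalization_is_affine_invariant():
    """Gain and offset cancel exactly: normalize(a F + b) == normalize(F)."""
    t, v = ideal_fluorescence()
    base = normalize_fluorescence(RawTrace(t, v, "fluorescence", "induction"), 10)
    scaled = normalize_fluorescence(
        RawTrace(t, 3.7 * v + 0.42, "fluorescence", "induction"), 10
    )
    assert np.max(np.abs(base.value - scaled.value)) <= 1e-9
    # the ideal trace is already normalized, so the identity is recovered
    assert np.max(np.abs(base.value - v)) <= 1e-9


def test_normalization_relaxation_phase():
    t, v = ideal_fluorescence("relaxation")
    norm = normalize_fluorescence(RawTrace(t, 2.0 * v + 1.0, "fluorescence",
                                           "relaxation"), 10)
    assert np.max(np.abs(norm.value - v)) <= 1e-9
    assert norm.normalization["Fmax"] > norm.normalization["F0"]


def test_normalization_degenerate_and_channel_guards():
    t = np.linspace(0, 1, 50)
    flat = RawTrace(t, np.ones_like(t), "fluorescence", "induction")
    with pytest.raises(ValueError):
        normalize_fluorescence(flat, 10)
    with pytest.raises(ValueError):
        normalize_fluorescence(RawTrace(t, t, "absorption", "induction"), 10)
    with pytest.raises(ValueError):
        normalize_absorption(RawTrace(t, np.zeros_like(t), "absorption",
                                      "induction"))


def test_normalize_absorption_recovers_affine_x():
    t, v = ideal_fluorescence()
    norm = normalize_absorption(RawTrace(t, 5.0 * v, "absorption", "induction"))
    assert np.max(np.abs(norm.value - v)) <= 1e-9


def test_eliminate_time_pairs():
    t = np.linspace(0, 1, 101)
    from excilat.traces import NormalizedTrace

    a = NormalizedTrace(t, t, "phi")
    b = NormalizedTrace(t, t, "x")
    x, ph = eliminate_time(a, b)
    assert np.allclose(x, ph)  # diagonal
    # interpolation consistency against a direct CMF phi(x) evaluation
    tt = np.linspace(0.0, 5.0 / TRUTH.k_I, 800)
    trace = induction_trace_cmf(TRUTH, tt)
    phi_n = NormalizedTrace(tt, np.clip(trace.phi, 0, 1), "phi")
    x_n = NormalizedTrace(tt[::2], np.clip(trace.x[::2], 0, 1), "x")
    xv, pv = eliminate_time(phi_n, x_n)
    direct = np.interp(xv, trace.x, trace.phi)
    assert np.max(np.abs(pv - direct)) <= 1e-4
    with pytest.raises(ValueError):
        eliminate_time(NormalizedTrace(t, t, "phi"),
                       NormalizedTrace(t + 10.0, t, "x"))


def test_fit_joliot_recovers_noiseless_p():
    x = np.linspace(0.02, 1.0, 60)
    res = fit_joliot(x, phi_joliot(x, 0.5))
    assert abs(res.p_hat - 0.5) <= 1e-6
    assert res.J_hat == pytest.approx(res.p_hat / (1 - res.p_hat))
    assert res.converged
    diag = fit_joliot(x, x)
    assert diag.p_hat <= 1e-5
    with pytest.raises(ValueError):
        fit_joliot([0.5, 0.6], [0.4, 0.5])


def test_fit_joliot_reciprocal_weighting():
    x = np.linspace(0.05, 1.0, 50)
    res = fit_joliot(x, phi_joliot(x, 0.6), weighting="reciprocal")
    assert abs(res.p_hat - 0.6) <= 1e-9
    assert res.converged


def test_reciprocal_diagnostics_joliot_line_exact():
    """With the analytic complementary area the reciprocal law is exact."""
    from excilat.traces import NormalizedTrace

    params = ModelParams(p=0.5, n=1, k_I=1.0)
    trace = joliot_kinetics(params, np.linspace(0.0, 6.0, 500))
    phi_n = NormalizedTrace(trace.t, np.clip(trace.phi, 0, 1), "phi")
    with pytest.warns(UserWarning):
        diag = reciprocal_diagnostics(phi_n, C=trace.x / params.k_I)
    assert np.max(np.abs(diag["fit_C"]["residuals"])) <= 1e-6
    assert diag["fit_C"]["slope"] == pytest.approx(2.0, abs=1e-8)
    assert diag["fit_C"]["p_hat"] == pytest.approx(0.5, abs=1e-6)
    assert diag["fit_C"]["k_I_hat"] == pytest.approx(1.0, abs=1e-6)


def test_reciprocal_diagnostics_detects_wandering_curvature():
    """Finite-lifetime wandering bends the reciprocal plot systematically."""
    from excilat.traces import NormalizedTrace

    t = np.linspace(0.0, 6.0 / TRUTH.k_I, 600)
    trace = induction_trace_cmf(TRUTH, t)
    phi_n = NormalizedTrace(t, np.clip(trace.phi, 0, 1), "phi")
    with pytest.warns(UserWarning):
        diag = reciprocal_diagnostics(phi_n, C=trace.x / TRUTH.k_I)
    assert diag["fit_C"]["sign_changes"] >= 1


def test_synth_traces_noiseless_and_roundtrip(rng, tmp_path):
    noise = NoiseModel(sigma=0.0, f0_offset=0.25, gain=2.0, drift=0.0)
    fl, ab = synth_traces(TRUTH, rng, approach="cmf", phase="induction",
                          noise=noise, n_points=200)
    model = induction_trace_cmf(TRUTH, fl.t)
    assert np.max(np.abs(fl.signal - (2.0 * model.phi + 0.25))) <= 1e-9
    assert np.max(np.abs(ab.signal - 2.0 * model.x)) <= 1e-9
    write_trace_csv(fl, tmp_path / "f.csv")
    back = read_trace_csv(tmp_path / "f.csv")
    assert np.max(np.abs(back.signal - fl.signal)) <= 1e-9
    assert back.channel == "fluorescence" and back.phase == "induction"
    with pytest.raises(ValueError):
        NoiseModel(sigma=-0.1)


def test_noisy_relaxation_recovery_vs_noiseless_oracle(rng):
    """Noisy pipeline lands within 0.05 of the noiseless LMF best-fit p."""
    truth = ModelParams(p=0.6, n=2, k_I=1000.0)
    x_dense = np.linspace(0.01, 1.0, 400)
    oracle = fit_joliot(x_dense, phi_lmf(x_dense, truth)).p_hat
    fl, ab = synth_traces(truth, rng, approach="lmf", phase="relaxation",
                          noise=NoiseModel(sigma=0.01), n_points=500)
    xv, pv = eliminate_time(normalize_fluorescence(fl, 10),
                            normalize_absorption(ab, 10))
    fitted = fit_joliot(xv, pv).p_hat
    assert abs(fitted - oracle) <= 0.05


def test_raw_trace_validation():
    with pytest.raises(ValueError):
        RawTrace(np.array([0.0, 0.0, 1.0]), np.zeros(3), "fluorescence", "induction")
    with pytest.raises(ValueError):
        RawTrace(np.array([0.0, 1.0]), np.array([0.0, np.inf]), "fluorescence",
                 "induction")
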