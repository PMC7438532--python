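"""Kinetic-trace layer: normalisation, time elimination, Joliot-p fitting,
double-reciprocal diagnostics, and a synthetic trace generator.

The generator emulates paired fluorescence / P+ absorption kinetics of
single-turnover bacterial cells: a sub-second induction rise produced by one
of the model solvers (CMF by default, since closure is correlated) and a
dark relaxation decay in which uncorrelated reopening follows
x(t) = exp(-k_rec t) (P+ Q_B- charge recombination, ~1 s) with the yield
given quasi-statically by the LMF curve.  Raw signals add gain, a constant
baseline F0, slow linear drift and white Gaussian noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import minimize_scalar

from .cmf import induction_trace_cmf
from .meanfield import (
    KineticTrace,
    ModelParams,
    joliot_kinetics,
    kinetics_from_phi,
    phi_joliot,
    phi_lmf,
)

__all__ = [
    "RawTrace",
    "NormalizedTrace",
    "FitResult",
    "NoiseModel",
    "normalize_fluorescence",
    "normalize_absorption",
    "eliminate_time",
    "fit_joliot",
    "reciprocal_diagnostics",
    "synth_traces",
    "write_trace_csv",
    "read_trace_csv",
]


@dataclass
class RawTrace:
    """Detector-unit kinetic trace of one channel and phase."""

    t: np.ndarray
    signal: np.ndarray
    channel: str  # "fluorescence" | "absorption"
    phase: str  # "induction" | "relaxation"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")


@dataclass
class NormalizedTrace:
    """Unit-interval trace: phi (variable fluorescence) or x (closed fraction)."""

    t: np.ndarray
    value: np.ndarray
    kind: str  # "phi" | "x"
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.value, dtype=float)
        if v.min() < -0.05 or v.max() > 1.05:
            raise ValueError("normalized values outside the [-0.05, 1.05] band")
        self.value = v


@dataclass
class FitResult:
    """Joliot connectivity fit: p_hat and J_hat = p_hat/(1 - p_hat)."""

    p_hat: float
    J_hat: float
    rss: float
    residuals: np.ndarray
    converged: bool
    k_I_hat: float | None = None
    weighting: str = "uniform"


@dataclass(frozen=True)
class NoiseModel:
    """Additive detector model: gain * value + f0_offset + drift * t + noise."""

    sigma: float = 0.01
    f0_offset: float = 0.1
    gain: float = 1.0
    drift: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise level sigma must be nonnegative")


def _window_mask(t: np.ndarray, window) -> np.ndarray:
    if isinstance(window, int):
        if window < 3:
            raise ValueError("initial window must contain >= 3 points")
        m = np.zeros(t.size, dtype=bool)
        m[:window] = True
        return m
    lo, hi = window
    m = (t >= lo) & (t <= hi)
    if m.sum() < 3:
        raise ValueError("initial window must contain >= 3 points")
    return m


def _intercept_at_zero(t: np.ndarray, y: np.ndarray) -> float:
    """Intercept at t=0 of the least-squares line through (t, y)."""
    slope, intercept = np.polyfit(t, y, 1)
    return float(intercept)


def normalize_fluorescence(raw: RawTrace, window=10) -> NormalizedTrace:
    """Variable fluorescence phi = (F - F0)/(Fmax - F0).

    Induction: F0 is the t=0 intercept of a straight line fitted over the
    initial window (int = first-N points, or a (t_lo, t_hi) range); Fmax is
    the plateau mean over the final decile.  Relaxation mirrors this: the
    initial intercept estimates Fmax and the final decile F0.
    """
    if raw.channel != "fluorescence":
        raise ValueError("expected a fluorescence-channel trace")
    t, F = raw.t, raw.signal
    mask = _window_mask(t, window)
    head = _intercept_at_zero(t[mask], F[mask])
    tail = float(F[-max(3, t.size // 10):].mean())
    F0, Fmax = (head, tail) if raw.phase == "induction" else (tail, head)
    if Fmax - F0 <= 1e-9 * max(1.0, abs(F0), abs(Fmax)):
        raise ValueError("degenerate trace: Fmax <= F0")
    return NormalizedTrace(
        t=t,
        value=(F - F0) / (Fmax - F0),
        kind="phi",
        normalization={"F0": F0, "Fmax": Fmax, "phase": raw.phase},
    )


def normalize_absorption(raw: RawTrace, window=10) -> NormalizedTrace:
    """Closed fraction x = signal / plateau (P+ electrochromic signal).

    The plateau is the final-decile mean during induction and the initial
    t=0 line intercept during relaxation.
    """
    if raw.channel != "absorption":
        raise ValueError("expected an absorption-channel trace")
    t, S = raw.t, raw.signal
    if raw.phase == "induction":
        plateau = float(S[-max(3, t.size // 10):].mean())
    else:
        mask = _window_mask(t, window)
        plateau = _intercept_at_zero(t[mask], S[mask])
    if plateau <= 0:
        raise ValueError("degenerate trace: nonpositive plateau")
    return NormalizedTrace(
        t=t,
        value=np.clip(S / plateau, -0.05, 1.05),
        kind="x",
        normalization={"plateau": plateau, "phase": raw.phase},
    )


def eliminate_time(
    phi_trace: NormalizedTrace, x_trace: NormalizedTrace
) -> tuple[np.ndarray, np.ndarray]:
    """Pair phi with x by eliminating the time variable.

    phi is interpolated (piecewise linear) onto the x trace's time grid over
    the overlapping time range; the pairs are returned sorted by x.
    """
    lo = max(phi_trace.t[0], x_trace.t[0])
    hi = min(phi_trace.t[-1], x_trace.t[-1])
    if lo >= hi:
        raise ValueError("traces have no overlapping time range")
    sel = (x_trace.t >= lo) & (x_trace.t <= hi)
    t_common = x_trace.t[sel]
    phi = np.interp(t_common, phi_trace.t, phi_trace.value)
    x = x_trace.value[sel]
    order = np.argsort(x, kind="stable")
    return x[order], phi[order]


def fit_joliot(x, phi, weighting: str = "uniform") -> FitResult:
    """Least-squares Joliot connectivity fit phi = (1-p) x / (1 - p x).

    weighting="uniform" minimises the direct residual sum of squares over
    p in [0, 1); weighting="reciprocal" fits the double-reciprocal line
    1/phi = 1/((1-p) x) - p/(1-p) instead and converts its slope back to p.
    """
    x = np.asarray(x, dtype=float)
    phi = np.asarray(phi, dtype=float)
    keep = (x > 0) & (x <= 1.05)
    x, phi = np.clip(x[keep], 0.0, 1.0), phi[keep]
    if x.size < 3:
        raise ValueError("need at least 3 pairs with x in (0, 1]")

    if weighting == "uniform":
        def rss_of(p):
            return float(np.sum((phi - phi_joliot(x, p)) ** 2))

        res = minimize_scalar(
            rss_of, bounds=(0.0, 1.0 - 1e-6), method="bounded",
            options={"xatol": 1e-10},
        )
        p_hat = float(res.x)
        resid = phi - phi_joliot(x, p_hat)
        return FitResult(
            p_hat=p_hat,
            J_hat=p_hat / (1.0 - p_hat),
            rss=float(res.fun),
            residuals=resid,
            converged=bool(res.success),
            weighting="uniform",
        )
    if weighting == "reciprocal":
        ok = phi > 0
        if ok.sum() < 3:
            raise ValueError("need at least 3 pairs with phi > 0")
        slope, intercept = np.polyfit(1.0 / x[ok], 1.0 / phi[ok], 1)
        converged = slope >= 1.0
        p_hat = float(np.clip(1.0 - 1.0 / slope, 0.0, 1.0 - 1e-9)) if slope > 0 else 0.0
        resid = 1.0 / phi[ok] - (slope / x[ok] + intercept)
        return FitResult(
            p_hat=p_hat,
            J_hat=p_hat / (1.0 - p_hat),
            rss=float(np.sum(resid**2)),
            residuals=resid,
            converged=bool(converged),
            weighting="reciprocal",
        )
    raise ValueError(f"unknown weighting {weighting!r}")


def _linfit(u: np.ndarray, v: np.ndarray) -> dict:
    slope, intercept = np.polyfit(u, v, 1)
    resid = v - (slope * u + intercept)
    signs = np.sign(resid[np.abs(resid) > 0])
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "residuals": resid,
        "sign_changes": int(np.count_nonzero(np.diff(signs))),
    }


def reciprocal_diagnostics(
    phi_trace: NormalizedTrace,
    x_trace: NormalizedTrace | None = None,
    C: np.ndarray | None = None,
) -> dict:
    """Double-reciprocal linearity diagnostics of the hyperbolic model.

    Builds 1/phi against 1/C (complementary area) and, when a paired x
    trace is given, against 1/x.  A pure Joliot process gives exact straight
    lines (slopes 1/(k_I (1-p)) and 1/(1-p)); wandering with finite exciton
    lifetime leaves patterned, sign-changing residuals.  ``C`` may be
    supplied (e.g. computed analytically); otherwise it is accumulated by
    trapezoid from the phi trace.  Points with phi <= 0 are excluded with a
    warning.
    """
    t, phi = phi_trace.t, phi_trace.value
    if C is None:
        C = cumulative_trapezoid(1.0 - phi, t, initial=0.0)
    C = np.asarray(C, dtype=float)
    ok = (phi > 0) & (C > 0)
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} points with phi or C <= 0")
    table = pd.DataFrame(
        {"t": t[ok], "phi": phi[ok], "C": C[ok],
         "inv_phi": 1.0 / phi[ok], "inv_C": 1.0 / C[ok]}
    )
    out: dict = {"table": table}
    fit_C = _linfit(table["inv_C"].to_numpy(), table["inv_phi"].to_numpy())
    # Eq-style line: 1/phi = 1/(k_I (1-p)) 1/C - p/(1-p)
    b = fit_C["intercept"]
    p_from_C = max(b / (b - 1.0), 0.0) if b < 0 else 0.0
    fit_C["p_hat"] = float(p_from_C)
    fit_C["k_I_hat"] = float(1.0 / (fit_C["slope"] * (1.0 - p_from_C)))
    out["fit_C"] = fit_C
    if x_trace is not None:
        xv, phv = eliminate_time(phi_trace, x_trace)
        good = (xv > 0) & (phv > 0)
        fit_x = _linfit(1.0 / xv[good], 1.0 / phv[good])
        fit_x["p_hat"] = float(np.clip(1.0 - 1.0 / fit_x["slope"], 0.0, 1.0)) \
            if fit_x["slope"] > 0 else 0.0
        out["fit_x"] = fit_x
    return out


def _induction_model(truth: ModelParams, approach: str, t: np.ndarray) -> KineticTrace:
    if approach == "cmf":
        return induction_trace_cmf(truth, t)
    if approach == "lmf":
        return kinetics_from_phi(
            lambda x: float(phi_lmf(x, truth)), truth, t_max=float(t[-1]), t_grid=t
        )
    if approach == "joliot":
        return joliot_kinetics(truth, t)
    raise ValueError(f"unknown approach {approach!r}")


def synth_traces(
    truth: ModelParams,
    rng: np.random.Generator,
    approach: str = "cmf",
    phase: str = "induction",
    noise: NoiseModel = NoiseModel(),
    n_points: int = 500,
    t_max: float | None = None,
    k_rec: float = 1.0,
) -> tuple[RawTrace, RawTrace]:
    """Synthetic fluorescence / absorption raw-trace pair.

    Induction uses the requested solver; relaxation uses exponential
    uncorrelated reopening x(t) = exp(-k_rec t) with the quasi-static yield
    of the matching relaxation model (LMF, or the Joliot hyperbola for
    approach="joliot").  Times are in seconds: the induction time scale is
    set by truth.k_I and the relaxation scale by k_rec.
    """
    if phase == "induction":
        if t_max is None:
            t_max = 6.0 / truth.k_I
        t = np.linspace(0.0, t_max, n_points)
        model = _induction_model(truth, approach, t)
        phi, x = model.phi, model.x
    elif phase == "relaxation":
        if t_max is None:
            t_max = 6.0 / k_rec
        t = np.linspace(0.0, t_max, n_points)
        x = np.exp(-k_rec * t)
        phi = phi_joliot(x, truth.p) if approach == "joliot" \
            else np.asarray(phi_lmf(x, truth), dtype=float)
    else:
        raise ValueError(f"unknown phase {phase!r}")

    meta = {
        "truth": {"p": truth.p, "n": truth.n, "z": truth.z, "k_I": truth.k_I},
        "approach": approach,
        "phase": phase,
        "noise": vars(noise) | {},
        "k_rec": k_rec,
        "synthetic": True,
    }
    F = noise.gain * phi + noise.f0_offset + noise.drift * t \
        + noise.sigma * rng.standard_normal(t.size)
    A = noise.gain * x + noise.drift * t \
        + noise.sigma * rng.standard_normal(t.size)
    return (
        RawTrace(t, F, "fluorescence", phase, dict(meta)),
        RawTrace(t, A, "absorption", phase, dict(meta)),
    )


def write_trace_csv(trace: RawTrace, path) -> None:
    """Write a trace as CSV (t, signal) plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"t": trace.t, "signal": trace.signal}).to_csv(
        path, index=False, float_format="%.12g"
    )
    sidecar = {"channel": trace.channel, "phase": trace.phase,
               "metadata": trace.metadata}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_trace_csv(path) -> RawTrace:
    """Read a trace written by :func:`write_trace_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    side = path.with_suffix(".json")
    channel, phase, meta = "fluorescence", "induction", {}
    if side.exists():
        info = json.loads(side.read_text())
        channel = info.get("channel", channel)
        phase = info.get("phase", phase)
        meta = info.get("metadata", {})
    return RawTrace(df["t"].to_numpy(), df["signal"].to_numpy(), channel, phase, meta)
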