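"""Derived observables: absorbed fraction, absorption cross-section, mean
exciton step count, and induction/relaxation hysteresis curves.

Every exciton ends either absorbed by an open RC (photochemistry) or lost
as fluorescence, so A + phi = 1 exactly.  The absorption cross-section
sigma_A = A / (1 - x) measures how much the open RCs' effective capture
area grows as their neighbourhood closes; the mean number of visited RCs
<n> = sum_{k=0}^{n-1} p**k G_k interpolates between 1 (all open) and
(1 - p**n)/(1 - p) (all closed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cmf import gk_cmf, induction_trace_cmf, phi_cmf
from .meanfield import (
    ModelParams,
    YieldCurve,
    gk_lmf,
    phi_lmf,
    phi_series,
    square_weights,
)

__all__ = [
    "ObservableSet",
    "absorption",
    "sigma_A",
    "n_avg",
    "lmf_correlations",
    "observables_lmf",
    "observables_cmf",
    "hysteresis_curves",
    "HysteresisResult",
]


@dataclass
class ObservableSet:
    """Observables on a grid of closed fractions x for one approach."""

    x: np.ndarray
    phi: np.ndarray
    A: np.ndarray
    sigma_A: np.ndarray
    n_avg: np.ndarray
    approach: str
    params: ModelParams | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "phi": self.phi,
                "A": self.A,
                "sigma_A": self.sigma_A,
                "n_avg": self.n_avg,
            }
        )


def _check_G(G: Sequence) -> list:
    G = [np.asarray(g, dtype=float) for g in G]
    if len(G) < 2:
        raise ValueError("need G_0..G_n with n >= 1")
    if not np.allclose(G[0], 1.0):
        raise ValueError("G_0 must equal 1")
    return G


def absorption(G: Sequence, p: float):
    """Absorbed fraction A = sum_{k=1}^n p**(k-1) (G_{k-1} - G_k).

    ``G`` holds G_0..G_n (G_0 = 1, G_1 = x).  Complements the fluorescence
    series exactly: A + phi = 1.
    """
    G = _check_G(G)
    n = len(G) - 1
    A = np.zeros_like(G[0])
    for k in range(1, n + 1):
        A = A + p ** (k - 1) * (G[k - 1] - G[k])
    return A if A.ndim else float(A)


def sigma_A(x, phi):
    """Absorption cross-section sigma_A = (1 - phi)/(1 - x); undefined at x=1."""
    x = np.asarray(x, dtype=float)
    if np.any(x >= 1.0):
        raise ValueError("sigma_A is undefined at x = 1")
    out = (1.0 - np.asarray(phi, dtype=float)) / (1.0 - x)
    return out if out.ndim else float(out)


def n_avg(G: Sequence, p: float):
    """Mean number of RC visits <n> = sum_{k=0}^{n-1} p**k G_k."""
    G = _check_G(G)
    n = len(G) - 1
    out = np.zeros_like(G[0])
    for k in range(n):
        out = out + p**k * G[k]
    return out if out.ndim else float(out)


def lmf_correlations(x, params: ModelParams, weights=None) -> list:
    """G_0..G_n on the LMF (uncorrelated, relaxation) factorisation."""
    if weights is None:
        weights = square_weights(max(params.n, 2))
    return [gk_lmf(x, weights, k) for k in range(params.n + 1)]


def observables_lmf(x, params: ModelParams) -> ObservableSet:
    """Relaxation-phase observables from the LMF correlations."""
    x = np.asarray(x, dtype=float)
    weights = square_weights(max(params.n, 2))
    G = lmf_correlations(x, params, weights)
    phi = phi_series(G[1:], params.p, params.n)
    return ObservableSet(
        x=x,
        phi=phi,
        A=absorption(G, params.p),
        sigma_A=sigma_A(x, phi),
        n_avg=n_avg(G, params.p),
        approach="lmf",
        params=params,
    )


def _cmf_x2_of_x(params: ModelParams, x_grid: np.ndarray) -> np.ndarray:
    """Bond density x2 along the CMF induction trajectory, at given x values."""
    t_hi = 8.0 / params.k_I / max(1.0 - params.p, 0.1)
    t = np.linspace(0.0, t_hi, 4000)
    trace = induction_trace_cmf(params, t)
    # x(t) is strictly increasing during induction -> invertible
    return np.interp(x_grid, trace.x, trace.x2, right=1.0)


def observables_cmf(x, params: ModelParams) -> ObservableSet:
    """Induction-phase observables from the CMF pair trajectory at matched x."""
    x = np.asarray(x, dtype=float)
    weights = square_weights(max(params.n, 2))
    x2 = _cmf_x2_of_x(params, x)
    G = [gk_cmf(x, x2, weights, k) for k in range(params.n + 1)]
    phi = phi_series(G[1:], params.p, params.n)
    return ObservableSet(
        x=x,
        phi=phi,
        A=absorption(G, params.p),
        sigma_A=sigma_A(x, phi),
        n_avg=n_avg(G, params.p),
        approach="cmf",
        params=params,
    )


@dataclass
class HysteresisResult:
    """Paired induction (CMF) and relaxation (LMF) yield curves."""

    induction: YieldCurve
    relaxation: YieldCurve
    area: float
    max_gap: float

    def gap(self) -> np.ndarray:
        return self.induction.phi - self.relaxation.phi


def hysteresis_curves(params: ModelParams, x_grid=None) -> HysteresisResult:
    """phi_ind(x) (CMF along induction) vs phi_rel(x) (LMF polynomial).

    The hysteresis scalar is the enclosed area int (phi_ind - phi_rel) dx;
    the maximal vertical gap is reported alongside.
    """
    if x_grid is None:
        x_grid = np.linspace(0.0, 1.0, 401)
    x_grid = np.asarray(x_grid, dtype=float)
    phi_rel = np.asarray(phi_lmf(x_grid, params), dtype=float)
    weights = square_weights(max(params.n, 2))
    x2 = _cmf_x2_of_x(params, x_grid)
    phi_ind = np.asarray(phi_cmf(x_grid, x2, params, weights), dtype=float)
    gap = phi_ind - phi_rel
    area = float(np.trapezoid(gap, x_grid))
    return HysteresisResult(
        induction=YieldCurve(x_grid, phi_ind, "cmf", params),
        relaxation=YieldCurve(x_grid, phi_rel, "lmf", params),
        area=area,
        max_gap=float(np.max(gap)),
    )
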