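"""Joliot and lattice mean-field (LMF) fluorescence-yield models.

An exciton arrives at a reaction center (RC) and, while it keeps meeting
closed RCs, hops on with probability ``p`` (up to ``n`` visits in total) or
is lost as fluorescence with probability ``1 - p``.  With ``G_k`` the
probability that the first k visited RCs are all closed, the fluorescence
yield is

    phi = sum_{k=1}^{n-1} (1 - p) p**(k-1) G_k  +  p**(n-1) G_n.

The Joliot (standard mean-field) model takes G_k = x**k with unlimited n,
giving the hyperbola phi = (1-p)x / (1-px).  The LMF model restricts hops to
nearest neighbours on a lattice and factorises site occupations, G_k =
sum_j c_j(k) x**j with the exact walk weights of :mod:`excilat.walkstats`,
making phi an n-th degree polynomial in the closed fraction x.

Induction kinetics follow from dx/dt = k_I (1 - phi(x)), x(0) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy.integrate import cumulative_trapezoid, quad, solve_ivp
from scipy.optimize import brentq

from .walkstats import LatticeSpec, WeightTable, build_weight_table

__all__ = [
    "ModelParams",
    "KineticTrace",
    "YieldCurve",
    "phi_series",
    "phi_joliot",
    "gk_lmf",
    "phi_lmf",
    "lmf_phi_coeffs",
    "kinetics_from_phi",
    "time_of_x_quadrature",
    "joliot_kinetics",
    "complementary_area",
    "x_closed_n1",
    "x_closed_n2",
    "t_implicit_n3",
    "square_weights",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the exciton-wandering model.

    p    : probability that an exciton on a closed RC hops onward, in [0, 1)
    n    : maximal number of RC visits (exciton lifetime), >= 1
    z    : lattice coordination number (4 = square lattice)
    k_I  : photochemical rate constant; sets the time unit (default 1)
    """

    p: float
    n: int
    z: int = 4
    k_I: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p < 1.0:
            raise ValueError("hopping probability p must lie in [0, 1)")
        if self.n < 1:
            raise ValueError("maximal step count n must be >= 1")
        if self.z < 2:
            raise ValueError("coordination number z must be >= 2")
        if self.k_I <= 0:
            raise ValueError("photochemical rate k_I must be positive")

    @property
    def J(self) -> float:
        """Joliot connectivity parameter J = p / (1 - p)."""
        return self.p / (1.0 - self.p)


@dataclass
class KineticTrace:
    """Time course of closure x(t) and fluorescence yield phi(t).

    Optional channels: nearest-neighbour pair density ``x2``, connected
    correlation ``xtilde2 = x2 - x**2``, absorbed fraction ``A = 1 - phi``
    and complementary area ``C(t) = int_0^t (1 - phi) dt'``.
    """

    t: np.ndarray
    x: np.ndarray
    phi: np.ndarray
    x2: np.ndarray | None = None
    xtilde2: np.ndarray | None = None
    A: np.ndarray | None = None
    C: np.ndarray | None = None
    approach: str = ""
    params: ModelParams | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t, "x": self.x, "phi": self.phi}
        for name in ("x2", "xtilde2", "A", "C"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols)


@dataclass
class YieldCurve:
    """Fluorescence yield phi as a function of the closed fraction x."""

    x: np.ndarray
    phi: np.ndarray
    approach: str
    params: ModelParams | None = None
    phi_se: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"x": self.x, "phi": self.phi}
        if self.phi_se is not None:
            cols["phi_se"] = self.phi_se
        return pd.DataFrame(cols)


@lru_cache(maxsize=8)
def _cached_square_weights(max_k: int) -> WeightTable:
    return build_weight_table(LatticeSpec.square(), max_k)


def square_weights(max_k: int) -> WeightTable:
    """Memoised square-lattice (z=4) weight table up to walk length max_k."""
    return _cached_square_weights(max_k)


def phi_series(G: Sequence[float] | np.ndarray, p: float, n: int | None = None):
    """Fluorescence yield from the first-passage series over closed-RC runs.

    ``G`` holds G_1 .. G_n (each scalar or array over a common grid).  The
    final term carries no (1-p) factor: an exciton still on a closed RC at
    step n is lost by construction.
    """
    G = list(G)
    if n is None:
        n = len(G)
    if n < 1 or len(G) != n:
        raise ValueError("need G_1..G_n with n >= 1")
    if not 0.0 <= p < 1.0:
        raise ValueError("p must lie in [0, 1)")
    phi = p ** (n - 1) * np.asarray(G[-1], dtype=float)
    for k in range(1, n):
        phi = phi + (1.0 - p) * p ** (k - 1) * np.asarray(G[k - 1], dtype=float)
    return phi


def phi_joliot(x, p: float):
    """Joliot hyperbola phi = (1-p) x / (1 - p x)."""
    x = np.asarray(x, dtype=float)
    out = (1.0 - p) * x / (1.0 - p * x)
    return out if out.ndim else float(out)


def gk_lmf(x, weights: WeightTable, k: int):
    """LMF multi-site correlation G_k = sum_j c_j(k) x**j (G_1 = x, G_0 = 1)."""
    x = np.asarray(x, dtype=float)
    if k == 0:
        return np.ones_like(x) if x.ndim else 1.0
    if k == 1:
        return x if x.ndim else float(x)
    g = np.zeros_like(x)
    for j, c in weights.weights(k).items():
        g = g + c * x**j
    return g if g.ndim else float(g)


def lmf_phi_coeffs(params: ModelParams, weights: WeightTable | None = None) -> np.ndarray:
    """Coefficients of the degree-n LMF yield polynomial phi(x)."""
    n = params.n
    if weights is None:
        if params.z != 4:
            raise ValueError("built-in weights cover the square lattice only")
        weights = square_weights(max(n, 2))
    coeffs = np.zeros(n + 1)
    for k in range(1, n + 1):
        w = params.p ** (n - 1) if k == n else (1.0 - params.p) * params.p ** (k - 1)
        if k == 1:
            coeffs[1] += w
        else:
            for j, c in weights.weights(k).items():
                coeffs[j] += w * c
    return coeffs


def phi_lmf(x, params: ModelParams, weights: WeightTable | None = None):
    """LMF fluorescence yield: degree-n polynomial in the closed fraction x."""
    x = np.asarray(x, dtype=float)
    out = npoly.polyval(x, lmf_phi_coeffs(params, weights))
    return out if x.ndim else float(out)


def kinetics_from_phi(
    phi_of_x: Callable[[float], float],
    params: ModelParams,
    t_max: float,
    n_points: int = 400,
    t_grid: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> KineticTrace:
    """Integrate dx/dt = k_I (1 - phi(x)) from x(0) = 0 on a time grid.

    Raises if phi reaches 1 in the interior of [0, 1), where the closure
    rate would vanish before saturation.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, t_max, n_points)
    t_grid = np.asarray(t_grid, dtype=float)
    probe = np.linspace(0.0, 0.999, 200)
    if np.any(np.asarray([phi_of_x(float(v)) for v in probe]) >= 1.0):
        raise ValueError("phi(x) >= 1 in the interior: singular closure rate")

    def rhs(t, y):
        x = min(y[0], 1.0)
        return [params.k_I * (1.0 - phi_of_x(x))]

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [0.0],
        t_eval=t_grid,
        method="DOP853",
        rtol=rtol,
        atol=atol,
    )
    x = np.clip(sol.y[0], 0.0, 1.0)
    phi = np.asarray([phi_of_x(float(v)) for v in x])
    trace = KineticTrace(t=t_grid, x=x, phi=phi, A=1.0 - phi, params=params)
    trace.C = complementary_area(trace)
    return trace


def time_of_x_quadrature(
    phi_of_x: Callable[[float], float], params: ModelParams, x: float
) -> float:
    """Separable-quadrature cross-check: t(x) = int_0^x dx' / (k_I (1 - phi))."""
    if not 0.0 <= x < 1.0:
        raise ValueError("x must lie in [0, 1)")
    val, _ = quad(lambda u: 1.0 / (1.0 - phi_of_x(u)), 0.0, x, limit=200)
    return val / params.k_I


def joliot_kinetics(params: ModelParams, t_grid: np.ndarray) -> KineticTrace:
    """Joliot induction x(t) from the implicit form t = p x - (1-p) ln(1-x).

    dx/dt = k_I (1-x)/(1-px) separates exactly; the implicit relation is
    inverted by bracketed root finding at every requested time.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    p = params.p
    x = np.empty_like(t_grid)
    for i, t in enumerate(t_grid * params.k_I):
        if t <= 0.0:
            x[i] = 0.0
            continue
        # substitute w = -ln(1-x): f is monotone on w >= 0 with no poles
        f = lambda w: -p * np.expm1(-w) + (1.0 - p) * w - t
        w = brentq(f, 0.0, (t + 1.0) / (1.0 - p), xtol=1e-14)
        x[i] = -np.expm1(-w)
    phi = phi_joliot(x, p)
    trace = KineticTrace(
        t=t_grid, x=x, phi=phi, A=1.0 - phi, approach="joliot", params=params
    )
    trace.C = complementary_area(trace)
    return trace


def complementary_area(trace: KineticTrace) -> np.ndarray:
    """Complementary area C(t) = int_0^t (1 - phi) dt' (trapezoidal).

    For any trace obeying dx/dt = k_I (1 - phi), x(t) = k_I C(t); for
    Joliot-generated traces 1/phi is linear in 1/C with slope
    1/(k_I (1-p)) and intercept -p/(1-p).
    """
    t = np.asarray(trace.t, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return cumulative_trapezoid(1.0 - trace.phi, t, initial=0.0)


# ---------------------------------------------------------------------------
# closed-form LMF induction kinetics for n = 1, 2, 3 (square lattice)
# ---------------------------------------------------------------------------

def x_closed_n1(t):
    """n=1 closure: x(t) = 1 - exp(-t) (phi = x, no wandering)."""
    return -np.expm1(-np.asarray(t, dtype=float))


def x_closed_n2(t, p: float):
    """n=2 closure: x(t) = (e^{(1+p)t} - 1) / (e^{(1+p)t} + p)."""
    e = np.exp((1.0 + p) * np.asarray(t, dtype=float))
    return (e - 1.0) / (e + p)


def t_implicit_n3(x, p: float):
    """n=3 implicit time t(x); principal arctan branch.

    Derived from 1 - phi = (1-x)(1 + px + 3/4 (px)^2) by partial fractions.
    """
    x = np.asarray(x, dtype=float)
    d = 1.0 + p + 0.75 * p**2
    term1 = ((1.0 + 1.5 * p) / np.sqrt(2.0) / d) * (
        np.arctan((1.5 * p * x + 1.0) / np.sqrt(2.0)) - np.arctan(1.0 / np.sqrt(2.0))
    )
    term2 = (1.0 / (2.0 * d)) * np.log(
        np.abs(1.0 - x) ** 2 / np.abs(1.0 + p * x + 0.75 * (p * x) ** 2)
    )
    return term1 - term2
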