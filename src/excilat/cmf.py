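"""Cluster mean-field (CMF) dynamics of closed-RC pairs during induction.

The CMF approach tracks two variables: the open-site probability
``q = P_o`` and the open-pair probability ``u = P_oo`` on nearest-neighbour
bonds.  Closure of an open site happens when a photon lands on it directly
(rate 1 in units of k_I) or lands on a closed neighbour and the exciton hops
over (probability p/z per orientation).  With the pair-approximation closure
P_oo. ~ P_oo P_o. / P_o the dynamics reads

    -d ln q / dt = 1 + p (q - u) / q
    -(1/2) d ln u / dt = 1 + p (z-1)/z (q - u) / q

which combine to the exact invariant u = q**(2(z-1)/z) exp(-2t/z) and admit
a closed-form q(t) for z > 2.  Multi-site correlations are then built from
x = 1 - q and the bond density x2 = 1 - 2q + u via

    G_k = sum_j c_j(k) x2**(j-1) / x**(j-2),

capturing the bunching (x2 > x**2) of closed RCs that makes the
fluorescence yield larger during induction than during relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .meanfield import KineticTrace, ModelParams, phi_series
from .walkstats import WeightTable

__all__ = [
    "PairState",
    "pair_closed_form",
    "pair_ode",
    "gk_cmf",
    "phi_cmf",
    "induction_trace_cmf",
]


@dataclass(frozen=True)
class PairState:
    """One-site and pair probabilities of a two-site RC cluster.

    q = P_o (open site), u = P_oo (open pair); both may be arrays over a
    common time grid.  Derived: x = 1-q, x2 = 1-2q+u, xtilde2 = x2 - x**2,
    p_open_closed = q-u, p_closed_closed = x2.
    """

    t: np.ndarray
    q: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        q, u = np.atleast_1d(self.q), np.atleast_1d(self.u)
        tol = 1e-9
        if np.any(u > q + tol) or np.any(u < -tol) or np.any(q > 1 + tol):
            raise ValueError("pair state requires 0 <= u <= q <= 1")
        if np.any(1.0 - 2.0 * q + u < -tol):
            raise ValueError("closed-pair probability 1 - 2q + u is negative")

    @property
    def x(self) -> np.ndarray:
        return 1.0 - self.q

    @property
    def x2(self) -> np.ndarray:
        return 1.0 - 2.0 * self.q + self.u

    @property
    def xtilde2(self) -> np.ndarray:
        return self.x2 - self.x**2

    @property
    def p_open_closed(self) -> np.ndarray:
        return self.q - self.u


def pair_closed_form(params: ModelParams, t) -> PairState:
    """Analytic solution of the pair dynamics.

    For z > 2:
        q(t) = e^{2t/(z-2)} [ (a + e^{t(1+a)}) / (a + 1) ]^{z/(2-z)},
        a = p (z-2)/z,
    and for z = 2: q(t) = exp[-(1+p) t + p (1 - e^{-t})].
    In both cases u(t) = q**(2(z-1)/z) e^{-2t/z}.
    """
    if params.z < 2:
        raise ValueError("z must be >= 2")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    p, z = params.p, params.z
    tau = params.k_I * t
    if z == 2:
        q = np.exp(-(1.0 + p) * tau + p * (1.0 - np.exp(-tau)))
    else:
        a = p * (z - 2.0) / z
        q = np.exp(2.0 * tau / (z - 2.0)) * (
            (a + np.exp(tau * (1.0 + a))) / (a + 1.0)
        ) ** (z / (2.0 - z))
    u = q ** (2.0 * (z - 1.0) / z) * np.exp(-2.0 * tau / z)
    return PairState(t=t, q=q, u=u)


def pair_ode(
    params: ModelParams, t_grid, rtol: float = 1e-11, atol: float = 1e-13
) -> PairState:
    """Numerical pair dynamics, integrated in log space (lq = ln q, lu = ln u).

    Independent cross-check of :func:`pair_closed_form`; also verifies the
    invariant u q**(-2(z-1)/z) e^{2t/z} = 1 along the trajectory.
    """
    if params.z < 2:
        raise ValueError("z must be >= 2")
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    p, z, kI = params.p, params.z, params.k_I

    def rhs(t, y):
        lq, lu = y
        # (q-u)/q = 1 - exp(lu - lq), safe for q -> 0
        ratio = 1.0 - np.exp(min(lu - lq, 0.0))
        dlq = -kI * (1.0 + p * ratio)
        dlu = -2.0 * kI * (1.0 + p * (z - 1.0) / z * ratio)
        return [dlq, dlu]

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        [0.0, 0.0],
        t_eval=t_grid,
        method="DOP853",
        rtol=rtol,
        atol=atol,
    )
    return PairState(t=t_grid, q=np.exp(sol.y[0]), u=np.exp(sol.y[1]))


def gk_cmf(x, x2, weights: WeightTable, k: int):
    """CMF multi-site correlation G_k = sum_j c_j(k) x2**(j-1) / x**(j-2).

    Requires a consistent pair state (0 <= x2 <= x); since each term is
    bounded by x2 (x2/x)**(j-2), the x -> 0 limit is defined as 0.
    Reduces to the LMF value when x2 = x**2.
    """
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x2 > x + 1e-12) or np.any(x2 < -1e-12):
        raise ValueError("inconsistent pair state: need 0 <= x2 <= x")
    if k == 0:
        return np.ones_like(x) if x.ndim else 1.0
    if k == 1:
        return x if x.ndim else float(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(x > 0.0, np.minimum(x2 / np.where(x > 0, x, 1.0), 1.0), 0.0)
    g = np.zeros_like(x)
    for j, c in weights.weights(k).items():
        g = g + c * x2 * ratio ** (j - 2)
    return g if g.ndim else float(g)


def phi_cmf(x, x2, params: ModelParams, weights: WeightTable):
    """CMF fluorescence yield: the closure series evaluated with gk_cmf."""
    G = [gk_cmf(x, x2, weights, k) for k in range(1, params.n + 1)]
    return phi_series(G, params.p, params.n)


def induction_trace_cmf(
    params: ModelParams,
    t_grid,
    weights: WeightTable | None = None,
    mode: str = "printed",
) -> KineticTrace:
    """CMF induction trace: x(t), x2(t) from pair dynamics, phi from the series.

    mode="printed"    : pair equations as stated (single-hop closure); the
                        exciton lifetime n enters only through phi.  For
                        n = 2 this is self-consistent (dx/dt = k_I (1-phi)).
    mode="consistent" : same (q, u) trajectory, but time is reparameterised
                        so that dx/dt = k_I (1 - phi(x, x2)) holds for any n;
                        the x2(x) relation is unchanged.
    """
    from .meanfield import square_weights

    if weights is None:
        if params.z != 4:
            raise ValueError("built-in weights cover the square lattice only")
        weights = square_weights(max(params.n, 2))
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))

    if mode == "printed":
        state = pair_closed_form(params, t_grid)
        x, x2, t_out = state.x, state.x2, t_grid
    elif mode == "consistent":
        # evolve internal pair time s with ds/dt = (1-phi)/(q + p(q-u)) so the
        # one-site closure rate matches the n-step yield series
        p = params.p

        def rhs(t, y):
            s = y[0]
            st = pair_closed_form(params, s)
            q, u = float(st.q[0]), float(st.u[0])
            xx, xx2 = 1.0 - q, 1.0 - 2.0 * q + u
            phi = float(phi_cmf(xx, xx2, params, weights))
            denom = q + p * (q - u)
            if denom < 1e-14:
                return [1.0]
            return [(1.0 - phi) / denom * params.k_I / params.k_I]

        sol = solve_ivp(
            rhs,
            (0.0, float(t_grid[-1])),
            [0.0],
            t_eval=t_grid,
            method="DOP853",
            rtol=1e-10,
            atol=1e-12,
        )
        state = pair_closed_form(params, sol.y[0])
        x, x2, t_out = state.x, state.x2, t_grid
    else:
        raise ValueError(f"unknown mode {mode!r}")

    phi = np.asarray(phi_cmf(x, x2, params, weights), dtype=float)
    trace = KineticTrace(
        t=t_out,
        x=x,
        phi=phi,
        x2=x2,
        xtilde2=x2 - x**2,
        A=1.0 - phi,
        approach="cmf",
        params=params,
    )
    from .meanfield import complementary_area

    trace.C = complementary_area(trace)
    return trace
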