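"""Monte Carlo lattice simulator of RC closure and fluorescence.

Each reaction center is a site of an L x L torus, open (0) or closed (1).
Photons land one at a time on uniformly random sites; the exciton walks by
the same rules as the mean-field series (hop with probability p, up to n
visits), closing the first open RC it meets or being lost as fluorescence.
Model time advances by 1/(N k_I) per photon, so dx/dt = k_I (1 - phi) holds
in expectation.

Induction runs mutate the lattice progressively (correlated closure);
relaxation is modelled as a quasi-static sweep over uncorrelated
configurations probed by non-perturbing excitons, matching the assumption
that reopening in the dark is uncorrelated in space and time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .meanfield import ModelParams, YieldCurve

__all__ = [
    "Lattice",
    "ExcitonOutcome",
    "SimTrace",
    "walk_exciton",
    "run_induction",
    "sample_uncorrelated",
    "probe_phi",
    "relaxation_curve",
    "measure_x2",
]

_SEED_MAX = 2**31 - 1


@dataclass
class Lattice:
    """Binary closed-RC configuration on an L x L torus (z = 4)."""

    states: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.states)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("lattice must be a square 2-D array")
        if not np.isin(s, (0, 1)).all():
            raise ValueError("lattice states must be binary")
        self.states = s.astype(np.uint8)

    @property
    def L(self) -> int:
        return self.states.shape[0]

    @property
    def N(self) -> int:
        return self.states.size

    @property
    def x(self) -> float:
        """Fraction of closed RCs."""
        return float(self.states.mean())


@dataclass(frozen=True)
class ExcitonOutcome:
    """Fate of a single exciton: 'absorbed' or 'fluoresced', at which step
    (1..n) and at which terminal site."""

    fate: str
    step: int
    site: tuple[int, int]


@dataclass
class SimTrace:
    """Replicate-averaged induction record.

    phi is the across-replicate fraction of fluoresced outcomes at each
    recorded photon index (unbiased, no windowing); x and x2 are lattice
    averages with across-replicate standard errors.  ``snapshots`` maps each
    requested closed density to an array of shape (R, L, L) holding the
    lattice of every replicate when it first reached that density.
    """

    t: np.ndarray
    photon_index: np.ndarray
    x: np.ndarray
    x_se: np.ndarray
    phi: np.ndarray
    phi_se: np.ndarray
    x2: np.ndarray
    x2_se: np.ndarray
    snapshots: dict[float, np.ndarray] = field(default_factory=dict)
    x_rep: np.ndarray | None = None
    x2_rep: np.ndarray | None = None
    out_rep: np.ndarray | None = None
    params: ModelParams | None = None
    seeds: np.ndarray | None = None

    @property
    def xtilde2(self) -> np.ndarray:
        return self.x2 - self.x**2


def walk_exciton(
    lattice: Lattice,
    start: tuple[int, int],
    params: ModelParams,
    rng: np.random.Generator,
    mutate: bool = False,
) -> ExcitonOutcome:
    """Walk one exciton from its arrival site (step 1).

    At an open RC the exciton is absorbed (and closes it if ``mutate``); at
    a closed RC with steps remaining it hops to one of the 4 torus
    neighbours with probability p (returns allowed) or fluoresces; at step n
    on a closed RC it fluoresces.
    """
    s, L = lattice.states, lattice.L
    r, c = start
    step = 1
    offsets = ((1, 0), (0, 1), (-1, 0), (0, -1))
    while True:
        if s[r, c] == 0:
            if mutate:
                s[r, c] = 1
            return ExcitonOutcome("absorbed", step, (r, c))
        if step == params.n:
            return ExcitonOutcome("fluoresced", step, (r, c))
        if rng.random() < params.p:
            dr, dc = offsets[rng.integers(0, 4)]
            r, c = (r + dr) % L, (c + dc) % L
            step += 1
        else:
            return ExcitonOutcome("fluoresced", step, (r, c))


def run_induction(
    L: int,
    params: ModelParams,
    replicates: int,
    rng: np.random.Generator,
    t_max: float = 6.0,
    record_times: np.ndarray | None = None,
    snapshot_densities: tuple[float, ...] = (),
) -> SimTrace:
    """Simulate induction on ``replicates`` independent L x L lattices.

    Photon index m corresponds to model time t = m/(N k_I).  Snapshots are
    captured per replicate when the closed fraction first reaches each
    requested density.
    """
    if L < 2 or replicates < 1:
        raise ValueError("need L >= 2 and replicates >= 1")
    N = L * L
    if record_times is None:
        record_times = np.linspace(0.0, t_max, 121)
    record_times = np.asarray(record_times, dtype=float)
    rec_idx = np.unique(np.round(record_times * N * params.k_I).astype(np.int64))
    n_photons = int(rec_idx[-1]) + 1
    snap_counts = np.asarray(
        [max(1, int(round(d * N))) for d in snapshot_densities], dtype=np.int64
    )
    seeds = rng.integers(0, _SEED_MAX, size=replicates)

    n_rec = rec_idx.size
    X = np.empty((replicates, n_rec))
    X2 = np.empty((replicates, n_rec))
    OUT = np.empty((replicates, n_rec), dtype=np.int8)
    snaps = np.empty((replicates, len(snap_counts), L, L), dtype=np.uint8)
    for r in range(replicates):
        x_r, x2_r, out_r, sn, _ = _kernels.induction_kernel(
            L, params.p, params.n, n_photons, rec_idx, snap_counts, int(seeds[r])
        )
        X[r], X2[r], OUT[r] = x_r, x2_r, out_r
        snaps[r] = sn

    sqrtR = np.sqrt(replicates)
    ddof = 1 if replicates > 1 else 0
    # binomial SE with a Jeffreys-style shrunk proportion so that runs where
    # every replicate (doesn't) fluoresce keep a nonzero error bar
    p_shrunk = (OUT.sum(axis=0) + 0.5) / (replicates + 1.0)
    return SimTrace(
        t=rec_idx / (N * params.k_I),
        photon_index=rec_idx,
        x=X.mean(axis=0),
        x_se=X.std(axis=0, ddof=ddof) / sqrtR,
        phi=OUT.mean(axis=0),
        phi_se=np.sqrt(p_shrunk * (1.0 - p_shrunk) / replicates),
        x2=X2.mean(axis=0),
        x2_se=X2.std(axis=0, ddof=ddof) / sqrtR,
        snapshots={
            d: snaps[:, i] for i, d in enumerate(snapshot_densities)
        },
        x_rep=X,
        x2_rep=X2,
        out_rep=OUT,
        params=params,
        seeds=seeds,
    )


def sample_uncorrelated(L: int, x: float, rng: np.random.Generator) -> Lattice:
    """Uncorrelated configuration with exactly round(x N) closed sites."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must lie in [0, 1]")
    N = L * L
    n_closed = int(round(x * N))
    flat = np.zeros(N, dtype=np.uint8)
    flat[rng.permutation(N)[:n_closed]] = 1
    return Lattice(flat.reshape(L, L))


def probe_phi(
    lattice: Lattice,
    params: ModelParams,
    n_probes: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Fluorescence yield from non-perturbing probe excitons.

    Returns (phi_hat, binomial standard error); the lattice is unchanged.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    seed = int(rng.integers(0, _SEED_MAX))
    fl = _kernels.probe_kernel(
        lattice.states, lattice.L, params.p, params.n, n_probes, seed
    )
    phi = fl / n_probes
    se = np.sqrt(phi * (1.0 - phi) / n_probes)
    return float(phi), float(se)


def relaxation_curve(
    L: int,
    params: ModelParams,
    x_grid: np.ndarray,
    n_probes: int,
    rng: np.random.Generator,
) -> YieldCurve:
    """Quasi-static relaxation yield: probe uncorrelated maps at each x."""
    x_grid = np.asarray(x_grid, dtype=float)
    phi = np.empty_like(x_grid)
    se = np.empty_like(x_grid)
    for i, x in enumerate(x_grid):
        lat = sample_uncorrelated(L, float(x), rng)
        phi[i], se[i] = probe_phi(lat, params, n_probes, rng)
    return YieldCurve(x=x_grid, phi=phi, approach="mc", params=params, phi_se=se)


def measure_x2(lattice: Lattice) -> float:
    """Nearest-neighbour pair density: mean of s_i s_j over all 2N torus bonds."""
    s = lattice.states.astype(np.float64)
    return float(
        0.5 * ((s * np.roll(s, 1, axis=0)).mean() + (s * np.roll(s, 1, axis=1)).mean())
    )
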