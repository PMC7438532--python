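"""Numba inner loops for the lattice Monte Carlo simulator.

Kept free of Python objects so the photon loop compiles to machine code;
the public API lives in :mod:`excilat.mc_sim`.  Randomness uses numba's
per-thread legacy np.random state, seeded explicitly per call, which makes
every kernel run bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def walk_kernel(states, L, r, c, p, n, mutate):
    """Single exciton walk; returns (fate, step, r, c) with fate 0=absorbed,
    1=fluoresced.  Mutate closes the absorbing open RC (induction)."""
    step = 1
    while True:
        if states[r, c] == 0:
            if mutate:
                states[r, c] = 1
            return 0, step, r, c
        if step == n:
            return 1, step, r, c
        if np.random.random() < p:
            d = np.random.randint(0, 4)
            if d == 0:
                r = (r + 1) % L
            elif d == 1:
                c = (c + 1) % L
            elif d == 2:
                r = (r - 1 + L) % L
            else:
                c = (c - 1 + L) % L
            step += 1
        else:
            return 1, step, r, c


@njit(cache=False)
def bond_density(states, L):
    """Fraction of closed-closed pairs over all 2 L^2 torus bonds."""
    tot = 0
    for r in range(L):
        for c in range(L):
            if states[r, c] == 1:
                if states[(r + 1) % L, c] == 1:
                    tot += 1
                if states[r, (c + 1) % L] == 1:
                    tot += 1
    return tot / (2.0 * L * L)


@njit(cache=False)
def induction_kernel(L, p, n, n_photons, record_idx, snap_counts, seed):
    """One induction replicate: photons land uniformly, walk, close open RCs.

    record_idx : sorted unique photon indices m; x and x2 are recorded in
                 the state *before* photon m (so t = m/(N k_I)), and the
                 fate of photon m itself is stored (1 = fluoresced).
    snap_counts: closed-site counts at which to snapshot the lattice.
    """
    np.random.seed(seed)
    states = np.zeros((L, L), dtype=np.uint8)
    N = L * L
    n_rec = record_idx.shape[0]
    x_rec = np.empty(n_rec)
    x2_rec = np.empty(n_rec)
    out_rec = np.zeros(n_rec, dtype=np.int8)
    n_snap = snap_counts.shape[0]
    snaps = np.zeros((n_snap, L, L), dtype=np.uint8)
    snap_done = np.zeros(n_snap, dtype=np.uint8)
    closed = 0
    rec_ptr = 0
    for m in range(n_photons):
        is_rec = rec_ptr < n_rec and record_idx[rec_ptr] == m
        if is_rec:
            x_rec[rec_ptr] = closed / N
            x2_rec[rec_ptr] = bond_density(states, L)
        site = np.random.randint(0, N)
        fate, step, rr, cc = walk_kernel(states, L, site // L, site % L, p, n, True)
        if fate == 0:
            closed += 1
            for s in range(n_snap):
                if snap_done[s] == 0 and closed >= snap_counts[s]:
                    snaps[s] = states.copy()
                    snap_done[s] = 1
        if is_rec:
            out_rec[rec_ptr] = fate
            rec_ptr += 1
    return x_rec, x2_rec, out_rec, snaps, states


@njit(cache=False)
def probe_kernel(states, L, p, n, n_probes, seed):
    """Count fluoresced outcomes of non-perturbing probe excitons."""
    np.random.seed(seed)
    N = L * L
    fl = 0
    for i in range(n_probes):
        site = np.random.randint(0, N)
        fate, step, r, c = walk_kernel(states, L, site // L, site % L, p, n, False)
        fl += fate
    return fl
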