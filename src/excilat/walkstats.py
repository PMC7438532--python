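"""Exact distinct-site statistics of nearest-neighbour lattice walks.

A *k-site walk* arrives at a lattice site on step 1 and then makes k-1
nearest-neighbour hops (returns allowed), so there are z**(k-1) walks from a
fixed arrival site on a lattice with coordination number z.  The census
``N_j`` counts walks that visit exactly ``j`` distinct sites; the fractions
``c_j = N_j / z**(k-1)`` are the weights that turn powers of the closed-RC
density into the multi-site correlations of the lattice mean-field and
cluster mean-field fluorescence models.

Two conventions are exposed side by side because they differ by a factor z:

* ``counts``        N_j(k)  — raw walk counts, sum to z**(k-1);
* ``table entries`` T_j(k) = N_j(k) / z — the integers conventionally
  tabulated for the square lattice (row sums 4**(k-2), diagonal equal to
  the self-avoiding-walk counts divided by 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator

import pandas as pd

__all__ = [
    "LatticeSpec",
    "WalkCensus",
    "WeightTable",
    "enumerate_walks",
    "walk_census_dp",
    "census_to_weights",
    "build_weight_table",
]

#: largest number of walks we are willing to enumerate exhaustively
_MAX_WALKS = 4 ** 13


@dataclass(frozen=True)
class LatticeSpec:
    """Bravais lattice described by its nearest-neighbour displacement set."""

    dimension: int
    z: int
    neighbor_offsets: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if len(self.neighbor_offsets) != self.z:
            raise ValueError("number of neighbor offsets must equal z")
        offs = set(self.neighbor_offsets)
        for d in offs:
            if len(d) != self.dimension:
                raise ValueError("offset dimensionality mismatch")
            if tuple(-c for c in d) not in offs:
                raise ValueError("neighbor offsets must be closed under negation")

    @staticmethod
    def chain() -> "LatticeSpec":
        """One-dimensional chain, z = 2."""
        return LatticeSpec(1, 2, ((1,), (-1,)))

    @staticmethod
    def square() -> "LatticeSpec":
        """Square lattice, z = 4; offset order fixed (+x, +y, -x, -y)."""
        return LatticeSpec(2, 4, ((1, 0), (0, 1), (-1, 0), (0, -1)))


@dataclass(frozen=True)
class WalkCensus:
    """Counts ``N_j`` of k-site walks visiting exactly j distinct sites."""

    z: int
    k: int
    counts: dict[int, int]

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        total = sum(self.counts.values())
        if total != self.z ** (self.k - 1):
            raise ValueError(
                f"census does not partition the walk set: {total} != z^(k-1)"
            )
        if any(j < 2 or j > self.k for j in self.counts):
            raise ValueError("distinct-site count j must lie in [2, k]")

    @property
    def n_walks(self) -> int:
        return self.z ** (self.k - 1)

    def table_entries(self) -> dict[int, Fraction]:
        """T_j(k) = N_j(k)/z (integers on Bravais lattices)."""
        return {j: Fraction(n, self.z) for j, n in sorted(self.counts.items())}


@dataclass
class WeightTable:
    """Walk-weight fractions c_j(k) for k = 2..max_k on one lattice.

    ``c[(k, j)]`` is the fraction of k-site walks visiting j distinct sites;
    rows sum to one.  ``table_entries[(k, j)]`` holds N_j(k)/z.
    """

    z: int
    max_k: int
    c: dict[tuple[int, int], float] = field(default_factory=dict)
    table_entries: dict[tuple[int, int], Fraction] = field(default_factory=dict)

    def weights(self, k: int) -> dict[int, float]:
        """Row k as a map j -> c_j(k)."""
        if k < 2 or k > self.max_k:
            raise ValueError(f"k={k} outside weight table range [2, {self.max_k}]")
        return {j: self.c[(kk, j)] for (kk, j) in self.c if kk == k}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (k, j), cval in sorted(self.c.items()):
            t = self.table_entries[(k, j)]
            rows.append(
                {
                    "k": k,
                    "j": j,
                    "N": int(t * self.z),
                    "c": cval,
                    "table_entry": float(t),
                }
            )
        return pd.DataFrame(rows)


def _check_k(spec: LatticeSpec, k: int) -> None:
    if k < 2:
        raise ValueError("walk length k must be >= 2")
    if spec.z ** (k - 1) > _MAX_WALKS:
        raise ValueError(
            f"z^(k-1) = {spec.z ** (k - 1)} walks exceed the enumeration guard"
        )


def enumerate_walks(spec: LatticeSpec, k: int) -> WalkCensus:
    """Exhaustive depth-first census of all z**(k-1) k-site walks.

    The walk starts at the origin (arrival step); each of the k-1 hops ranges
    over all z neighbour offsets, so the same site may be revisited.
    """
    _check_k(spec, k)
    counts: dict[int, int] = {}
    offsets = spec.neighbor_offsets
    origin = (0,) * spec.dimension
    visited: dict[tuple[int, ...], int] = {origin: 1}

    def dfs(pos: tuple[int, ...], steps_left: int) -> None:
        if steps_left == 0:
            j = len(visited)
            counts[j] = counts.get(j, 0) + 1
            return
        for d in offsets:
            nxt = tuple(a + b for a, b in zip(pos, d))
            visited[nxt] = visited.get(nxt, 0) + 1
            dfs(nxt, steps_left - 1)
            if visited[nxt] == 1:
                del visited[nxt]
            else:
                visited[nxt] -= 1

    dfs(origin, k - 1)
    return WalkCensus(z=spec.z, k=k, counts=counts)


def walk_census_dp(spec: LatticeSpec, k: int) -> WalkCensus:
    """Independent census via dynamic programming over visited-site shapes.

    The state of a partial walk is its set of visited sites expressed
    relative to the current position; walks sharing a state evolve
    identically, so their multiplicities are merged.  Must agree with
    :func:`enumerate_walks` exactly.
    """
    _check_k(spec, k)
    origin = (0,) * spec.dimension
    # state: frozenset of visited sites relative to current position -> count
    states: dict[frozenset, int] = {frozenset([origin]): 1}
    for _ in range(k - 1):
        nxt_states: dict[frozenset, int] = {}
        for visited, mult in states.items():
            for d in spec.neighbor_offsets:
                shifted = frozenset(
                    tuple(a - b for a, b in zip(site, d)) for site in visited
                )
                new_state = shifted | {origin}
                nxt_states[new_state] = nxt_states.get(new_state, 0) + mult
        states = nxt_states
    counts: dict[int, int] = {}
    for visited, mult in states.items():
        j = len(visited)
        counts[j] = counts.get(j, 0) + mult
    return WalkCensus(z=spec.z, k=k, counts=counts)


def census_to_weights(*censuses: WalkCensus) -> WeightTable:
    """Convert one or more censuses (same z) into a :class:`WeightTable`."""
    if not censuses:
        raise ValueError("at least one census required")
    z = censuses[0].z
    if any(c.z != z for c in censuses):
        raise ValueError("all censuses must share the same z")
    table = WeightTable(z=z, max_k=max(c.k for c in censuses))
    for cen in censuses:
        denom = z ** (cen.k - 1)
        for j, n in cen.counts.items():
            table.c[(cen.k, j)] = n / denom
            table.table_entries[(cen.k, j)] = Fraction(n, z)
    return table


def build_weight_table(
    spec: LatticeSpec, max_k: int, method: str = "enumerate"
) -> WeightTable:
    """Weight table for all walk lengths k = 2..max_k."""
    if max_k < 2:
        raise ValueError("max_k must be >= 2")
    fn = {"enumerate": enumerate_walks, "dp": walk_census_dp}
    if method not in fn:
        raise ValueError(f"unknown method {method!r}")
    return census_to_weights(*(fn[method](spec, k) for k in range(2, max_k + 1)))


def iter_table_rows(table: WeightTable) -> Iterator[tuple[int, int, int]]:
    """Yield (k, j, T_j(k)) integer rows of the square-lattice weight table."""
    for (k, j), t in sorted(table.table_entries.items()):
        yield k, j, int(t)
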