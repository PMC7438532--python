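# excilat

Exciton wandering on reaction-center lattices: connectivity models of
bacterial photosynthetic units, from exact random-walk combinatorics to
Monte Carlo simulation of fluorescence induction.

## The problem

In purple photosynthetic bacteria, light absorbed by the antenna migrates as
an exciton until it is trapped by an **open** reaction center (RC,
photochemistry) or lost as fluorescence. A closed RC (oxidized special pair,
P⁺) reflects the exciton, which may wander on to a neighbouring
photosynthetic unit. The measured fluorescence yield φ therefore reports the
connectivity of the units and the spatial arrangement of the closed RCs.

The classical Joliot–Lavergne–Trissl treatment assumes an unlimited exciton
lifetime and distance-independent hops, giving the hyperbola
φ = (1−p)x / (1−px), where x = P⁺ is the closed fraction and p the hopping
probability (connectivity J = p/(1−p)). Measured induction/relaxation pairs
deviate from this hyperbola in two ways: the curve is asymmetric, and φ(x)
is *hysteretic* — larger during induction than during relaxation at the same
x. `excilat` implements the lattice generalisation that explains both:
excitons make at most `n` nearest-neighbour hops on a square lattice of RCs
(z = 4), and progressive closure under illumination *bunches* the closed RCs
(x₂ > x²), while dark reopening leaves them uncorrelated.

## The model

With G_k the probability that the first k visited RCs are all closed, the
yield is the first-passage series

    φ = Σ_{k=1}^{n−1} (1−p) p^(k−1) G_k + p^(n−1) G_n,    A = 1 − φ,

and induction kinetics follow dx/dt = k_I (1 − φ(x)). The approximations
differ only in G_k:

* **Joliot**: G_k = x^k, n → ∞ (hyperbola);
* **LMF** (lattice mean field, relaxation): G_k = Σ_j c_j^(k) x^j with exact
  walk-census weights c_j^(k) — the fraction of k-site nearest-neighbour
  walks visiting j distinct sites (`excilat.walkstats` enumerates them
  exhaustively);
* **CMF** (cluster mean field, induction): G_k = Σ_j c_j^(k) x₂^(j−1)/x^(j−2)
  with the nearest-neighbour pair density x₂ evolved by a two-site
  pair-approximation master equation that has a closed-form solution.

A numba-accelerated Monte Carlo simulator runs the exact stochastic process
on an L×L torus, and a percolation module shows that bunching lowers the
effective site-percolation threshold of the closed-RC clusters (uncorrelated
reference 0.5927460). A trace layer normalises fluorescence/P⁺ kinetics,
pairs them by eliminating time, and fits the effective Joliot p.

## Worked example

```python
import numpy as np
from excilat import (ModelParams, NoiseModel, hysteresis_curves, synth_traces,
                     normalize_fluorescence, normalize_absorption,
                     eliminate_time, fit_joliot)

params = ModelParams(p=0.9, n=3)
h = hysteresis_curves(params)
print(f"hysteresis area (p=0.9, n=3): {h.area:.4f}")
print(f"largest yield gap phi_ind - phi_rel: {h.max_gap:.4f}")

truth = ModelParams(p=0.9, n=3, k_I=1000.0)
rng = np.random.default_rng(0)
fl_i, ab_i = synth_traces(truth, rng, approach="cmf", phase="induction",
                          noise=NoiseModel(sigma=0.01))
fl_r, ab_r = synth_traces(truth, rng, approach="lmf", phase="relaxation",
                          noise=NoiseModel(sigma=0.01))
xi, pi = eliminate_time(normalize_fluorescence(fl_i, 10), normalize_absorption(ab_i, 10))
xr, pr = eliminate_time(normalize_fluorescence(fl_r, 10), normalize_absorption(ab_r, 10))
print(f"fitted Joliot p during induction : {fit_joliot(xi, pi).p_hat:.3f}")
print(f"fitted Joliot p during relaxation: {fit_joliot(xr, pr).p_hat:.3f}")
```

prints

```
hysteresis area (p=0.9, n=3): 0.0091
largest yield gap phi_ind - phi_rel: 0.0175
fitted Joliot p during induction : 0.660
fitted Joliot p during relaxation: 0.727
```

The loop area is the hysteresis between the induction (CMF) and relaxation
(LMF) yield curves at equal x. The last two lines reproduce the hallmark of
bunching on noisy synthetic traces with one shared true p: a Joliot fit
returns a *smaller* effective connectivity during induction than during
relaxation, because correlated closed clusters keep the fluorescence higher
on the way up.

A command-line interface mirrors the library
(`excilat walks|solve|simulate|percolate|observables|synth|fit`); every run
writes a `manifest.json` with the resolved parameters, seed and output
checksums so artifacts are regenerable.

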