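# Methods

## Model

Reaction centers (RCs) occupy the sites of a square lattice (coordination
number z = 4); each is open (σ = 0, a perfect exciton trap) or closed
(σ = 1, a perfect reflector). Photons arrive uniformly at rate k_I per site.
An exciton arriving at a site counts as its first visit; on a closed RC it
hops to a uniformly chosen nearest neighbour with probability p (returns
allowed) or is lost as fluorescence with probability 1 − p, up to a maximum
of n visits; on an open RC it is absorbed and, during induction, closes
that RC. Every exciton ends absorbed or fluoresced, so the absorbed
fraction and fluorescence yield obey A + φ = 1 identically.

With G_k the probability that the first k visited RCs are all closed, the
yield is

    φ = Σ_{k=1}^{n−1} (1−p) p^(k−1) G_k + p^(n−1) G_n.

The exponent convention deserves emphasis: the weight of the k-th term is
p^(k−1) (k − 1 completed hops before the k-th visit), and the final term
carries no (1 − p) factor because an exciton still on a closed RC at step n
is lost unconditionally. This is the unique convention under which n = 1
gives φ = x, the n → ∞ limit with G_k = x^k gives the Joliot hyperbola
φ = (1−p)x/(1−px), and A + φ = 1 holds term by term against
A = Σ p^(k−1)(G_{k−1} − G_k). Induction kinetics follow
dx/dt = k_I (1 − φ(x)), x(0) = 0; k_I is fixed to 1 in model units and only
the trace layer rescales time to seconds.

## Walk census and weight conventions

`walkstats` enumerates all z^(k−1) k-site nearest-neighbour walks from a
fixed arrival site and counts N_j^(k), the number visiting exactly j
distinct sites. Three scalings are exposed because the literature mixes
them: raw counts N_j (sum z^(k−1)), fractions c_j = N_j / z^(k−1) (the
weights entering G_k), and table entries T_j = N_j / z — integers whose
rows sum to 4^(k−2) and whose diagonal T_k^(k) equals the square-lattice
self-avoiding-walk counts divided by 4. These identities, plus an
independent dynamic-programming census over visited-site shapes, are the
correctness oracles. Neighbour order is fixed (+x, +y, −x, −y) for
reproducible traversal; counts are order-independent. The enumeration guard
(z^(k−1) ≤ 4^13) keeps exhaustive runs in seconds; the acceptance-level
table (k ≤ 10, 262 144 walks at worst) regenerates in well under a second.

## Mean-field closures

* **LMF** (relaxation): occupations are spatially uncorrelated, x_j = x^j,
  so φ is a degree-n polynomial with the census weights.
* **CMF** (induction): multi-site correlations factorise through
  nearest-neighbour pairs, x_j = x₂^(j−1)/x^(j−2). Since x₂ ≤ x every term
  is bounded by x₂ (x₂/x)^(j−2); the x → 0 limit is defined as 0. Supplying
  x₂ = x² recovers LMF exactly, which is asserted in tests.

The pair state (q = P∘, u = P∘∘) obeys

    −d ln q/dt = 1 + p (q−u)/q,
    −(1/2) d ln u/dt = 1 + p (z−1)/z (q−u)/q,

using the pair-approximation closure P∘∘• ≈ P∘∘ P∘•/P∘ for the three-site
term. The combination (z−1)/z d ln q/dt − (1/2) d ln u/dt = 1/z is exact
for these equations and yields the invariant u = q^(2(z−1)/z) e^(−2t/z),
an analytic q(t) for z > 2, and a separate closed form for z = 2. The
numerical route integrates (ln q, ln u) with DOP853 at rtol 1e−11 /
atol 1e−13 (log-space integration keeps q → 0 benign) and is checked
against the closed form to 1e−8.

These pair equations describe single-hop closure. For n > 2 the package
keeps them unchanged and lets n act only inside φ (mode `printed`); an
alternative mode `consistent` rescales time so that dx/dt = k_I (1 − φ)
holds for the n-step yield, preserving the ratio structure of the pair
equations. Because both equations are rescaled by the same factor, the two
modes traverse the *same* (q, u) path — the x₂(x) relation and hence the
hysteresis loop φ_ind(x) are mode-independent; only the clock differs. For
n = 2 the printed dynamics is already self-consistent
(A = q + p(q−u) = 1 − φ), which is asserted numerically.

## Kinetics integration

`kinetics_from_phi` integrates dx/dt = k_I (1 − φ(x)) with DOP853 at
rtol 1e−10 / atol 1e−12; the separable quadrature t(x) = ∫ dx′/(1 − φ) is
retained as a cross-check, and the analytic n = 1, 2 solutions and the
implicit n = 3 relation (partial fractions of
1 − φ = (1 − x)(1 + px + ¾(px)²), principal arctan branch — validated only
against numerical integration) pin the accuracy at 1e−8/1e−6. Joliot
kinetics invert t = p x − (1 − p) ln(1 − x) by bracketed root finding in
w = −ln(1 − x), which is monotone and pole-free. The complementary area
C(t) = ∫ (1 − φ) dt′ is accumulated by trapezoid on the trace grid; the
exact identity x = k_I C is asserted with adaptive quadrature rather than
the trapezoid accumulator, whose discretisation error would dominate at
1e−8.

## Monte Carlo simulator

Replicated L×L torus lattices receive one photon per 1/(N k_I) of model
time at uniformly random sites; the walk kernel applies exactly the rules
above (the deterministic time increment is distribution-identical to
exponential waiting times for all recorded quantities at N ≫ 1 and is
cheaper). φ(t) is estimated as the across-replicate fraction of fluoresced
outcomes at each recorded photon index — unbiased with no windowing; its
error bar is the binomial standard error with a Jeffreys-style shrunk
proportion (r + ½)/(R + 1) so that checkpoints where every replicate
(doesn't) fluoresce keep a nonzero error bar. x and x₂ use across-replicate
standard errors. Snapshots are captured per replicate when the closed
fraction first reaches each requested density. Relaxation is modelled as a
quasi-static sweep: exact-count uncorrelated maps probed by non-perturbing
excitons, matching the assumption that dark reopening is uncorrelated;
an explicit exponential-reopening time course (rate k_rec) is provided by
the trace generator instead. All randomness flows from caller-supplied
numpy Generators; per-replicate kernel seeds are drawn below 2³¹ and runs
are bit-reproducible for a fixed master seed.

Default comparison sizes — L = 256 with R = 64 replicates for induction
against CMF, L = 200 with 200 replicates for percolation contrasts,
2 × 10⁴ probes per yield estimate — were chosen so that three standard
errors resolve the effects under study (bunching corrections of order
10⁻³–10⁻², yield gaps of order 10⁻²) while a full suite run stays at the
minute scale.

## Percolation analysis

Clusters of closed RCs are labeled with 4-connectivity (two-pass connected
-component labeling via scipy.ndimage behind the module surface; a
brute-force flood fill serves as the test oracle). Spanning is side-to-side
on open boundaries; a periodic labeling mode merges seam clusters for
structural statistics. Threshold estimation bisects the spanning
probability to 1/2. By default it uses spanning along a *single* axis: on a
square domain that probability tends to exactly 1/2 at the threshold, so
the crossing density converges with only weak finite-size bias
(≈ +8 × 10⁻⁴ at L = 128 in our runs); either-axis spanning crosses 1/2
systematically below threshold (≈ −5 × 10⁻³ at these sizes) and remains
available as an option. Per-size estimates at L ∈ {128, 256} are averaged;
the quoted uncertainty combines the binomial error propagated through the
local slope with the between-size spread. "Compact vs fractal" giant
clusters are operationalised purely comparatively (mass fraction, radius of
gyration, bounding-box fill) at equal density — no fractal dimension is
fitted.

## Trace layer and synthetic data

The generator emulates paired fluorescence/P⁺ kinetics of single-turnover
cells: induction from a chosen solver (CMF by default, k_I = 1000 s⁻¹ scale
→ millisecond rise), relaxation as x(t) = e^(−k_rec t) with k_rec = 1 s⁻¹
(the second-scale P⁺Q_B⁻ recombination) and the quasi-static LMF yield.
Raw signals add gain, a constant fluorescence baseline F₀, linear drift and
white Gaussian noise (σ = 0.01 of full scale by default). Deliberately not
emulated: detector nonlinearity, scattering corrections, flash sampling of
the relaxation probe, multi-exponential recombination, and correlated
baseline wander — so passing tests demonstrate the *pipeline's* behaviour
on idealised single-turnover kinetics, not instrument robustness.

Normalisation estimates F₀ as the t = 0 intercept of a least-squares line
over a caller-chosen initial window (the window is a required choice, first
10 points by default) and F_max as the final-decile plateau mean during
induction; relaxation mirrors the roles. This removes gain and offset
exactly in the noiseless limit (affine invariance is asserted to 1e−9);
recovering the *true* φ additionally depends on the window estimator's
curvature bias, which is why truth-recovery tests use traces with flat head
and tail segments or coarser tolerances. Time elimination interpolates φ
piecewise-linearly onto the P⁺ trace's grid over the overlap. The Joliot
fit minimises the direct residual of φ = (1−p)x/(1−px) over p ∈ [0, 1) by
bounded scalar search (xatol 1e−10); a double-reciprocal variant fits
1/φ against 1/x and converts the slope. Reciprocal diagnostics report
signed residual sequences and their sign changes; an exactly hyperbolic
process gives straight lines, finite-lifetime wandering gives patterned
curvature.

## Known limitations

* The CMF pair closure is approximate for n > 2; the `printed`/`consistent`
  mode choice brackets the ambiguity, and Monte Carlo comparisons quantify
  the (small) differences rather than resolving which is "correct".
* Nearest-neighbour hops on a regular Bravais lattice only — no
  Förster-kernel step lengths, disordered RC placement, or explicit
  LH1/LH2 substructure.
* The relative bunching weight x̃₂/x² is range-checked (4–25% for
  x ≤ 0.6 at p = 0.9, n = 2) rather than pinned, since both the natural
  denominator (x₂ vs x²) and the evaluation point are convention choices.
* Threshold estimation reports statistical uncertainty only; residual
  finite-size bias at L ≤ 256 is below that uncertainty for the default
  single-axis criterion but is not extrapolated away.
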