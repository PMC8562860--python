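# Methods

## The binding motif and its exact stationary law

The elementary reaction pair

```
A + B  -->  C    propensity (k_f/Ω)·A·B
C  -->  A + B    propensity k_b·C
```

conserves the totals `A_T = A + C` and `B_T = B + C`.  When binding and
unbinding are much faster than every other reaction touching A, B or C,
the conditional stationary law of the unbound count A given the totals is
the quantity a reduced model needs.  Writing `K_d = k_b·Ω/k_f` for the
dimensionless dissociation constant and `A_0 = max(0, A_T − B_T)` for the
lowest reachable state, the stationary chemical-master-equation solution
is

```
π(l) ∝ K_d^(l−A_0) / ( l! · (A_T−l)! · (B_T−A_T+l)! ),   l ∈ [A_0, A_T].
```

`stoqssa` evaluates these weights as log-gamma expressions and normalizes
with log-sum-exp, so the law, its mean ⟨A⟩ (the *stochastic QSSA*), its
variance, and the Fano factor `F_A = Var(A)/⟨A⟩` are finite and accurate
for totals beyond 10^6.  Factorials are never formed directly.

For scans over large totals, moments are computed on an adaptive window
around the mode (which coincides with the deterministic tQSSA value):
the window is grown until the boundary log-weights are 46 nats below the
maximum (≈1e−20 relative mass).  The law is log-concave, so this
truncation is safe; the full-support and windowed paths agree to 1e−12
relative in tests.

## Approximations

**stQSSA** (stochastic total QSSA).  The Morrison/tQSSA root

```
A_tq = ½[(A_T−B_T−K_d) + √((A_T−B_T−K_d)² + 4·A_T·K_d)]
```

evaluated on dimensionless copy numbers, with the companion values
`C_tq = A_T − A_tq` and `B_tq = B_T − C_tq`.  In the tight-binding branch
(`A_T − B_T − K_d < 0`) the root is computed as
`2·A_T·K_d / (√disc + (B_T+K_d−A_T))` to avoid subtracting nearly equal
numbers.  `A_tq ≥ ⟨A⟩` always; the relative error
`R_A = (A_tq − ⟨A⟩)/⟨A⟩` is bracketed by `F_A·S_A ≤ R_A ≤ 2·F_A·S_A`,
where the relative sensitivity is

```
S_A = 1 / √((A_T−B_T−K_d)² + 4·A_T·K_d),
```

peaking at `1/√(4·A_T·K_d)` when `B_T = A_T − K_d`.  Since the law is
sub-Poissonian (`F_A < 1`, verified numerically on broad grids), the
stQSSA fails only where `S_A` is large: near 1:1 molar ratio with tight
binding, and its worst-case error falls below 10% once `A_T·K_d` exceeds
roughly 10 (the measured 0.1 contour of the exact error sits at
`A_T·K_d ≈ 12.5`).

**slQSSA** (stochastic low-state QSSA).  The mean of the law truncated to
the k lowest reachable states `[A_0, A_0+k−1]`.  It converges to the
exact mean as k grows (exactly so once the truncation covers the
support) and is accurate precisely where the stQSSA fails: the measured
worst-case error of the 2-state form is below 10% for `A_T·K_d < 0.1`,
and of the 5-state form for `A_T·K_d < 10`.

**sQSSA**.  The Michaelis–Menten-type complex value
`C_sq = A_T·B/(B+K_d)`, valid only when `B_T + K_d ≫ A_T`.

## Certified switching policies

`find_policy(K_d, ε, L_max)` certifies a total-copy-number threshold:
totals at or above it use the stQSSA, totals below use the L-state
slQSSA, both with worst-case relative error ≤ ε over a partner scan.
Because the exact error is not provably monotone in the total,
certification is by exhaustive evaluation on a log-dense integer grid
(every integer up to 256, then ≥ 40 points per decade), with the partner
scanned on a log grid over `[0, 4·total]` plus a dense integer window
around `B_T = total − K_d` where `S_A` peaks.  Above the analytic
ceiling `1/(K_d·ε²)` no scan is needed: `R_A ≤ 2·S_A ≤ 1/√(A_T·K_d) ≤ ε`
there.  L is searched ascending, so the cheapest certified truncation
wins; totals exactly at the threshold use the stQSSA (half-open
convention).  Policies serialize to JSON, including the scan grid.

## Simulation engine

The engine is the plain Gillespie direct method: per event one
exponential waiting time and one categorical choice, no tau-leaping.
Randomness comes from a seeded `numpy.random.Generator` (PCG64); uniform
draws are taken in fixed-size blocks purely to amortize call overhead,
which leaves the stream unchanged, so a (network, t_end, seed,
recording) tuple reproduces a path bit-for-bit.  Propensities are
mass-action factors (falling factorials for consumed reactants, plain
powers for catalytic modifiers, bimolecular rates carrying 1/Ω) times an
optional QSSA factor.  QSSA factors are re-evaluated from the current
slow totals at every refresh and cached per totals tuple; only reactions
whose inputs changed are refreshed after an event (a static dependency
graph).  Recording is fixed-grid by default (memory-bounded for stiff
full models) with event-driven recording for small runs.  Declared
conserved totals are validated against every reaction's stoichiometry at
construction.

## Case-study models and placeholder rates

Three small systems exercise the framework in the regimes where the
stQSSA fails.  The dissociation constants, totals, and the isolated
motif's absolute rates (k_f/Ω = 1e4 s⁻¹, k_b = 1 s⁻¹) are the published
regime values; the remaining slow rates are package defaults chosen so
each system shows its qualitative behavior at desk-scale simulation cost
(minutes, one CPU).  They are flagged `placeholder_rates=True` in every
model's metadata and should not be read as the original systems'
kinetics.

* **Gene network** (D_T = P_T = 10, K_d = 1e−2 tight regime): repressed
  transcript M_R reads unbound DNA, activated transcript M_A reads the
  complex; α_R = α_A = 1, δ = 1, k_b = 25.  The stQSSA-reduced model
  overproduces M_R roughly threefold while M_A is reproduced faithfully.
* **Sequestration oscillator** (A_T = 5, K_d = 1e−4): activator-driven
  transcription (α_M = 100 per free A), M decay δ_M = 1, translation
  α_P = 0.05, three maturation steps β = 1, free-repressor decay
  δ_R = 3, complex decay δ_C = 0.02, k_b = 400.  Free-R-dominant decay
  makes the descent of R_T linger at the 1:1 point, where the reduced
  model's propensities (transcription from free A, decay from free R)
  are exactly the quantities the stQSSA overestimates ~45-fold; the
  stQSSA-reduced clock therefore runs measurably fast, while the 5-state
  slQSSA reduction tracks the full model.  k_b = 400 keeps the full
  model's finite-timescale-separation bias small against that effect.
* **Bistable switch** (B_T = 6, total cyclin pool C_T = 20,
  K_d = 1e−3): basal activation k_0 = 0.24, free-M-mediated positive
  feedback k_1 = 1.0 (the Cdc25 loop collapsed to its equilibrated
  linear form), common inactivation δ = 2, k_b = 50.  M_T is bimodal
  with modes separated by M_T = B_T; the stQSSA's overestimate of free M
  at the separatrix biases occupancy toward the upper mode, which the
  slQSSA reduction removes.

What the synthetic systems do **not** emulate: realistic absolute
timescales (a real transcription-factor residence is sub-second against
~hours of protein turnover; here the separation is 2–3 decades, the
smallest that keeps full-model paths affordable), extrinsic noise,
multi-site or cooperative binding, and cell growth/division.  Passing
tests therefore demonstrate the reduction machinery and the direction of
its failure modes, not quantitative kinetics of the original biological
systems.

## Statistical checks and their sizes

Directional figure-level claims are tested with one-sided
Mann–Whitney rank tests on per-cycle periods (oscillator) and per-path
upper-mode occupancies (bistable switch), at fixed seeds:

* oscillator: 8 full-model paths of 250 time units and 10 reduced paths
  of 300 units (~100–200 cycles per arm); peaks of M after a 2-unit
  moving average, prominence 20 counts, minimum separation 4 units;
* bistable switch: 192 paths of 200 units per arm started in the
  inactive state, time-weighted occupancy above M_T = B_T after a 20%
  burn-in (a matched window that includes the approach to
  stationarity — mode switching is slow enough that per-path occupancy
  carries only a few independent dwells, so power comes from the path
  count); "matches within Monte-Carlo error" means within 3 pooled
  standard errors.

The SSA-vs-exact-mean agreement uses a single long motif path and a
conservative effective-sample-size estimate (one independent sample per
unbinding time).  These sizes were chosen as the smallest that kept the
seeded outcomes stable across independent seed batches during
development.

## Numerical conventions and degenerate inputs

* Totals must be non-negative integers for the exact law and slQSSA
  (near-integer floats are rounded at tolerance 1e−9); the
  stQSSA/tQSSA accepts reals.
* `K_d` must be positive and finite; `B_T = 0` gives a point mass at
  `A_T`; `A_T = 0` gives a point mass at 0, where the Fano factor and
  relative error are reported as undefined (`UndefinedValueError`)
  rather than infinite.
* Histogram burn-in defaults to the first 20% of the horizon; period
  defaults (25% IQR prominence, half the dominant autocorrelation lag as
  separation) suit smooth oscillations and are exposed because pulse
  trains with variable amplitudes need explicit values.
* Exit codes of the CLI: 0 success, 2 usage, 3 numerical/certification
  failure.

## Known limitations

* Error certification is grid-based; between grid totals the ε guarantee
  is an interpolation, not a proof (the grid is recorded in the policy).
* The engine recomputes propensities per event in Python; it is
  comfortable up to ~10^7 events per run but is not a performance-tuned
  SSA (no next-reaction method, no tau-leaping by design).
* One policy governs one binding pair; networks with several rapid pairs
  need one policy each, and joint fast-pair interactions are out of
  scope.
* The sub-Poissonian property is verified numerically on grids, not
  proven symbolically.
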