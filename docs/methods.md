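# Methods

## Model and discretization

The state is the probability density `n(s, t)` over elapsed time `s`
since last discharge, on a uniform grid of cells `[i·ds, (i+1)·ds)`
truncated at `s_max`.  Cell values are cell-average densities;
coefficients are evaluated at the left nodes `s_i = i·ds`, so a point
map `ψ` that lands on a node is represented exactly.  The time step
always equals the cell width (`dt = ds`): unit-speed aging is then an
exact one-cell shift, which is the backbone of the scheme's exact
conservation.

One step applies, in order:

1. **Activity.** `N` is evaluated on the pre-step density (see below).
2. **Discharge.** Cell `i` loses the exact exponential fraction
   `1 − exp(−p(s_i, N)·dt)` of its mass.  This is unconditionally
   positive and free of CFL restrictions.
3. **Redistribution.** The removed mass is routed through a
   column-stochastic, lower-triangular matrix built from the kernel.
   For point maps `K = δ(s − ψ(u))`, the mass of discharge node `u_j`
   is split between the two nodes bracketing `ψ(u_j)` with weights that
   preserve the first moment exactly, so the discrete kernel inherits
   the continuum moment bound `∫ s K(s,u) ds ≤ θ u`.  Columns are
   renormalized to 1 exactly, making conservation a matter of algebra,
   not accuracy.
4. **Transport.** Exact right shift with zero inflow at `s = 0`.

**Tail handling.** The default is a *reflecting tail*: mass reaching
the last cell keeps discharging at the ceiling rate `p_M` instead of
leaving the domain.  Beyond the largest threshold the density decays
like `exp(−p_M s)`, so with the default `s_max = 4σ_max + 10/p_M` the
buffered mass is `O(e^{−10})`; total mass is then conserved to machine
precision (the test suite asserts `< 1e−10` over 10⁴ steps; the
observed drift is `~1e−15`).  The stationary eigensolver instead uses
an outflow tail, which is what its boundary identity requires.

## The activity equation and root selection

The total activity solves the implicit equation `N = ∫ p(s, N) n ds`.
With the threshold rate families the response
`R(N) = ∫ p(s, N) n ds` is non-decreasing in `N`, `R(0) ≥ 0` and
`R(p_M) ≤ p_M`, so a root always exists, but in the strongly coupled
regime several roots coexist (hysteresis) and a selection rule is part
of the scheme.  Three rules are provided:

* **lagged** (default): `N_k = R(N_{k−1})` — one Picard step per time
  step, i.e. the threshold is evaluated with the previous activity.
  This resolves the ambiguity causally and follows the algorithmic
  lineage of elapsed-time neuron models.  The run is seeded at `t = 0`
  by the implicit solve below.
* **continuation**: solve the implicit equation by scanning
  `G(N) = R(N) − N` on `[0, p_M]` and bisecting every downward sign
  change (bisection is robust across the jump discontinuities of step
  rates); among the roots, return the one nearest the previous `N`.
* **largest**: as above, returning the largest root.

The rules agree wherever the root is unique (asserted in the tests).
The lagged rule is the default because it reproduces the reference
phenomenology best across the study configurations: convergence for
`α = 2` with `ψ(u) = u/2`; clean periodic orbits (period 8.0, peak
spacing CV below 10⁻³) whose shape depends on the initial data for
`α = 4` with full reset; and a unique periodic orbit (identical for
both built-in initial profiles, sup-discrepancy at the phase-aligned
optimum below 10⁻⁴) for `α = 3` with `ψ(u) = u/2`.  Under the implicit
rules the third regime degrades (continuation turns it aperiodic and
initial-data dependent; largest collapses it to a near-constant
ripple).

**Known limitation.** For `α = 4` with `ψ(u) = u/2` this discretization
produces a *sustained aperiodic* oscillation (peak-spacing coefficient
of variation ≈ 0.22–0.27, stable under `ds ∈ {0.005, 0.01, 0.02}`,
horizons up to `T = 1500`, and all three root rules), and the two
built-in initial profiles do not land on pointwise-identical orbits.
The synchronization-versus-convergence dichotomy is still reproduced —
the activity does not converge and oscillates across the full band —
but the uniqueness of the orbit at this parameter point is not.  The
regime tests therefore assert orbit identity at `α = 3` and assert the
`α = 4` case at regime level only.

## Stationary states

The linear stationary problem is regularized on `[0, R]` with the
boundary feedback `A(0) = ε ∫ A` and solved as the principal eigenpair
of the positive one-step operator (discharge + redistribution + shift
with outflow, boundary cell set to `ε·mass`) by normalized power
iteration.  The discrete mass balance of that operator gives

```
λ = (growth − 1)/dt = ε − Ã(R)
```

*exactly*, where `Ã(R)` is the pre-transport boundary trace stored in
the result; the continuum identity and the bracket `ε − 2/R ≤ λ ≤ ε`
follow.  Iteration stops when successive eigenvalue iterates differ by
less than `1e−10` and the profile is L¹-stationary to `1e−11`; the
returned residual is the L¹ defect of the one-step operator per unit
time.

The physical profile is extracted by running `ε ∈ {1e−2, 1e−4, 1e−6}`
at fixed `R = max(4σ_max, 20/p_M)` with warm starts, reporting the L¹
distance between the last two profiles as a convergence indicator.
Cell 0 carries the boundary value `ε` by construction; for kernels with
an atom at `s = 0` the limit profile is discontinuous there, so oracle
comparisons (e.g. against `e^{−s}` for `p ≡ 1`, full reset) exclude the
boundary cell.  Observed sup-norm accuracy is first order in `ds`
(0.0195 / 0.0099 / 0.0050 at `ds = 0.04 / 0.02 / 0.01`).

The coupled stationary activity `A*` is the root of `F(N) − N` on
`[0, p_M]`, where each `F(N)` evaluation freezes the rate at `N` and
extracts the stationary profile.  The frozen rate enters as *cell
averages* rather than node samples: for indicator rates this makes the
discrete operator — and hence `F` — continuous in `N`, which is what
lets bisection reach `|F(A*) − A*| < 1e−8`; node sampling would leave
`F` with `O(p_M·ds·A(σ))` jumps.  All sign-change brackets found on the
coarse scan are reported (uniqueness is not asserted); rates that do
not depend on `N` short-circuit to a single evaluation.

## Dual weight and decay certificates

The dual weight `P` solves a Volterra-type integro-differential
equation whose memory term only involves `P` on `[0, s]`; it is
integrated by a forward march with an exponential integrator (exact
when the memory vanishes, e.g. constant rate with full reset, where
`P = e^{(λ+p_M)s}` is recovered to ~1e−13).  For point-map kernels the
measure part of the memory integral evaluates `P(ψ(s))` by linear
interpolation — exact treatment of the atom, no smoothing parameter.
Sharp step rates contribute a point mass to `|p*'|` at `σ*`, handled as
a discrete downward jump of `P` at the crossing cell.

The certified eigenvalue scan tries `λ_k = −(p_M/4)·2^{−k}`,
`k = 20 … 0`, from the closest to zero downward, accepting a candidate
when its weight stays positive and is nondecreasing beyond `σ*`
(monotonicity tolerance `1e−10` per cell, overflow cap `1e12`); the
deepest admissible candidate wins.  A failed smallness condition
(`B* ≥ 1`) and an exhausted scan are reported as distinct reasons.

`B*` is computed by trapezoidal quadrature of the frozen rate on
`[0, σ*]`, with the total-variation term including the terminal jump of
step rates — for the oscillatory study rates this gives
`B* = σ*·p_M ≥ 1`, correctly flagging them as outside the
weak-coupling hypotheses.  The exponential-moment witness is searched
on a logarithmic grid of 200 values `μ ∈ [1e−4, 10]` (first witness
wins); the direct-decay rate `ν` is the grid infimum of
`p·ψ̲' − |p'|·ψ̲` with `ψ̲(u) = u − ψ(u)`, defined only for point maps
with differentiable rates.

**Measured realization.** In the weakly coupled study configuration
(ramp rate, constant `σ = 0.3`, width 0.2, `ψ(u) = u/2`; `B* ≈ 0.387`)
the certified eigenvalue is `λ = −0.25` and the simulator's weighted
norm `ds·Σ P|M|` decays at an empirical rate 0.268 (log-linear fit,
r² = 0.999) — at least the certified rate, as the theory demands.  The
fit window ends before the functional reaches its floor: the weighted
norm bottoms out at the `O(ds)` mismatch between the eigensolver's
profile and the simulator's invariant density (amplified by the
exponentially growing weight), around `4e−3` at `ds = 0.01`.

## Diagnostics

`M(s, t) = ∫₀ˢ (n − A)` is the running discrete integral (`cumsum·ds`);
its time derivative `J` uses centered differences in the interior and
one-sided ones at the ends (exact on parabolas in the interior).  Decay
rates are least-squares slopes of `log(functional)` over a window,
dropping values below the double-precision floor `1e−13` (the report
says when that shrinks the window).

Regime classification looks at the last half of `N(t)`: *converged*
when the peak-to-peak amplitude is below `1e−3` of the late mean (the
tolerance is a config knob; no figure-level numeric exists to calibrate
it against), *periodic* when at least three peaks above the midpoint of
late mean and late max occur with spacing coefficient-of-variation
under 5%, *irregular* otherwise.  Peak spacing is used rather than
spectral estimators because the threshold dynamics produces short,
strongly non-sinusoidal waveforms.

## Synthetic initial data

Two generators, both renormalized to discrete mass 1 exactly:
`exp_decay` (the memoryless profile `e^{−s}`, the canonical
desynchronized start) and `multi_bump` — a sum of Gaussian bumps
(defaults: centers 1 and 3, width 0.2, equal weights) standing in for
structured "complex" initial conditions that seed synchronization.
The defaults put both bumps inside the refractory zone of every study
threshold, which is what makes the full-reset orbit comparison
informative.  What the generators do **not** emulate: finite-population
noise, heterogeneous thresholds, or spatial structure — passing the
regime tests says nothing about those effects.

## Problem sizes and determinism

Default production resolution is `ds = dt = 0.01`
(2600–4200 cells for the study thresholds); convergence studies use
`ds = 0.04 / 0.02`.  The tests and the acceptance script run the study
horizons `T = 50–200`.  There is no randomness anywhere in the library;
runs are bit-reproducible from a configuration, and the only seeded
randomness in the repository is the sampling used by property tests and
the acceptance script's ordering check.
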