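# Methods

## Model and assumptions

The package models an isogenic, self-replicating population whose
individuals carry a binary phenotype in a binary, randomly switching
environment.  Three assumptions define the scope:

1. **Memoryless environment.**  `x(t)` is a telegraph process with
   constant rates `λ12, λ21 ≥ 0` (not both zero): exponential dwell
   times, stationary occupancy `P(x_i) = λ_ji/(λ_ij + λ_ji)`.
   Non-exponential dwell times, more than two states and time-varying
   rates are out of scope.
2. **Deterministic fractions.**  Demographic noise in population growth
   is neglected, so the phenotype composition is a single deterministic
   fraction `f_{y1}(t)` driven by switching and selection.  Absolute
   population size, extinction and stochastic fixation are not modeled.
3. **Fittest labeling.**  Phenotype `y_i` is the fastest grower in
   environment `x_i` (`g(y_i|x_i) ≥ g(y_j|x_i)`).  The convention fixes
   the sign of the normalized fitness; a violating matrix is accepted
   with a warning because relabeling `1↔2` restores it.

Within an epoch of fixed environment the fraction obeys the scalar
Riccati equation

```
f' = A f² + B f + C,
A = −Δg,  B = Δg − k12 − k21,  C = k21,
Δg  = g(y1|x_i) − g(y2|x_i),
k12 = k(y1→y2|x_i),  k21 = k(y2→y1|x_i),
```

and `f` is continuous across switches (a switch changes rates, not the
standing composition).

## Parameters

| parameter | meaning | units | default / preset |
|---|---|---|---|
| `λ12, λ21` | environment switching rates | 1/time | preset-specific |
| `g(y_j\|x_i)` | growth (possibly negative) of phenotype j in environment i | 1/time | — |
| `k(y_j→y_k\|x_i)` | phenotype switching rates | 1/time | — |
| `μ, ρ` | symmetric preset: fit / unfit growth, `μ > ρ` | 1/time | 4, 1 (fixing `μ−ρ = 3`) |
| `ka, kb` | symmetric preset: switching away from / toward the fit phenotype, `kb ≥ ka` | 1/time | regime-specific |
| `μ1, μ2` | dormancy preset: death rate under stress, growth rate in the benign state | 1/time | `μ2 = 1` |
| `k` | dormancy preset: all four switching rates | 1/time | 0.01 |
| `f0` | initial fraction in `y1` | — | 0.5 |
| `n_transitions` | trajectory length in environmental transitions | count | 1e5 |
| `burn_in_fraction` | initial time fraction discarded before averaging | — | 0.01 |
| `output_resolution` | interior samples per epoch (both endpoints always included) | count | 50 library / 30 sweeps |

Time units are arbitrary ("per unit time"); only rate ratios matter.
The dormancy preset pins the stationary stress probability by setting
`λ12 = λ21 (1 − P_x1)/P_x1`.

Labeling note: in the dormancy preset `x1` is the stressful environment
and `y1` the dormant phenotype (growth 0 in both environments), so the
growth matrix is `[[0, −μ1], [0, μ2]]`.  All reported quantities are
invariant under the simultaneous relabeling of environments and
phenotypes, so the opposite convention yields identical results.

## Numerical choices

**Per-epoch propagation is exact.**  Because the Riccati coefficients are
constant within an epoch, the flow map has a closed form: with distinct
real roots `r_s` (stable) and `r_o` of `A f² + B f + C` and
`s = A(r_s − r_o) < 0`,

```
f(t) = r_o + (r_s − r_o) / (1 − w0 e^{st}),   w0 = (f0 − r_s)/(f0 − r_o),
```

with separate linear (`A = 0`) and double-root branches.  With nonzero
switching in both directions the discriminant is strictly positive and
exactly one root lies in `[0, 1]`, so the generic branch covers the unit
interval; the decaying exponential makes the formula overflow-free.  An
adaptive Runge–Kutta route (`method="rk45"`, scipy `solve_ivp`, rtol
1e-8 / atol 1e-10, hard restarts at epoch boundaries) is retained as an
independent cross-check; the test suite verifies agreement at 5e-8.  The
analytic route costs microseconds per epoch and makes 150-point sweeps at
1e5 transitions per point feasible on one CPU.

**Exact epoch means for time averages.**  The closed-form solution also
integrates in closed form,

```
(1/τ)∫₀^τ f dt = r_s − (r_s − r_o)/(sτ) · log1p(−w0·expm1(sτ)/(1 − w0)),
```

so analytic trajectories carry exact per-epoch time averages of `f`.
The joint-law estimator prefers these; for numerically integrated or
hand-built trajectories it falls back to the trapezoid rule on the
per-epoch uniform grid.  The fallback carries an O((τ/m)²) bias from the
within-epoch exponential relaxation (~1e-3 at default resolution), which
is why the exact route is the default: the single-individual oracle
comparison resolves deviations below that level.  Epoch boundaries are
always integration breakpoints — the environment indicator is never
interpolated across a switch.

**Clamping.**  Floating-point overshoot can push `f` marginally outside
`[0, 1]` near absorbing-like boundaries (dormancy with small `k`); values
are clamped and excursions beyond 1e-9 raise a warning.

**Burn-in.**  Estimators discard whole epochs starting within the first
1% of total time, removing the transient from the arbitrary `f0 = 0.5`.
A sensitivity test shows doubling the burn-in moves estimates by far less
than Monte-Carlo noise at the default trajectory length.

**Zero-probability logs.**  `0·log 0 ≡ 0` throughout; entries below
1e-15 are treated as exact zeros before log evaluation.  The marginal
information value returns `+inf` at the independence corner (where
`dI/dp = 0`) and `0` on the upper Fréchet boundary (where `dI/dp`
diverges); both endpoints are singular limits of the interior chain rule
`dΓ/dI = [1/(P_x1(1−P_x1))] / log2[(P11 P22)/(P12 P21)]`.

**Fixed-point tie-break.**  With both switching rates zero (pure
selection) the fraction dynamics has two boundary fixed points; the
selection-stable one is returned.  All-zero dynamics (every `f` steady)
raise an error.

**Maximal information.**  `I_max(P_x1, P_y1)` is computed operationally
as the mutual information of the joint law at the upper Fréchet boundary
`P11 = min(P_x1, P_y1)` — the configuration that also attains `Γ_max` —
rather than from a two-branch closed form; the legible closed-form branch
is cross-checked symbolically in the tests.  When the marginals match it
equals the environment entropy, the channel ceiling.

## Study conditions emulated by the generators

The synthetic pipelines reproduce four canonical computational
experiments:

- **Symmetric regimes** — slow (`λ = 0.1`) and fast (`λ = 10`)
  environments with responsive switching `ka = 0.1, kb = 1.2`, an
  intermediate responsive point, and a non-responsive point
  `ka = kb = 0.5`, all with relative growth rate `μ − ρ = 3`.  The
  intermediate point uses `λ = 1`, chosen once as a mid-timescale
  representative (the regime is specified only as "sufficiently slow").
  Simulated `(I, Γ)` pairs collapse onto the analytic master curve
  `Γ_sym = 4p − 1`, `I_sym = 1 + (1−2p)log2(1−2p) + 2p log2(2p)`
  regardless of the individual rates.
- **Feasible region** — purely analytic traces of `(Γ, I)` over the
  corner probability at fixed marginals, with the bounds `Γ_max`, `I_max`
  peaking at matched marginals.
- **Marginal value profile** — the closed-form `dΓ/dI` against `I`,
  grid-free.
- **Dormancy sweep** — `μ2 = 1`, `k = 0.01`, `λ21 = 0.5`, stress
  probability `P_x1 ∈ {0.1, …, 0.5}`, sweeping the kill rate `μ1` over 30
  log-spaced values in `[0.01, 100]·μ2`.  The upper end of the grid was
  set so that the interior maximum of `Γ` is bracketed even at
  `P_x1 = 0.1`, where dormancy only pays at large kill rates.  The sweep
  exhibits: dormant fraction and information rising monotonically with
  `μ1`; `⟨γ⟩ ≥ ⟨γ⟩_ind` throughout; and `Γ` peaking in the interior.
  Empirically the peak sits where the dormant fraction crosses one half —
  for the balanced environment this is also where `P_y1 = P_x1`.

Default sweeps use 1e5 environmental transitions (desk scale; assertions
scale tolerances as `1/√n_transitions`); longer trajectories are a config
field away.  Per-point seeds derive as `seed + point_index` so identical
sweep specifications give bit-identical tables.

## What passing tests do and do not show

The generator produces exactly the model's own world: memoryless binary
environments, instantaneous rate switches, noiseless deterministic
fractions.  Passing tests therefore validate the mathematics and the
estimators, not the biological fidelity of any particular system.  Real
populations have finite size (demographic noise, extinction), more than
two phenotypes, environments with memory, and switching machinery whose
responsiveness itself carries a fitness cost — none of which are modeled.
The information–fitness equivalence quantified here is exact only at
fixed marginals; the dormancy sweep illustrates how freely moving
marginals decouple `Γ` from `I`.

## Known limitations

- Two states per axis only; the channel carries at most 1 bit.
- No inferential error bars on estimated probabilities; Monte-Carlo
  uncertainty is handled by tolerance scaling in tests.
- The trapezoid fallback (numerical trajectories) biases time averages at
  O(resolution⁻²); use the analytic route for quantitative work.
- Costs of acquiring information (e.g. growth penalties of sensing) are
  outside the model; the marginal information value prices the benefit
  side only.
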