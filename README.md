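# bethedge

Simulation and information–fitness analytics for **two-state bet-hedging
populations in fluctuating environments**.

Isogenic populations often maintain several phenotypes even when only one
of them is fit for the current conditions — bacterial persisters under
antibiotics, dormant algae in dry spells, drug-tolerant cancer subclones.
This *bet-hedging* pays off because the environment fluctuates: when
conditions flip, a pre-existing minority phenotype survives and regrows the
population. `bethedge` provides a complete, seeded pipeline to quantify
how much a population's phenotype composition "knows" about the
environment, in bits, and exactly how much fitness that knowledge buys.

## Model

The environment `x(t)` is a two-state telegraph process: states `x1, x2`
with constant switching rates `λ12, λ21`, so dwell times are exponential
and the stationary occupancy is `P(x_i) = λ_ji / (λ_ij + λ_ji)`.
Individuals carry a two-state phenotype `y ∈ {y1, y2}`; phenotype `y_j`
grows at rate `g(y_j|x_i)` in environment `x_i` and switches at rate
`k(y_j→y_k|x_i)`.  Neglecting demographic noise, the fraction
`f = f_{y1}` of the population in phenotype `y1` obeys, within each
environment epoch, the scalar Riccati equation

```
df/dt = k(y2→y1|xi)(1−f) − k(y1→y2|xi) f + [g(y1|xi) − g(y2|xi)] f(1−f)
```

with `f` continuous across environment switches.  Time-averaging the
trajectory gives a genuine joint probability law
`P(x_i, y_j) = lim (1/T) ∫ f_{y_j}(t) 1_{x_i}(x(t)) dt`, from which the
package computes:

- **mutual information** `I = Σ_ij P_ij log2[P_ij/(P_i· P_·j)]` (bits),
- **mean fitness** `⟨γ⟩ = Σ_ij g(y_j|x_i) P_ij` and its decorrelated
  reference `⟨γ⟩_ind` (same marginals, independent phenotype),
- **normalized fitness** `Γ = (⟨γ⟩ − ⟨γ⟩_ind)/(⟨γ⟩_max − ⟨γ⟩_ind)`,
  which reduces to the growth-rate-free form
  `Γ = (P11 − P_x1 P_y1)/(P_x1(1 − P_x1))`,
- the closed-form bounds `Γ_max`, `I_max` at fixed marginals, and the
  **marginal information value** `dΓ/dI` — the fitness gained per extra
  bit, which diverges at `I = 0` and decays monotonically.

Two named presets cover the classic scenarios: a fully **symmetric**
bet-hedging model (fit growth `μ`, unfit growth `ρ`, responsive switching
`ka`/`kb`), whose `(I, Γ)` points collapse onto a single analytic master
curve, and a **dormant–proliferating** model (dormant phenotype with zero
growth; proliferating phenotype growing at `μ2` in the benign state and
dying at `μ1` under stress) where the marginals move and the master-curve
collapse breaks down.

## Worked example

A slow symmetric environment with responsive switching — the regime where
bet-hedging shines:

```python
from bethedge import (make_symmetric_model, sample_environment, integrate_fractions,
                      estimate_joint_distribution, compute_metrics)

config = make_symmetric_model(mu=4.0, rho=1.0, ka=0.1, kb=1.2, lam=0.1)
env = sample_environment(config.env_rates, n_transitions=100_000, seed=1)
frac = integrate_fractions(env, config, f0=0.5)
joint = estimate_joint_distribution(env, frac)
report = compute_metrics(joint, config)
```

which prints (via the obvious f-strings):

```
P(x1,y1) = 0.4676   P(x1) = 0.4973   P(y1) = 0.4974
mean fitness        <g>     = 3.8213 per unit time
independent fitness <g>_ind = 2.5000 per unit time
normalized fitness  Gamma   = 0.8808
mutual information  I       = 0.6742 bits (H(x) = 1.0000)
bounds: Gamma_max = 0.9997, I_max = 0.9983 bits
```

Read: the population spends ~47% of the time in the matched
(environment 1, fit phenotype 1) cell versus 25% for an oblivious
population, so its composition carries 0.67 bits about the environment
and grows at 3.82 per unit time instead of the oblivious 2.50 — 88% of
the maximum possible improvement.  The point `(I, Γ) = (0.674, 0.881)`
lies on the symmetric master curve `Γ_sym(I)` to within ~1e-5.

The same pipeline is scriptable from a shell:

```sh
bethedge simulate --config model.json --transitions 100000 --seed 1 --out run
bethedge sweep-symmetric --out symmetric.csv
bethedge sweep-region --px1 0.4 --out region.csv
bethedge sweep-marginal-value --px1 0.5 --out value.csv
bethedge sweep-dormancy --px1-list 0.1,0.3,0.5 --out dormancy.csv
```

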