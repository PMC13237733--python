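# synkin

Seeded amyloid aggregation kinetics with fragmentation cycles:
simulation, curve fitting, and fibril-length statistics for
α-synuclein ThT assays.

## What problem this addresses

In strongly seeded aggregation assays, α-synuclein monomer adds to the
ends of preformed fibrils (PFFs) and the thioflavin-T (ThT) fluorescence
rises as a single exponential to a plateau set by the monomer solubility.
A *fragmentation-cycle* experiment extends this design: once a reaction
plateaus, the sample is ultrasonicated — fibrils shorten, some fibril
mass transiently disassembles to monomer, and the reaction regrows — and
the cycle is repeated (aggregation rounds A1–A4 with sonications S1–S3).
Three read-outs characterise each round: the plate-reader ThT kinetics,
the residual monomer in the supernatant (A280), and per-fibril
length/height tables from AFM.

`synkin` is a library for scientists running or modelling such assays.
It provides

- a deterministic moment-equation simulator of the full schedule,
  including instantaneous sonication events (fragmentation, partial
  disassembly, polymorph conversion) and a two-polymorph ThT
  brightness model;
- a stochastic, length-explicit population simulator (integer monomer
  bookkeeping, Gillespie kernel with tau-leaping) that produces
  realistic AFM length samples;
- the measurement-to-parameter estimation chain;
- Weibull analysis of length distributions and Gaussian-mixture height
  summaries;
- the usual significance tests (one/two-way ANOVA, Tukey HSD, Pearson);
- a synthetic-data generator that emulates complete experiments for all
  five variants (WT, H50Q, A30P, E46K, A53T).

## The model

Elongation-dominated growth with monomer `m`, fibril mass `M`, and
fibril number concentration `P`:

    dm/dt = −n_ends · k₊ · P · (m − m_eq),      M = c_tot − m

so `m(t) = m_eq + (m₀ − m_eq)·e^(−t/τ)` with `τ = 1/(n_ends·k₊·P)`.
Optional secondary-nucleation (`k₂ mⁿ² M`) and quiescent-fragmentation
terms extend `dP/dt`. The estimation chain inverts this model from
measurements:

1. fit `F(t) = F_∞ − (F_∞ − F₀)e^(−(t−t₀)/τ)` to each ThT growth phase;
2. residual monomer from Beer–Lambert, `c = A280/(ε·l)` with
   ε₂₈₀ = 5960 M⁻¹cm⁻¹; yield = (c_tot − c)/c_tot;
3. `P = (fibril mass)/(mean length · ρ)` with ρ ≈ 4.26 monomers/nm
   (two protofilaments, 0.47 nm cross-β rise);
4. `k₊ = 1/(n_ends·τ·P)` and elongation speed
   `v = n_ends·k₊·(m₀ − m_eq)/ρ` in nm/min.

Fibril lengths follow a Weibull distribution
`f(L) = (κ/λ)(L/λ)^(κ−1)·exp(−(L/λ)^κ)`; κ ≈ 1 indicates random
growth/scission, κ > 1 length-dependent breakage. Fitting is by profile
maximum likelihood with a seeded bootstrap CI for κ.

## Worked example

```
$ python examples/02_estimate_rate_constant.py
exponential fit: tau = 4.720 h, R² = 1.0000
A280 = 0.0626 → residual monomer 10.50 μM → yield 80.0%
P = 1.410e-08 M (mean length 700 nm)
k+ = 2087 M⁻¹s⁻¹ (fixture truth 2087)
elongation speed at start of phase = 2.47 nm/min
```

A noiseless wild-type first aggregation phase (50 μM monomer, 2.5 μM ≈5%
seeds) is simulated and pushed through the full estimation chain: the
fitted time constant (4.72 h), the 80% fibril yield from the supernatant
absorbance, and the 700 nm mean length combine to recover the elongation
rate constant of 2087 M⁻¹s⁻¹ the trajectory was generated with, plus a
per-fibril growth speed of ~2.5 nm/min at the start-of-phase monomer
level.

```
$ python examples/01_simulate_fragmentation_cycles.py
 variant  end ThT (son.)  end ThT (ctl.)   gain %  fibril mass μM
      WT           42.00           42.00      0.0           42.00
    ...
    A53T          331.80          210.00     58.0           26.25
```

Full-schedule simulations reproduce the variant-specific end-point ThT
gains of the sonicated samples over their continuously aggregated
controls (0/0/34/55/58% for WT/H50Q/A30P/E46K/A53T) at constant fibril
mass — the polymorph-conversion signature.

Other examples cover the synthetic plate + pipeline round trip (`03`),
stochastic sonicate→regrow cycles with rising Weibull κ (`04`), length
distribution fits per phase (`05`), and the group statistics (`06`).
A thin CLI mirrors these capabilities (`synkin generate|simulate|fit|
estimate|weibull|stats|report`).

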