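# Methods

## Moment-equation model of seeded aggregation

The deterministic simulator (`synkin.kinetics`) tracks free monomer
`m` (μM), fibril mass per polymorph `M_A`, `M_B` (μM), and fibril number
concentration `P` over a schedule of aggregation phases separated by
instantaneous sonication events. Within a phase

    dm/dt = −n_ends·k₊·P·(m − m_eq) − k₂·mⁿ²·M
    dP/dt =  k₂·mⁿ²·M + k_frag·M
    dM/dt = −dm/dt

with `M = M_A + M_B`. `k₊` (M⁻¹s⁻¹) is the elongation rate constant,
`m_eq` (μM) the solubility (equilibrium monomer level), `n_ends ∈ {1,2}`
the number of growth-competent ends, and `k₂`/`n₂`/`k_frag` optional
secondary-nucleation and quiescent-fragmentation extensions (defaults 0:
strongly seeded reactions are elongation-dominated, visible in their
concave, lag-free kinetics). The system is integrated with LSODA at
rtol 1e-8 on a fixed output grid; the state vector is `[m, M_B, P]` and
`M_A = c_tot − m − M_B` is reconstructed from the balance, so total
protein is conserved to machine precision by construction.

Assumptions: well-mixed quiescent reactions; fibril number constant
during elongation; no primary nucleation (5% seed load bypasses it);
temperature effects outside scope.

### Sonication events

A 20 s sonication is ~5 orders of magnitude faster than the hours-scale
growth, so it is modelled as an instantaneous composite event at a phase
boundary:

1. the mean fibril length is divided by `length_divisor` (default 5),
   floored at `min_mean_length` — fibrils do not break below a minimum
   stable size;
2. a fraction δ (`disassembly_fraction`) of fibril mass is released to
   monomer, removed pro rata from both polymorphs;
3. `P` is recomputed from the remaining mass and the new mean length;
4. mass re-polymerising in the following phase is routed to polymorph B
   with probability `conversion_prob`, else to A.

The event is deterministic in the moment model (conversion is a mass
fraction); stochastic breakage lives in the population simulator.

### Observation model

`F = (β_A·M_A + β_B·M_B)·exp(−decline_rate·max(0, t−t_plateau)) +
baseline`, with optional multiplicative lognormal noise of coefficient
of variation `noise_cv`. The two-polymorph brightness model is the
minimal mechanism for the observed phenomenon of end-point ThT rising
across fragmentation cycles at constant fibril mass: ThT intensity per
unit mass depends on fibril structure, so conversion into a brighter
fold (B) raises the signal without changing the amount of fibril. The
post-plateau decline is applied to the signal, not the mass (photobleaching
and mass loss are excluded mechanisms; lateral association/clustering
reduces effective ThT binding). Its clock starts when the monomer has
relaxed to within 1% of its phase amplitude and resets at phase
boundaries. The default `decline_rate` is 0, and the variant fixtures
keep it there: the end-point-gain calibration (below) compares sonicated
and control wells at a single end time, and a nonzero decline applied to
a control that plateaued ~290 h earlier than the final regrowth would
fold an arbitrary decline choice into the calibrated gains. Decline is
exercised in unit tests as an observation-layer feature.

## Variant fixtures

`synkin.fixtures` encodes one reference parameter set per variant
(WT, H50Q, A30P, E46K, A53T). Anchored values: WT k₊ = 2087 M⁻¹s⁻¹;
yields 80/80/50/30/50% of c_tot = 52.5 μM (setting m_eq = 10.5, 10.5,
26.25, 36.75, 26.25 μM); A1 mean lengths 700 nm (midpoint of the
600–800 nm range) except A53T at 350 nm; end-point ThT gains
0/0/34/55/58%; post-sonication mean-length floors 150 nm (200 nm for
H50Q and A53T, whose sonicated fibrils stay longer); heights ~5.5 nm
with H50Q drifting to 8.4 nm, E46K starting thin at 4.0 nm, and A53T
carrying a 15% subpopulation at 9 nm. Non-anchored rate constants
(H50Q 2500, A30P 800, E46K 1500, A53T 4000 M⁻¹s⁻¹) were chosen once as
plausible within the observed fast/slow ordering; they only set phase
timescales.

The seed number concentration is derived from self-consistency: `P` is
constant during pure elongation, so the A1-end mean length equals the
A1-end fibril mass divided by `P·ρ`. With the WT numbers (42 μM mass,
700 nm, ρ = 2/0.47 ≈ 4.255 monomers/nm from two intertwined
protofilaments at one monomer per 0.47 nm cross-β rise) this gives
P = 1.41·10⁻⁸ M and τ = 4.72 h.

Conversion calibration: with disassembly fraction δ_k and conversion
probability p_k at sonication k, the polymorph-B mass fraction obeys
`f_B(k) = (1−δ_k)·f_B(k−1) + p_k·δ_k`, and the end-point gain over the
control is `f_B(end)·(β_B/β_A − 1)`. The same δ = 0.4 is used at every
event of every variant — the sonication treatment is identical across
samples, so the released fraction should be too — except E46K, where
δ = (0.4, 0, 0) and p = (1, 0, 0) encode its observed one-shot
conversion with no later dissociation/reaggregation. p schedules:
A53T (1,1,1) (conversion at every round), A30P (1, 0.5, 0.5) (most of
the gain in the first reaggregation), WT/H50Q 0. β_B/β_A is then solved
from the target gain: 1.74 (A53T), 2.38 (E46K), 1.73 (A30P). The value
δ = 0.4 is additionally constrained from below by fit quality: the
regrowth amplitude relative to the 2% multiplicative plate noise sets
the attainable R² of single-exponential fits, and shallow dips
(δ ≲ 0.3) cannot reach the R² ≥ 0.90 that well-formed growth phases
show; δ = 0.4 leaves headroom while keeping dips in the visually
plausible range for these assays.

Absolute brightnesses β_A (1.0–2.0 a.u./μM; A53T 8.0) encode the
~5-fold brighter A53T end point at roughly half the WT fibril mass.

## Stochastic population simulator

`synkin.population` represents every fibril as an integer monomer count.
Channels: elongation (rate `n_ends·k₊·m` per fibril), depolymerisation
(`n_ends·k₊·m_eq` per fibril, so the stationary monomer level is the
solubility), and breakage (per-fibril rate `k_b·e(L)·(L−1)^γ`, where
`e(L)` counts bonds whose scission leaves both fragments ≥ `L_min`).
γ = 0 (default) is random scission; γ > 0 tilts breakage towards long
fibrils. The kernel is an exact Gillespie simulation up to an expected
~50k events, switching to tau-leaping (Poisson event batches,
multinomial allocation over fibrils, leaps capped at 10% of the free
monomer pool — which automatically tracks the relaxation time) above
that. Monomer conservation is exact and asserted after every run.

Sonication pulses break each eligible bond independently with
probability `sonic_bond_break_prob`, implemented as a sequential
left-to-right scan that recurses into the remaining fragment. The
sequential form is deliberate: simultaneous independent breaks can
strand fragments below `L_min` (two adjacent eligible bonds both
firing), whereas the scan re-evaluates eligibility after each cut and
at saturation (p = 1) terminates in the unique minimal tiling
(2-mers plus one 3-mer per odd fibril when `L_min` = 2).
`disassemble_population` sheds a mass fraction from fibril ends into
the free pool (stochastic rounding, floor-respecting), emulating the
transient sonication-induced monomer release that precedes regrowth.

`L_min` defaults to 30 monomers (~7 nm): the experiments constrain a
~150 nm post-sonication *mean*, not a hard floor, so the floor is a
free mechanistic parameter set well below that mean.

## Estimation pipeline

Single-exponential fits use bounded nonlinear least squares
(`F(t) = F_∞ − (F_∞−F₀)e^(−(t−t₀)/τ)`), initialised at F₀ = first
value, F_∞ = 95th percentile, τ = half-rise time/ln 2, with
τ ∈ [dt, 10·window]. A failed optimisation, τ at its bounds, or a
degenerate amplitude returns `converged = False` rather than raising.
R² is reported on the fit window.

Curve selection: a phase is fitted only if its noise-robust total rise
(interior running-median maximum minus the median of the first kernel
width) exceeds 3× the robust noise scale (1.4826·MAD of first
differences/√2) — the quantitative form of "omit curves with no clear
exponential increase". Median-filter edges are excluded because
`scipy.signal.medfilt` zero-pads and corrupts boundary values.

Fit window: `window="auto"` runs a two-pass fit — a first fit over the
whole phase estimates τ, then the fit is repeated on
[t₀, t₀ + 5τ̂]. A fixed absolute cap after the plateau was rejected:
regrowth phases have τ ≈ 1–2 h inside 96 h rounds, and any window much
longer than ~5τ is dominated by stationary plateau noise, bounding R²
near 0.85 regardless of data quality. The τ-scaled window adapts from
the slow first phase to fast regrowths. Known limitation: with the
window ending near plateau attainment, F_∞ is partially extrapolated,
and any post-plateau decline inside the window is absorbed into a
slight F_∞ bias rather than modelled.

A30P's biphasic first phase (two sequential exponential components,
40/60 amplitude split, τ₂ = 3τ₁ — pure shape emulation, not mechanism)
is fitted by the single-exponential model only if it passes the
selection rule, mirroring the omission practice for non-exponential
curves.

Yield uses c_tot = 52.5 μM including seed mass (explicit, configurable;
the denominators in per-cent-of-source-material plots are ambiguous).
Negative residuals are clipped to zero with a logged warning; residuals
exceeding c_tot by >5% raise.

The k₊ and speed formulas are convention-dependent in `n_ends` and ρ;
both are explicit parameters, and the round trip is convention-invariant
whenever simulator and estimator share the physical product `n_ends·k₊`.

## Weibull analysis

Maximum likelihood on raw lengths (not binned least squares): for fixed
κ the scale has the closed form `λ̂ = (mean Lᵢ^κ)^{1/κ}`, and the profile
score `g(κ) = 1/κ + mean(ln L) − Σ L^κ ln L / Σ L^κ` is solved by a
safeguarded Newton iteration (log-shifted weights for overflow safety),
vectorised across bootstrap resamples. This matches
`scipy.stats.weibull_min.fit(floc=0)` to ~6 significant figures at
roughly 100× the speed, which makes the 95% percentile bootstrap CI for
κ (default 200 resamples, seeded) and its coverage validation cheap.
A histogram least-squares mode exists for comparison with binned-fit
conventions; MLE is the default. Degenerate (zero-variance) samples and
n < 20 raise.

Heights: mean/SD plus an optional two-component Gaussian mixture
(EM, 10 restarts, seeded; components sorted by mean) accepted only when
its BIC beats the single Gaussian — detecting a coexisting thicker
polymorph population without overfitting unimodal data.

AFM loading filters lengths below a minimum measurable length (default
50 nm, logged); generated samples are unfiltered draws.

## Synthetic data generator

`generate_tht_plate` emulates a 96-well experiment: 10 sonicated wells
plus 4 continuous controls per variant, 6 samples/h over 383 h
(A1 96 h, A2 96 h, A3 96 h, A4 95 h), replicate attrition of 2 wells
per sonication round (10→8→6→4, never below 4). Noise model:
per-point multiplicative lognormal (CV 2%) × per-well scale factor
(CV 5%) + a small baseline offset — pipetting, optical gain and plate
inhomogeneity, respectively. `generate_absorbance` returns
`A280 = m_eq·ε·10⁻⁶` with 1% noise and an opt-in flagged bias emulating
non-pelletable ThT-positive aggregates (E46K shows these; off by
default, and the E46K fixture keeps m_eq constant across rounds so the
yield-constancy property holds — its observed post-S1 equilibrium shift
is a documented non-feature). `generate_afm_table` draws lengths from
phase-dependent Weibull distributions (κ = 1.0/1.3/1.6/1.9 across
A1–A4, 1.8–2.2 immediately post-sonication; scale set to hit the phase
mean length: the A1 mean, then 0.45/0.38/0.35× it, floored at the
sonicated floor — the printed record gives A1 means and the ~150 nm
sonicated mean, so the interior multipliers emulate the observed
shorten-then-oscillate pattern) and heights from the fixture's normal
or mixture model with linear drift across phases.

What the generator does *not* emulate: drifting baselines, evaporation
trends, well-edge effects, pipetting dropouts, AFM surface-affinity
bias in length sampling (A53T sticks progressively better to mica in
reality), and any true biphasic mechanism for A30P. Passing tests
therefore demonstrate correctness of the analysis chain under the
stated statistical structure, not robustness to every artefact of real
plates.

## Statistics

One-way ANOVA, Tukey HSD and Pearson correlation wrap scipy; two-way
ANOVA uses statsmodels OLS with Type-II sums of squares — appropriate
for the unbalanced layouts that replicate attrition produces, where
Type-I would make factor tests order-dependent. Fewer than three groups
reduce Tukey to a pooled t-test with a warning.

## Numerical choices and degenerate inputs

- ODE: LSODA, rtol 1e-8, atol 1e-12; mass balance exact by state
  reconstruction.
- Exponential fit: xtol/ftol/gtol 1e-12; τ bounds [dt, 10·window].
- Weibull Newton: 80 iterations max with bisection fallback,
  κ ∈ [1e-3, 200].
- Empty populations, zero fibril numbers, non-positive durations,
  zero-variance samples, and inconsistent measurements raise
  `ValueError` with specific messages; fit non-convergence is a flag,
  not an exception.
- Problem sizes in tests and the acceptance script (populations of
  ~10²–10³ fibrils, 100-run recovery ensembles, 500-replication
  bootstrap studies, 2000-replication ANOVA nulls) were chosen as the
  smallest that make the corresponding statistical statements
  well-resolved.

## Known limitations

- The two-polymorph conversion model is the minimal sufficient
  mechanism; real samples may host many folds with a brightness
  continuum.
- Conversion probabilities and brightness ratios are jointly
  identifiable only through their product at a single end point; the
  fixtures pin them by convention (p = 1 at fully converting events).
- The moment model carries a single mean length per state, not a
  distribution; length-distribution statements come from the population
  simulator.
- No global multi-phase fitting: each phase is fitted independently.
- The estimator assumes elongation dominance; strong secondary
  nucleation (suspected for A53T reaggregation) biases τ-based k₊.
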