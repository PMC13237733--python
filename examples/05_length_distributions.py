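"""Weibull analysis of fibril length distributions across phases.

Fits Weibull distributions (shape κ, scale λ) to synthetic AFM length
tables for each aggregation phase.  κ ≈ 1 after the seeded reaction
indicates exponential-like lengths (random growth and scission); κ
grows with each sonication round as breakage becomes length-dependent
and the distribution narrows.
"""

from synkin import (
    LengthSample,
    fit_weibull,
    generate_afm_table,
    get_fixture,
    summarize_lengths,
)

fx = get_fixture("WT")
print(f"{'phase':>6} {'mean±sem nm':>15} {'κ':>6} {'95% CI':>15} {'λ nm':>8}")
for i, phase in enumerate(("A1", "A2", "A3", "A4")):
    df = generate_afm_table(fx, phase=phase, n_lengths=200, rng_seed=10 + i)
    lengths = df.length_nm.dropna().to_numpy()
    sample = LengthSample(lengths, variant="WT", phase_label=phase)
    mean, sem, _ = summarize_lengths(sample)
    fit = fit_weibull(sample, n_bootstrap=200, seed=0)
    lo, hi = fit.kappa_ci
    print(f"{phase:>6} {mean:>9.0f}±{sem:<5.0f} {fit.kappa:>6.2f} "
          f"[{lo:>5.2f}, {hi:>5.2f}] {fit.lam:>8.0f}")
print("\nn = 200 per phase, as in an AFM census; κ increases and the mean"
      "\nshortens across sonication rounds.")
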