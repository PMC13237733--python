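"""Recover the elongation rate constant from a simulated experiment.

Builds the standard measurement chain on a noiseless wild-type first
aggregation phase: a single-exponential fit gives the relaxation time τ;
the supernatant absorbance gives the residual monomer and hence the
fibril yield; the AFM mean length converts fibril mass to a fibril
number concentration P; and k+ = 1/(n_ends·τ·P).
"""

from synkin import (
    AbsorbanceMeasurement,
    ThTTrajectory,
    estimate_elongation_rate_constant,
    fibril_yield,
    fit_single_exponential,
    generate_absorbance,
    get_fixture,
    residual_monomer_conc,
    simulate_phase,
)

fx = get_fixture("WT")
traj = simulate_phase(
    fx.conditions(), fx.kinetic_params(), fx.observation_params(noise_cv=0.0),
    fx.initial_state(), duration=96.0, dt=1 / 6,
)
fit = fit_single_exponential(ThTTrajectory(times=traj.times, values=traj.F))
print(f"exponential fit: tau = {fit.tau:.3f} h, R² = {fit.r_squared:.4f}")

ab = generate_absorbance(fx, phase_ends=("A1",), noise_cv=0.0)
residual = residual_monomer_conc(AbsorbanceMeasurement(a280=float(ab.a280[0])))
y = fibril_yield(residual, fx.conditions().c_tot)
print(f"A280 = {ab.a280[0]:.4f} → residual monomer {residual:.2f} μM "
      f"→ yield {y.yield_percent:.1f}%")

est = estimate_elongation_rate_constant(
    fit, y, fx.mean_length_A1_nm, fx.rho, n_ends=2)
print(f"P = {est.P:.3e} M (mean length {fx.mean_length_A1_nm:.0f} nm)")
print(f"k+ = {est.k_plus:.0f} M⁻¹s⁻¹ (fixture truth {fx.k_plus:.0f})")
print(f"elongation speed at start of phase = {est.elongation_speed:.2f} nm/min")
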