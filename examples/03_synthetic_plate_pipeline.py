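"""Generate a complete synthetic experiment and analyse it end-to-end.

Produces a noisy 10+4-replicate ThT plate with replicate attrition,
end-point absorbance readings and per-phase AFM tables for the A53T
variant, then runs the full estimation pipeline and prints the tidy
per-phase summary (τ, R², yield, fibril number, k+, speed, Weibull κ/λ).
"""

import pandas as pd

from synkin import (
    ThTTrajectory,
    analyze_experiment,
    generate_absorbance,
    generate_afm_table,
    generate_tht_plate,
    get_fixture,
)

fx = get_fixture("A53T")
plate = generate_tht_plate(fx, rng_seed=1)
absorbance = generate_absorbance(fx, rng_seed=2)
afm = pd.concat(
    [generate_afm_table(fx, phase=ph, rng_seed=3 + i)
     for i, ph in enumerate(("A1", "A2", "A3", "A4"))],
    ignore_index=True,
)

trajs = []
for (well, variant, phase), grp in plate.groupby(["well", "variant", "phase"]):
    grp = grp.sort_values("time_h")
    trajs.append(ThTTrajectory(
        times=grp.time_h.to_numpy(), values=grp.fluorescence_au.to_numpy(),
        replicate_id=well, variant=variant, phase_label=phase,
    ))

table = analyze_experiment(trajs, absorbance, afm)
cols = ["variant", "phase", "n_fits", "tau_h", "r2", "yield_pct",
        "mean_length_nm", "kappa", "k_plus", "speed_nm_min"]
print(table[cols].round(3).to_string(index=False))
print("\nτ shortens after each sonication (more fibril ends), the yield is"
      "\nflat near 50%, κ rises across rounds, and k+ stays near the"
      "\ngenerating value — the fingerprints of elongation-dominated"
      "\nfragmentation cycling.")
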