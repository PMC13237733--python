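"""End-to-end analysis: plate + absorbance + AFM tables → kinetic estimates.

Ties the per-module operations into the per-variant, per-phase summary a
fragmentation-cycle experiment produces: exponential time constants and
fit quality, fibril yields, number concentrations, elongation rate
constants and speeds, and Weibull length statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .distributions import LengthSample, fit_weibull, summarize_lengths
from .estimation import (
    AbsorbanceMeasurement,
    ThTTrajectory,
    estimate_elongation_rate_constant,
    fibril_yield,
    fit_single_exponential,
    is_fittable,
    residual_monomer_conc,
)

__all__ = ["analyze_experiment"]


def analyze_experiment(
    trajectories: list[ThTTrajectory],
    absorbance: pd.DataFrame,
    afm: pd.DataFrame,
    c_tot: float = 52.5,
    rho: float | None = None,
    n_ends: int = 2,
    m_start_by_phase: dict | None = None,
    weibull_bootstrap: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full estimation chain and return a tidy per-phase table.

    Sonicated wells (ids not starting with ``C``) are pooled per variant
    and phase by fitting each replicate and averaging the fitted τ of
    replicates that pass the curve-selection rule.  Yields come from the
    phase-end absorbance, mean lengths from the AFM table, and the rate
    constant and elongation speed from the standard chain.
    """
    from .kinetics import RHO_DEFAULT

    rho = rho or RHO_DEFAULT
    rows = []
    traj_df = {}
    for tr in trajectories:
        if tr.replicate_id.startswith("C"):
            continue
        traj_df.setdefault((tr.variant, tr.phase_label), []).append(tr)

    for (variant, phase), trs in sorted(traj_df.items()):
        fits = []
        for tr in trs:
            if not is_fittable(tr):
                continue
            fit = fit_single_exponential(tr, window="auto")
            if fit.converged:
                fits.append(fit)
        ab = absorbance[
            (absorbance["sample"] == variant) & (absorbance["phase"] == phase)
        ]
        af = afm[(afm["sample"] == variant) & (afm["phase"] == phase)]
        lengths = af["length_nm"].dropna().to_numpy()

        row = {"variant": variant, "phase": phase, "n_fits": len(fits)}
        if fits:
            row["tau_h"] = float(np.mean([f.tau for f in fits]))
            row["F0"] = float(np.mean([f.F0 for f in fits]))
            row["F_inf"] = float(np.mean([f.F_inf for f in fits]))
            row["r2"] = float(np.mean([f.r_squared for f in fits]))
            row["r2_min"] = float(min(f.r_squared for f in fits))
        if not ab.empty:
            residual = residual_monomer_conc(
                AbsorbanceMeasurement(a280=float(ab["a280"].iloc[0]))
            )
            y = fibril_yield(residual, c_tot)
            row["yield_pct"] = y.yield_percent
        if lengths.size >= 2:
            mean, sem, _ = summarize_lengths(LengthSample(lengths))
            row["mean_length_nm"] = mean
            row["mean_length_sem"] = sem
            if lengths.size >= 20 and np.ptp(lengths) > 0:
                wf = fit_weibull(
                    LengthSample(lengths), n_bootstrap=weibull_bootstrap,
                    seed=seed,
                )
                row["kappa"] = wf.kappa
                row["lambda_nm"] = wf.lam
        if fits and "yield_pct" in row and "mean_length_nm" in row:
            best = fits[int(np.argmax([f.r_squared for f in fits]))]
            y = fibril_yield(
                residual_monomer_conc(
                    AbsorbanceMeasurement(a280=float(ab["a280"].iloc[0]))
                ),
                c_tot,
            )
            m_start = None
            if m_start_by_phase is not None:
                m_start = m_start_by_phase.get(phase)
            est = estimate_elongation_rate_constant(
                best, y, row["mean_length_nm"], rho, n_ends=n_ends,
                m_start=m_start,
            )
            row["P_M"] = est.P
            row["k_plus"] = est.k_plus
            row["speed_nm_min"] = est.elongation_speed
        rows.append(row)
    return pd.DataFrame(rows)
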