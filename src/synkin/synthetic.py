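"""Synthetic experiment generator: ThT plates, absorbance, AFM tables.

Generates complete fragmentation-cycle datasets with the statistical
structure the analysis pipeline assumes: replicate ThT trajectories from
the moment model with multiplicative plate-reader noise and replicate
attrition, supernatant A280 readings from the variant solubility, and
per-fibril AFM length/height tables whose Weibull shape parameter grows
across sonication rounds.

The noise model is multiplicative lognormal per time point (CV 2% by
default) on top of a per-replicate scale factor (CV 5%), which mimics
well-to-well pipetting and optical-gain variation in plate readers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import EPSILON_280
from .fixtures import PHASE_DURATIONS, VariantFixture
from .kinetics import Schedule, StateTrajectory, simulate_schedule
from .units import M_PER_UM

__all__ = [
    "PlateLayout",
    "generate_tht_plate",
    "generate_absorbance",
    "generate_afm_table",
    "simulate_fixture",
]

#: Weibull shape parameter by phase: ≈1 after the seeded reaction
#: (random growth and scission), rising across sonication rounds as
#: breakage becomes length-dependent.
PHASE_KAPPA = {
    "A1": 1.0, "A2": 1.3, "A3": 1.6, "A4": 1.9,
    "S1": 1.8, "S2": 2.0, "S3": 2.2,
}
#: A-phase mean lengths relative to the A1 mean, floored at the
#: sonicated floor: shortening then oscillation around a regrown mean.
PHASE_MEAN_FACTOR = {"A1": 1.0, "A2": 0.45, "A3": 0.38, "A4": 0.35}


@dataclass(frozen=True)
class PlateLayout:
    """Replicate structure of the plate experiment."""

    replicates_sonicated: int = 10
    replicates_control: int = 4
    sampling_rate: float = 6.0      # points per hour
    attrition_per_round: int = 2    # wells lost at each sonication round
    replicate_scale_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.replicates_sonicated <= 0 or self.replicates_control <= 0:
            raise ValueError("replicate counts must be positive")
        n_rounds = len(PHASE_DURATIONS) - 1
        if self.replicates_sonicated - n_rounds * self.attrition_per_round < 4:
            raise ValueError("attrition would leave fewer than 4 replicates")

    def sonicated_wells_in_phase(self, phase_index: int) -> int:
        return self.replicates_sonicated - phase_index * self.attrition_per_round


def simulate_fixture(
    fixture: VariantFixture,
    sonicated: bool = True,
    sampling_rate: float = 6.0,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> StateTrajectory:
    """Run the fixture's full A1–A4 schedule (or its matched control)."""
    return simulate_schedule(
        fixture.conditions(),
        fixture.kinetic_params(),
        fixture.observation_params(noise_cv=noise_cv),
        fixture.schedule(sonicated=sonicated, sampling_rate=sampling_rate),
        state0=fixture.initial_state(),
        rng=rng,
    )


def _biphasic_reshape(times, F, phase_labels, tau1_h: float,
                      split: float = 0.4, tau_ratio: float = 3.0):
    """Reshape the A1 rise as a sum of two sequential exponentials.

    Emulates the biphasic growth seen for A30P's first seeded reaction;
    preserves the A1 start and end values exactly (pure shape emulation,
    no mechanism).
    """
    F = F.copy()
    sel = phase_labels == "A1"
    t = times[sel] - times[sel][0]
    F0, F1 = F[sel][0], F[sel][-1]
    T = t[-1]

    def shape(tt):
        c1 = split * (1 - np.exp(-tt / tau1_h))
        c2 = (1 - split) * (1 - np.exp(-tt / (tau_ratio * tau1_h)))
        return c1 + c2

    F[sel] = F0 + (F1 - F0) * shape(t) / shape(T)
    return F


def generate_tht_plate(
    fixture: VariantFixture,
    layout: PlateLayout | None = None,
    rng_seed: int = 0,
    schedule: Schedule | None = None,
) -> pd.DataFrame:
    """Generate a long-format ThT plate table for one variant.

    Columns: time_h, well, variant, phase, fluorescence_au.  Wells
    S01..S10 follow the sonicated schedule with replicate attrition at
    each round; wells C01..C04 are the continuously aggregated control.
    Deterministic for a fixed seed.
    """
    layout = layout or PlateLayout()
    rng = np.random.default_rng(rng_seed)

    base_son = simulate_fixture(fixture, sonicated=True,
                                sampling_rate=layout.sampling_rate)
    base_ctl = simulate_fixture(fixture, sonicated=False,
                                sampling_rate=layout.sampling_rate)
    if fixture.biphasic:
        # biphasic first phase: reshape A1 with a slow second component
        from .kinetics import closed_form_tau_h
        tau1 = 0.5 * closed_form_tau_h(
            fixture.kinetic_params(), fixture.initial_state().P
        )
        for base in (base_son, base_ctl):
            base.F = _biphasic_reshape(base.times, base.F, base.phase_labels, tau1)

    phase_order = [lbl for lbl, _ in fixture.schedule().phases]
    noise_cv = fixture.noise_cv
    sigma = math.sqrt(math.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    scale_sigma = math.sqrt(math.log1p(layout.replicate_scale_cv**2))

    frames = []
    for kind, base, n_wells in (
        ("S", base_son, layout.replicates_sonicated),
        ("C", base_ctl, layout.replicates_control),
    ):
        for w in range(n_wells):
            well = f"{kind}{w + 1:02d}"
            if layout.replicate_scale_cv > 0:
                scale = rng.lognormal(-0.5 * scale_sigma**2, scale_sigma)
            else:
                scale = 1.0
            if sigma > 0:
                baseline = rng.uniform(0.0, 0.01) * float(base.F.max())
                noise = rng.lognormal(-0.5 * sigma**2, sigma, size=base.F.size)
            else:
                baseline = 0.0
                noise = 1.0
            F = base.F * scale * noise + baseline
            df = pd.DataFrame({
                "time_h": base.times,
                "well": well,
                "variant": fixture.name,
                "phase": base.phase_labels.astype(str),
                "fluorescence_au": F,
            })
            if kind == "S":
                # replicate attrition: this well only reports up to the
                # round in which it is withdrawn
                last_phase = len(phase_order) - 1
                surviving = layout.replicates_sonicated
                for pi in range(1, len(phase_order)):
                    surviving -= layout.attrition_per_round
                    if w >= surviving:
                        last_phase = pi - 1
                        break
                keep = df["phase"].isin(phase_order[: last_phase + 1])
                df = df[keep]
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_absorbance(
    fixture: VariantFixture,
    phase_ends: tuple[str, ...] = ("A1", "A2", "A3", "A4"),
    rng_seed: int = 0,
    noise_cv: float = 0.01,
    nonpelletable_bias: float = 0.0,
) -> pd.DataFrame:
    """Supernatant A280 readings at each aggregation end point.

    a280 = m_eq·ε280·10⁻⁶ with 1% multiplicative noise by default.
    ``nonpelletable_bias`` adds a flagged fractional bias emulating
    ThT-positive aggregates too small to pellet (observed for E46K);
    it is off by default.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for phase in phase_ends:
        a280 = fixture.m_eq * M_PER_UM * EPSILON_280
        if noise_cv > 0:
            sigma = math.sqrt(math.log1p(noise_cv**2))
            a280 *= rng.lognormal(-0.5 * sigma**2, sigma)
        biased = nonpelletable_bias > 0 and phase != "A1"
        if biased:
            a280 *= 1.0 + nonpelletable_bias
        rows.append({
            "sample": fixture.name, "phase": phase,
            "a280": a280, "bias_flagged": biased,
        })
    return pd.DataFrame(rows)


def _phase_mean_length(fixture: VariantFixture, phase: str) -> float:
    if phase.startswith("S"):
        return fixture.sonicated_floor_nm
    factor = PHASE_MEAN_FACTOR[phase]
    return max(fixture.sonicated_floor_nm, factor * fixture.mean_length_A1_nm)


def _phase_height_mean(fixture: VariantFixture, phase: str) -> float:
    order = ["A1", "A2", "A3", "A4"]
    idx = order.index(phase) if phase in order else int(phase[1])  # S_k ≈ A_{k+1}
    frac = idx / (len(order) - 1)
    return fixture.height_mean_A1_nm + frac * (
        fixture.height_mean_A4_nm - fixture.height_mean_A1_nm
    )


def generate_afm_table(
    fixture: VariantFixture,
    phase: str = "A1",
    n_lengths: int = 200,
    n_heights: int = 120,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Per-fibril AFM measurement table for one sample and phase.

    Lengths are Weibull with a phase-dependent shape (κ ≈ 1 after the
    seeded reaction, increasing with each sonication round) and scale set
    to hit the phase mean; heights are Gaussian with per-variant drift,
    or a two-component mixture for variants with a thicker coexisting
    population.  Columns: fibril_id, image_id, sample, phase, length_nm,
    height_nm (height_nm is NaN for fibrils beyond the height census).
    """
    if phase not in PHASE_KAPPA:
        raise ValueError(f"unknown phase {phase!r}")
    rng = np.random.default_rng(rng_seed)
    kappa = PHASE_KAPPA[phase]
    mean = _phase_mean_length(fixture, phase)
    lam = mean / math.gamma(1.0 + 1.0 / kappa)
    lengths = lam * rng.weibull(kappa, size=n_lengths)
    lengths = np.maximum(lengths, 1.0)  # nm; AFM cannot log zero length

    mu = _phase_height_mean(fixture, phase)
    if fixture.height_mixture is not None:
        mu2, sd2, w2 = fixture.height_mixture
        comp = rng.random(n_heights) < w2
        heights = np.where(
            comp,
            rng.normal(mu2, sd2, size=n_heights),
            rng.normal(mu, fixture.height_sd_nm, size=n_heights),
        )
    else:
        heights = rng.normal(mu, fixture.height_sd_nm, size=n_heights)
    heights = np.maximum(heights, 0.5)

    n = max(n_lengths, n_heights)
    height_col = np.full(n, np.nan)
    height_col[:n_heights] = heights
    length_col = np.full(n, np.nan)
    length_col[:n_lengths] = lengths
    return pd.DataFrame({
        "fibril_id": np.arange(1, n + 1),
        "image_id": 1 + (np.arange(n) % 7),
        "sample": fixture.name,
        "phase": phase,
        "length_nm": length_col,
        "height_nm": height_col,
    })
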