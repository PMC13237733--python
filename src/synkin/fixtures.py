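"""Reference parameter sets for the five α-synuclein variants.

Each :class:`VariantFixture` bundles everything needed to simulate one
variant's fragmentation-cycle experiment: elongation rate constant,
solubility (which sets the fibril yield), seed census via the A1-end
mean fibril length, the per-sonication disassembly fractions and
polymorph-conversion probabilities, and the AFM height model.

The polymorph-B brightness ratio βB/βA is calibrated so that the
deterministic conversion bookkeeping reproduces each variant's observed
end-point ThT gain over its continuously aggregated control: with
disassembly fraction δ_k and conversion probability p_k at sonication k,
the polymorph-B mass fraction evolves as
f_B(k) = (1−δ_k)·f_B(k−1) + p_k·δ_k, and the end-point gain is
f_B(end)·(βB/βA − 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kinetics import (
    RHO_DEFAULT,
    AssayConditions,
    KineticParameters,
    ObservationParameters,
    PhaseState,
    Schedule,
    SonicationEvent,
)

__all__ = ["VariantFixture", "VARIANTS", "get_fixture"]

#: A1 .. A4 phase durations (h); events sit at the three internal boundaries.
PHASE_DURATIONS = (96.0, 96.0, 96.0, 95.0)


@dataclass(frozen=True)
class VariantFixture:
    name: str
    k_plus: float                       # M⁻¹ s⁻¹
    m_eq: float                         # μM; sets the yield vs c_tot 52.5
    mean_length_A1_nm: float            # A1-end AFM mean length
    sonicated_floor_nm: float           # post-sonication mean-length floor
    endpoint_gain_pct: float            # sonicated vs control end-point ThT
    disassembly_fractions: tuple[float, float, float]
    conversion_probs: tuple[float, float, float]
    beta_A: float = 1.0                 # a.u. per μM, polymorph A
    length_divisor: float = 5.0
    height_mean_A1_nm: float = 5.5
    height_mean_A4_nm: float = 5.5
    height_sd_nm: float = 0.5
    height_mixture: tuple[float, float, float] | None = None  # (mu2, sd2, w2)
    biphasic: bool = False
    decline_rate: float = 0.0           # h⁻¹
    noise_cv: float = 0.02
    rho: float = RHO_DEFAULT

    @property
    def polymorph_b_fraction(self) -> float:
        """End-point polymorph-B mass fraction implied by the event chain."""
        f = 0.0
        for d, p in zip(self.disassembly_fractions, self.conversion_probs):
            f = (1.0 - d) * f + p * d
        return f

    @property
    def beta_ratio(self) -> float:
        """βB/βA calibrated to the end-point ThT gain."""
        f = self.polymorph_b_fraction
        if f <= 0 or self.endpoint_gain_pct <= 0:
            return 1.0
        return 1.0 + self.endpoint_gain_pct / 100.0 / f

    def conditions(self) -> AssayConditions:
        return AssayConditions(monomer_conc=50.0, seed_conc=2.5)

    def kinetic_params(self) -> KineticParameters:
        return KineticParameters(k_plus=self.k_plus, m_eq=self.m_eq, rho=self.rho)

    def observation_params(self, noise_cv: float | None = None) -> ObservationParameters:
        return ObservationParameters(
            beta_A=self.beta_A,
            beta_B=self.beta_A * self.beta_ratio,
            decline_rate=self.decline_rate,
            noise_cv=self.noise_cv if noise_cv is None else noise_cv,
        )

    def initial_state(self) -> PhaseState:
        """Seeds as polymorph A; seed number chosen so the A1-end mean
        length (constant fibril number during elongation) matches the AFM
        value."""
        cond = self.conditions()
        P_uM = (cond.c_tot - self.m_eq) / (self.mean_length_A1_nm * self.rho)
        return PhaseState(
            m=cond.monomer_conc, M_A=cond.seed_conc, M_B=0.0, P_uM=P_uM
        )

    def schedule(self, sonicated: bool = True, sampling_rate: float = 6.0) -> Schedule:
        phases = tuple(zip(("A1", "A2", "A3", "A4"), PHASE_DURATIONS))
        if not sonicated:
            return Schedule(phases=phases, events=(), sampling_rate=sampling_rate)
        t = 0.0
        events = []
        for (label, dur), d, p in zip(
            phases[:-1], self.disassembly_fractions, self.conversion_probs
        ):
            t += dur
            events.append(SonicationEvent(
                time=t,
                length_divisor=self.length_divisor,
                min_mean_length=self.sonicated_floor_nm,
                disassembly_fraction=d,
                conversion_prob=p,
            ))
        return Schedule(phases=phases, events=tuple(events),
                        sampling_rate=sampling_rate)


VARIANTS: dict[str, VariantFixture] = {
    "WT": VariantFixture(
        name="WT", k_plus=2087.0, m_eq=10.5,
        mean_length_A1_nm=700.0, sonicated_floor_nm=150.0,
        endpoint_gain_pct=0.0,
        disassembly_fractions=(0.4, 0.4, 0.4),
        conversion_probs=(0.0, 0.0, 0.0),
        beta_A=1.0,
    ),
    "H50Q": VariantFixture(
        name="H50Q", k_plus=2500.0, m_eq=10.5,
        mean_length_A1_nm=700.0, sonicated_floor_nm=200.0,
        endpoint_gain_pct=0.0,
        disassembly_fractions=(0.4, 0.4, 0.4),
        conversion_probs=(0.0, 0.0, 0.0),
        beta_A=1.2,
        height_mean_A4_nm=8.4,
    ),
    "A30P": VariantFixture(
        name="A30P", k_plus=800.0, m_eq=26.25,
        mean_length_A1_nm=700.0, sonicated_floor_nm=150.0,
        endpoint_gain_pct=34.0,
        disassembly_fractions=(0.4, 0.4, 0.4),
        conversion_probs=(1.0, 0.5, 0.5),
        beta_A=1.5,
        biphasic=True,
    ),
    "E46K": VariantFixture(
        name="E46K", k_plus=1500.0, m_eq=36.75,
        mean_length_A1_nm=700.0, sonicated_floor_nm=150.0,
        endpoint_gain_pct=55.0,
        disassembly_fractions=(0.4, 0.0, 0.0),
        conversion_probs=(1.0, 0.0, 0.0),
        beta_A=2.0,
        height_mean_A1_nm=4.0, height_mean_A4_nm=6.0,
    ),
    "A53T": VariantFixture(
        name="A53T", k_plus=4000.0, m_eq=26.25,
        mean_length_A1_nm=350.0, sonicated_floor_nm=200.0,
        endpoint_gain_pct=58.0,
        disassembly_fractions=(0.4, 0.4, 0.4),
        conversion_probs=(1.0, 1.0, 1.0),
        beta_A=8.0,
        height_mixture=(9.0, 0.5, 0.15),
    ),
}


def get_fixture(name: str) -> VariantFixture:
    try:
        return VARIANTS[name]
    except KeyError:
        raise KeyError(
            f"unknown variant {name!r}; choose from {sorted(VARIANTS)}"
        ) from None
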