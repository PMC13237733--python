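"""Deterministic moment-equation model of seeded amyloid aggregation.

The model tracks three moments of a fibril population growing from
preformed seeds: free monomer ``m`` (μM), polymerised mass split over two
polymorphs ``M_A`` and ``M_B`` (μM), and fibril number concentration ``P``
(reported in M).  Growth is elongation-dominated,

    dm/dt  = -n_ends · k+ · P · (m - m_eq)  -  k2 · m^n2 · M
    dM/dt  = -dm/dt
    dP/dt  =  k2 · m^n2 · M  +  k_frag · M

with optional secondary nucleation (``k2``) and quiescent fragmentation
(``k_frag``), both zero by default for strongly seeded reactions.  The
closed-form solution in the elongation-only limit is a single exponential
relaxation of the monomer towards its solubility ``m_eq`` with time
constant τ = 1/(n_ends·k+·P), which is what plate-reader ThT curves are
fitted to downstream.

Ultrasonication is modelled as an instantaneous composite event between
aggregation phases: the mean fibril length is divided (with a floor),
a fraction δ of fibril mass is released back to monomer, and mass that
re-polymerises during the following phase is routed to the brighter
polymorph B with a per-event conversion probability.  The ThT observation
layer maps polymorph masses to fluorescence through per-polymorph
brightness coefficients, an optional post-plateau signal decline, and
optional multiplicative noise.

Internal unit conventions: concentrations in μM, time in hours; the
second-order elongation rate constant is supplied in the field's
customary M⁻¹ s⁻¹ and converted internally (see :mod:`synkin.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .units import M_PER_UM, S_PER_H, kplus_to_per_uM_per_h

__all__ = [
    "AssayConditions",
    "KineticParameters",
    "ObservationParameters",
    "SonicationEvent",
    "Schedule",
    "PhaseState",
    "StateTrajectory",
    "closed_form_monomer",
    "closed_form_tau_h",
    "simulate_phase",
    "apply_sonication_event",
    "simulate_schedule",
    "tht_signal",
]

#: default monomers per nm of fibril contour length: two intertwined
#: protofilaments at one monomer per 0.47 nm cross-β rise each.
RHO_DEFAULT = 2.0 / 0.47


@dataclass(frozen=True)
class AssayConditions:
    """Bulk composition of a seeded aggregation reaction."""

    monomer_conc: float = 50.0      # μM free monomer at t=0
    seed_conc: float = 2.5          # μM monomer-equivalents of preformed seeds
    tht_conc: float = 20.0          # μM, metadata only
    temperature: float = 37.0       # °C, metadata only
    include_seed_in_total: bool = True

    def __post_init__(self) -> None:
        if self.monomer_conc <= 0:
            raise ValueError("monomer_conc must be positive")
        if self.seed_conc < 0:
            raise ValueError("seed_conc must be non-negative")

    @property
    def c_tot(self) -> float:
        """Total protein concentration (μM) used as the mass-balance and
        yield denominator."""
        if self.include_seed_in_total:
            return self.monomer_conc + self.seed_conc
        return self.monomer_conc

    @property
    def seed_fraction(self) -> float:
        """Seed load as a fraction of the free monomer concentration."""
        return self.seed_conc / self.monomer_conc


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and solubility governing the moment equations.

    ``k_plus`` is in M⁻¹ s⁻¹; ``m_eq`` (μM) is the equilibrium monomer
    concentration that sets the fibril yield; ``k2``/``n2`` parameterise
    secondary nucleation (k2 in μM^(1−n2) h⁻¹ so that k2·m^n2·M is μM/h);
    ``k_frag`` is the quiescent per-bond fragmentation rate (s⁻¹);
    ``n_ends`` the number of growth-competent fibril ends; ``rho`` the
    monomers-per-nm conversion for length bookkeeping.
    """

    k_plus: float = 2087.0
    m_eq: float = 10.5
    k2: float = 0.0
    n2: float = 2.0
    k_frag: float = 0.0
    n_ends: int = 2
    rho: float = RHO_DEFAULT

    def __post_init__(self) -> None:
        if self.k_plus <= 0:
            raise ValueError("k_plus must be positive")
        if self.m_eq < 0:
            raise ValueError("m_eq must be non-negative")
        if self.n_ends not in (1, 2):
            raise ValueError("n_ends must be 1 or 2")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.k2 < 0 or self.k_frag < 0:
            raise ValueError("rate constants must be non-negative")


@dataclass(frozen=True)
class ObservationParameters:
    """ThT observation model: fluorescence per unit fibril mass by polymorph."""

    beta_A: float = 1.0         # a.u. per μM fibril mass, polymorph A
    beta_B: float = 1.0         # a.u. per μM fibril mass, polymorph B
    baseline: float = 0.0       # a.u.
    decline_rate: float = 0.0   # h⁻¹, post-plateau fractional signal decline
    noise_cv: float = 0.0       # multiplicative noise CV

    def __post_init__(self) -> None:
        if not (self.beta_B >= self.beta_A > 0):
            raise ValueError("require beta_B >= beta_A > 0")
        if self.decline_rate < 0 or self.noise_cv < 0:
            raise ValueError("decline_rate and noise_cv must be non-negative")


@dataclass(frozen=True)
class SonicationEvent:
    """Instantaneous fragmentation / partial-disassembly / conversion event."""

    time: float                     # h, at a phase boundary
    length_divisor: float = 5.0     # mean length reduced by this factor
    min_mean_length: float = 150.0  # nm floor on the post-event mean length
    disassembly_fraction: float = 0.0   # δ: fibril mass released to monomer
    conversion_prob: float = 0.0        # regrown mass routed to polymorph B

    def __post_init__(self) -> None:
        if self.length_divisor < 1:
            raise ValueError("length_divisor must be >= 1")
        if not (0 <= self.disassembly_fraction < 1):
            raise ValueError("disassembly_fraction must be in [0, 1)")
        if not (0 <= self.conversion_prob <= 1):
            raise ValueError("conversion_prob must be in [0, 1]")
        if self.min_mean_length <= 0:
            raise ValueError("min_mean_length must be positive")


@dataclass(frozen=True)
class Schedule:
    """Ordered aggregation phases with sonication events at their boundaries."""

    phases: tuple[tuple[str, float], ...] = (
        ("A1", 96.0), ("A2", 96.0), ("A3", 96.0), ("A4", 95.0),
    )
    events: tuple[SonicationEvent, ...] = ()
    sampling_rate: float = 6.0  # points per hour

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if any(d <= 0 for _, d in self.phases):
            raise ValueError("phase durations must be positive")
        bounds = set(np.cumsum([d for _, d in self.phases])[:-1].round(9))
        last = -np.inf
        for ev in self.events:
            if ev.time <= last:
                raise ValueError("event times must be strictly increasing")
            if round(ev.time, 9) not in bounds:
                raise ValueError(
                    f"event at t={ev.time} h is not at a phase boundary"
                )
            last = ev.time

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.phases))

    def total_excitation_time_s(self, exposure_s: float = 20e-6) -> float:
        """Cumulative ThT excitation time over the whole run (s)."""
        return self.total_duration * self.sampling_rate * exposure_s

    def without_events(self) -> "Schedule":
        """The matched continuously-aggregated control schedule."""
        return replace(self, events=())

    def event_before_phase(self, index: int) -> SonicationEvent | None:
        if index == 0:
            return None
        t = float(np.cumsum([d for _, d in self.phases])[index - 1])
        for ev in self.events:
            if abs(ev.time - t) < 1e-9:
                return ev
        return None


@dataclass
class PhaseState:
    """Instantaneous moment-model state between or within phases."""

    m: float        # μM free monomer
    M_A: float      # μM fibril mass, polymorph A
    M_B: float      # μM fibril mass, polymorph B
    P_uM: float     # fibril number concentration, μM

    @property
    def M_tot(self) -> float:
        return self.M_A + self.M_B

    @property
    def P(self) -> float:
        """Number concentration in M."""
        return self.P_uM * M_PER_UM

    def mean_length_nm(self, rho: float = RHO_DEFAULT) -> float:
        if self.P_uM <= 0:
            raise ValueError("no fibrils present")
        return self.M_tot / self.P_uM / rho


@dataclass
class StateTrajectory:
    """Time-resolved output of the moment model with its ThT observation."""

    times: np.ndarray          # h
    m: np.ndarray              # μM
    M_A: np.ndarray            # μM
    M_B: np.ndarray            # μM
    P: np.ndarray              # M
    F: np.ndarray              # a.u.
    phase_labels: np.ndarray   # str per sample
    c_tot: float

    def final_state(self) -> PhaseState:
        return PhaseState(
            m=float(self.m[-1]), M_A=float(self.M_A[-1]),
            M_B=float(self.M_B[-1]), P_uM=float(self.P[-1]) / M_PER_UM,
        )

    def check_mass_balance(self, rtol: float = 1e-9) -> None:
        total = self.m + self.M_A + self.M_B
        if not np.allclose(total, self.c_tot, rtol=rtol, atol=0):
            raise AssertionError("mass balance violated")


def closed_form_tau_h(params: KineticParameters, P: float) -> float:
    """Elongation time constant τ = 1/(n_ends·k+·P) in hours, P in M."""
    if P <= 0:
        raise ValueError("no fibril ends: P must be positive")
    return 1.0 / (params.n_ends * params.k_plus * P * S_PER_H)


def closed_form_monomer(
    conditions: AssayConditions,
    params: KineticParameters,
    P: float,
    t: float | np.ndarray,
    m0: float | None = None,
) -> float | np.ndarray:
    """Monomer concentration under elongation-only kinetics.

    m(t) = m_eq + (m0 − m_eq)·exp(−t/τ) with τ = 1/(n_ends·k+·P);
    ``t`` in hours, ``P`` in M, result in μM.
    """
    if P <= 0:
        raise ValueError("no fibril ends: P must be positive")
    if m0 is None:
        m0 = conditions.monomer_conc
    if m0 < params.m_eq:
        raise ValueError("closed form assumes m0 >= m_eq")
    tau = closed_form_tau_h(params, P)
    return params.m_eq + (m0 - params.m_eq) * np.exp(-np.asarray(t) / tau)


def tht_signal(
    M_A: float | np.ndarray,
    M_B: float | np.ndarray,
    obs: ObservationParameters,
    t_since_plateau: float | np.ndarray = 0.0,
    rng: np.random.Generator | None = None,
) -> float | np.ndarray:
    """ThT fluorescence for given polymorph masses (μM).

    F = (β_A·M_A + β_B·M_B)·exp(−decline_rate·max(0, t_since_plateau))
        + baseline, with optional multiplicative lognormal noise of the
    configured CV when an RNG is supplied.
    """
    M_A = np.asarray(M_A, dtype=float)
    M_B = np.asarray(M_B, dtype=float)
    if np.any(M_A < 0) or np.any(M_B < 0):
        raise ValueError("fibril masses must be non-negative")
    decay = np.exp(-obs.decline_rate * np.maximum(0.0, np.asarray(t_since_plateau)))
    F = (obs.beta_A * M_A + obs.beta_B * M_B) * decay + obs.baseline
    if rng is not None and obs.noise_cv > 0:
        sigma = np.sqrt(np.log1p(obs.noise_cv**2))
        F = F * rng.lognormal(-0.5 * sigma**2, sigma, size=np.shape(F))
    return F if F.shape else float(F)


def _phase_rhs(conditions, params, conv_frac):
    """Right-hand side over state y = [m, M_B, P_uM]; M_A by mass balance."""
    a = params.n_ends * kplus_to_per_uM_per_h(params.k_plus)  # μM⁻¹ h⁻¹
    c_tot = conditions.c_tot
    k2, n2 = params.k2, params.n2
    kf_h = params.k_frag * S_PER_H

    def rhs(t, y):
        m, M_B, P_uM = y
        M = c_tot - m
        growth = a * P_uM * (m - params.m_eq) + k2 * max(m, 0.0) ** n2 * M
        # polymorph routing: new mass to B with the current conversion
        # fraction; net depolymerisation removes mass pro rata.
        if growth >= 0 or M <= 0:
            dM_B = conv_frac * growth
        else:
            dM_B = growth * (M_B / M)
        dP = k2 * max(m, 0.0) ** n2 * M + kf_h * M
        return (-growth, dM_B, dP)

    return rhs


def simulate_phase(
    conditions: AssayConditions,
    params: KineticParameters,
    obs: ObservationParameters,
    state0: PhaseState,
    duration: float,
    dt: float,
    conv_frac: float = 0.0,
    phase_label: str = "A1",
    t_offset: float = 0.0,
    rng: np.random.Generator | None = None,
    rtol: float = 1e-8,
) -> StateTrajectory:
    """Integrate one aggregation phase on a fixed output grid.

    ``dt`` is the sampling interval in hours (1/sampling_rate); the
    trajectory carries absolute times ``t_offset + [0, dt, ..., duration]``.
    Mass conservation is exact by construction (M_A is reconstructed from
    the balance).  The post-plateau decline clock starts when the monomer
    has relaxed to within 1% of its phase amplitude.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if min(state0.m, state0.M_A, state0.M_B) < 0 or state0.P_uM < 0:
        raise ValueError("state must be non-negative")
    c_tot = conditions.c_tot
    if abs(state0.m + state0.M_tot - c_tot) > 1e-6 * c_tot:
        raise ValueError("initial state is not mass-consistent")

    n = int(round(duration / dt))
    times = np.linspace(0.0, duration, n + 1)
    sol = solve_ivp(
        _phase_rhs(conditions, params, conv_frac),
        (0.0, duration),
        [state0.m, state0.M_B, state0.P_uM],
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover - LSODA is robust here
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    m = sol.y[0]
    M_B = np.clip(sol.y[1], 0.0, None)
    P_uM = sol.y[2]
    M_A = np.clip(c_tot - m - M_B, 0.0, None)

    # plateau time: monomer within 1% of its phase amplitude of m_eq
    amp0 = state0.m - params.m_eq
    if amp0 > 0:
        rel = (m - params.m_eq) / amp0
        idx = np.nonzero(rel <= 0.01)[0]
        t_plateau = times[idx[0]] if idx.size else times[-1]
    else:
        t_plateau = 0.0
    F = tht_signal(M_A, M_B, obs, times - t_plateau, rng=rng)

    return StateTrajectory(
        times=times + t_offset,
        m=m, M_A=M_A, M_B=M_B,
        P=P_uM * M_PER_UM,
        F=np.asarray(F, dtype=float),
        phase_labels=np.full(times.shape, phase_label, dtype=object),
        c_tot=c_tot,
    )


def apply_sonication_event(
    state: PhaseState,
    event: SonicationEvent,
    rho: float = RHO_DEFAULT,
    rng_seed: int | None = None,
) -> PhaseState:
    """Apply an instantaneous sonication event to a moment-model state.

    The mean fibril length is divided by ``length_divisor`` (floored at
    ``min_mean_length``), a fraction δ of fibril mass is released to
    monomer (removed pro rata from both polymorphs) and the fibril number
    is recomputed from the remaining mass and the new mean length.  Total
    protein is conserved exactly.  The event is deterministic; the
    ``rng_seed`` argument exists for interface uniformity with the
    stochastic simulator.  Conversion routing of regrown mass is applied
    by the following phase via the event's ``conversion_prob``.
    """
    del rng_seed  # deterministic in the moment model
    if state.M_tot <= 0 or state.P_uM <= 0:
        raise ValueError("cannot sonicate an empty fibril state")
    L_nm = state.mean_length_nm(rho)
    L_new = max(event.min_mean_length, L_nm / event.length_divisor)
    delta = event.disassembly_fraction
    released = delta * state.M_tot
    M_A = state.M_A * (1.0 - delta)
    M_B = state.M_B * (1.0 - delta)
    P_uM = (M_A + M_B) / (L_new * rho)
    return PhaseState(m=state.m + released, M_A=M_A, M_B=M_B, P_uM=P_uM)


def simulate_schedule(
    conditions: AssayConditions,
    params: KineticParameters,
    obs: ObservationParameters,
    schedule: Schedule,
    state0: PhaseState | None = None,
    rng: np.random.Generator | None = None,
) -> StateTrajectory:
    """Run a full multi-phase schedule with sonication events at boundaries.

    Regrown mass in the phase following each event is routed to polymorph
    B with that event's ``conversion_prob``.  With no events this is the
    continuously-aggregated control.
    """
    if state0 is None:
        # all seed mass starts as polymorph A; number from seed mean length
        # is supplied through P_uM by the caller when it matters; default:
        # seeds short enough that the A1-end mean length is set elsewhere.
        raise ValueError("state0 is required (seed number sets the kinetics)")
    dt = 1.0 / schedule.sampling_rate
    segments: list[StateTrajectory] = []
    state = state0
    t0 = 0.0
    for i, (label, duration) in enumerate(schedule.phases):
        ev = schedule.event_before_phase(i)
        conv = 0.0
        if ev is not None:
            state = apply_sonication_event(state, ev, rho=params.rho)
            conv = ev.conversion_prob
        seg = simulate_phase(
            conditions, params, obs, state, duration, dt,
            conv_frac=conv, phase_label=label, t_offset=t0, rng=rng,
        )
        state = seg.final_state()
        t0 += duration
        segments.append(seg)

    def cat(attr):
        parts = [getattr(segments[0], attr)]
        for s in segments[1:]:
            parts.append(getattr(s, attr)[1:])  # drop duplicated boundary
        return np.concatenate(parts)

    return StateTrajectory(
        times=cat("times"), m=cat("m"), M_A=cat("M_A"), M_B=cat("M_B"),
        P=cat("P"), F=cat("F"), phase_labels=cat("phase_labels"),
        c_tot=conditions.c_tot,
    )
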