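"""Stochastic, length-explicit simulator of fibril populations.

Every fibril is an integer monomer count; free monomer is an integer
pool.  Three reaction channels operate between sonication pulses:

- elongation: each fibril gains one monomer per end at rate
  n_ends·k+·m (m the free-monomer concentration);
- depolymerisation: each fibril loses one monomer per end at rate
  n_ends·k+·m_eq, so detailed balance places the stationary monomer
  level at the solubility m_eq;
- breakage: a fibril of length L with e(L) breakable bonds fragments at
  rate k_b·e(L)·(L−1)^γ, where only bonds leaving both daughters at or
  above the minimum fragment size L_min are breakable and γ ≥ 0 tilts
  breakage towards long fibrils.

The kernel is an exact Gillespie simulation at test scale, switching to
tau-leaping (Poisson event batches) when the expected number of events
is large.  Monomer conservation is exact and integer.

Sonication pulses are modelled separately (:func:`sonicate_population`)
as a sequential left-to-right scan over breakable bonds, each breaking
independently with a per-pulse probability; the scan recurses into the
remaining fragment so the minimum-fragment floor can never be violated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import RHO_DEFAULT
from .units import S_PER_H, kplus_to_per_uM_per_h

__all__ = [
    "FibrilPopulation",
    "PopulationParameters",
    "simulate_population",
    "sonicate_population",
    "sample_lengths",
]


@dataclass
class FibrilPopulation:
    """Explicit fibril list: lengths in monomers, polymorph label per fibril."""

    lengths: np.ndarray             # int monomer counts
    polymorph: np.ndarray           # 'A'/'B' per fibril
    free_monomer: int               # monomer count
    volume_scale: float = 100.0     # monomers per μM (sets the system volume)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if self.polymorph is None or len(self.polymorph) == 0:
            self.polymorph = np.full(self.lengths.size, "A", dtype=object)
        self.polymorph = np.asarray(self.polymorph, dtype=object)
        if self.polymorph.size != self.lengths.size:
            raise ValueError("polymorph labels must match lengths")
        if self.free_monomer < 0:
            raise ValueError("free_monomer must be non-negative")
        if self.lengths.size and self.lengths.min() < 2:
            raise ValueError("fibrils must contain at least 2 monomers")

    @property
    def n_fibrils(self) -> int:
        return int(self.lengths.size)

    @property
    def total_monomers(self) -> int:
        return int(self.free_monomer + self.lengths.sum())

    @property
    def monomer_conc_uM(self) -> float:
        return self.free_monomer / self.volume_scale

    @property
    def fibril_mass_uM(self) -> float:
        return float(self.lengths.sum()) / self.volume_scale

    def mean_length_nm(self, rho: float = RHO_DEFAULT) -> float:
        if self.n_fibrils == 0:
            raise ValueError("empty population")
        return float(self.lengths.mean()) / rho

    @classmethod
    def from_concentrations(
        cls,
        n_fibrils: int,
        mean_length_monomers: float,
        monomer_uM: float,
        volume_scale: float = 100.0,
        rng: np.random.Generator | None = None,
        distribution: str = "exponential",
        L_min: int = 2,
    ) -> "FibrilPopulation":
        """Build a seed population with exponential (or constant) lengths."""
        rng = rng or np.random.default_rng(0)
        if distribution == "exponential":
            lengths = L_min + rng.exponential(
                max(mean_length_monomers - L_min, 1.0), size=n_fibrils
            )
        elif distribution == "constant":
            lengths = np.full(n_fibrils, mean_length_monomers)
        else:
            raise ValueError(f"unknown distribution {distribution!r}")
        return cls(
            lengths=np.maximum(np.round(lengths), L_min).astype(np.int64),
            polymorph=np.full(n_fibrils, "A", dtype=object),
            free_monomer=int(round(monomer_uM * volume_scale)),
            volume_scale=volume_scale,
        )


@dataclass(frozen=True)
class PopulationParameters:
    """Rates and constraints for the length-explicit simulator."""

    k_plus: float = 2087.0              # M⁻¹ s⁻¹
    m_eq: float = 10.5                  # μM
    n_ends: int = 2
    rho: float = RHO_DEFAULT            # monomers per nm
    breakage_rate_per_bond: float = 0.0  # s⁻¹
    breakage_length_exponent: float = 0.0  # γ
    L_min_monomers: int = 30
    sonic_bond_break_prob: float = 0.005

    def __post_init__(self) -> None:
        if self.L_min_monomers < 2:
            raise ValueError("L_min_monomers must be >= 2")
        if not (0 <= self.sonic_bond_break_prob <= 1):
            raise ValueError("sonic_bond_break_prob must be in [0, 1]")
        if self.breakage_length_exponent < 0:
            raise ValueError("breakage_length_exponent must be >= 0")


def _eligible_bonds(lengths: np.ndarray, L_min: int) -> np.ndarray:
    """Number of bonds per fibril whose scission leaves both fragments >= L_min."""
    return np.maximum(lengths - 2 * L_min + 1, 0)


def _breakage_rates_per_h(lengths, params: PopulationParameters) -> np.ndarray:
    e = _eligible_bonds(lengths, params.L_min_monomers)
    kb_h = params.breakage_rate_per_bond * S_PER_H
    if params.breakage_length_exponent > 0:
        return kb_h * e * np.maximum(lengths - 1, 1) ** params.breakage_length_exponent
    return kb_h * e.astype(float)


def simulate_population(
    pop0: FibrilPopulation,
    params: PopulationParameters,
    duration: float,
    rng_seed: int,
    tau_leap_threshold: float = 50_000.0,
) -> FibrilPopulation:
    """Advance a fibril population by ``duration`` hours.

    Exact stochastic simulation when the expected event count is modest;
    tau-leaping (Poisson batches over 1% of the remaining interval,
    capped so leaps stay well inside the monomer pool) otherwise.
    """
    if pop0.n_fibrils == 0 and pop0.free_monomer == 0:
        raise ValueError("nothing to simulate: empty population, no monomer")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = np.random.default_rng(rng_seed)
    lengths = pop0.lengths.copy()
    poly = pop0.polymorph.copy()
    free = int(pop0.free_monomer)
    vs = pop0.volume_scale
    total0 = pop0.total_monomers

    a_el = params.n_ends * kplus_to_per_uM_per_h(params.k_plus)  # μM⁻¹ h⁻¹
    no_breakage = params.breakage_rate_per_bond == 0.0
    _zero = np.zeros(0)

    def rates():
        m_uM = free / vs
        r_el = a_el * m_uM * lengths.size          # h⁻¹, total elongation
        r_de = a_el * params.m_eq * lengths.size   # h⁻¹, total depolymerisation
        if no_breakage:
            return r_el, r_de, _zero
        return r_el, r_de, _breakage_rates_per_h(lengths, params)

    t = 0.0
    r_el, r_de, r_br = rates()
    expected = (r_el + r_de + float(r_br.sum())) * duration
    use_leap = expected > tau_leap_threshold

    if not use_leap:
        while t < duration and lengths.size:
            r_el, r_de, r_br = rates()
            r_br_tot = float(r_br.sum())
            r_tot = r_el + r_de + r_br_tot
            if r_tot <= 0:
                break
            t += rng.exponential(1.0 / r_tot)
            if t >= duration:
                break
            u = rng.uniform(0, r_tot)
            if u < r_el:
                if free > 0:
                    i = rng.integers(lengths.size)
                    lengths[i] += 1
                    free -= 1
            elif u < r_el + r_de:
                i = rng.integers(lengths.size)
                if lengths[i] > 2:
                    lengths[i] -= 1
                    free += 1
            else:
                i = int(np.searchsorted(np.cumsum(r_br), u - r_el - r_de))
                L = int(lengths[i])
                e = L - 2 * params.L_min_monomers + 1
                if e > 0:
                    cut = params.L_min_monomers + int(rng.integers(e))
                    lengths[i] = cut
                    lengths = np.append(lengths, L - cut)
                    poly = np.append(poly, poly[i])
    else:
        while t < duration and lengths.size:
            r_el, r_de, r_br = rates()
            r_br_tot = float(r_br.sum())
            r_tot = r_el + r_de + r_br_tot
            if r_tot <= 0:
                break
            dt = min(duration - t, max(duration * 0.01, 10.0 / r_tot))
            # keep the leap small relative to the monomer pool
            if r_el * dt > 0.1 * max(free, 1):
                dt = max(0.1 * free / r_el, 1e-9)
                dt = min(dt, duration - t)
            n_el = min(rng.poisson(r_el * dt), free)
            n_de = rng.poisson(r_de * dt)
            # distribute additions/removals uniformly over fibrils
            add = rng.multinomial(n_el, np.full(lengths.size, 1 / lengths.size))
            rem = rng.multinomial(n_de, np.full(lengths.size, 1 / lengths.size))
            rem = np.minimum(rem, lengths - 2)  # never shrink below 2
            lengths = lengths + add - rem
            free += int(rem.sum()) - int(add.sum())
            n_br = rng.poisson(r_br * dt)
            for i in np.nonzero(n_br)[0]:
                L = int(lengths[i])
                e = L - 2 * params.L_min_monomers + 1
                if e > 0:
                    cut = params.L_min_monomers + int(rng.integers(e))
                    lengths[i] = cut
                    lengths = np.append(lengths, L - cut)
                    poly = np.append(poly, poly[i])
            t += dt

    out = FibrilPopulation(
        lengths=lengths, polymorph=poly, free_monomer=free, volume_scale=vs
    )
    assert out.total_monomers == total0, "monomer conservation violated"
    return out


def _sonicate_one(L: int, p: float, L_min: int, rng) -> list[int]:
    """Sequential scan of breakable bonds from the left; each breaks with
    probability p, and the scan continues within the right fragment."""
    frags: list[int] = []
    while True:
        e = L - 2 * L_min + 1
        if e <= 0 or p <= 0:
            frags.append(L)
            return frags
        hits = rng.random(e) < p
        idx = np.nonzero(hits)[0]
        if idx.size == 0:
            frags.append(L)
            return frags
        cut = L_min + int(idx[0])
        frags.append(cut)
        L = L - cut


def sonicate_population(
    pop: FibrilPopulation,
    params: PopulationParameters,
    pulses: int = 1,
    rng_seed: int = 0,
) -> FibrilPopulation:
    """Fragment a population with ``pulses`` ultrasonication pulses.

    Each pulse scans every fibril's breakable bonds (those leaving both
    fragments ≥ L_min) and breaks each with ``sonic_bond_break_prob``,
    optionally scaled up for long fibrils when the breakage length
    exponent γ > 0.  Conservation is exact; the mean length cannot
    increase.
    """
    if pulses < 1:
        raise ValueError("pulses must be >= 1")
    rng = np.random.default_rng(rng_seed)
    lengths = pop.lengths
    poly = pop.polymorph
    total0 = pop.total_monomers
    L_min = params.L_min_monomers
    gamma = params.breakage_length_exponent
    p0 = params.sonic_bond_break_prob
    for _ in range(pulses):
        new_lengths: list[int] = []
        new_poly: list = []
        for L, lab in zip(lengths, poly):
            p = p0
            if gamma > 0:
                p = min(1.0, p0 * ((L - 1) / max(2 * L_min - 1, 1)) ** gamma)
            frags = _sonicate_one(int(L), p, L_min, rng)
            new_lengths.extend(frags)
            new_poly.extend([lab] * len(frags))
        lengths = np.asarray(new_lengths, dtype=np.int64)
        poly = np.asarray(new_poly, dtype=object)
    out = FibrilPopulation(
        lengths=lengths, polymorph=poly,
        free_monomer=pop.free_monomer, volume_scale=pop.volume_scale,
    )
    assert out.total_monomers == total0, "monomer conservation violated"
    return out


def disassemble_population(
    pop: FibrilPopulation,
    fraction: float,
    params: PopulationParameters,
    rng_seed: int = 0,
) -> FibrilPopulation:
    """Release a fraction of fibril mass to free monomer from fibril ends.

    Emulates the transient sonication-induced disassembly that precedes
    regrowth: each fibril sheds monomers pro rata (never below L_min),
    and the shed monomers join the free pool.  Integer conservation is
    exact.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    total0 = pop.total_monomers
    lengths = pop.lengths.copy()
    # pro-rata target with stochastic rounding, clipped at the floor
    shed_f = fraction * lengths
    shed = np.floor(shed_f).astype(np.int64)
    shed += (rng.random(lengths.size) < (shed_f - shed)).astype(np.int64)
    shed = np.minimum(shed, np.maximum(lengths - params.L_min_monomers, 0))
    lengths = lengths - shed
    out = FibrilPopulation(
        lengths=lengths, polymorph=pop.polymorph.copy(),
        free_monomer=pop.free_monomer + int(shed.sum()),
        volume_scale=pop.volume_scale,
    )
    assert out.total_monomers == total0, "monomer conservation violated"
    return out


def sample_lengths(
    pop: FibrilPopulation,
    n: int,
    rng_seed: int,
    rho: float = RHO_DEFAULT,
    replace_draw: bool | None = None,
) -> np.ndarray:
    """Uniform random sample of ``n`` fibril lengths, converted to nm.

    Mimics counting fibrils in AFM fields of view.  Sampling is without
    replacement when the population is large enough, with replacement
    otherwise (or when forced via ``replace_draw``).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if pop.n_fibrils == 0:
        raise ValueError("empty population")
    if replace_draw is None:
        replace_draw = n > pop.n_fibrils
    rng = np.random.default_rng(rng_seed)
    picked = rng.choice(pop.lengths, size=n, replace=replace_draw)
    return picked.astype(float) / rho
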