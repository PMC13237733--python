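"""Measurement-to-parameter pipeline for seeded aggregation assays.

Chains the quantities a plate-reader experiment actually yields into
kinetic parameters:

1. single-exponential fits to ThT growth phases give the relaxation
   time constant τ;
2. supernatant A280 readings give residual monomer and hence fibril
   yield (Beer–Lambert, ε280 = 5960 M⁻¹cm⁻¹ for α-synuclein);
3. fibril mass and AFM mean length give the fibril number
   concentration P;
4. τ and P give the elongation rate constant k+ = 1/(n_ends·τ·P), and
   k+ with the net monomer supply gives the elongation speed in nm/min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .units import M_PER_UM, hours_to_seconds

__all__ = [
    "ThTTrajectory",
    "ExponentialFit",
    "AbsorbanceMeasurement",
    "YieldResult",
    "RateEstimate",
    "fit_single_exponential",
    "is_fittable",
    "residual_monomer_conc",
    "fibril_yield",
    "number_concentration",
    "estimate_elongation_rate_constant",
    "elongation_speed",
]

logger = logging.getLogger(__name__)

EPSILON_280 = 5960.0  # M⁻¹ cm⁻¹, α-synuclein tyrosine absorbance


@dataclass
class ThTTrajectory:
    """One well's fluorescence series within one aggregation phase."""

    times: np.ndarray   # h, strictly increasing
    values: np.ndarray  # a.u.
    replicate_id: str = ""
    variant: str = ""
    phase_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ExponentialFit:
    """F(t) = F_inf − (F_inf − F0)·exp(−(t − t_start)/τ) on a fit window."""

    F0: float
    F_inf: float
    tau: float          # h
    r_squared: float
    fit_window: tuple[float, float]
    converged: bool


@dataclass(frozen=True)
class AbsorbanceMeasurement:
    a280: float
    pathlength: float = 1.0           # cm
    epsilon: float = EPSILON_280      # M⁻¹ cm⁻¹

    def __post_init__(self) -> None:
        if self.a280 < 0:
            raise ValueError("a280 must be non-negative")
        if self.epsilon <= 0 or self.pathlength <= 0:
            raise ValueError("epsilon and pathlength must be positive")


@dataclass(frozen=True)
class YieldResult:
    residual_monomer: float  # μM
    c_tot: float             # μM
    yield_fraction: float    # 0–1

    @property
    def fibril_mass(self) -> float:
        """Polymerised mass in μM."""
        return self.c_tot - self.residual_monomer

    @property
    def yield_percent(self) -> float:
        return 100.0 * self.yield_fraction


@dataclass(frozen=True)
class RateEstimate:
    P: float                 # fibril number concentration, M
    k_plus: float            # M⁻¹ s⁻¹
    elongation_speed: float  # nm/min
    inputs_used: dict


def robust_noise_scale(values: np.ndarray) -> float:
    """Robust σ of point-to-point noise from first differences.

    1.4826·MAD of ΔF, divided by √2 because differencing doubles the
    noise variance.
    """
    d = np.diff(np.asarray(values, dtype=float))
    mad = np.median(np.abs(d - np.median(d)))
    return 1.4826 * mad / np.sqrt(2.0)


def _robust_rise(values: np.ndarray, kernel: int = 31) -> float:
    """Total signal rise, measured noise-robustly.

    Start level is the median of the first ``kernel`` points; the top
    level is the maximum of a running median restricted to the interior
    (edges of a median filter are padding-contaminated).
    """
    from scipy.signal import medfilt

    n = values.size
    k = min(kernel, n if n % 2 else n - 1)
    start = float(np.median(values[: max(k, 1)]))
    if k < 3:
        return float(values.max() - start)
    s = medfilt(values, k)
    h = k // 2
    interior = s[h : n - h] if n > 2 * h else s
    return float(interior.max() - start)


def is_fittable(traj: ThTTrajectory, k: float = 3.0) -> bool:
    """Curve-selection rule: a phase is fit only if its total rise exceeds
    ``k`` times the robust noise scale (curves with no clear exponential
    increase are omitted, as is standard practice for these assays).
    The rise is measured on a median-smoothed series so that plateau
    noise excursions cannot masquerade as growth."""
    rise = _robust_rise(traj.values)
    return rise > k * max(robust_noise_scale(traj.values), 1e-12)


def fit_single_exponential(
    traj: ThTTrajectory,
    window: tuple[float, float] | str | None = None,
    growth_window_taus: float = 5.0,
) -> ExponentialFit:
    """Bounded nonlinear least-squares fit of a single exponential rise.

    The window defaults to the whole trajectory.  ``window="auto"``
    performs a two-pass fit: a first fit over the whole phase estimates
    τ, then the fit is repeated on [t0, t0 + growth_window_taus·τ̂] so
    that a long stationary plateau (or its slow decline) does not
    dominate the residuals of a fast growth phase.  Returns
    ``converged=False`` (never raises) when the optimiser fails or τ
    sticks at its bounds.
    """
    t_all, F_all = traj.times, traj.values
    if window == "auto":
        first = fit_single_exponential(traj, window=None)
        if not first.converged:
            return first
        end = float(t_all[0]) + growth_window_taus * first.tau
        if end >= float(t_all[-1]):
            return first
        sel = t_all <= end
        if sel.sum() < 8:
            return first
        second = fit_single_exponential(
            traj, window=(float(t_all[0]), end)
        )
        return second if second.converged else first

    t, F = t_all, F_all
    if window is None:
        window = (float(t[0]), float(t[-1]))
    sel = (t >= window[0]) & (t <= window[1])
    t, F = t[sel], F[sel]
    if t.size < 8:
        raise ValueError("need at least 8 points in the fit window")
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite fluorescence values in window")

    t0 = t[0]
    dt = float(np.min(np.diff(t)))
    span = float(t[-1] - t[0])
    tau_lo, tau_hi = dt, 10.0 * span

    F0_init = float(F[0])
    Finf_init = float(np.percentile(F, 95))
    # time to half rise sets the initial tau
    half = F0_init + 0.5 * (Finf_init - F0_init)
    above = np.nonzero(F >= half)[0]
    t_half = float(t[above[0]] - t0) if above.size else span / 2
    tau_init = np.clip(t_half / np.log(2.0), tau_lo * 1.01, tau_hi * 0.99)

    def resid(p):
        F0, Finf, tau = p
        return Finf - (Finf - F0) * np.exp(-(t - t0) / tau) - F

    scale = max(abs(Finf_init), abs(F0_init), 1.0)
    try:
        res = least_squares(
            resid,
            x0=[F0_init, Finf_init, float(tau_init)],
            bounds=([-np.inf, -np.inf, tau_lo], [np.inf, np.inf, tau_hi]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        ok = res.success
        F0_hat, Finf_hat, tau_hat = res.x
    except Exception:  # pragma: no cover - defensive
        ok = False
        F0_hat, Finf_hat, tau_hat = F0_init, Finf_init, float(tau_init)

    ss_res = float(np.sum(resid([F0_hat, Finf_hat, tau_hat]) ** 2))
    ss_tot = float(np.sum((F - np.mean(F)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    at_bounds = tau_hat <= tau_lo * (1 + 1e-6) or tau_hat >= tau_hi * (1 - 1e-6)
    degenerate = abs(Finf_hat - F0_hat) <= 1e-9 * scale or ss_tot == 0
    converged = bool(ok and not at_bounds and not degenerate)
    return ExponentialFit(
        F0=float(F0_hat), F_inf=float(Finf_hat), tau=float(tau_hat),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        fit_window=(float(t[0]), float(t[-1])), converged=converged,
    )


def residual_monomer_conc(meas: AbsorbanceMeasurement) -> float:
    """Residual monomer concentration (μM) by Beer–Lambert."""
    return meas.a280 / (meas.epsilon * meas.pathlength) / M_PER_UM


def fibril_yield(residual: float, c_tot: float) -> YieldResult:
    """Fraction of source protein converted into pelletable fibrils."""
    if c_tot <= 0:
        raise ValueError("c_tot must be positive")
    if residual < 0:
        logger.warning("negative residual monomer %.3g μM clipped to 0", residual)
        residual = 0.0
    if residual > c_tot:
        if residual > 1.05 * c_tot:
            raise ValueError(
                f"residual monomer {residual:.3g} μM exceeds total protein "
                f"{c_tot:.3g} μM by more than 5%: inconsistent measurement"
            )
        logger.warning("residual %.3g μM > c_tot, clipped", residual)
        residual = c_tot
    return YieldResult(
        residual_monomer=residual, c_tot=c_tot,
        yield_fraction=(c_tot - residual) / c_tot,
    )


def number_concentration(
    fibril_mass: float, mean_length_nm: float, rho: float
) -> float:
    """Fibril number concentration P (M) from mass (μM) and mean length.

    A fibril of mean length L nm contains L·rho monomers, so
    P = (fibril_mass·10⁻⁶)/(L·rho).
    """
    if mean_length_nm <= 0:
        raise ValueError("mean length must be positive")
    if fibril_mass <= 0 or rho <= 0:
        raise ValueError("fibril_mass and rho must be positive")
    return fibril_mass * M_PER_UM / (mean_length_nm * rho)


def estimate_elongation_rate_constant(
    fit: ExponentialFit,
    yield_result: YieldResult,
    mean_length_nm: float,
    rho: float,
    n_ends: int = 2,
    m_start: float | None = None,
    m_eq: float | None = None,
) -> RateEstimate:
    """Elongation rate constant from the fitted τ and the fibril census.

    P comes from the yield's fibril mass and the AFM mean length;
    k+ = 1/(n_ends·τ·P) with τ in seconds.  When the starting and
    equilibrium monomer concentrations are supplied the per-fibril
    elongation speed (nm/min) is reported as well.
    """
    if not fit.converged:
        raise ValueError("cannot estimate a rate from a non-converged fit")
    P = number_concentration(yield_result.fibril_mass, mean_length_nm, rho)
    tau_s = hours_to_seconds(fit.tau)
    k_plus = 1.0 / (n_ends * tau_s * P)
    if m_start is None:
        m_start = yield_result.c_tot
    if m_eq is None:
        m_eq = yield_result.residual_monomer
    speed = elongation_speed(k_plus, m_start, m_eq, rho, n_ends)
    return RateEstimate(
        P=P, k_plus=k_plus, elongation_speed=speed,
        inputs_used=dict(
            tau_h=fit.tau, yield_fraction=yield_result.yield_fraction,
            mean_length_nm=mean_length_nm, rho=rho, n_ends=n_ends,
            m_start=m_start, m_eq=m_eq,
        ),
    )


def elongation_speed(
    k_plus: float, m_start: float, m_eq: float, rho: float, n_ends: int = 2
) -> float:
    """Net fibril growth speed in nm/min at the start-of-phase monomer level.

    Monomer additions per fibril per second are n_ends·k+·(m_start − m_eq)
    (concentrations in M); dividing by rho converts to nm/s.
    """
    if m_start < m_eq:
        raise ValueError("m_start must be >= m_eq")
    per_s = n_ends * k_plus * (m_start - m_eq) * M_PER_UM
    return per_s / rho * 60.0
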