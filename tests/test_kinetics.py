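"""Moment-model tests: closed form, conservation, events, schedules."""

import numpy as np
import pytest

from synkin import (
    AssayConditions,
    KineticParameters,
    ObservationParameters,
    PhaseState,
    Schedule,
    SonicationEvent,
    apply_sonication_event,
    closed_form_monomer,
    closed_form_tau_h,
    get_fixture,
    simulate_phase,
    simulate_schedule,
    tht_signal,
)
from synkin.kinetics import RHO_DEFAULT

from conftest import make_state


class TestClosedForm:
    def test_equilibrium_is_fixed_point(self, wt_conditions):
        params = KineticParameters(k_plus=2087.0, m_eq=10.0)
        for t in (0.0, 1.0, 100.0):
            m = closed_form_monomer(wt_conditions, params, P=1e-8, t=t, m0=10.0)
            assert m == pytest.approx(10.0)

    def test_tau_definition(self, wt_conditions, wt_params):
        """At t = τ the supersaturation has decayed by exactly 1/e."""
        P = 1e-8
        tau = closed_form_tau_h(wt_params, P)
        m = closed_form_monomer(wt_conditions, wt_params, P, tau, m0=52.5)
        assert m == pytest.approx(10.5 + 42.0 * np.exp(-1.0), rel=1e-12)

    def test_wt_reference_time_constant(self, wt_params):
        # 1/(2 · 2087 M⁻¹s⁻¹ · 1.41e-8 M) = 16991 s = 4.72 h
        tau = closed_form_tau_h(wt_params, P=1.41e-8)
        assert tau * 3600 == pytest.approx(1.0 / (2 * 2087.0 * 1.41e-8), rel=1e-12)
        assert tau == pytest.approx(4.72, abs=0.005)

    def test_nonpositive_fibril_number_rejected(self, wt_conditions, wt_params):
        with pytest.raises(ValueError, match="fibril ends"):
            closed_form_monomer(wt_conditions, wt_params, P=0.0, t=1.0)

    def test_monotone_decay(self, wt_conditions, wt_params):
        t = np.linspace(0, 50, 200)
        m = closed_form_monomer(wt_conditions, wt_params, 1.41e-8, t, m0=50.0)
        assert np.all(np.diff(m) <= 0)


class TestSimulatePhase:
    def test_matches_closed_form_in_elongation_limit(
        self, wt_conditions, wt_params, unit_obs, wt_state
    ):
        traj = simulate_phase(
            wt_conditions, wt_params, unit_obs, wt_state, duration=96.0, dt=1 / 6
        )
        expected = closed_form_monomer(
            wt_conditions, wt_params, wt_state.P, traj.times, m0=wt_state.m
        )
        assert np.max(np.abs(traj.m - expected)) / wt_conditions.c_tot <= 1e-6

    def test_closed_form_equivalence_random_draws(self):
        """ODE ≡ closed form to 1e-6 relative for 100 random parameter sets."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            cond = AssayConditions(
                monomer_conc=rng.uniform(10, 100), seed_conc=rng.uniform(0.5, 10)
            )
            params = KineticParameters(
                k_plus=rng.uniform(200, 8000),
                m_eq=rng.uniform(0, 0.8) * cond.monomer_conc,
            )
            state = PhaseState(
                m=cond.monomer_conc, M_A=cond.seed_conc, M_B=0.0,
                P_uM=rng.uniform(1e-4, 1e-1),
            )
            dur = rng.uniform(5, 60)
            traj = simulate_phase(cond, params, ObservationParameters(),
                                  state, dur, dt=dur / 50)
            expected = closed_form_monomer(cond, params, state.P, traj.times,
                                           m0=state.m)
            assert np.max(np.abs(traj.m - expected)) / cond.c_tot <= 1e-6

    def test_mass_conservation(self, wt_conditions, wt_params, unit_obs, wt_state):
        traj = simulate_phase(
            wt_conditions, wt_params, unit_obs, wt_state, duration=96.0, dt=1 / 6
        )
        traj.check_mass_balance(rtol=1e-9)
        assert np.all(traj.m >= 0) and np.all(traj.M_A >= 0)
        assert np.all(traj.P[traj.M_A + traj.M_B > 0] > 0)

    def test_steady_state_attained(self, wt_conditions, wt_params, unit_obs, wt_state):
        tau = closed_form_tau_h(wt_params, wt_state.P)
        traj = simulate_phase(
            wt_conditions, wt_params, unit_obs, wt_state, duration=12 * tau,
            dt=tau / 5,
        )
        assert abs(traj.m[-1] - wt_params.m_eq) / wt_params.m_eq <= 1e-3

    def test_net_depolymerization_below_solubility(self, unit_obs):
        """Starting below the solubility, fibrils shed mass (dm/dt > 0)."""
        cond = AssayConditions(monomer_conc=5.0, seed_conc=20.0)
        params = KineticParameters(k_plus=2087.0, m_eq=10.5)
        state = PhaseState(m=5.0, M_A=20.0, M_B=0.0, P_uM=0.05)
        traj = simulate_phase(cond, params, unit_obs, state, 20.0, 0.5)
        M = traj.M_A + traj.M_B
        assert M[-1] < M[0]
        assert traj.m[-1] == pytest.approx(10.5, rel=1e-3)
        traj.check_mass_balance()

    def test_invalid_steps_rejected(self, wt_conditions, wt_params, unit_obs, wt_state):
        with pytest.raises(ValueError):
            simulate_phase(wt_conditions, wt_params, unit_obs, wt_state, -1.0, 0.1)
        with pytest.raises(ValueError):
            simulate_phase(wt_conditions, wt_params, unit_obs, wt_state, 1.0, 0.0)


class TestSonicationEvent:
    def test_null_event_identity(self):
        state = make_state(m=10.5, M_A=42.0, M_B=0.0, mean_length_nm=700.0)
        ev = SonicationEvent(time=96.0, length_divisor=1.0,
                             min_mean_length=1.0, disassembly_fraction=0.0)
        out = apply_sonication_event(state, ev)
        assert out.m == state.m
        assert out.M_A == state.M_A
        assert out.P_uM == pytest.approx(state.P_uM, rel=1e-12)

    def test_disassembly_arithmetic(self):
        state = make_state(m=10.5, M_A=42.0, M_B=0.0, mean_length_nm=700.0)
        ev = SonicationEvent(time=96.0, length_divisor=1.0,
                             min_mean_length=1.0, disassembly_fraction=0.1)
        out = apply_sonication_event(state, ev)
        assert out.m == pytest.approx(14.7)
        assert out.M_tot == pytest.approx(37.8)
        # exact conservation
        assert out.m + out.M_tot == pytest.approx(state.m + state.M_tot, rel=1e-15)

    def test_length_floor_binds(self):
        state = make_state(m=10.5, M_A=42.0, M_B=0.0, mean_length_nm=700.0)
        ev = SonicationEvent(time=96.0, length_divisor=10.0, min_mean_length=150.0)
        out = apply_sonication_event(state, ev)
        assert out.mean_length_nm() == pytest.approx(150.0)

    def test_proportional_removal_from_both_polymorphs(self):
        state = make_state(m=10.5, M_A=30.0, M_B=12.0, mean_length_nm=700.0)
        ev = SonicationEvent(time=96.0, disassembly_fraction=0.25)
        out = apply_sonication_event(state, ev)
        assert out.M_A / out.M_B == pytest.approx(30.0 / 12.0, rel=1e-12)

    def test_empty_state_rejected(self):
        state = PhaseState(m=52.5, M_A=0.0, M_B=0.0, P_uM=0.0)
        with pytest.raises(ValueError, match="empty"):
            apply_sonication_event(state, SonicationEvent(time=96.0))


class TestSchedule:
    def test_event_must_sit_at_phase_boundary(self):
        with pytest.raises(ValueError, match="boundary"):
            Schedule(events=(SonicationEvent(time=50.0),))

    def test_excitation_time_and_seed_fraction(self):
        # 383 h × 6 points/h × 20 μs = 0.046 s of cumulative excitation
        sched = Schedule()
        assert sched.total_duration == pytest.approx(383.0)
        assert sched.total_excitation_time_s() == pytest.approx(0.046, abs=5e-4)
        cond = AssayConditions(monomer_conc=50.0, seed_conc=2.5)
        assert cond.seed_fraction == pytest.approx(0.05)
        assert cond.c_tot == pytest.approx(52.5)

    def test_no_event_schedule_equals_continuous_control(self, wt):
        fx = wt
        sched = fx.schedule(sonicated=True)
        # identity events: no disassembly, no fragmentation, no conversion
        null_events = tuple(
            SonicationEvent(time=ev.time, length_divisor=1.0,
                            min_mean_length=1e-9, disassembly_fraction=0.0,
                            conversion_prob=0.0)
            for ev in sched.events
        )
        null_sched = Schedule(phases=sched.phases, events=null_events,
                              sampling_rate=sched.sampling_rate)
        obs = fx.observation_params(noise_cv=0.0)
        a = simulate_schedule(fx.conditions(), fx.kinetic_params(), obs,
                              null_sched, state0=fx.initial_state())
        b = simulate_schedule(fx.conditions(), fx.kinetic_params(), obs,
                              fx.schedule(sonicated=False),
                              state0=fx.initial_state())
        assert abs(a.F[-1] - b.F[-1]) / b.F[-1] <= 1e-6

    def test_conversion_raises_endpoint_at_constant_mass(self):
        """With βB > βA and conversion on, end-of-phase ThT rises across
        rounds while total fibril mass stays constant within 1%."""
        fx = get_fixture("A53T")
        traj = simulate_schedule(
            fx.conditions(), fx.kinetic_params(),
            fx.observation_params(noise_cv=0.0), fx.schedule(sonicated=True),
            state0=fx.initial_state(),
        )
        ends = {}
        for lbl in ("A2", "A3", "A4"):
            idx = np.nonzero(traj.phase_labels == lbl)[0][-1]
            ends[lbl] = (traj.F[idx], traj.M_A[idx] + traj.M_B[idx])
        assert ends["A2"][0] < ends["A3"][0] < ends["A4"][0]
        masses = [v[1] for v in ends.values()]
        assert (max(masses) - min(masses)) / max(masses) <= 0.01

    def test_yield_constancy_across_rounds(self, wt):
        traj = simulate_schedule(
            wt.conditions(), wt.kinetic_params(),
            wt.observation_params(noise_cv=0.0), wt.schedule(sonicated=True),
            state0=wt.initial_state(),
        )
        masses = []
        for lbl in ("A1", "A2", "A3", "A4"):
            idx = np.nonzero(traj.phase_labels == lbl)[0][-1]
            masses.append(traj.M_A[idx] + traj.M_B[idx])
        assert (max(masses) - min(masses)) / max(masses) <= 0.01
        traj.check_mass_balance()

    def test_a53t_endpoint_gain_matches_observed(self):
        """Sonicated A53T finishes 58% above its continuous control."""
        fx = get_fixture("A53T")
        son = simulate_schedule(
            fx.conditions(), fx.kinetic_params(),
            fx.observation_params(noise_cv=0.0), fx.schedule(sonicated=True),
            state0=fx.initial_state(),
        )
        ctl = simulate_schedule(
            fx.conditions(), fx.kinetic_params(),
            fx.observation_params(noise_cv=0.0), fx.schedule(sonicated=False),
            state0=fx.initial_state(),
        )
        gain = 100.0 * (son.F[-1] - ctl.F[-1]) / ctl.F[-1]
        assert gain == pytest.approx(58.0, abs=3.0)


class TestThTSignal:
    def test_baseline_only_when_no_fibrils(self):
        obs = ObservationParameters(beta_A=1.0, beta_B=2.0, baseline=7.0)
        assert tht_signal(0.0, 0.0, obs) == pytest.approx(7.0)

    def test_identity_observation(self):
        obs = ObservationParameters(beta_A=1.0, beta_B=1.0)
        assert tht_signal(30.0, 12.0, obs) == pytest.approx(42.0)

    def test_brightness_linearity_on_conversion(self):
        obs = ObservationParameters(beta_A=1.0, beta_B=2.0)
        all_a = tht_signal(42.0, 0.0, obs)
        all_b = tht_signal(0.0, 42.0, obs)
        assert all_b == pytest.approx(2 * all_a)

    def test_post_plateau_decline(self):
        obs = ObservationParameters(beta_A=1.0, beta_B=1.0, decline_rate=0.01)
        f0 = tht_signal(42.0, 0.0, obs, t_since_plateau=0.0)
        f1 = tht_signal(42.0, 0.0, obs, t_since_plateau=100.0)
        assert f1 == pytest.approx(f0 * np.exp(-1.0))
        # decline clock does not run before the plateau
        assert tht_signal(42.0, 0.0, obs, t_since_plateau=-5.0) == pytest.approx(f0)

    def test_negative_mass_rejected(self, unit_obs):
        with pytest.raises(ValueError):
            tht_signal(-1.0, 0.0, unit_obs)


class TestValidation:
    def test_invariant_violations_raise(self):
        with pytest.raises(ValueError):
            AssayConditions(monomer_conc=0.0)
        with pytest.raises(ValueError):
            KineticParameters(k_plus=-1.0)
        with pytest.raises(ValueError):
            KineticParameters(n_ends=3)
        with pytest.raises(ValueError):
            ObservationParameters(beta_A=2.0, beta_B=1.0)
        with pytest.raises(ValueError):
            SonicationEvent(time=96.0, disassembly_fraction=1.0)
        with pytest.raises(ValueError):
            SonicationEvent(time=96.0, length_divisor=0.5)
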