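"""Pointwise model functions: frozen oracle values, invariants, derivatives."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import epidyn.model_core as mc
from epidyn.model_core import (ModelParameters, ModelState, ProtocolSchedule,
                               STATE_FIELDS)

P = ModelParameters()
SCHED = ProtocolSchedule()
V_GRID = np.linspace(-120.0, 20.0, 281)


def hp(expr):
    """Extended-precision reference evaluation."""
    return float(expr)


# ---------------------------------------------------------------------------
# Sigmoids and algebraic functions against frozen high-precision values
# ---------------------------------------------------------------------------

class TestPointwise:
    @pytest.mark.parametrize("c_out,c_in,expected", [
        (2.5, 140.0, -105.0617),   # baseline potassium reversal
        (151.0, 10.0, 70.8535),    # baseline sodium reversal
    ])
    def test_nernst_frozen(self, c_out, c_in, expected):
        assert mc.nernst(c_out, c_in, 26.1) == pytest.approx(expected, abs=5e-4)

    def test_nernst_equal_concentrations_zero(self):
        assert mc.nernst(3.7, 3.7, 26.1) == 0.0

    def test_nernst_extended_precision_contract(self):
        ref = np.longdouble("26.1") * np.log(np.longdouble("2.5")
                                             / np.longdouble("140"))
        assert abs(mc.nernst(2.5, 140.0, 26.1) - float(ref)) < 1e-12 * abs(ref)

    def test_nernst_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mc.nernst(0.0, 140.0)
        with pytest.raises(ValueError):
            mc.nernst(2.5, -1.0)

    def test_pump_current_frozen(self):
        # 23 / ((1+e)(1+e^5)) at the resting concentrations
        expected = 23.0 / ((1.0 + np.e) * (1.0 + np.exp(5.0)))
        assert mc.pump_current(2.5, 10.0, P) == pytest.approx(expected,
                                                              rel=1e-12)
        assert expected == pytest.approx(0.0414, abs=1e-4)

    def test_pump_saturates_at_max(self):
        assert mc.pump_current(1e3, 1e3, P) == pytest.approx(P.I_pump_max,
                                                             rel=1e-9)

    def test_pump_monotone_in_both(self):
        assert mc.pump_current(5.0, 15.0, P) > mc.pump_current(2.5, 10.0, P)
        k = mc.pump_current(V_GRID * 0 + np.linspace(1, 10, 281), 10.0, P)
        assert np.all(np.diff(k) > 0)

    @pytest.mark.parametrize("V,expected,tol", [
        (-47.77, 0.5, 1e-12),
        (0.0, 0.9462, 1e-4),
        (-120.0, 0.0129, 1e-4),
    ])
    def test_f_nmda_frozen(self, V, expected, tol):
        assert mc.f_nmda(V, P) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("V,expected,tol", [
        (-30.0, 0.5, 1e-12),
        (-40.0, 0.0542, 1e-4),
        (0.0, 0.99981, 1e-5),
    ])
    def test_nu_main_frozen(self, V, expected, tol):
        assert mc.nu_main(V, P) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("V,expected", [
        (-35.0, 1.0),      # threshold belongs to the firing branch
        (-35.0001, 0.0),
        (0.0, 1.0),
        (-80.0, 0.0),
    ])
    def test_nu_noisy_unit_step(self, V, expected):
        assert mc.nu_noisy(V, P) == expected

    @pytest.mark.parametrize("V,expected,tol", [
        (-65.63, 0.5, 1e-12),
        (-27.0, 0.0192, 1e-4),
        (-100.0, 0.9707, 1e-4),
    ])
    def test_f_trans_frozen(self, V, expected, tol):
        assert mc.f_trans(V, P) == pytest.approx(expected, abs=tol)

    def test_f_block_limits(self):
        assert mc.f_block(0.0, SCHED, P) == pytest.approx(1.0, abs=1e-12)
        assert mc.f_block(SCHED.t_block, SCHED, P) == pytest.approx(0.85)
        assert mc.f_block(SCHED.t_block + 1e7, SCHED, P) == pytest.approx(0.70)
        t = np.linspace(0, 1e6, 500)
        assert np.all(np.diff(mc.f_block(t, SCHED, P)) <= 0)

    def test_f_block_disabled_is_identity(self):
        s = SCHED.with_(block_enabled=False)
        assert mc.f_block(5e5, s, P) == 1.0

    def test_window_limits(self):
        mid = 0.5 * (SCHED.t_start_window + SCHED.t_end_window)
        assert mc.window_W(mid, SCHED) == pytest.approx(1.0, abs=1e-4)
        assert mc.window_W(SCHED.t_start_window, SCHED) == pytest.approx(
            0.5, abs=1e-4)
        assert mc.window_W(0.0, SCHED) == pytest.approx(0.0, abs=1e-4)
        assert mc.window_W(mid, SCHED.with_(window_enabled=False)) == 0.0

    def test_sigmoids_bounded_and_monotone_on_grid(self):
        for fn, increasing in ((mc.f_nmda, True), (mc.nu_main, True),
                               (mc.f_trans, False)):
            y = fn(V_GRID, P)
            assert np.all((y > 0) & (y < 1))
            d = np.diff(y)
            assert np.all(d > 0) if increasing else np.all(d < 0)


# ---------------------------------------------------------------------------
# Currents and conductances
# ---------------------------------------------------------------------------

def state_at(t=0.0, **kw) -> ModelState:
    base = dict(t=t, V=-70.4, V_noisy=-70.4, G_noise=0.0, T_syn=0.0,
                chi_syn=1.0, chi_NMDA=1.0, G_trans=0.0, G_pers=0.0,
                K_out=2.5, Na_in=10.0)
    base.update(kw)
    return ModelState(**base)


class TestCurrents:
    def test_transient_reversal_by_construction(self):
        st = state_at(G_trans=1.0, t=300_000.0)  # deep inside the window
        V_K = mc.nernst(2.5, 140.0, 26.1)
        V_Na = mc.nernst(151.0, 10.0, 26.1)
        U_rev = P.m_K * V_K + P.m_Na * V_Na
        assert U_rev == pytest.approx(-69.9, abs=0.1)
        assert mc.transient_current(U_rev, st, SCHED, P) == pytest.approx(
            0.0, abs=1e-9)
        assert mc.transient_current(-50.0, state_at(G_trans=0.0), SCHED, P) == 0

    def test_persistent_current_ohmic(self):
        st = state_at(G_pers=1.0, t=300_000.0)
        V_K = mc.nernst(2.5, 140.0, 26.1)
        W = mc.window_W(300_000.0, SCHED)
        assert mc.persistent_current(V_K, st, SCHED, P) == pytest.approx(0.0)
        assert mc.persistent_current(V_K + 10.0, st, SCHED, P) == \
            pytest.approx(20.0 * W, rel=1e-9)
        st0 = state_at(G_pers=1.0, t=0.0)
        assert abs(mc.persistent_current(-30.0, st0,
                                         SCHED.with_(window_enabled=False),
                                         P)) == 0.0

    def test_reciprocal_conductance_frozen(self):
        # pre-block, V = -30, all resources available
        st = state_at(V=-30.0, t=0.0)
        expected = 30.0 * (0.33 + 0.67 * mc.f_nmda(-30.0, P)) * 0.5
        got = mc.reciprocal_conductance(st, SCHED, P)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(12.42, abs=0.01)
        assert mc.reciprocal_conductance(state_at(V=-30.0, chi_syn=0.0),
                                         SCHED, P) == 0.0
        assert mc.reciprocal_conductance(state_at(V=-120.0), SCHED, P) < 1e-10

    def test_reciprocal_nmda_scale_hook(self):
        st = state_at(V=-30.0)
        s = SCHED.with_(nmda_scale=0.0)
        assert mc.reciprocal_conductance(st, s, P) == pytest.approx(
            30.0 * 0.33 * mc.f_block(0.0, s, P) * 0.5, rel=1e-9)

    def test_trigger_conductance(self):
        assert mc.trigger_conductance(state_at(T_syn=0.0), SCHED, P) == 0.0
        full = state_at(T_syn=1.0)
        assert mc.trigger_conductance(full, SCHED, P) == pytest.approx(
            9.5, abs=1e-6)
        late = state_at(T_syn=1.0, t=SCHED.t_block + 1e7)
        assert mc.trigger_conductance(late, SCHED, P) == pytest.approx(
            9.5 * 0.7, rel=1e-6)

    def test_input_conductance_model(self):
        assert mc.input_conductance_model(state_at(), SCHED, P) == \
            pytest.approx(3.0, abs=1e-4)
        off = SCHED.with_(window_enabled=False)
        st = state_at(G_trans=1.0, G_pers=1.0)
        assert mc.input_conductance_model(st, off, P) == pytest.approx(3.0)
        mid = state_at(t=300_000.0, V=-65.63, G_trans=1.0, G_pers=1.0)
        assert mc.input_conductance_model(mid, SCHED, P) == pytest.approx(
            6.0, abs=1e-3)


# ---------------------------------------------------------------------------
# Derivatives: fixed points, sign convention, unit conversion, oracles
# ---------------------------------------------------------------------------

class TestDerivatives:
    def test_leak_pump_balance_near_rest(self, rest_state):
        assert rest_state.V == pytest.approx(-72.9, abs=0.1)
        dy = mc.derivatives(rest_state, SCHED, P)
        # residual drive from the recurrent input at nu(V*) ~ 5e-6
        assert abs(dy[STATE_FIELDS.index("V")]) < 1e-3

    def test_chi_fixed_point_when_silent(self):
        st = state_at(V=-120.0, chi_syn=1.0)  # nu ~ 7e-12
        dy = mc.derivatives(st, SCHED, P)
        assert abs(dy[STATE_FIELDS.index("chi_syn")]) < 1e-12

    def test_chi_syn_equilibrium_under_sustained_firing(self):
        # with nu = 1, chi_syn settles at 1/(1 + r_rs * tau_rs) = 1/5.5
        def rhs(t, y):
            st = state_at(V=50.0, chi_syn=float(np.clip(y[0], 0, 1)))
            return [mc.derivatives(st, SCHED, P)[STATE_FIELDS.index("chi_syn")]]

        sol = solve_ivp(rhs, (0.0, 10_000.0), [1.0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(1.0 / 5.5, rel=1e-4)

    def test_pump_flux_unit_conversion_pinned(self):
        # 23 pA over 300 µm³ of extracellular space -> 7.945e-4 mM/ms
        assert mc.pump_flux(23.0, P) == pytest.approx(7.945e-4, rel=1e-3)
        st = state_at(V=-120.0, V_noisy=-120.0)
        dy = mc.derivatives(st, SCHED, P)
        i_pump = mc.pump_current(2.5, 10.0, P)
        assert dy[STATE_FIELDS.index("K_out")] == pytest.approx(
            -2.0 * i_pump * 1e3 / (P.faraday * P.v_extracell), rel=1e-9)
        assert dy[STATE_FIELDS.index("K_out")] == pytest.approx(-2.9e-6,
                                                                rel=0.05)

    def test_ion_relaxation_without_pump(self):
        p0 = ModelParameters(I_pump_max=0.0)
        st = state_at(V=-120.0, V_noisy=-120.0, K_out=5.0, Na_in=14.0)
        dy = mc.derivatives(st, SCHED, p0)
        assert dy[STATE_FIELDS.index("K_out")] == pytest.approx(
            (2.5 - 5.0) / p0.tau_K, rel=1e-9)
        assert dy[STATE_FIELDS.index("Na_in")] == pytest.approx(
            (10.0 - 14.0) / p0.tau_Na, rel=1e-9)

    def test_all_ionic_currents_inward_below_reversals(self):
        st = state_at(V=-120.0, V_noisy=-120.0)
        dy = mc.derivatives(st, SCHED, P)
        assert dy[STATE_FIELDS.index("V")] > 0
        assert dy[STATE_FIELDS.index("V_noisy")] > 0

    def test_derivatives_match_closed_form_linear_subsystems(self):
        """RHS agrees with finite differences of the analytic solutions.

        The decoupled linear equations (noise drift, trigger gate, the
        resources and conductance gates at frozen firing rate, ion
        relaxation without firing) all solve to
        x(t) = x_inf + (x0 - x_inf) exp(-t/tau_eff).
        """
        h = 1e-3
        checks = []
        # noise conductance drift: x_inf = 0, tau = tau_noise
        checks.append(("G_noise", dict(G_noise=3.0), 0.0, P.tau_noise, 3.0))
        # trigger gate with the noisy population firing (V_noisy = 0)
        tau_T_eff = 1.0 / (1.0 + 1.0 / P.tau_T)
        checks.append(("T_syn", dict(V_noisy=0.0, T_syn=0.2),
                       tau_T_eff, tau_T_eff, 0.2))
        # fast resource at frozen nu(V=-30) = 0.5
        nu = mc.nu_main(-30.0, P)
        k = P.r_rs * nu + 1.0 / P.tau_rs
        checks.append(("chi_syn", dict(V=-30.0, chi_syn=0.7),
                       (1.0 / P.tau_rs) / k, 1.0 / k, 0.7))
        # slow NMDA resource at the same frozen nu
        kN = P.r_rN * nu + 1.0 / P.tau_rN
        checks.append(("chi_NMDA", dict(V=-30.0, chi_NMDA=0.9),
                       (1.0 / P.tau_rN) / kN, 1.0 / kN, 0.9))
        # transient gate driven at nu * chi_syn with chi_syn = 1
        kt = P.r_trans * nu * 1.0 + 1.0 / P.tau_trans
        checks.append(("G_trans", dict(V=-30.0, G_trans=0.4),
                       P.r_trans * nu / kt, 1.0 / kt, 0.4))
        # persistent gate likewise
        kp = P.r_pers * nu * 1.0 + 1.0 / P.tau_pers
        checks.append(("G_pers", dict(V=-30.0, G_pers=0.1),
                       P.r_pers * nu / kp, 1.0 / kp, 0.1))

        p0 = ModelParameters(I_pump_max=0.0)  # silences the pump coupling
        for name, kw, x_inf, tau_eff, x0 in checks:
            idx = STATE_FIELDS.index(name)

            def x_of(t):
                return x_inf + (x0 - x_inf) * np.exp(-t / tau_eff)

            t_probe = 0.35 * tau_eff
            st = state_at(**{**kw, name: x_of(t_probe)})
            got = mc.derivatives(st, SCHED, p0)[idx]
            fd = (x_of(t_probe + h) - x_of(t_probe - h)) / (2 * h)
            assert got == pytest.approx(fd, rel=1e-6), name


# ---------------------------------------------------------------------------
# Type invariants
# ---------------------------------------------------------------------------

class TestTypes:
    def test_parameter_invariants_enforced(self):
        with pytest.raises(ValueError):
            ModelParameters(m_K=0.9, m_Na=0.2)
        with pytest.raises(ValueError):
            ModelParameters(block_fraction=1.5)
        with pytest.raises(ValueError):
            ModelParameters(tau_K=-1.0)

    def test_state_invariants_enforced(self):
        with pytest.raises(ValueError):
            ModelState(chi_syn=1.2)
        with pytest.raises(ValueError):
            ModelState(K_out=-0.1)
        with pytest.raises(ValueError):
            ModelState(G_noise=-1.0)

    def test_schedule_invariants_enforced(self):
        with pytest.raises(ValueError):
            ProtocolSchedule(dt=0.0)
        with pytest.raises(ValueError):
            ProtocolSchedule(t_start_window=5e5, t_end_window=4e5)
        with pytest.raises(ValueError):
            ProtocolSchedule(inj_onsets=(100.0, 200.0), inj_duration=250.0)

    def test_ion_pool_positive(self):
        with pytest.raises(ValueError):
            mc.IonPool(K_out=0.0)

    def test_state_array_round_trip(self):
        st = state_at(V=-55.0, G_trans=0.3, K_out=4.2)
        back = ModelState.from_array(st.t, st.as_array())
        assert all(getattr(back, f) == getattr(st, f) for f in STATE_FIELDS)
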