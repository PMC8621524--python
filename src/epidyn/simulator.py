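"""Stochastic forward integration of the discharge model.

The ten-variable ODE system is advanced with an explicit Euler scheme
(reference step 0.05 ms); the shot-noise conductance of the trigger
population receives instantaneous jumps at pre-sampled Poisson event
times, applied at the step boundary that contains each event.  A
numba-compiled kernel carries the inner loop; a plain-Python step
(:func:`step`) built directly on :func:`epidyn.model_core.derivatives`
serves as the slow reference implementation for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from numba import njit

from . import model_core as mc
from .model_core import (ModelParameters, ModelState, ProtocolSchedule,
                         STATE_FIELDS)

__all__ = [
    "NoiseEvent",
    "SimulationTrace",
    "IntegrationError",
    "sample_noise_events",
    "step",
    "run",
]

DT_MAX = 0.1  # ms; explicit Euler is inaccurate beyond this for tau=25 ms


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""

    def __init__(self, t: float, variable: str):
        self.t = t
        self.variable = variable
        super().__init__(
            f"non-finite value in '{variable}' at t = {t:.3f} ms")


@dataclass(frozen=True)
class NoiseEvent:
    """One shot-noise event: an instantaneous conductance jump."""

    time: float       # ms
    amplitude: float  # nS


def sample_noise_events(t_end_run: float, lambda_hz: float, mu: float,
                        sigma: float, seed: int | np.random.Generator,
                        ) -> list[NoiseEvent]:
    """Sample the Poisson shot-noise events driving the noisy population.

    Event times follow a homogeneous Poisson process of rate
    ``lambda_hz`` (events/s) on [0, t_end_run] ms; amplitudes are i.i.d.
    Gaussian with mean ``mu`` and s.d. ``sigma``, redrawn if negative
    (negligible at the default mu/sigma ratio).  Times are drawn before
    amplitudes so traces are reproducible for a given seed.
    """
    if lambda_hz < 0 or sigma < 0:
        raise ValueError("lambda_hz and sigma must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if lambda_hz == 0:
        return []
    rate_per_ms = lambda_hz / 1000.0
    # draw inter-arrival times in blocks until past the end of the run
    times: list[float] = []
    t = 0.0
    while True:
        gaps = rng.exponential(1.0 / rate_per_ms, size=256)
        for g in gaps:
            t += g
            if t > t_end_run:
                break
            times.append(t)
        if t > t_end_run:
            break
    amps = rng.normal(mu, sigma, size=len(times))
    bad = amps < 0
    while np.any(bad):  # truncate at zero by redrawing
        amps[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = amps < 0
    return [NoiseEvent(t, a) for t, a in zip(times, amps)]


# ---------------------------------------------------------------------------
# Parameter packing for the compiled kernel
# ---------------------------------------------------------------------------

_PVEC_FIELDS = (
    "C", "g_K_leak", "g_Na_leak", "g_Cl_leak", "V_Glut",
    "g_trig", "g_Glut", "g_trans", "g_pers", "m_K", "m_Na",
    "I_pump_max", "pump_K_half", "pump_Na_half", "pump_Na_slope",
    "tau_noise", "tau_T", "tau_rs", "tau_rN", "tau_trans", "tau_pers",
    "tau_K", "tau_Na",
    "r_rs", "r_rN", "r_trans", "r_pers", "r_K", "r_Na",
    "gamma_vol", "v_extracell", "faraday",
    "nernst_scale", "boltz_half", "boltz_slope", "nu_half", "nu_slope",
    "nu_noisy_threshold", "nmda_half", "nmda_slope",
    "ampa_fraction", "nmda_fraction", "block_fraction",
    "K_in", "Na_out", "K_out_rest", "Na_in_rest",
)
# schedule scalars appended after the parameter block
_SVEC_FIELDS = ("t_start_window", "t_end_window", "t_block",
                "block_tau", "window_tau", "nmda_scale")
_IDX = {name: i for i, name in enumerate(_PVEC_FIELDS + _SVEC_FIELDS)}
_I_VCL = len(_IDX)          # precomputed V_Cl
_I_WINDOW_ON = _I_VCL + 1   # 1.0 / 0.0 flags
_I_BLOCK_ON = _I_VCL + 2
_NPV = _I_VCL + 3


def _pack(p: ModelParameters, sched: ProtocolSchedule) -> np.ndarray:
    pv = np.empty(_NPV)
    for name in _PVEC_FIELDS:
        pv[_IDX[name]] = getattr(p, name)
    for name in _SVEC_FIELDS:
        pv[_IDX[name]] = getattr(sched, name)
    pv[_I_VCL] = p.V_Cl
    pv[_I_WINDOW_ON] = 1.0 if sched.window_enabled else 0.0
    pv[_I_BLOCK_ON] = 1.0 if sched.block_enabled else 0.0
    return pv


@njit(cache=True)
def _rhs(t, y, pv, I_inj, dy):  # pragma: no cover - exercised via run()
    V = y[0]
    Vn = y[1]
    G_noise = y[2]
    T_syn = y[3]
    chi_s = y[4]
    chi_N = y[5]
    G_tr = y[6]
    G_pe = y[7]
    K_out = y[8]
    Na_in = y[9]

    scale = pv[32]
    V_K = scale * np.log(K_out / pv[43])
    V_Na = scale * np.log(pv[44] / Na_in)
    V_Cl = pv[_I_VCL]

    I_pump = pv[11] / ((1.0 + np.exp(pv[12] - K_out))
                       * (1.0 + np.exp((pv[13] - Na_in) / pv[14])))

    if pv[_I_BLOCK_ON] != 0.0:
        fb = 1.0 - pv[42] / (1.0 + np.exp((pv[49] - t) / pv[50]))
    else:
        fb = 1.0
    if pv[_I_WINDOW_ON] != 0.0:
        rise = 1.0 / (1.0 + np.exp((pv[47] - t) / pv[51]))
        fall = 1.0 / (1.0 + np.exp((pv[48] - t) / pv[51]))
        W = rise * (1.0 - fall)
    else:
        W = 0.0

    nu = 1.0 / (1.0 + np.exp(pv[36] * (pv[35] - V)))
    fN = 1.0 / (1.0 + np.exp(pv[39] * (pv[38] - V)))
    nuN = 1.0 if Vn >= pv[37] else 0.0

    G_trig = pv[5] * T_syn * chi_s * fb
    G_rec = pv[6] * (pv[40] * fb + pv[41] * pv[52] * fN * chi_N) * chi_s * nu

    # transient/persistent currents at either membrane voltage
    ftr_V = 1.0 / (1.0 + np.exp((V - pv[33]) / pv[34]))
    ftr_Vn = 1.0 / (1.0 + np.exp((Vn - pv[33]) / pv[34]))
    I_tr_V = (pv[7] * (pv[9] * (V - V_K) + pv[10] * (V - V_Na))
              * ftr_V * G_tr * W)
    I_tr_Vn = (pv[7] * (pv[9] * (Vn - V_K) + pv[10] * (Vn - V_Na))
               * ftr_Vn * G_tr * W)
    I_pe_V = pv[8] * G_pe * (V - V_K) * W
    I_pe_Vn = pv[8] * G_pe * (Vn - V_K) * W

    leak_V = (pv[1] * (V - V_K) + pv[2] * (V - V_Na) + pv[3] * (V - V_Cl))
    leak_Vn = (pv[1] * (Vn - V_K) + pv[2] * (Vn - V_Na) + pv[3] * (Vn - V_Cl))

    dy[0] = -(leak_V + I_pump + G_trig * (V - pv[4]) + G_rec * (V - pv[4])
              + I_tr_V + I_pe_V - I_inj) / pv[0]
    dy[1] = -(leak_Vn + I_pump + G_noise * (Vn - pv[4])
              + I_tr_Vn + I_pe_Vn) / pv[0]
    dy[2] = -G_noise / pv[15]
    dy[3] = nuN * (1.0 - T_syn) - T_syn / pv[16]
    dy[4] = -pv[23] * nu * chi_s + (1.0 - chi_s) / pv[17]
    dy[5] = -pv[24] * nu * chi_N + (1.0 - chi_N) / pv[18]
    dy[6] = pv[25] * nu * chi_s * (1.0 - G_tr) - G_tr / pv[19]
    dy[7] = pv[26] * nu * chi_s * (1.0 - G_pe) - G_pe / pv[20]

    flux = I_pump * 1e3 / (pv[31] * pv[30])
    dy[8] = pv[27] * nu - 2.0 * flux + (pv[45] - K_out) / pv[21]
    dy[9] = pv[28] * nu - 3.0 * flux / pv[29] + (pv[46] - Na_in) / pv[22]


@njit(cache=True)
def _integrate(y0, t0, n_steps, dt, stride, pv,
               ev_t, ev_a, inj_on, inj_off, inj_amp):  # pragma: no cover
    n_rec = n_steps // stride + 1
    rec = np.empty((n_rec, 10))
    y = y0.copy()
    dy = np.empty(10)
    rec[0] = y
    i_ev = 0
    i_inj = 0
    n_ev = ev_t.shape[0]
    n_inj = inj_on.shape[0]
    max_clamp = 0.0
    fail_step = -1
    fail_var = -1
    for k in range(n_steps):
        t = t0 + k * dt
        while i_inj < n_inj and t >= inj_off[i_inj]:
            i_inj += 1
        I_inj = 0.0
        if i_inj < n_inj and t >= inj_on[i_inj]:
            I_inj = inj_amp[i_inj]
        _rhs(t, y, pv, I_inj, dy)
        for j in range(10):
            y[j] += dt * dy[j]
        t_new = t + dt
        while i_ev < n_ev and ev_t[i_ev] <= t_new:
            y[2] += ev_a[i_ev]
            i_ev += 1
        # clamp gate variables against round-off excursions
        for j in range(3, 8):
            if y[j] < 0.0:
                if -y[j] > max_clamp:
                    max_clamp = -y[j]
                y[j] = 0.0
            elif y[j] > 1.0:
                if y[j] - 1.0 > max_clamp:
                    max_clamp = y[j] - 1.0
                y[j] = 1.0
        if (k + 1) % stride == 0:
            r = (k + 1) // stride
            rec[r] = y
            if fail_step < 0:
                for j in range(10):
                    if not np.isfinite(y[j]):
                        fail_step = k + 1
                        fail_var = j
                        break
            if fail_step >= 0:
                return rec[:r + 1], fail_step, fail_var, max_clamp
    return rec, fail_step, fail_var, max_clamp


# ---------------------------------------------------------------------------
# Trace container
# ---------------------------------------------------------------------------

_DERIVED_COLUMNS = ("V_K_mV", "V_Na_mV", "I_pump_pA", "G_trig_nS",
                    "G_recip_nS", "I_trans_pA", "I_pers_pA", "G_input_nS",
                    "I_inj_pA")

_STATE_COLUMNS = {"V": "V_mV", "V_noisy": "V_noisy_mV",
                  "G_noise": "G_noise_nS", "T_syn": "T_syn",
                  "chi_syn": "chi_syn", "chi_NMDA": "chi_NMDA",
                  "G_trans": "G_trans", "G_pers": "G_pers",
                  "K_out": "K_out_mM", "Na_in": "Na_in_mM"}


@dataclass
class SimulationTrace:
    """Uniformly sampled trajectory plus run provenance.

    ``states`` has one column per entry of
    :data:`epidyn.model_core.STATE_FIELDS`.  Derived currents and
    conductances are recomputed on demand from the recorded state through
    the model-core functions, so they are always consistent with it.
    """

    times: np.ndarray                  # ms
    states: np.ndarray                 # (n, 10)
    params: ModelParameters
    schedule: ProtocolSchedule
    max_gate_clamp: float = 0.0

    def state_at(self, i: int) -> ModelState:
        return ModelState.from_array(float(self.times[i]), self.states[i])

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_FIELDS.index(name)]

    def derived(self) -> dict[str, np.ndarray]:
        p, sched = self.params, self.schedule
        t = self.times
        V = self.column("V")
        K_out, Na_in = self.column("K_out"), self.column("Na_in")
        V_K = mc.nernst(K_out, p.K_in, p.nernst_scale)
        V_Na = mc.nernst(p.Na_out, Na_in, p.nernst_scale)
        I_pump = mc.pump_current(K_out, Na_in, p)
        fb = mc.f_block(t, sched, p)
        W = mc.window_W(t, sched)
        nu = mc.nu_main(V, p)
        chi_s, chi_N = self.column("chi_syn"), self.column("chi_NMDA")
        G_tr, G_pe = self.column("G_trans"), self.column("G_pers")
        G_trig = p.g_trig * self.column("T_syn") * chi_s * fb
        G_rec = p.g_Glut * (p.ampa_fraction * fb
                            + p.nmda_fraction * sched.nmda_scale
                            * mc.f_nmda(V, p) * chi_N) * chi_s * nu
        drive = p.m_K * (V - V_K) + p.m_Na * (V - V_Na)
        I_trans = p.g_trans * drive * mc.f_trans(V, p) * G_tr * W
        I_pers = p.g_pers * G_pe * (V - V_K) * W
        G_input = (p.g_K_leak + p.g_Na_leak + p.g_Cl_leak
                   + W * (p.g_trans * mc.f_trans(V, p) * G_tr
                          + p.g_pers * G_pe))
        return {
            "V_K_mV": V_K, "V_Na_mV": V_Na, "I_pump_pA": I_pump,
            "G_trig_nS": G_trig, "G_recip_nS": G_rec,
            "I_trans_pA": I_trans, "I_pers_pA": I_pers,
            "G_input_nS": G_input,
            "I_inj_pA": mc.injected_current(t, sched),
        }

    def to_frame(self, include_derived: bool = True) -> pd.DataFrame:
        data = {"time_ms": self.times}
        for f, col in _STATE_COLUMNS.items():
            data[col] = self.column(f)
        if include_derived:
            data.update(self.derived())
        return pd.DataFrame(data)

    def to_csv(self, path, include_derived: bool = True) -> None:
        self.to_frame(include_derived).to_csv(path, index=False)

    def config_echo(self) -> dict:
        return {"params": asdict(self.params),
                "schedule": asdict(self.schedule)}


# ---------------------------------------------------------------------------
# Stepping and running
# ---------------------------------------------------------------------------

def step(state: ModelState, dt: float, events, sched: ProtocolSchedule,
         p: ModelParameters) -> ModelState:
    """One explicit Euler step of the reference (pure-Python) integrator.

    ``events`` are :class:`NoiseEvent` objects whose times fall in
    ``(state.t, state.t + dt]``; their amplitudes are added to the noise
    conductance after the deterministic update.  Gate variables are
    clamped to [0, 1] against round-off.
    """
    if dt > DT_MAX:
        raise ValueError(f"dt = {dt} exceeds dt_max = {DT_MAX} ms")
    y = state.as_array()
    dy = mc.derivatives(state, sched, p)
    y = y + dt * dy
    for ev in events:
        y[2] += ev.amplitude
    y[3:8] = np.clip(y[3:8], 0.0, 1.0)
    if not np.all(np.isfinite(y)):
        j = int(np.argmin(np.isfinite(y)))
        raise IntegrationError(state.t + dt, STATE_FIELDS[j])
    return ModelState.from_array(state.t + dt, y)


def run(params: ModelParameters | None = None,
        sched: ProtocolSchedule | None = None,
        initial_state: ModelState | None = None,
        events: list[NoiseEvent] | None = None) -> SimulationTrace:
    """Integrate the model over ``[0, t_end_run]`` and record a trace.

    Noise events are sampled from the schedule seed unless an explicit
    ``events`` list is supplied.  Deterministic for a given seed.
    """
    p = params or ModelParameters()
    sched = sched or ProtocolSchedule()
    if sched.dt > DT_MAX:
        raise ValueError(f"dt = {sched.dt} exceeds dt_max = {DT_MAX} ms")
    state0 = initial_state or ModelState.initial(p)
    if events is None:
        events = sample_noise_events(sched.t_end_run, p.lambda_noise,
                                     p.mu_noise, p.sigma_noise, sched.seed)
    ev_t = np.array([e.time for e in events], dtype=float)
    ev_a = np.array([e.amplitude for e in events], dtype=float)
    order = np.argsort(ev_t, kind="stable")
    ev_t, ev_a = ev_t[order], ev_a[order]

    inj_on = np.asarray(sched.inj_onsets, dtype=float)
    inj_off = inj_on + sched.inj_duration
    inj_amp = np.full_like(inj_on, sched.inj_amplitude)

    n_steps = int(round((sched.t_end_run - state0.t) / sched.dt))
    if n_steps <= 0:
        raise ValueError("initial state time must precede t_end_run")
    pv = _pack(p, sched)
    rec, fail_step, fail_var, max_clamp = _integrate(
        state0.as_array(), state0.t, n_steps, sched.dt, sched.record_stride,
        pv, ev_t, ev_a, inj_on, inj_off, inj_amp)
    if fail_step >= 0:
        raise IntegrationError(state0.t + fail_step * sched.dt,
                               STATE_FIELDS[fail_var])
    times = state0.t + sched.dt * sched.record_stride * np.arange(rec.shape[0])
    return SimulationTrace(times=times, states=rec, params=p, schedule=sched,
                           max_gate_clamp=float(max_clamp))
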