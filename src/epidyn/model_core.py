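"""Core equations of the two-population epileptiform-discharge model.

The model describes a cortical slice in a pro-epileptic bath as two
interacting neural populations: a *main* population holding most
glutamatergic neurons, and a small *noisy* population that fires
spontaneous synchronized bursts and can trigger a discharge in the main
one.  Both populations share a single extracellular compartment, so the
extracellular potassium concentration ``K_out``, the intracellular sodium
``Na_in``, the Na+/K+ pump current, the synaptic resources and the
activity-dependent conductances are global variables.

All quantities use a consistent unit system in which no conversion
factors appear in the current-balance equations:

====================  =========
quantity              unit
====================  =========
time                  ms
voltage               mV
conductance           nS
current               pA
capacitance           pF
concentration         mM
====================  =========

The single exception is the conversion of the pump current (pA) into an
ion flux (mM/ms), which involves the Faraday constant and the
extracellular volume per neuron; see :func:`pump_flux`.

Everything in this module is pure and side-effect free; the stochastic
jump process driving the noisy population lives in
:mod:`epidyn.simulator`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "IonPool",
    "ModelParameters",
    "ModelState",
    "ProtocolSchedule",
    "STATE_FIELDS",
    "nernst",
    "pump_current",
    "pump_flux",
    "f_nmda",
    "nu_main",
    "nu_noisy",
    "f_block",
    "window_W",
    "f_trans",
    "transient_current",
    "persistent_current",
    "reciprocal_conductance",
    "trigger_conductance",
    "injected_current",
    "derivatives",
    "input_conductance_model",
    "leak_pump_rest_voltage",
]

ArrayLike = Union[float, np.ndarray]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonPool:
    """Ion concentrations (mM) on both sides of the membrane.

    ``K_out`` and ``Na_in`` are dynamical during a simulation; the other
    four are clamped by the bath and the pipette solution.
    """

    K_out: float = 2.5
    K_in: float = 140.0
    Na_out: float = 151.0
    Na_in: float = 10.0
    Cl_out: float = 133.0
    Cl_in: float = 10.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"concentration {f.name} must be positive")


@dataclass(frozen=True)
class ModelParameters:
    """All model constants with their published defaults.

    Conductances in nS, capacitance in pF, currents in pA, time constants
    in ms, rates in 1/ms (``r_K``/``r_Na`` in mM/ms), voltages in mV.
    """

    # membrane & leaks
    C: float = 100.0                 # pF
    g_K_leak: float = 1.9            # nS
    g_Na_leak: float = 0.4           # nS
    g_Cl_leak: float = 0.7           # nS
    V_Glut: float = 0.0              # mV, glutamatergic reversal

    # synaptic / activity-dependent maximal conductances
    g_trig: float = 9.5              # nS, trigger input to main population
    g_Glut: float = 30.0             # nS, reciprocal AMPAR+NMDAR input
    g_trans: float = 2.0             # nS, transient Ca-dependent conductance
    g_pers: float = 2.0              # nS, persistent K+ conductance

    # mixed-ion weights of the transient current (reversal ~ -62 mV)
    m_K: float = 0.8
    m_Na: float = 0.2

    # Na/K pump
    I_pump_max: float = 23.0         # pA
    pump_K_half: float = 3.5         # mM
    pump_Na_half: float = 25.0       # mM
    pump_Na_slope: float = 3.0       # mM

    # time constants (ms)
    tau_noise: float = 25.0
    tau_T: float = 25.0
    tau_rs: float = 1500.0
    tau_rN: float = 52000.0
    tau_trans: float = 920.0
    tau_pers: float = 35000.0
    tau_K: float = 7500.0
    tau_Na: float = 52000.0

    # activity-driven rates
    r_rs: float = 0.003              # 1/ms, fast synaptic depression
    r_rN: float = 0.00007            # 1/ms, slow NMDAR downregulation
    r_trans: float = 0.03            # 1/ms
    r_pers: float = 0.00065          # 1/ms
    r_K: float = 0.0017              # mM/ms
    r_Na: float = 0.0016             # mM/ms

    # shot-noise statistics of the noisy population
    mu_noise: float = 8.0            # nS, mean jump amplitude
    sigma_noise: float = 1.5         # nS, jump amplitude s.d.
    lambda_noise: float = 1.5        # Hz, Poisson event rate

    # volumes & physical constants
    gamma_vol: float = 5.0           # intracellular/extracellular volume ratio
    v_extracell: float = 300.0       # µm³ extracellular space per neuron
    faraday: float = 96485.0         # C/mol

    # sigmoid shapes
    nernst_scale: float = 26.1       # mV (RT/F at recording temperature)
    boltz_half: float = -65.63       # mV, transient-conductance Boltzmann
    boltz_slope: float = 9.82        # mV
    nu_half: float = -30.0           # mV, main-population gain midpoint
    nu_slope: float = 0.286          # 1/mV
    nu_noisy_threshold: float = -35.0  # mV, unit-step threshold
    nmda_half: float = -47.77        # mV, Mg-block relief midpoint
    nmda_slope: float = 0.06         # 1/mV

    # receptor fractions and drug block
    ampa_fraction: float = 0.33
    nmda_fraction: float = 0.67
    block_fraction: float = 0.3      # fraction of AMPARs that are CP-AMPARs

    # clamped ion concentrations (mM) and resting baselines
    K_in: float = 140.0
    Na_out: float = 151.0
    Cl_in: float = 10.0
    Cl_out: float = 133.0
    K_out_rest: float = 2.5
    Na_in_rest: float = 10.0

    def __post_init__(self) -> None:
        nonneg = (
            "C", "g_K_leak", "g_Na_leak", "g_Cl_leak", "g_trig", "g_Glut",
            "g_trans", "g_pers", "I_pump_max", "tau_noise", "tau_T", "tau_rs",
            "tau_rN", "tau_trans", "tau_pers", "tau_K", "tau_Na", "r_rs",
            "r_rN", "r_trans", "r_pers", "r_K", "r_Na", "sigma_noise",
            "lambda_noise",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.m_K + self.m_Na - 1.0) > 1e-12:
            raise ValueError("m_K + m_Na must equal 1")
        if abs(self.ampa_fraction + self.nmda_fraction - 1.0) > 1e-12:
            raise ValueError("ampa_fraction + nmda_fraction must equal 1")
        if not 0.0 <= self.block_fraction <= 1.0:
            raise ValueError("block_fraction must lie in [0, 1]")
        for name in ("K_in", "Na_out", "Cl_in", "Cl_out",
                     "K_out_rest", "Na_in_rest"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def V_Cl(self) -> float:
        """Chloride reversal potential (mV); fixed, as both Cl pools are."""
        return nernst(self.Cl_in, self.Cl_out, self.nernst_scale)

    def ions(self, K_out: float, Na_in: float) -> IonPool:
        return IonPool(K_out=K_out, K_in=self.K_in, Na_out=self.Na_out,
                       Na_in=Na_in, Cl_out=self.Cl_out, Cl_in=self.Cl_in)


#: integration order of the dynamical variables
STATE_FIELDS = ("V", "V_noisy", "G_noise", "T_syn", "chi_syn", "chi_NMDA",
                "G_trans", "G_pers", "K_out", "Na_in")


@dataclass
class ModelState:
    """The ten dynamical variables at one instant ``t``."""

    t: float = 0.0            # ms
    V: float = -70.4          # mV, main population
    V_noisy: float = -70.4    # mV, noisy (trigger) population
    G_noise: float = 0.0      # nS, shot-noise conductance
    T_syn: float = 0.0        # trigger transduction gate
    chi_syn: float = 1.0      # fast synaptic resource
    chi_NMDA: float = 1.0     # available NMDAR fraction
    G_trans: float = 0.0      # transient conductance gate
    G_pers: float = 0.0       # persistent conductance gate
    K_out: float = 2.5        # mM
    Na_in: float = 10.0       # mM

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("T_syn", "chi_syn", "chi_NMDA", "G_trans", "G_pers"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name}={x} outside [0, 1]")
        if self.G_noise < 0:
            raise ValueError("G_noise must be >= 0")
        if self.K_out <= 0 or self.Na_in <= 0:
            raise ValueError("ion concentrations must be positive")

    @classmethod
    def initial(cls, p: ModelParameters | None = None) -> "ModelState":
        p = p or ModelParameters()
        return cls(t=0.0, V=-70.4, V_noisy=-70.4, G_noise=0.0, T_syn=0.0,
                   chi_syn=1.0, chi_NMDA=1.0, G_trans=0.0, G_pers=0.0,
                   K_out=p.K_out_rest, Na_in=p.Na_in_rest)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, t: float, y: np.ndarray) -> "ModelState":
        return cls(t=t, **dict(zip(STATE_FIELDS, (float(v) for v in y))))


@dataclass(frozen=True)
class ProtocolSchedule:
    """Timing of the run, the conductance window and the drug block.

    The default protocol is a 600-s run in which the activity-dependent
    conductances are allowed between 120 s and 480 s (sigmoid edges,
    ``window_tau``) and a simulated CP-AMPAR blocker takes half effect at
    450 s (``block_tau`` sigmoid).  ``nmda_scale`` < 1 additionally scales
    the NMDAR term of the reciprocal input, emulating an NMDAR
    antagonist; 1 reproduces the unmodified model.

    ``inj_onsets``/``inj_duration``/``inj_amplitude`` describe optional
    rectangular current steps injected into the main population, used for
    in-silico input-conductance measurements.
    """

    t_end_run: float = 600_000.0       # ms
    dt: float = 0.05                   # ms
    t_start_window: float = 120_000.0  # ms
    t_end_window: float = 480_000.0    # ms
    t_block: float = 450_000.0         # ms
    block_tau: float = 15_000.0        # ms, drug-block sigmoid
    window_tau: float = 10_000.0       # ms, window sigmoid edges
    seed: int = 0
    nmda_scale: float = 1.0
    record_stride: int = 20            # record every stride-th step (1 ms)
    window_enabled: bool = True
    block_enabled: bool = True
    inj_onsets: tuple = ()             # ms, sorted, non-overlapping
    inj_duration: float = 250.0        # ms
    inj_amplitude: float = -25.0       # pA

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_start_window >= self.t_end_window:
            raise ValueError("t_start_window must precede t_end_window")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if len(self.inj_onsets) > 1:
            on = np.asarray(self.inj_onsets, dtype=float)
            if np.any(np.diff(on) < self.inj_duration):
                raise ValueError("injection steps overlap")

    def with_(self, **kw) -> "ProtocolSchedule":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Pointwise functions
# ---------------------------------------------------------------------------

def nernst(c_out: ArrayLike, c_in: ArrayLike, scale: float = 26.1) -> ArrayLike:
    """Nernst potential ``scale * ln(c_out / c_in)`` in mV.

    For K+ and Na+ pass (outside, inside); for Cl- pass (inside, outside),
    which absorbs the negative valence.
    """
    c_out = np.asarray(c_out, dtype=float)
    c_in = np.asarray(c_in, dtype=float)
    if np.any(c_out <= 0) or np.any(c_in <= 0):
        raise ValueError("Nernst potential requires positive concentrations")
    out = scale * np.log(c_out / c_in)
    return float(out) if out.ndim == 0 else out


def pump_current(K_out: ArrayLike, Na_in: ArrayLike,
                 p: ModelParameters) -> ArrayLike:
    """Na+/K+ pump current (pA), sigmoidal in both substrate concentrations."""
    out = p.I_pump_max / (
        (1.0 + np.exp(p.pump_K_half - np.asarray(K_out, dtype=float)))
        * (1.0 + np.exp((p.pump_Na_half - np.asarray(Na_in, dtype=float))
                        / p.pump_Na_slope))
    )
    return float(out) if np.ndim(out) == 0 else out


def pump_flux(I_pump: ArrayLike, p: ModelParameters) -> ArrayLike:
    """Convert a pump current (pA) into an extracellular flux (mM/ms).

    1 pA = 1e-12 C/s and 1 µm³ = 1e-15 L, so
    I/(F·v) = I_pA·1e-12 / (F · v_µm³·1e-15) mol/(L·s), and mol/(L·s)
    is numerically equal to mmol/(L·ms); hence the factor 1e3/(F·v).
    """
    return I_pump * 1e3 / (p.faraday * p.v_extracell)


def f_nmda(V: ArrayLike, p: ModelParameters | None = None) -> ArrayLike:
    """Voltage-dependent relief of the NMDAR Mg2+ block, in (0, 1)."""
    p = p or ModelParameters()
    out = 1.0 / (1.0 + np.exp(p.nmda_slope * (p.nmda_half - np.asarray(V))))
    return float(out) if np.ndim(out) == 0 else out


def nu_main(V: ArrayLike, p: ModelParameters | None = None) -> ArrayLike:
    """Sigmoidal input-output (firing-rate) function of the main population."""
    p = p or ModelParameters()
    out = 1.0 / (1.0 + np.exp(p.nu_slope * (p.nu_half - np.asarray(V))))
    return float(out) if np.ndim(out) == 0 else out


def nu_noisy(V: ArrayLike, p: ModelParameters | None = None) -> ArrayLike:
    """Unit-step input-output function of the noisy population (0 or 1)."""
    p = p or ModelParameters()
    out = np.where(np.asarray(V) >= p.nu_noisy_threshold, 1.0, 0.0)
    return float(out) if np.ndim(out) == 0 else out


def f_block(t: ArrayLike, sched: ProtocolSchedule,
            p: ModelParameters | None = None) -> ArrayLike:
    """Sigmoid drug-block factor on the CP-AMPAR fraction.

    Decreases from 1 towards ``1 - block_fraction`` with half effect at
    ``t_block``; identically 1 when the block is disabled.
    """
    p = p or ModelParameters()
    t = np.asarray(t, dtype=float)
    if not sched.block_enabled:
        out = np.ones_like(t)
    else:
        out = 1.0 - p.block_fraction * expit((t - sched.t_block)
                                             / sched.block_tau)
    return float(out) if out.ndim == 0 else out


def window_W(t: ArrayLike, sched: ProtocolSchedule) -> ArrayLike:
    """Sigmoid-edged gate confining the activity-dependent conductances.

    Rises towards 1 around ``t_start_window`` and falls back around
    ``t_end_window``; identically 0 when the window is disabled.
    """
    t = np.asarray(t, dtype=float)
    if not sched.window_enabled:
        out = np.zeros_like(t)
    else:
        rise = expit((t - sched.t_start_window) / sched.window_tau)
        fall = expit((t - sched.t_end_window) / sched.window_tau)
        out = rise * (1.0 - fall)
    return float(out) if out.ndim == 0 else out


def f_trans(V: ArrayLike, p: ModelParameters | None = None) -> ArrayLike:
    """Boltzmann voltage dependence of the transient conductance.

    Decreasing in V (inward rectification), midpoint ``boltz_half``.
    """
    p = p or ModelParameters()
    out = 1.0 / (1.0 + np.exp((np.asarray(V) - p.boltz_half) / p.boltz_slope))
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Currents and conductances assembled from a state
# ---------------------------------------------------------------------------

def transient_current(U: ArrayLike, state: ModelState,
                      sched: ProtocolSchedule, p: ModelParameters) -> ArrayLike:
    """Transient activity-dependent current (pA) at membrane voltage ``U``.

    Mixed K+/Na+ current gated by the shared ``G_trans`` variable, the
    rectifying Boltzmann factor and the protocol window.  ``U`` may be
    the voltage of either population.
    """
    V_K = nernst(state.K_out, p.K_in, p.nernst_scale)
    V_Na = nernst(p.Na_out, state.Na_in, p.nernst_scale)
    drive = p.m_K * (U - V_K) + p.m_Na * (U - V_Na)
    return (p.g_trans * drive * f_trans(U, p) * state.G_trans
            * window_W(state.t, sched))


def persistent_current(U: ArrayLike, state: ModelState,
                       sched: ProtocolSchedule, p: ModelParameters) -> ArrayLike:
    """Persistent K+ current (pA) at voltage ``U``; reverses at V_K."""
    V_K = nernst(state.K_out, p.K_in, p.nernst_scale)
    return (p.g_pers * state.G_pers * (U - V_K)
            * window_W(state.t, sched))


def reciprocal_conductance(state: ModelState, sched: ProtocolSchedule,
                           p: ModelParameters) -> float:
    """AMPAR+NMDAR conductance (nS) of the recurrent input to the main population.

    The AMPAR fraction is subject to the drug block, the NMDAR fraction to
    Mg-block relief, NMDAR availability and the ``nmda_scale`` hook; both
    are gated by the fast synaptic resource and the population firing rate.
    """
    fb = f_block(state.t, sched, p)
    return p.g_Glut * (
        p.ampa_fraction * fb
        + p.nmda_fraction * sched.nmda_scale * f_nmda(state.V, p) * state.chi_NMDA
    ) * state.chi_syn * nu_main(state.V, p)


def trigger_conductance(state: ModelState, sched: ProtocolSchedule,
                        p: ModelParameters) -> float:
    """Trigger conductance (nS) from the noisy onto the main population."""
    return (p.g_trig * state.T_syn * state.chi_syn
            * f_block(state.t, sched, p))


def injected_current(t: ArrayLike, sched: ProtocolSchedule) -> ArrayLike:
    """Injected current (pA) of the step protocol at time ``t`` (0 outside steps)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for onset in sched.inj_onsets:
        out = np.where((t >= onset) & (t < onset + sched.inj_duration),
                       sched.inj_amplitude, out)
    return float(out) if out.ndim == 0 else out


def derivatives(state: ModelState, sched: ProtocolSchedule,
                p: ModelParameters) -> np.ndarray:
    """Time derivative of every dynamical variable, in ``STATE_FIELDS`` order.

    The jump part of the noise process is excluded (the simulator applies
    it); only the exponential drift ``-G_noise/tau_noise`` appears here.
    """
    t = state.t
    V, Vn = state.V, state.V_noisy
    V_K = nernst(state.K_out, p.K_in, p.nernst_scale)
    V_Na = nernst(p.Na_out, state.Na_in, p.nernst_scale)
    V_Cl = p.V_Cl
    I_pump = pump_current(state.K_out, state.Na_in, p)

    def leaks(U: float) -> float:
        return (p.g_K_leak * (U - V_K) + p.g_Na_leak * (U - V_Na)
                + p.g_Cl_leak * (U - V_Cl))

    G_trig = trigger_conductance(state, sched, p)
    G_rec = reciprocal_conductance(state, sched, p)
    I_inj = injected_current(t, sched)

    # Kirchhoff balance, outward-positive currents on the right-hand side
    dV = -(leaks(V) + I_pump
           + G_trig * (V - p.V_Glut) + G_rec * (V - p.V_Glut)
           + transient_current(V, state, sched, p)
           + persistent_current(V, state, sched, p)
           - I_inj) / p.C
    dVn = -(leaks(Vn) + I_pump
            + state.G_noise * (Vn - p.V_Glut)
            + transient_current(Vn, state, sched, p)
            + persistent_current(Vn, state, sched, p)) / p.C

    dG_noise = -state.G_noise / p.tau_noise
    dT = nu_noisy(Vn, p) * (1.0 - state.T_syn) - state.T_syn / p.tau_T

    nu = nu_main(V, p)
    dchi_s = -p.r_rs * nu * state.chi_syn + (1.0 - state.chi_syn) / p.tau_rs
    dchi_N = -p.r_rN * nu * state.chi_NMDA + (1.0 - state.chi_NMDA) / p.tau_rN
    dG_tr = (p.r_trans * nu * state.chi_syn * (1.0 - state.G_trans)
             - state.G_trans / p.tau_trans)
    dG_pe = (p.r_pers * nu * state.chi_syn * (1.0 - state.G_pers)
             - state.G_pers / p.tau_pers)

    flux = pump_flux(I_pump, p)
    dK = (p.r_K * nu - 2.0 * flux
          + (p.K_out_rest - state.K_out) / p.tau_K)
    dNa = (p.r_Na * nu - 3.0 * flux / p.gamma_vol
           + (p.Na_in_rest - state.Na_in) / p.tau_Na)

    return np.array([dV, dVn, dG_noise, dT, dchi_s, dchi_N,
                     dG_tr, dG_pe, dK, dNa])


def input_conductance_model(state: ModelState, sched: ProtocolSchedule,
                            p: ModelParameters) -> float:
    """Total input conductance (nS): leaks plus gated activity-dependent terms."""
    W = window_W(state.t, sched)
    return (p.g_K_leak + p.g_Na_leak + p.g_Cl_leak
            + W * (p.g_trans * f_trans(state.V, p) * state.G_trans
                   + p.g_pers * state.G_pers))


def leak_pump_rest_voltage(p: ModelParameters,
                           K_out: float | None = None,
                           Na_in: float | None = None) -> float:
    """Noise-free resting voltage where leak currents balance the pump.

    Solves g_K(V-V_K) + g_Na(V-V_Na) + g_Cl(V-V_Cl) + I_pump = 0 at the
    given (default baseline) ion concentrations.  With the defaults this
    sits near -72.9 mV.
    """
    K_out = p.K_out_rest if K_out is None else K_out
    Na_in = p.Na_in_rest if Na_in is None else Na_in
    V_K = nernst(K_out, p.K_in, p.nernst_scale)
    V_Na = nernst(p.Na_out, Na_in, p.nernst_scale)
    V_Cl = p.V_Cl
    I_pump = pump_current(K_out, Na_in, p)

    def balance(V: float) -> float:
        return (p.g_K_leak * (V - V_K) + p.g_Na_leak * (V - V_Na)
                + p.g_Cl_leak * (V - V_Cl) + I_pump)

    return brentq(balance, -150.0, 50.0, xtol=1e-10)
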