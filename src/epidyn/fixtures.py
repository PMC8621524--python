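"""Synthetic experiment-shaped inputs with known ground truth.

Three generators emulate the data the analysis layer consumes, without
running the simulator: replicate series of the single-exponential
post-discharge conductance decay, noisy samples of the rectifying
Boltzmann I-V curve, and long current-clamp-style voltage traces with
discharges implanted at Poisson onsets (plus optional current-step
deflections).  Every generator returns its ground truth next to the
data, so a generate -> analyze round trip can be checked exactly.

Defaults reproduce the measured study conditions: decay parameters
(A_baseline 4.1 nS, A_transient 1.5 nS, tau 920 ms), the I-V fit
(gain 2.25 nS, reversal -60.28 mV, Boltzmann half -65.63 mV / slope
9.82 mV), and status-epilepticus-like discharge statistics (0.21 Hz,
480 ms, baseline -74.7 mV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "FixtureSpec",
    "DecaySeries",
    "IVSamples",
    "VoltageTrace",
    "gen_decay_series",
    "gen_iv_samples",
    "gen_voltage_trace",
    "DEFAULT_IV_GRID",
]

#: holding-voltage grid (mV) matching the plotted I-V span
DEFAULT_IV_GRID = tuple(range(-107, -26, 10))

DECAY_SAMPLE_TIMES = (500.0, 1500.0, 2500.0, 3500.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Serializable description of one fixture (kind + ground truth + noise)."""

    kind: str                      # decay | iv | voltage_trace
    params: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("decay", "iv", "voltage_trace"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def generate(self):
        if self.kind == "decay":
            return gen_decay_series(noise_sd=self.noise_sd,
                                    n=self.n_replicates, seed=self.seed,
                                    **self.params)
        if self.kind == "iv":
            return gen_iv_samples(noise_sd=self.noise_sd, seed=self.seed,
                                  **self.params)
        return gen_voltage_trace(noise_sd=self.noise_sd, seed=self.seed,
                                 **self.params)


@dataclass
class DecaySeries:
    times: np.ndarray        # ms since discharge
    replicates: np.ndarray   # (n, len(times)) nS
    truth: dict

    @property
    def mean(self) -> np.ndarray:
        return self.replicates.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.replicates.T,
                          columns=[f"G_nS_rep{i}" for i in
                                   range(self.replicates.shape[0])])
        df.insert(0, "time_ms", self.times)
        df["G_nS"] = self.mean
        return df


@dataclass
class IVSamples:
    data: pd.DataFrame       # columns V_mV, I_pA
    truth: dict


@dataclass
class VoltageTrace:
    times: np.ndarray        # ms
    V: np.ndarray            # mV
    events: pd.DataFrame     # ground-truth onset_ms/offset_ms
    truth: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times, "V_mV": self.V})


def gen_decay_series(A_baseline: float = 4.1, A_transient: float = 1.5,
                     tau: float = 920.0,
                     sample_times=DECAY_SAMPLE_TIMES,
                     noise_sd: float = 0.1, n: int = 13,
                     seed: int = 0) -> DecaySeries:
    """Replicate realizations of the post-discharge conductance decay.

    ``n`` noisy copies of ``A_baseline + A_transient * exp(-t/tau)`` at
    ``sample_times`` (ms); i.i.d. Gaussian noise of s.d. ``noise_sd`` nS.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(sample_times, dtype=float)
    rng = np.random.default_rng(seed)
    clean = A_baseline + A_transient * np.exp(-t / tau)
    reps = clean[None, :] + noise_sd * rng.standard_normal((n, t.size))
    truth = {"A_baseline": A_baseline, "A_transient": A_transient,
             "tau_transient": tau, "noise_sd": noise_sd, "n": n, "seed": seed}
    return DecaySeries(times=t, replicates=reps, truth=truth)


def gen_iv_samples(a: float = 2.25, V_rev: float = -60.28,
                   h: float = -65.63, k: float = 9.82,
                   grid=DEFAULT_IV_GRID, noise_sd: float = 0.0,
                   seed: int = 0) -> IVSamples:
    """Noisy samples of the rectifying I-V curve ``a * f(v) * (v - V_rev)``."""
    if k <= 0:
        raise ValueError("Boltzmann slope k must be positive")
    v = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    f = 1.0 / (1.0 + np.exp((v - h) / k))
    i = a * f * (v - V_rev) + noise_sd * rng.standard_normal(v.size)
    truth = {"gain_a": a, "V_rev": V_rev, "boltz_half": h, "boltz_slope": k,
             "noise_sd": noise_sd, "seed": seed}
    return IVSamples(data=pd.DataFrame({"V_mV": v, "I_pA": i}), truth=truth)


def _trapezoid(t_rel: np.ndarray, duration: float, ramp: float) -> np.ndarray:
    """Unit-amplitude trapezoid on [0, duration] with linear ramps."""
    up = np.clip(t_rel / ramp, 0.0, 1.0)
    down = np.clip((duration - t_rel) / ramp, 0.0, 1.0)
    return np.where((t_rel >= 0) & (t_rel <= duration),
                    np.minimum(up, down), 0.0)


def gen_voltage_trace(rate: float = 0.21, duration_s: float = 600.0,
                      discharge_duration_ms: float = 480.0,
                      discharge_amp: float = 45.0,
                      baseline_V: float = -74.7,
                      noise_sd: float = 1.0,
                      dt_ms: float = 1.0,
                      ramp_ms: float = 20.0,
                      refractory_ms: float = 1000.0,
                      step_onsets=(), step_delta_V: float = 0.0,
                      step_duration_ms: float = 250.0,
                      seed: int = 0) -> VoltageTrace:
    """Voltage trace with trapezoidal discharges implanted at Poisson onsets.

    Onsets form a renewal process: exponential gaps with an enforced
    refractory interval of ``discharge_duration_ms + refractory_ms`` so
    discharges never overlap, with the exponential mean corrected so the
    overall rate stays at ``rate``.  Only onset, offset and duration are
    contractual; the trapezoid shape (linear ``ramp_ms`` rise/fall) is a
    plumbing choice.  Optional rectangular hyperpolarizing deflections of
    ``step_delta_V`` mV emulate current-step responses.
    """
    if rate < 0 or duration_s < 0:
        raise ValueError("rate and duration must be >= 0")
    duration_ms = duration_s * 1000.0
    min_gap = discharge_duration_ms + refractory_ms
    rng = np.random.default_rng(seed)
    onsets: list[float] = []
    if rate > 0:
        mean_gap = 1000.0 / rate
        if mean_gap <= min_gap:
            raise ValueError("requested discharge density is infeasible "
                             "given the refractory gap")
        t = float(rng.exponential(mean_gap - min_gap))
        while t <= duration_ms - discharge_duration_ms:
            onsets.append(t)
            t += min_gap + float(rng.exponential(mean_gap - min_gap))
    times = np.arange(0.0, duration_ms, dt_ms)
    V = baseline_V + noise_sd * rng.standard_normal(times.size)
    for onset in onsets:
        sel = (times >= onset) & (times <= onset + discharge_duration_ms)
        V[sel] += discharge_amp * _trapezoid(times[sel] - onset,
                                             discharge_duration_ms, ramp_ms)
    for onset in step_onsets:
        sel = (times >= onset) & (times < onset + step_duration_ms)
        V[sel] -= step_delta_V
    events = pd.DataFrame({
        "onset_ms": onsets,
        "offset_ms": [o + discharge_duration_ms for o in onsets]})
    truth = {"rate_hz": rate, "duration_s": duration_s,
             "discharge_duration_ms": discharge_duration_ms,
             "discharge_amp_mV": discharge_amp, "baseline_V_mV": baseline_V,
             "noise_sd_mV": noise_sd, "n_events": len(onsets),
             "step_delta_V_mV": step_delta_V, "seed": seed}
    return VoltageTrace(times=times, V=V, events=events, truth=truth)
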