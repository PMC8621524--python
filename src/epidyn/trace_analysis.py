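"""Quantification of voltage/current/conductance time series.

Mirrors the analyses a patch-clamp experimenter performs on recordings of
status-epilepticus-like activity: detecting discharges by threshold
crossing, summarizing their frequency and duration, estimating the input
conductance from hyperpolarizing current steps (Ohm's law), fitting a
single exponential to the post-discharge conductance decay, and fitting a
rectifying Boltzmann I-V curve to the post-discharge current.

All fits use unweighted least squares with a small multi-start around
data-driven heuristics, and report the residual sum of squares plus any
degeneracy flags rather than failing silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DischargeEvent",
    "DischargeStats",
    "DecayFit",
    "IVFit",
    "detect_discharges",
    "detect_episodes",
    "discharge_stats",
    "classify_events",
    "input_conductance",
    "step_delta_v",
    "fit_conductance_decay",
    "build_iv",
    "fit_iv",
    "rectification_index",
    "post_discharge_current",
    "read_trace_csv",
]

#: default detection rule: the model's trigger threshold separates
#: sub-threshold noise from discharges
DEFAULT_THRESHOLD_MV = -35.0
DEFAULT_MIN_DURATION_MS = 100.0
DEFAULT_MERGE_GAP_MS = 200.0
#: events longer than this are seizure-like events rather than short discharges
SLE_DURATION_MS = 5000.0


@dataclass(frozen=True)
class DischargeEvent:
    """One detected supra-threshold burst."""

    onset: float    # ms
    offset: float   # ms
    peak_V: float   # mV

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("offset must follow onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class DischargeStats:
    frequency_hz: float
    mean_duration_s: float   # nan when no events fall in the window
    n_events: int


@dataclass(frozen=True)
class DecayFit:
    """Single-exponential fit G(t) = A_baseline + A_transient*exp(-t/tau)."""

    A_baseline: float      # nS
    A_transient: float     # nS
    tau_transient: float   # ms
    rss: float             # nS^2
    flags: tuple = ()

    @property
    def ok(self) -> bool:
        return not self.flags

    def predict(self, t):
        return self.A_baseline + self.A_transient * np.exp(
            -np.asarray(t, dtype=float) / self.tau_transient)


@dataclass(frozen=True)
class IVFit:
    """Rectifying I-V fit I(v) = a * f(v) * (v - V_rev),
    f(v) = 1/(1+exp((v-h)/k))."""

    gain_a: float              # nS
    V_rev: float               # mV
    boltz_half: float          # mV
    boltz_slope: float         # mV
    rectification_index: float
    rss: float                 # pA^2
    flags: tuple = ()

    @property
    def ok(self) -> bool:
        return not self.flags

    def predict(self, v):
        v = np.asarray(v, dtype=float)
        f = 1.0 / (1.0 + np.exp((v - self.boltz_half) / self.boltz_slope))
        return self.gain_a * f * (v - self.V_rev)


# ---------------------------------------------------------------------------
# Discharge detection and statistics
# ---------------------------------------------------------------------------

def _check_uniform(times: np.ndarray) -> float:
    dt = np.diff(times)
    if len(dt) == 0:
        raise ValueError("need at least two samples")
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("time grid must be uniform and increasing")
    return float(dt[0])


def detect_discharges(times, V,
                      threshold: float = DEFAULT_THRESHOLD_MV,
                      min_duration: float = DEFAULT_MIN_DURATION_MS,
                      merge_gap: float = DEFAULT_MERGE_GAP_MS,
                      ) -> list[DischargeEvent]:
    """Find maximal intervals with V >= threshold on a uniform time grid.

    Intervals separated by less than ``merge_gap`` ms are merged, then
    intervals shorter than ``min_duration`` ms are discarded.  Returns
    non-overlapping events in time order.
    """
    times = np.asarray(times, dtype=float)
    V = np.asarray(V, dtype=float)
    if times.shape != V.shape:
        raise ValueError("times and V must have the same shape")
    dt = _check_uniform(times)
    above = V >= threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)   # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(V))
    # merge intervals separated by short gaps
    merged: list[list[int]] = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if (s - merged[-1][1]) * dt < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = []
    for s, e in merged:
        onset, offset = times[s], times[s] + (e - s) * dt
        if offset - onset >= min_duration:
            events.append(DischargeEvent(onset=onset, offset=offset,
                                         peak_V=float(V[s:e].max())))
    return events


def discharge_stats(events, t_window_start: float,
                    t_window_end: float) -> DischargeStats:
    """Event frequency (Hz) and mean duration (s) over a time window.

    Frequency counts events whose *onset* falls in the window, divided by
    the window length.  With no events the duration is undefined (nan).
    """
    if t_window_end <= t_window_start:
        raise ValueError("window length must be positive")
    sel = [e for e in events if t_window_start <= e.onset < t_window_end]
    window_s = (t_window_end - t_window_start) / 1000.0
    if not sel:
        return DischargeStats(0.0, float("nan"), 0)
    mean_dur = float(np.mean([e.duration for e in sel])) / 1000.0
    return DischargeStats(len(sel) / window_s, mean_dur, len(sel))


def classify_events(events, sle_duration: float = SLE_DURATION_MS):
    """Split events into seizure-like events (long) and short discharges."""
    sles = [e for e in events if e.duration > sle_duration]
    ssds = [e for e in events if e.duration <= sle_duration]
    return sles, ssds


#: within a seizure-like episode bursts recur every ~1 s, far below the
#: ~5 s inter-discharge interval of the steady-state regime
EPISODE_MERGE_GAP_MS = 2000.0


def detect_episodes(times, V,
                    threshold: float = DEFAULT_THRESHOLD_MV,
                    min_duration: float = DEFAULT_MIN_DURATION_MS,
                    merge_gap: float = EPISODE_MERGE_GAP_MS,
                    ) -> list[DischargeEvent]:
    """Episode-level detection for seizure-like events.

    Identical to :func:`detect_discharges` but with an episode-scale
    merge gap, so a depolarized plateau carrying a dense burst cluster —
    the mean-field appearance of a seizure-like event — registers as one
    long event instead of many short ones.
    """
    return detect_discharges(times, V, threshold=threshold,
                             min_duration=min_duration, merge_gap=merge_gap)


# ---------------------------------------------------------------------------
# Input conductance from current steps
# ---------------------------------------------------------------------------

def input_conductance(delta_V: float, I_step: float = 25.0) -> float:
    """Input conductance ``I_step / delta_V`` (nS), Ohm's law.

    Pass magnitudes (or consistent signs); the result is reported
    positive for hyperpolarizing steps.
    """
    if delta_V == 0:
        raise ZeroDivisionError("delta_V must be nonzero")
    return I_step / delta_V


def step_delta_v(times, V, step_onset: float, step_duration: float = 250.0,
                 plateau_window: float = 50.0,
                 baseline_window: float = 50.0) -> float:
    """Voltage deflection (mV, magnitude) of one current-step response.

    The plateau is the mean over the last ``plateau_window`` ms of the
    step; the baseline is the mean over ``baseline_window`` ms just
    before the onset.
    """
    times = np.asarray(times, dtype=float)
    V = np.asarray(V, dtype=float)
    t_end = step_onset + step_duration
    plateau = (times >= t_end - plateau_window) & (times < t_end)
    base = (times >= step_onset - baseline_window) & (times < step_onset)
    if not plateau.any() or not base.any():
        raise ValueError("step window not covered by the trace")
    return float(abs(V[plateau].mean() - V[base].mean()))


# ---------------------------------------------------------------------------
# Curve fits
# ---------------------------------------------------------------------------

_N_STARTS = 5


def _multistart_ls(residual, x0, perturb, bounds, rng_seed=0):
    """Bounded least squares from ``x0`` plus perturbed restarts."""
    rng = np.random.default_rng(rng_seed)
    best = None
    starts = [np.asarray(x0, dtype=float)]
    for _ in range(_N_STARTS - 1):
        starts.append(starts[0] * (1.0 + perturb * rng.standard_normal(len(x0)))
                      + 1e-6 * rng.standard_normal(len(x0)))
    lo, hi = bounds
    for s in starts:
        s = np.clip(s, lo, hi)
        try:
            res = least_squares(residual, s, bounds=bounds)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def fit_conductance_decay(times_since_discharge, G) -> DecayFit:
    """Fit ``A_baseline + A_transient * exp(-t/tau)`` to conductance samples.

    Expects at least 4 points (the step protocol applies 4 steps at 1-s
    intervals after each discharge).  Degenerate flat data yields
    ``A_transient ~ 0`` with an unidentifiable tau, flagged.
    """
    t = np.asarray(times_since_discharge, dtype=float)
    G = np.asarray(G, dtype=float)
    if t.shape != G.shape or t.size < 4:
        raise ValueError("need >= 4 (t, G) samples of equal length")
    span = float(t.max() - t.min())
    g_min, g_max = float(G.min()), float(G.max())
    x0 = [max(g_min, 0.0), max(g_max - g_min, 1e-6), max(span / 3.0, 1e-3)]

    def residual(x):
        return x[0] + x[1] * np.exp(-t / x[2]) - G

    bounds = ([0.0, -np.inf, 1e-9], [np.inf, np.inf, np.inf])
    best = _multistart_ls(residual, x0, 0.3, bounds)
    flags = []
    if best is None or not best.success:
        flags.append("no-convergence")
    if best is None:
        return DecayFit(float("nan"), float("nan"), float("nan"),
                        float("nan"), ("no-convergence",))
    A_b, A_t, tau = best.x
    rss = float(2.0 * best.cost)
    if abs(A_t) < 1e-6 * max(abs(A_b), 1.0) or tau > 100.0 * span:
        flags.append("tau-unidentifiable")
    return DecayFit(float(A_b), float(A_t), float(tau), rss, tuple(flags))


def build_iv(holding_V, I_post, I_baseline) -> pd.DataFrame:
    """Baseline-subtracted I-V dataset, sorted by voltage.

    Subtracting the pre-discharge baseline current isolates the transient
    component of the activity-induced conductance.
    """
    v = np.asarray(holding_V, dtype=float)
    post = np.asarray(I_post, dtype=float)
    base = np.asarray(I_baseline, dtype=float)
    if not (v.shape == post.shape == base.shape):
        raise ValueError("holding_V, I_post, I_baseline must share a shape")
    if v.size < 2:
        raise ValueError("need at least 2 holding voltages")
    order = np.argsort(v)
    return pd.DataFrame({"V_mV": v[order], "I_pA": (post - base)[order]})


def _zero_crossing(v: np.ndarray, i: np.ndarray) -> float:
    sign = np.sign(i)
    idx = np.flatnonzero(np.diff(sign) != 0)
    if len(idx) == 0:
        return float(v[np.argmin(np.abs(i))])
    j = idx[0]
    # linear interpolation between the bracketing samples
    return float(v[j] - i[j] * (v[j + 1] - v[j]) / (i[j + 1] - i[j]))


def fit_iv(iv: pd.DataFrame) -> IVFit:
    """Fit the rectifying model ``a * f(v) * (v - V_rev)`` to an I-V dataset.

    ``f(v) = 1/(1+exp((v-h)/k))`` is a Boltzmann factor describing inward
    rectification.  The fit is flagged when all points lie on one side of
    the zero crossing (V_rev is then an extrapolation).
    """
    v = np.asarray(iv["V_mV"], dtype=float)
    i = np.asarray(iv["I_pA"], dtype=float)
    if v.size < 5:
        raise ValueError("need >= 5 I-V points")
    flags = []
    if np.all(i >= 0) or np.all(i <= 0):
        flags.append("V_rev-extrapolated")
    v_rev0 = _zero_crossing(v, i)
    span = float(v.max() - v.min())
    # gain heuristic from the most hyperpolarized points where f ~ 1
    lo = v <= v.min() + 0.3 * span
    denom = v[lo] - v_rev0
    denom[denom == 0] = np.nan
    a0 = float(np.nanmedian(i[lo] / denom))
    if not np.isfinite(a0) or a0 == 0:
        a0 = 1.0
    x0 = [a0, v_rev0, v_rev0 - 5.0, 10.0]

    def residual(x):
        f = 1.0 / (1.0 + np.exp((v - x[2]) / x[3]))
        return x[0] * f * (v - x[1]) - i

    bounds = ([-np.inf, -np.inf, -np.inf, 1e-6],
              [np.inf, np.inf, np.inf, np.inf])
    best = _multistart_ls(residual, x0, 0.2, bounds)
    if best is None:
        return IVFit(*([float("nan")] * 5), float("nan"), ("no-convergence",))
    if not best.success:
        flags.append("no-convergence")
    a, v_rev, h, k = best.x
    ri = rectification_index(v, i, v_rev)
    return IVFit(float(a), float(v_rev), float(h), float(k), ri,
                 float(2.0 * best.cost), tuple(flags))


def rectification_index(V, I, V_rev: float) -> float:
    """Ratio of I-V slopes above vs. below the reversal potential.

    Straight lines are fitted separately to the points with V > V_rev and
    V < V_rev; values < 1 indicate inward rectification.  Undefined (nan)
    with fewer than 2 points on either side.
    """
    V = np.asarray(V, dtype=float)
    I = np.asarray(I, dtype=float)
    above, below = V > V_rev, V < V_rev
    if above.sum() < 2 or below.sum() < 2:
        return float("nan")
    slope_pos = np.polyfit(V[above], I[above], 1)[0]
    slope_neg = np.polyfit(V[below], I[below], 1)[0]
    return float(slope_pos / slope_neg)


def post_discharge_current(times, I, events, delay: float = 1500.0,
                           baseline_window: float = 100.0) -> list[float]:
    """Baseline-subtracted current (pA) ``delay`` ms after each event offset.

    The baseline is the mean current over ``baseline_window`` ms before
    the event onset.  Events whose sampling point lies beyond the trace
    end are skipped.
    """
    if delay <= 0:
        raise ValueError("delay must be positive")
    times = np.asarray(times, dtype=float)
    I = np.asarray(I, dtype=float)
    out = []
    for e in events:
        t_meas = e.offset + delay
        if t_meas > times[-1]:
            continue
        base = (times >= e.onset - baseline_window) & (times < e.onset)
        baseline = float(I[base].mean()) if base.any() else 0.0
        out.append(float(np.interp(t_meas, times, I)) - baseline)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trace_csv(path) -> pd.DataFrame:
    """Read a trace CSV in the documented dialect (time_ms, V_mV, ...)."""
    df = pd.read_csv(path)
    if "time_ms" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_ms'")
    return df
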