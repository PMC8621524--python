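# Methods

## Model structure and assumptions

The simulator implements a mean-field ("neural mass") description of a
cortical slice generating status-epilepticus-like activity. It is a
two-population extension of the Epileptor-2 family of discharge models:
instead of resolving individual neurons, each population is reduced to
one membrane-voltage variable whose firing rate is an instantaneous
function of voltage. The assumptions that matter:

- **Two populations, one bath.** A large main population and a small
  spontaneously bursting trigger population share the extracellular
  space, so `[K]_o`, `[Na]_i`, the pump current, the synaptic resources
  and the activity-dependent conductance gates are single global
  variables. Only the main population's firing rate ν(V) drives the
  resource and gate dynamics; the trigger population contributes
  through its threshold gate `T_syn` (unit-step input-output function
  at −35 mV).
- **No inhibition.** The experimental preparation contains gabazine, so
  GABA_A currents are absent by construction; GABA_B and Cl⁻ dynamics
  are likewise omitted (Cl⁻ concentrations fixed, its reversal −67.5 mV).
- **Discharge termination** arises from three interacting mechanisms:
  fast use-dependent synaptic depression (χ_syn), the shunting effect of
  the activity-dependent conductances, and the Na⁺/K⁺-pump current that
  grows as `[K]_o` and `[Na]_i` accumulate.
- **Units.** mV, ms, nS, pA, pF, mM throughout; with these choices the
  current balance needs no conversion factors. The single conversion is
  the pump term in the ion equations: a current I (pA) over the
  extracellular volume per neuron v (µm³) gives a flux
  `I·10³/(F·v)` mM/ms (numerically, mol/(L·s) ≡ mmol/(L·ms)); the
  intracellular compartment is γ = 5 times larger, so the Na⁺ flux
  carries an extra 1/γ.

## Key parameters

All defaults are the published study conditions; the ones most worth
knowing when exploring the model:

| parameter | default | meaning |
|---|---|---|
| `g_K_leak, g_Na_leak, g_Cl_leak` | 1.9, 0.4, 0.7 nS | leak conductances (sum = 3 nS baseline `G_input`) |
| `g_trig`, `g_Glut` | 9.5, 30 nS | trigger and recurrent glutamatergic maxima |
| `g_trans`, `g_pers` | 2, 2 nS | transient / persistent Ca-dependent conductance maxima |
| `tau_trans`, `tau_pers` | 920 ms, 35 s | their decay times (transient value from the measured post-discharge decay) |
| `m_K, m_Na` | 0.8, 0.2 | ion mixture of the transient current → reversal ≈ −69.9 mV at baseline ions |
| `I_pump_max` | 23 pA | pump saturation current |
| `mu/sigma/lambda_noise` | 8 nS / 1.5 nS / 1.5 Hz | shot-noise jump statistics and rate |
| `block_fraction` | 0.3 | CP-AMPAR share of the AMPAR conductance removed by the simulated blocker |
| window 120–480 s, block at 450 s | — | sigmoid edges 10 s and 15 s respectively |

The noise-free system (window off) rests at −72.9 mV where leaks balance
the pump; with the transient conductance fully recruited the baseline
sits near −74.7 mV, matching the hyperpolarization seen between
steady-state discharges.

## Numerical scheme

Explicit Euler with dt = 0.05 ms (hard cap 0.1 ms; the fastest time
constant is 25 ms, and the recruited membrane time constant C/G stays
above ~3 ms). Euler is the reference because the shot noise is a jump
process: each Poisson event adds its amplitude to `G_noise` exactly at
the step boundary containing it, which a higher-order smooth scheme
would not represent any better. A Richardson check (dt vs dt/2 vs dt/4
on a noise-free segment) confirming first-order endpoint convergence is
part of the test suite, as is a bit-level comparison of the compiled
kernel against the pure-Python reference step.

Event times are drawn as exponential inter-arrivals, then amplitudes
(Gaussian mean 8, s.d. 1.5 nS, redrawn if negative — a 5.3 σ tail), in
that fixed order, so a seed fully determines a trace. Gate variables
are clamped to [0, 1] after each step; the maximum clamp magnitude is
recorded and stays at round-off level at the reference step size.
Non-finite states abort the run with the offending variable and time.

Recorded traces store the ten state variables (default 1-ms sampling);
derived currents and conductances are recomputed from the recorded
state through the same model functions, so they can never drift out of
sync with it.

## Analysis choices

- **Discharge detection** is maximal-interval thresholding at −35 mV
  (the trigger threshold separates sub-threshold noise from discharges)
  with merge gap 200 ms and minimum duration 100 ms; all three exposed.
  The published recordings do not state a detection rule, so this is a
  package convention, and only onset/offset/duration are treated as
  contractual in tests.
- **Seizure-like events.** In a mean-field model an SLE appears as a
  depolarized plateau (tens of seconds, elevated `[K]_o`) carrying a
  dense cluster of bursts with ~0.5–1.5 s gaps, not as one unbroken
  supra-threshold excursion. `detect_episodes` therefore applies the
  same rule with an episode-scale merge gap (2 s, well below the ~5 s
  inter-discharge interval of the steady-state regime) and events
  longer than 5 s are classified as SLEs. At post-block rates
  (~0.5 Hz) inter-event gaps approach the episode merge gap, so episode
  counts are only meaningful before the block — the run summary
  restricts its SLE count accordingly.
- **Fits** use bounded, unweighted least squares with five starts from
  perturbed data-driven heuristics (decay: `A_baseline = min G`,
  `τ = span/3`; I-V: reversal from the interpolated zero crossing, gain
  from the hyperpolarized limb). Degenerate cases are flagged rather
  than guessed: flat decay data (`A_transient ≈ 0`, τ unidentifiable),
  one-sided I-V data (extrapolated reversal).
- **Input conductance** from step responses uses the mean over the last
  50 ms of a 250-ms, −25 pA step against a 50-ms pre-step baseline.
  Ohm's-law estimates measured this way on the simulator agree with the
  closed-form total conductance (leaks + gated activity-dependent
  terms) to within 10 % along the post-discharge decay; the residual
  discrepancy is the chord-vs-slope difference of the rectifying
  Boltzmann factor, plus the decay of the transient gate within a step.
- **Rectification index** is the ratio of straight-line slopes fitted
  separately above and below the reversal potential. Which points enter
  each limb is not specified in the experimental literature for this
  preparation; the per-side linear fit over all available points is our
  documented choice. Note the reference rectifying curve is nearly flat
  (slightly non-monotonic) above its reversal, so the index on the
  standard −107…−27 mV grid is close to zero.

## Synthetic data

The fixtures module emulates the three data shapes the analysis layer
consumes: replicate decay series (defaults 4.1 + 1.5·e^{−t/920 ms} nS
sampled at 0.5–3.5 s, 13 replicates, 0.1 nS noise), rectifying I-V
samples (gain 2.25 nS, reversal −60.28 mV, Boltzmann −65.63/9.82 mV on
−107…−27 mV), and voltage traces with trapezoidal discharges implanted
at renewal-process onsets (0.21 Hz, 480 ms, baseline −74.7 mV). Noise
is i.i.d. Gaussian per sample; real recordings have colored noise and
cell-to-cell variability that these fixtures deliberately do not
reproduce, so fixture-based tests validate the estimators' correctness
on their own model families, not robustness to every property of real
data. Each generator returns its ground truth beside the data; the
round trip generate → analyze → recover is the module's defining
property. With only four sample times the three-parameter decay fit is
intrinsically ill-conditioned: at the default noise level the
replicate-averaged τ estimate has a standard deviation near 150 ms, so
single-seed estimates scatter accordingly (the amplitude parameters are
far tighter).

## Extensions beyond the published equations

Two hooks extend the printed model without changing its defaults:
`nmda_scale` multiplies the NMDAR term of the recurrent input
(< 1 emulates an NMDAR antagonist such as MK-801), and a rectangular
current-step protocol (`inj_onsets`, −25 pA × 250 ms by default) can be
injected into the main population to measure input conductance exactly
as the experimental protocol does. With `nmda_scale = 1` and no steps
the equations are the published ones.

## Known limitations

- Mean-field voltages are population averages: spike shapes, unit
  activity and within-population heterogeneity are absent, so detected
  "discharges" are envelope events.
- No spatial structure, no GABAergic currents, no Cl⁻ dynamics, no
  adaptive step-size control.
- The drug block is a phenomenological conductance scaling; receptor
  kinetics and pharmacological selectivity are out of scope.
- Problem sizes used in the shipped tests (600-s runs over five seeds,
  200-s noise-statistics runs, 50-draw fit-recovery grids) were chosen
  to make the distributional checks statistically meaningful while the
  whole suite stays fast on a single CPU.
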