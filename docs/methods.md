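# Methods

## The plasticity model

`tstdpsim` simulates spike-timing-dependent plasticity (STDP) at two levels
of description: a mathematical rule and a behavioral model of an analog
CMOS synapse that realises the rule in accelerated time.

**Pair rule (PSTDP).** Each post-synaptic spike at time `t` potentiates the
synapse by `A+ · exp(-Δt/τ+)` where `Δt = t − t_pre` is the lag to the
nearest earlier pre-synaptic spike; each pre-synaptic spike depresses it by
`A− · exp(-Δt′/τ−)` with `Δt′` the lag to the nearest earlier post spike.
The sign convention throughout the package is `dt = t_post − t_pre`:
positive `dt` is the causal (pre-before-post) order that potentiates at low
repetition rates.

**Triplet rule (TSTDP).** Each pair term is multiplied by a bracket that
also senses the previous spike of the *same* train:

    post spike t:  Δw += exp(-(t − t_pre)/τ+) · [A2+ + A3+ · exp(-(t − t_prevpost − ε)/τ_y)]
    pre  spike t:  Δw −= exp(-(t − t_post)/τ−) · [A2− + A3− · exp(-(t − t_prevpre  − ε)/τ_x)]

The triplet term is present only when a previous same-train spike exists;
`ε` (default 1 µs biological) reads the same-train trace just *before* the
current spike resets it. Interactions are **nearest-spike**: every spike
supersedes earlier spikes of its own train, so each update sees only the
most recent opposite-train spike. The implementation is organised as
trace-resets evaluated per event; a brute-force oracle that explicitly
searches the full opposite train for every spike is part of the test suite
and must agree exactly.

Two algebraic organisations of the update are implemented — the expanded
sum of two exponential products and the factorised form natural to the
hardware (common pair factor times an amplitude bracket). They are the
same algebra; their identity to 1e−12 relative on randomized trains is an
asserted invariant.

**Rule variants.** `pstdp` (A3± = 0), `tstdp_full`,
`tstdp_minimal_hippocampal` (A3− = 0; fits pairing + triplet + quadruplet
phenomenology with one parameter set) and `tstdp_minimal_visual_cortex`
(A3− = A2+ = 0; frequency-dependent pairing and rate-based behaviour).

**Tie-break.** Coincident pre and post spikes are processed pre-first, so
the pair contributes a potentiation with `dt = 0`. None of the stimulation
protocols produce exact coincidence; the choice only pins down determinism.

**Defaults.** The presets use representative nearest-spike parameter
magnitudes from the experimental STDP literature: τ+ = 16.8 ms,
τ− = 33.7 ms, τ_x = 101 ms, τ_y = 114 ms; hippocampal-style amplitudes
A2+ = 4.6e−3, A2− = 3.0e−3, A3+ = 9.1e−3; visual-cortex-style A2+ = 0,
A2− = 8e−3, A3+ = 5e−2. Weight changes are dimensionless fractions;
weights are unbounded at the rule level (saturation is a circuit property).

## Stimulation protocols

All generators work on the biological timescale with 1 ms pulses and
enforce the spike-train invariants (strictly increasing times, same-train
gaps ≥ one pulse width):

- **Pairing**: `n` pre/post pairs with offset `dt` at repetition rate ρ
  (default 60 pairs; |dt| must be below the pair period, and dt = 0 is
  rejected as physically meaningless coincident pulses).
- **Triplet** (pre-post-pre / post-pre-post) with gaps `dt1`, `dt2`.
- **Extra triplet**: all six orderings of three spikes over two gaps,
  repeated at 0.2 Hz. `dt1`/`dt2` are taken as consecutive-gap magnitudes
  and the combo label is authoritative for the ordering; the six labels ×
  gap grid reproduce the standard six-region triplet maps. (Signed-gap
  conventions in the literature are mutually inconsistent across the two
  triplet families, so the package fixes the unambiguous gap+label form.)
- **Quadruplet**: a post-pre and a pre-post pair (intra-pair offset 5 ms by
  convention) separated by `T`, measured between the two inner spikes;
  `T > 0` puts the post-pre pair first, `T < 0` mirrors the order.
- **Poisson pair**: two independent homogeneous Poisson trains, thinned so
  no two same-train spikes fall within one pulse width (overlapping pulses
  cannot be represented by the hardware). The thinning is exactly the
  sequential keep-if-far-enough rule, implemented by sparse passes.
- **delay_train** shifts a train by a fixed delay; the circuit derives its
  previous-spike inputs this way (one pulse width).

## The circuit behavioral model

The synapse circuit operates its transistors in weak inversion, where the
drain current is exponential in the gate voltage, `I = I0·exp(κV_g/U_T)`.
Each plasticity time constant is made by a node capacitor `C_p` that a
spike pulse pulls to ground and a bias-controlled current `I_ramp`
recharges linearly toward the supply; the node voltage gates a branch
current onto (potentiation) or off (depression) the weight capacitor
`C_w`. A linear node ramp through the exponential gate characteristic
yields an exponential current decay with

    τ = C_p · U_T / (κ · I_ramp),     window = C_p · V_dd / I_ramp,

the *window* being the time for the ramp to reach the rail, beyond which
the branch is off (the gate current at the rail, `exp(-κV_dd/U_T)` ≈
e^−89 of its peak, is treated as zero). Amplitude branches carry
`I_X = I0·exp(κV_X/U_T)` set by their gate biases.

The circuit runs 1000× faster than biology with 1 µs pulses; trains enter
in biological seconds and are rescaled internally, and every reported
result is in circuit volts on the weight node (rescaled to biological time
for display). The weight voltage is clamped to the rails [0, V_dd];
potentiation moves it upward by convention.

Variants: **full18** (all branches), **minimal14** (triplet-depression
branch M1–M4 removed, sufficient for pairing/triplet/quadruplet
phenomenology since A3− ≈ 0 there), **minimal13** (additionally drops the
pair-potentiation amplitude device M7, i.e. A2+ = 0, sufficient for
frequency-dependent pairing and rate-based behaviour).

**Bias bookkeeping.** Ramp biases follow the PMOS convention (higher bias →
smaller recharge current → larger τ). The triplet-depression branch of the
full circuit carries its own amplitude bias `V_A3m` (default 0 V = branch
off): its ramp bias `V_tx` alone cannot double as an amplitude control,
since the two enter through opposite exponential conventions. Published
bias tables for such circuits list voltages without a recoverable
column-to-node mapping, so the package derives presets by inverting the
subthreshold mapping from rule parameters (`presets.biases_for_params`);
an event of unit exponential weight then moves the weight node by 0.1 V
per unit fractional weight change.

**Device defaults.** `I0` = 1 fA, κ = 0.7, `U_T` = 25.85 mV, `V_dd` =
3.3 V, `C_w` = 1 pF, node capacitors 5 fF. The subthreshold constants are
representative rather than process-specific and are fully configurable;
the node capacitors only set the τ scale jointly with the ramp currents,
so bias fitting absorbs their uncertainty.

### Two simulators, and how close they are

`simulate_event` applies the closed-form per-spike update (the circuit's
analytical abstraction): at each post spike,
`ΔV_w = (Δt_spk/C_w)·exp(-Δt1/τ+)·[I_A2p + I_A3p·exp(-Δt2/τ_y)]` within
the ramp windows, and symmetrically for depression.

`simulate_ramp_ode` integrates the mechanism: triangular node voltages
(grounded for one pulse width after their trigger, then linear to the
rail), subthreshold branch currents evaluated on the instantaneous node
voltages while the gating pulse of the opposite train is high, integrated
on `C_w` with sub-pulse steps (≤ pulse width / 10). The triplet nodes are
triggered by internally delayed copies of the trains (one pulse width),
the previous-spike inputs of the hardware.

The two schemes differ per pulse by a factor `(e^x − 1)/x` with
`x = Δt_spk/τ` (the event scheme samples the exponential at the pulse
onset lag; the ramp scheme integrates across the pulse after a one-pulse
hold). For canonical τ+ = 16.8 µs (circuit scale) that is ~3% per term;
protocols whose net change is a strong cancellation of potentiation
against depression (e.g. pre-post-pre at 5/5 ms) amplify the residual to
~7%. The cross-validation suite therefore compares the schemes at biases
realising τ ≥ ~30 µs circuit-scale (33.6/67.4/228 ms biological — ordinary
STDP magnitudes), where all compared protocols agree within 5%; the
presets for scientific use remain at the canonical values. This is a
property of the two integration schemes, not of the circuit.

With the ramp windows removed (`unbounded_windows`), the event simulator
*is* the triplet rule up to the global `Δt_spk/C_w` scale — an asserted
invariant tying the circuit model to the mathematics it implements.

## Rate-based (BCM-like) behaviour

Sweeping independent Poisson trains (pre rate fixed at 10 Hz, post rate
0→50 Hz, 10 train draws per point) maps timing-based plasticity onto
rate-based phenomenology: zero change without post activity, net
depression at low post rates, net potentiation at high rates, with a
single LTD→LTP crossing — the sliding modification threshold. The
crossing moves to higher rates as the pair-depression amplitude A2−
grows (any amplitude or time constant is exposed as a potential slider).
A pre-synaptically driven variant sets the post rate equal to the pre rate
(linear-neuron simplification) and shows the same LTD-then-LTP shape.

Sweep defaults: 200 s of Poisson activity per trial and 10 trials per
point, fixed once so that per-point means resolve the crossing region;
the acceptance sweeps use a grid refined below 12 Hz for the same reason.
`crossing_rate` interpolates the first negative-to-positive transition
linearly.

## Fitting

Goodness of fit is the normalized mean square error

    NMSE = (1/N) Σ_i ((Δw_exp_i − Δw_sim_i) / σ_i)²,

with σ_i each point's standard error of the mean; a fit within one SEM per
point scores ~1. Parameters are adjusted by a bounded derivative-free
Nelder–Mead simplex (scipy's implementation, the same family as Matlab's
`fminsearch`), with optional seeded multi-start; the returned point is
never worse than the start. Default bounds: amplitudes in [0, 0.1], time
constants in [1, 200] ms (typical STDP ranges). The circuit engine
co-fits one global volts-to-fraction scale factor, since circuit output is
a capacitor voltage while experimental weight changes are normalized
fractions.

The canonical experimental tables (13 hippocampal points: 2 pairing, 3
quadruplet, 8 triplet; 10 visual-cortex points: two offsets × five pairing
frequencies) are not distributed with the package. `make_synthetic_dataset`
generates datasets of exactly those compositions from known ground-truth
parameters, with SEMs of 10% of |Δw| (floored at 1e−3) and Gaussian
perturbation of the means scaled by `noise_scale`; at `noise_scale = 1`
the NMSE at the true parameters is a χ² mean of ~1, which calibrates what
a "good" fitted NMSE means. Transcribed experimental tables load through
the documented CSV layout. Because the synthetic generator shares the
forward model with the fitter, recovery tests demonstrate estimator
consistency and optimizer correctness — not that the rule describes any
particular biological dataset.

## Transistor mismatch

Fabrication scatters each transistor's threshold voltage; in weak
inversion a deviation `dV_th` rescales that device's current by
`exp(−κ·dV_th/U_T)` (positive deviations of the threshold magnitude weaken
conduction, for either polarity — with zero-mean Gaussian draws the sign
convention is immaterial to the distribution). The fixed label map:
amplitude devices rescale their branch currents (M7 → I_A2p; M12 → I_A2m;
M15, M16 → I_A3p; M3, M4 → I_A3m; the shared series devices M8, M9 touch
both potentiation branches and M10, M11 both depression branches); ramp
devices rescale τ and window together (M5 → τ+; M14 → τ−; M17 → τ_y;
M2 → τ_x); the switch devices M1, M6, M13, M18 are ideal and have no
effect.

The Monte Carlo draws i.i.d. `Normal(0, σ_vth)` per active transistor
(default σ = 10 mV, i.e. a 3σ point at 30 mV), re-evaluates every dataset
protocol with *fixed* biases, and records the NMSE per run; 1000 runs by
default, bit-reproducible under a fixed seed. σ = 0 collapses the
distribution onto the baseline and the spread grows monotonically with σ.

**Limitation.** Under this sensitivity model a 10 mV deviation moves a
device's current by ~±30%, so most MC runs land several SEM-widths from
baseline (right-skewed, heavy-tailed NMSE distributions; at seed 1 the
median NMSE is ~70× the baseline on the synthetic frequency-pairing set).
Reports of fabricated circuits of this family retaining near-baseline fits
in a majority of mismatch runs are *not* reproduced by this behavioral
abstraction — correlated layout effects, series-stack current limiting and
retuning headroom are outside its granularity. The MC machinery makes the
sensitivity explicit rather than asserting robustness.

## Numerical choices and degenerate inputs

- Event evaluation is vectorized per train (`searchsorted` nearest
  predecessors); rail clamping falls back to a sequential scan only when a
  trajectory would leave the rails.
- Empty trains, zero-rate Poisson inputs and spike-free simulations return
  exactly zero change; the zero-input ramp simulation rests all nodes at
  the rail.
- Cross-train pulses that would overlap on the accelerated timescale are
  rejected by the circuit simulators (the rule layer has no pulse physics
  and accepts them).
- The fitting objective precomputes each protocol's event geometry once
  (trains do not depend on parameters), making simplex evaluation cheap;
  the MC reuses cached geometry the same way since biases are fixed.
- Seeds: all stochastic components take integer seeds and derive
  per-trial/per-run streams via `SeedSequence`; identical configurations
  are bit-reproducible.

## What the tests do and do not show

The suite establishes internal correctness (closed forms, algebraic
identities, oracle equivalence, cross-simulator agreement, invariances),
faithful protocol construction, calibrated fitting on synthetic data, and
the statistical contracts of the stochastic components. It does not
establish agreement with any biological measurement: the experimental
datasets are external, and all quantitative results in the package are
computed on synthetic stand-ins whose generating model is the package's
own rule.
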