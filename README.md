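# tstdpsim

Triplet spike-timing-dependent plasticity, from rule to silicon.

Synapses strengthen or weaken depending on the relative timing of pre- and
post-synaptic spikes (STDP). Pair-based STDP — one exponential learning
window per spike pair — cannot reproduce several classic experiments:
triplet stimulation (pre-post-pre vs post-pre-post), quadruplets, the
frequency dependence of pairing, or rate-based BCM behaviour. The
*triplet* rule fixes this by letting each pair update also sense the
previous spike of the same train:

    post spike t:  Δw += exp(-(t−t_pre)/τ₊) · [A₂⁺ + A₃⁺·exp(-(t−t_prevpost−ε)/τ_y)]
    pre  spike t:  Δw −= exp(-(t−t_post)/τ₋) · [A₂⁻ + A₃⁻·exp(-(t−t_prevpre−ε)/τ_x)]

with nearest-spike interaction throughout. This package is for
computational neuroscientists and neuromorphic engineers who want to
simulate that rule and its compact analog-CMOS realisation: a handful of
subthreshold transistors running 1000× faster than biology (1 µs pulses),
where capacitor node ramps implement the exponential windows and a weight
capacitor integrates the branch currents.

It provides:

- **protocols** — generators for every standard stimulation paradigm
  (pairing, triplet, all-combination triplet, quadruplet, Poisson pairs),
  on the biological timescale;
- **rules** — reference PSTDP/TSTDP implementations (full and minimal
  variants), protocol runners, and BCM-style Poisson rate sweeps;
- **circuit** — a behavioral model of the 18-transistor triplet synapse
  and its 14/13-transistor minimal variants: bias-voltage → parameter
  mapping, an event-driven simulator, and a cross-validating time-stepped
  node-ramp simulator, with supply-rail clamping;
- **fitting** — NMSE goodness-of-fit, Nelder–Mead simplex fitting of rule
  parameters or circuit biases, and a synthetic-dataset generator
  mirroring the canonical 13-point (2 pairing / 3 quadruplet / 8 triplet)
  and 10-point frequency-pairing compositions;
- **mismatch** — Monte-Carlo transistor threshold-voltage mismatch
  analysis of the fitting error under fixed biases;
- a `tstdpsim` command-line interface for reproducible runs.

See `docs/methods.md` for the model, its assumptions and its limitations.

## Worked example

Triplet stimulation at matched (5 ms, 5 ms) timings, 60 repetitions at
1 Hz, with the hippocampal-style minimal parameter set — the experiment a
pair-based rule cannot get right:

```python
from tstdpsim import ProtocolSpec, run_protocol, simulate_event
from tstdpsim.presets import HIPPOCAMPAL_PARAMS, hippocampal_biases

for combo in ("pre_post_pre", "post_pre_post"):
    spec = ProtocolSpec("triplet", dt1=5e-3, dt2=5e-3, combo=combo, n_reps=60)
    dw = run_protocol(spec, HIPPOCAMPAL_PARAMS, "tstdp_minimal_hippocampal")
    pre, post = spec.build()
    dv = simulate_event(pre, post, hippocampal_biases()).total_dv
    print(f"{combo}: rule dw = {dw:+.4f}, circuit dV_w = {dv*1e3:+.3f} mV")
```

prints

```
pre_post_pre: rule dw = +0.0498, circuit dV_w = +4.983 mV
post_pre_post: rule dw = +0.4212, circuit dV_w = +42.117 mV
```

Post-pre-post potentiates ~8× more than pre-post-pre: the middle post
spike of post-pre-post both closes a causal pair and arms the triplet
trace for the final post spike, while pre-post-pre spends its second pre
spike on depression. A pair-based rule scores these two patterns
identically (one potentiation and one depression event at 5 ms each). The
circuit column is the voltage change on the 1 pF weight capacitor under
the matching bias preset — the same numbers scaled by 0.1 V per unit
weight change.

The same experiment from the shell, plus an STDP learning window:

```
tstdpsim triplet --preset hippocampal --out-dir out/
tstdpsim window --engine rule --preset hippocampal --dt-range -50:50:25 --out-dir out/
```

The window CSV shows potentiation for causal and depression for
anti-causal offsets, decaying exponentially with |dt|:

```
dt_ms,dw
-50.0,-0.0408
-25.0,-0.0857
25.0,0.0623
50.0,0.0141
```

Every command writes a `meta.json` (full configuration, seed, version)
alongside its CSV/JSON outputs, so a run can be re-executed exactly.

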