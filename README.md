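# cav33sim

Biophysical modelling toolkit for **Cav3.3 (T-type) calcium-channel gating
variants** and their neuronal consequences. Gain-of-function missense
variants in *CACNA1I* (I860N, I860M, I1306T, M1425I) left-shift the
channel's voltage dependence and slow its kinetics; this package provides
the computational chain from those gating parameters to cellular phenotype:

1. **`cav33sim.gating`** — Hodgkin–Huxley m²h channel model: Boltzmann
   steady states `m_inf(V) = 1/(1+exp(-(V-V½)/k))`, tabulated τ(V), exact
   exponential gate updates, ohmic current `I = g·m²h·(V-E_Ca)`, window
   currents, and a parameter file for wild-type + the four variants.
2. **`cav33sim.vclamp`** — the synthetic patch-clamp rig: I–V families,
   steady-state inactivation, tail-current and action-potential-clamp
   protocols, solved segment-by-segment in closed form, with optional
   Gaussian recording noise.
3. **`cav33sim.fitting`** — the current-analysis pipeline: peak/I–V
   analysis, fractional-activation and inactivation Boltzmann fits,
   mono-exponential kinetics, window comparison, per-spike charge metrics.
4. **`cav33sim.neuron`** — a single-compartment thalamic reticular nucleus
   (TRN)-style neuron (Traub Na/K + leak + the T current in density mode):
   rheobase searches, spike-train metrics, rebound/free-run protocols,
   firing-mode classification (LTF / SO), spike-shape metrics.
5. **`cav33sim.workbench`** — pipelines with run manifests, including the
   variant firing-phenotype table.

There is no command-line interface; the importable API plus the narrative
scripts in `examples/` are the public face.

## Worked example

```python
import numpy as np
from cav33sim import gating, vclamp, fitting

params = gating.load_shipped_params()          # WT, I860N, I860M, I1306T, M1425I
proto = vclamp.make_iv_protocol()              # hold -100 mV, 500-ms steps -90..+30

def activation_vhalf(p):
    sweeps = vclamp.simulate_sweeps(p, proto)
    levels = np.asarray(proto.extras["levels"])
    peaks = np.array([i.min() for i in sweeps.current])
    return fitting.fractional_activation(fitting.fit_iv(levels, peaks)).v_half

wt = activation_vhalf(params["WT"])
for name in ("I860N", "I860M"):
    print(name, round(activation_vhalf(params[name]) - wt, 1), "mV")
```

prints

```
I860N -15.5 mV
I860M -8.1 mV
```

— the measured hyperpolarizing shifts of the activation curve: the severe
variant I860N moves activation 15.5 mV toward the resting potential (a
strong gain of function), the mild variant I860M only 8.1 mV. Running
`examples/05_trn_firing_phenotypes.py` carries the same parameters into the
neuron model and prints, per variant, the rheobase (wild-type 0.29 nA,
falling to 0.18 nA for I860N), the evoked train at 0.35 nA, and whether
rebound activity is transient (wild-type) or continuous (I860N).

The `examples/` scripts cover the other capabilities: window currents
(`01`), I–V analysis (`02`), the full variant fingerprint table (`03`), and
action-potential-clamp calcium charge (`04`).

## Reproduction script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's headline computations from scratch — the voltage-clamp
pipeline on freshly synthesised sweep families (activation shifts, 500-ms
fractional inactivation, window comparison) and the TRN firing-phenotype
table under the frozen base model (rheobases, rebound metrics, continuity
flags, with reference values and tolerance flags) — printing each table and
writing the results JSON. `scripts/calibrate_base_model.py` documents the
one-time calibration that produced the frozen neuron configuration.

## Scientific notes

Model assumptions, the provenance of every shipped parameter, calibration
procedure and known limitations are documented in `docs/methods.md`.
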