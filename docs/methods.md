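# Methods

`cav33sim` models the gating of the Cav3.3 (T-type) calcium channel and its
four disease-associated variants (I860N, I860M, I1306T, M1425I), synthesises
whole-cell voltage-clamp data from that model, analyses such data the way a
patch-clamp study would, and embeds the channel in a conductance-based
thalamic reticular nucleus (TRN)-style neuron to convert gating parameters
into firing phenotypes.

## Channel model

The channel follows the Hodgkin–Huxley m²h formulation standard for
T-currents:

    m_inf(V) = 1 / (1 + exp(-(V - V½_act)/k_act))
    h_inf(V) = 1 / (1 + exp( (V - V½_inact)/k_inact))
    I(V)     = g_max · m^p · h · (V - E_Ca),   p = 2, E_Ca = +120 mV

Each gate relaxes first-order toward its steady state; at constant voltage
the update `x ← x_inf + (x - x_inf)·exp(-dt/τ)` is exact, which the code
exploits throughout.

**Choices made where the source characterisation is open:**

* *Gate exponent p = 2.* The m²h form is the standard T-current
  parameterisation in the thalamic modelling lineage; `p` is a parameter so
  p = 1 reproduces simpler fits.
* *Ohmic driving force.* A linear driving force with E_Ca = +120 mV is used;
  whether a constant-field (GHK) flux was used in the published simulations
  is not stated. The ohmic choice keeps the current proportional to g_max
  and makes analytic cross-checks exact.
* *τ(V) as tables.* Time constants are supplied as (V, τ) tables with linear
  interpolation and constant extrapolation, because experimental kinetics
  are reported at discrete test potentials. The m-gate uses a separate
  deactivation table at hyperpolarized voltages (tail-current kinetics),
  spliced below the activation table into one continuous curve so the neuron
  model sees no discontinuity.

## The shipped parameter file

The study reports variant effects as *differences* from wild-type; the
underlying absolute wild-type table (Supplementary material) is not part of
the extracted text available here. The shipped file
`params/cav33_variants.yaml` therefore:

1. fixes wild-type absolute values at literature-typical numbers chosen once
   so the wild-type m²h window peaks near −50 mV and a 500-ms pulse at Vmax
   inactivates 95–98 % of the current;
2. derives each variant by applying the reported deltas — activation-curve
   shifts of 15.5 / 8.1 / 14.5 / 13.7 mV (I860N/I860M/I1306T/M1425I),
   inactivation shifts of 6.6 / 5.9 / 0 / 6.8 mV, doubled conductance for
   M1425I, and τ scalings consistent with the reported kinetics (time to
   peak >3× / ~2× wild-type; deactivation ~9× slower for I860N, unchanged
   for I860M; 500-ms inactivation ≈52 % / ≈87 %).

Because the *measured* activation midpoint from a peak-current analysis is
biased by 1–2 mV relative to the underlying Boltzmann midpoint when kinetics
are slow (inactivation during the rising phase depresses peaks unevenly
across voltages), the underlying variant midpoints were solved (once, before
any test existed; provenance comments sit next to each value in the YAML) so
that the
full pipeline — simulate sweeps → peak I–V → conductance transform →
Boltzmann fit — returns the reported shifts exactly. For I1306T the main
text (14.5 mV) and a figure legend (6.6 mV) disagree; the file follows the
main text.

## Synthetic voltage clamp

All step protocols (I–V families, steady-state inactivation, tail currents)
are piecewise-constant, so the generator evaluates the gate trajectories
segment-by-segment in closed form — simulated sweeps are exact at the sample
times, and `dt` only sets the sampling grid. The smooth action-potential
command (piecewise-exponential, −70 → +20 mV, 1-ms rise, 4-ms decay,
repeated 99× at 20 Hz) is represented as a midpoint staircase, which is
second-order accurate; per-AP charges converge to <0.1 % under sample-rate
halving, though individual samples lying on the ~90 mV/ms command edge
differ at O(dt·slope) by construction.

Recording noise is white Gaussian, reproducible by seed. No leak/capacitive
artefacts, series-resistance error or line noise are simulated (a constant
ohmic leak can be superimposed for robustness tests); a green fit-recovery
test therefore establishes correctness of the analysis pipeline on ideal
currents plus white noise, not robustness to every artefact of real
recordings.

## Analysis pipeline

* **Fits** use damped least squares (`scipy.optimize.curve_fit`) with three
  starts jittered ±20 % (fixed seed) and report flagged results rather than
  raising on non-convergence.
* **Fractional activation** uses the conductance transform
  G(V) = I_peak/(V − E_rev) with E_rev from the I–V fit (not tail currents).
* **Steady-state inactivation** measures availability as the post/pre test-
  current ratio *at the matched latency of the pre-pulse peak*, averaged
  over 2 ms. This equals the peak ratio (pre and post share kinetics) but,
  unlike a min-of-samples ratio, is unbiased under noise — with 5 %-of-peak
  noise the recovered midpoint is unbiased within 1 mV. The descending
  Boltzmann fit carries a free amplitude because availability is normalised
  at the −100 mV holding, where a channel with a very negative midpoint is
  already partly inactivated.
* **Tail fits** start 2 samples after repolarization (real data carry a
  capacitive transient there; none is simulated, the convention is kept).

## TRN neuron model

Single compartment: transient Na⁺ and delayed-rectifier K⁺ currents with
Traub-type kinetics (voltage shift −57 mV sets the spike threshold), ohmic
leak, and the Cav3.3 model in density mode. Integration is fixed-step
(default dt = 0.025 ms): exponential updates for all gates, forward Euler
for the voltage; gate steady states and per-step decay factors are
pre-tabulated on a 0.05-mV grid. Spike detection: suprathreshold epochs
above −20 mV, one spike per epoch at its voltage maximum, 2-ms refractory.

"Setting the resting membrane potential" (−110 mV before rheobase pulses,
the −60 mV up-state before rebound runs) is realised by re-anchoring the
leak reversal so the stated level is a zero-current fixed point — the
standard way of positioning a model's rest. An injected-bias implementation
was rejected: the large depolarizing current needed to hold −60 mV from a
−72 mV leak drives artefactual tonic firing.

**Calibration.** The published simulations used a thalamic model whose
morphology and densities are not printed, so the base cell was calibrated
once (`scripts/calibrate_base_model.py`) to two wild-type anchors — rheobase
0.29 nA and a transient rebound burst with f0 near 255 Hz (within 15 %) —
plus two qualitative published behaviours used to select among
anchor-satisfying candidates: the wild-type rebound must be transient and
the severe variant I860N must sustain continuous rebound activity over the
full 10-s run. The result is frozen in `params/trn_base_model.yaml`
(g_leak 0.35, g_T 1.35, g_Na 60, g_K 80 mS/cm², E_K −95 mV, area
1.925·10⁻⁵ cm²; wild-type rebound f0 = 261.4 Hz). Because all currents are
densities, the area only converts nA to µA/cm² and is solved analytically
from the rheobase anchor. All variant simulations reuse the frozen file and
swap only the gating parameters, so the variant rheobases are predictions:
all four land within ±0.02 nA of the reported values (0.24/0.18/0.18/0.18
vs 0.22/0.20/0.19/0.18 nA for I860M/M1425I/I1306T/I860N).

**Known limitations of the frozen model.** The wild-type rebound burst is
transient but lasts ~1 s rather than the reported ~100 ms; evoked train
durations at 0.35 nA are longer than reported (wild-type 238 vs 132.7 ms);
mutant rebound frequencies are lower than reported; I860M rebound activity
is long-lasting but not continuous over 10 s, and the I1306T cell settles
into a spike-free depolarized state after release instead of the reported
continuous firing.
The firing-mode taxonomy (LTF / SO / LTF+SO / silent) implements the
published classification rule, but the slow-oscillation mode arises in
chromaffin cells, whose membrane differs from this model's Na/K machinery —
the classifier is validated on constructed traces, and the simulated I860N
cell classifies as continuous LTF. No Ih, calcium-activated or synaptic
currents are included; there is no multicompartment morphology and no
stochastic gating.

## Numerical conventions

Voltages are absolute membrane potentials in mV; inward current is negative;
whole-cell conductance in nS (current in pA), density mode in mS/cm²
(µA/cm²); charge in pC (1 pA·ms = 10⁻³ pC). Trapezoid integration is used
for window areas, charges and plateau areas. Rheobase searches ascend a
0.01-nA grid, so returned rheobases are grid multiples; ties are impossible
by construction. The 90–10 % decay slope is the chord between the two
amplitude crossings (linearly interpolated between samples), not a tangent.
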