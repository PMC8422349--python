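"""Single-compartment conductance-based model of a TRN-style neuron.

The cell carries transient Na⁺ and delayed-rectifier K⁺ currents (Traub-type
kinetics with an adjustable voltage shift), an ohmic leak, and the Cav3.3
T-type calcium current supplied as a :class:`~cav33sim.gating.GatingParams`
in density mode (mS/cm²).  Membrane equation:

    c_m dV/dt = I_inj/area − g_Na m³h(V−E_Na) − g_K n⁴(V−E_K)
                − g_L(V−E_L) − g_T m_T² h_T (V−E_Ca)

Gates are advanced with exponential (exact-relaxation) updates and the
voltage with forward Euler at a fixed time step (default 0.025 ms).  For
speed, steady states and per-step decay factors of all gates are pre-tabulated
on a 0.05-mV voltage grid; this quantisation is far below the 0.01-nA
rheobase resolution of interest.

Firing phenotypes: rheobase search from a −110 mV pre-clamp, spike-train
metrics (train duration, initial and steady-state frequency), a rebound/
free-run protocol, a firing-mode classifier (low-threshold firing LTF vs
subthreshold slow oscillations SO), and spike-shape metrics (plateau area,
90–10% decay slope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .gating import GatingParams, tau_gate

__all__ = [
    "NeuronModel",
    "StimulusProtocol",
    "VoltageTrace",
    "SpikeTrainMetrics",
    "load_base_config",
    "build_model",
    "set_rest",
    "pulse_from_rest",
    "integrate",
    "detect_spikes",
    "find_rheobase",
    "train_metrics",
    "rebound_run",
    "classify_firing_mode",
    "plateau_area",
    "decay_slope_90_10",
]

_VGRID_LO, _VGRID_HI, _VGRID_DV = -150.0, 60.0, 0.05


@dataclass
class StimulusProtocol:
    """Current-injection protocol: optional pre-clamp, then current segments."""

    segments: list[tuple[float, float]]  # (i_nA, duration ms)
    pre_clamp_mv: float | None = None    # voltage held (gates equilibrated) before onset

    def __post_init__(self) -> None:
        if any(dur <= 0 for _, dur in self.segments):
            raise ValueError("segment durations must be > 0")

    @property
    def total_ms(self) -> float:
        return sum(d for _, d in self.segments)


@dataclass
class VoltageTrace:
    """Simulated membrane-potential trace with the injected current."""

    time: np.ndarray   # ms
    v: np.ndarray      # mV
    i_inj: np.ndarray  # nA
    dt: float

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.v) == len(self.i_inj)):
            raise ValueError("trace arrays must have equal length")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass
class SpikeTrainMetrics:
    """Summary of one spike train."""

    spike_times: np.ndarray        # ms
    train_duration: float          # ms, first-to-last spike peak (0 if < 2 spikes)
    f0: float                      # Hz, 1000/first ISI (nan if < 2 spikes)
    f_ss: float                    # Hz, mean 1000/ISI over the final 500 ms of spiking
    firing_mode: str | None = None  # LTF | SO | LTF+SO | silent (set by classifier)
    rheobase: float | None = None  # nA, when produced by a search
    continuous: bool | None = None  # rebound runs: activity persists to the end


@dataclass
class NeuronModel:
    """Single-compartment TRN-style cell. Conductances in mS/cm², E in mV."""

    t_params: GatingParams          # density mode: g_max in mS/cm²
    c_m: float = 1.0                # µF/cm²
    area: float = 1.5e-4            # cm²
    g_na: float = 90.0
    g_k: float = 80.0
    g_leak: float = 0.05
    e_na: float = 50.0
    e_k: float = -95.0
    e_leak: float = -72.0
    v_shift: float = -57.0          # Traub-kinetics voltage shift (sets spike threshold)

    def __post_init__(self) -> None:
        if self.c_m <= 0 or self.area <= 0:
            raise ValueError("capacitance and area must be positive")
        if min(self.g_na, self.g_k, self.g_leak, self.t_params.g_max) < 0:
            raise ValueError("conductances must be non-negative")

    # -- Traub-type spike kinetics (rates in 1/ms, voltages relative to v_shift)

    @staticmethod
    def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
        # x / (exp(x/y) - 1) with the removable singularity handled
        out = np.empty_like(x)
        small = np.abs(x / y) < 1e-6
        out[small] = y * (1.0 - x[small] / (2.0 * y))
        out[~small] = x[~small] / np.expm1(x[~small] / y)
        return out

    def _rates(self, v: np.ndarray):
        u = v - self.v_shift
        a_m = 0.32 * self._vtrap(13.0 - u, 4.0)
        b_m = 0.28 * self._vtrap(u - 40.0, 5.0)
        a_h = 0.128 * np.exp((17.0 - u) / 18.0)
        b_h = 4.0 / (1.0 + np.exp((40.0 - u) / 5.0))
        a_n = 0.032 * self._vtrap(15.0 - u, 5.0)
        b_n = 0.5 * np.exp((10.0 - u) / 40.0)
        return a_m, b_m, a_h, b_h, a_n, b_n

    def steady_gates(self, v: float) -> dict[str, float]:
        """All gate steady states at a clamped voltage."""
        arr = np.array([v], dtype=float)
        a_m, b_m, a_h, b_h, a_n, b_n = (x[0] for x in self._rates(arr))
        p = self.t_params
        return {
            "m": float(a_m / (a_m + b_m)),
            "h": float(a_h / (a_h + b_h)),
            "n": float(a_n / (a_n + b_n)),
            "mt": 1.0 / (1.0 + math.exp(-(v - p.v_half_act) / p.k_act)),
            "ht": 1.0 / (1.0 + math.exp((v - p.v_half_inact) / p.k_inact)),
        }

    def tables(self, dt: float):
        """Pre-tabulated steady states and decay factors on the voltage grid."""
        v = np.arange(_VGRID_LO, _VGRID_HI + _VGRID_DV / 2, _VGRID_DV)
        a_m, b_m, a_h, b_h, a_n, b_n = self._rates(v)
        p = self.t_params
        mt_inf = 1.0 / (1.0 + np.exp(-(v - p.v_half_act) / p.k_act))
        ht_inf = 1.0 / (1.0 + np.exp((v - p.v_half_inact) / p.k_inact))
        tau_mt = np.array(p.tau_m(v), dtype=float)
        tau_ht = np.array(p.tau_h(v), dtype=float)
        tabs = {
            "m_inf": a_m / (a_m + b_m), "m_dec": np.exp(-dt * (a_m + b_m)),
            "h_inf": a_h / (a_h + b_h), "h_dec": np.exp(-dt * (a_h + b_h)),
            "n_inf": a_n / (a_n + b_n), "n_dec": np.exp(-dt * (a_n + b_n)),
            "mt_inf": mt_inf, "mt_dec": np.exp(-dt / tau_mt),
            "ht_inf": ht_inf, "ht_dec": np.exp(-dt / tau_ht),
        }
        return {k: arr.tolist() for k, arr in tabs.items()}


# ---------------------------------------------------------------------------
# Model assembly


def load_base_config() -> dict:
    """The calibrated base-model configuration shipped with the package."""
    ref = resources.files("cav33sim").joinpath("params/trn_base_model.yaml")
    return yaml.safe_load(ref.read_text())


def build_model(t_params: GatingParams, config: dict | str | Path | None = None) -> NeuronModel:
    """Assemble the cell from a config and a channel-variant parameter set.

    The T-current conductance density and reversal come from the config (they
    are properties of the cell, held fixed across variants); everything else
    about the T current — steady-state curves and kinetics — comes from
    ``t_params``.  Passing variants with identical config isolates the gating
    parameters as the only manipulated variable.
    """
    if t_params is None:
        raise ValueError("variant gating parameters are required")
    if config is None:
        config = load_base_config()
    elif isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    mem = config.get("membrane", {})
    spk = config.get("spike_kinetics", {})
    tc = config.get("t_current", {})
    from dataclasses import replace
    tp = replace(t_params,
                 g_max=float(tc.get("g_density", t_params.g_max)),
                 e_rev=float(tc.get("e_rev", t_params.e_rev)))
    return NeuronModel(
        t_params=tp,
        c_m=float(mem.get("c_m", 1.0)),
        area=float(mem.get("area", 1.5e-4)),
        g_na=float(spk.get("g_na", 90.0)),
        g_k=float(spk.get("g_k", 80.0)),
        g_leak=float(mem.get("g_leak", 0.05)),
        e_na=float(spk.get("e_na", 50.0)),
        e_k=float(spk.get("e_k", -95.0)),
        e_leak=float(mem.get("e_leak", -72.0)),
        v_shift=float(spk.get("v_shift", -57.0)),
    )


def set_rest(model: NeuronModel, v_rest: float) -> NeuronModel:
    """Copy of the model with the leak reversal adjusted so ``v_rest`` is rest.

    The protocols that "set the resting membrane potential" to a level
    (−110 mV before a rheobase pulse, the −60 mV up-state before a rebound
    step) are realised by solving E_leak so the total steady-state current
    vanishes at ``v_rest`` — the standard way of positioning the rest of a
    conductance-based model without injecting a depolarizing bias current.
    """
    if model.g_leak <= 0:
        raise ValueError("cannot set the rest of a model without leak conductance")
    g = model.steady_gates(v_rest)
    p = model.t_params
    i_other = (model.g_na * g["m"] ** 3 * g["h"] * (v_rest - model.e_na)
               + model.g_k * g["n"] ** 4 * (v_rest - model.e_k)
               + p.g_max * g["mt"] ** 2 * g["ht"] * (v_rest - p.e_rev))
    from dataclasses import replace as _replace
    return _replace(model, e_leak=v_rest + i_other / model.g_leak)


# ---------------------------------------------------------------------------
# Integration


def integrate(model: NeuronModel, stimulus: StimulusProtocol, dt: float = 0.025,
              v0: float | None = None, gates0: dict[str, float] | None = None) -> VoltageTrace:
    """Fixed-step integration: exponential gate updates, explicit voltage update.

    With a pre-clamp the membrane starts at the clamp level with all gates at
    their clamp steady state; otherwise at ``v0`` (default E_leak) with gates
    equilibrated there.  Deterministic; raises on numerical blow-up
    (|V| > 200 mV) with a pointer to ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if v0 is None:
        v0 = stimulus.pre_clamp_mv if stimulus.pre_clamp_mv is not None else model.e_leak
    g = dict(gates0) if gates0 is not None else model.steady_gates(v0)

    tabs = model.tables(dt)
    m_inf_t, m_dec_t = tabs["m_inf"], tabs["m_dec"]
    h_inf_t, h_dec_t = tabs["h_inf"], tabs["h_dec"]
    n_inf_t, n_dec_t = tabs["n_inf"], tabs["n_dec"]
    mt_inf_t, mt_dec_t = tabs["mt_inf"], tabs["mt_dec"]
    ht_inf_t, ht_dec_t = tabs["ht_inf"], tabs["ht_dec"]
    n_tab = len(m_inf_t) - 1
    inv_dv = 1.0 / _VGRID_DV
    lo = _VGRID_LO

    n_steps = int(round(stimulus.total_ms / dt))
    t_arr = np.arange(n_steps + 1) * dt
    v_arr = np.empty(n_steps + 1)
    i_arr = np.empty(n_steps + 1)

    # per-step injected current (nA), piecewise constant
    i_steps = np.empty(n_steps + 1)
    k0 = 0
    for i_nA, dur in stimulus.segments:
        k1 = k0 + int(round(dur / dt))
        i_steps[k0:min(k1, n_steps + 1)] = i_nA
        k0 = k1
    i_steps[-1] = stimulus.segments[-1][0]

    v = float(v0)
    m, h, n, mt, ht = g["m"], g["h"], g["n"], g["mt"], g["ht"]
    gna, gk, gl, gt = model.g_na, model.g_k, model.g_leak, model.t_params.g_max
    ena, ek, el, eca = model.e_na, model.e_k, model.e_leak, model.t_params.e_rev
    inv_cm = 1.0 / model.c_m
    inj_scale = 1.0e-3 / model.area  # nA -> µA/cm²
    v_arr[0] = v
    i_arr[:] = i_steps
    i_steps = i_steps.tolist()  # python floats: faster inner loop
    for k in range(n_steps):
        idx = int((v - lo) * inv_dv + 0.5)
        if idx < 0:
            idx = 0
        elif idx > n_tab:
            idx = n_tab
        xi = m_inf_t[idx]; m = xi + (m - xi) * m_dec_t[idx]
        xi = h_inf_t[idx]; h = xi + (h - xi) * h_dec_t[idx]
        xi = n_inf_t[idx]; n = xi + (n - xi) * n_dec_t[idx]
        xi = mt_inf_t[idx]; mt = xi + (mt - xi) * mt_dec_t[idx]
        xi = ht_inf_t[idx]; ht = xi + (ht - xi) * ht_dec_t[idx]
        i_ion = (gna * m * m * m * h * (v - ena)
                 + gk * n * n * n * n * (v - ek)
                 + gl * (v - el)
                 + gt * mt * mt * ht * (v - eca))
        v += dt * inv_cm * (i_steps[k] * inj_scale - i_ion)
        if v > 200.0 or v < -200.0:
            raise RuntimeError(
                f"membrane potential diverged (|V| > 200 mV) at t = {k * dt:.3f} ms; "
                f"reduce dt (currently {dt} ms)")
        v_arr[k + 1] = v
    return VoltageTrace(time=t_arr, v=v_arr, i_inj=i_arr, dt=dt)


# ---------------------------------------------------------------------------
# Spike detection and train metrics


def detect_spikes(trace: VoltageTrace, threshold: float = -20.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Spike times: peak of each suprathreshold excursion, refractory-merged.

    A spike is an upward crossing of ``threshold`` (default −20 mV); its time
    is the local voltage maximum of the contiguous suprathreshold epoch.
    Peaks closer than ``refractory`` ms to the previous accepted spike are
    discarded.
    """
    v = trace.v
    above = v > threshold
    if not np.any(above):
        return np.array([])
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(v)]
    times = []
    for s, e in zip(starts, ends):
        k = s + int(np.argmax(v[s:e]))
        t_pk = trace.time[k]
        if times and t_pk - times[-1] < refractory:
            continue
        times.append(float(t_pk))
    return np.asarray(times)


def train_metrics(trace: VoltageTrace, stimulus: StimulusProtocol | None = None,
                  threshold: float = -20.0, refractory: float = 2.0) -> SpikeTrainMetrics:
    """Spike-train summary: duration (first-to-last peak), f0, steady-state rate.

    f0 = 1000 / first interspike interval; f_ss = mean of 1000/ISI over the
    ISIs whose second spike falls in the final 500 ms of spiking.  With
    fewer than two spikes, duration is 0 and the frequencies are NaN.
    """
    spikes = detect_spikes(trace, threshold=threshold, refractory=refractory)
    if len(spikes) < 2:
        return SpikeTrainMetrics(spike_times=spikes, train_duration=0.0,
                                 f0=math.nan, f_ss=math.nan)
    isis = np.diff(spikes)
    f0 = 1000.0 / isis[0]
    late = spikes[1:] >= spikes[-1] - 500.0
    f_ss = float(np.mean(1000.0 / isis[late]))
    return SpikeTrainMetrics(
        spike_times=spikes,
        train_duration=float(spikes[-1] - spikes[0]),
        f0=float(f0),
        f_ss=f_ss,
    )


def find_rheobase(model: NeuronModel, pulse_ms: float = 200.0, v_init: float = -110.0,
                  i_min: float = 0.0, i_max: float = 0.5, step: float = 0.01,
                  dt: float = 0.025, threshold: float = -20.0) -> float | None:
    """Smallest current injection eliciting at least one spike during the pulse.

    The resting potential is set to ``v_init`` (default −110 mV,
    de-inactivating the T current) by re-anchoring the leak reversal;
    depolarizing pulses of increasing amplitude are searched in ascending
    0.01-nA steps.  Returns None if nothing in range is effective.
    """
    if i_min >= i_max or step <= 0:
        raise ValueError("need i_min < i_max and step > 0")
    rested = set_rest(model, v_init)
    amps = np.arange(i_min, i_max + step / 2, step)
    for amp in amps:
        stim = StimulusProtocol(segments=[(float(amp), pulse_ms)],
                                pre_clamp_mv=v_init)
        trace = integrate(rested, stim, dt=dt)
        spikes = detect_spikes(trace, threshold=threshold)
        if len(spikes) > 0 and spikes[0] <= pulse_ms:
            return float(round(amp / step) * step)
    return None


def pulse_from_rest(model: NeuronModel, amp_na: float, pulse_ms: float = 200.0,
                    rest_mv: float = -110.0, post_ms: float = 300.0,
                    dt: float = 0.025) -> VoltageTrace:
    """Depolarizing pulse from a set resting potential (leak re-anchored)."""
    rested = set_rest(model, rest_mv)
    stim = StimulusProtocol(
        segments=[(amp_na, pulse_ms), (0.0, post_ms)],
        pre_clamp_mv=rest_mv)
    return integrate(rested, stim, dt=dt)


def rebound_run(model: NeuronModel, v_up: float = -60.0, v_hyp: float = -110.0,
                hyp_ms: float = 200.0, total_ms: float = 10000.0,
                dt: float = 0.025) -> tuple[VoltageTrace, SpikeTrainMetrics]:
    """Up-state clamp, brief hyperpolarizing clamp, then unclamped evolution.

    Emulates release from hyperpolarization at the thalamic up-state: the
    resting potential is set to ``v_up`` by re-anchoring the leak reversal,
    the cell is clamped at ``v_hyp`` for ``hyp_ms`` (gate relaxation
    evaluated in closed form at the clamped voltage), then left free —
    unclamped — for the remainder of ``total_ms``.  The metrics flag whether
    activity is transient (wild-type rebound burst) or continues to the end
    of the run.
    """
    if total_ms < hyp_ms:
        raise ValueError("total_ms must be >= hyp_ms")
    model = set_rest(model, v_up)
    g = model.steady_gates(v_up)
    # closed-form clamp at v_hyp for hyp_ms (exact at constant voltage)
    tgt = model.steady_gates(v_hyp)
    arr = np.array([v_hyp], dtype=float)
    a_m, b_m, a_h, b_h, a_n, b_n = (x[0] for x in model._rates(arr))
    taus = {
        "m": 1.0 / float(a_m + b_m), "h": 1.0 / float(a_h + b_h),
        "n": 1.0 / float(a_n + b_n),
        "mt": float(model.t_params.tau_m(v_hyp)), "ht": float(model.t_params.tau_h(v_hyp)),
    }
    g = {k: tgt[k] + (g[k] - tgt[k]) * math.exp(-hyp_ms / taus[k]) for k in g}

    free_ms = total_ms - hyp_ms
    stim = StimulusProtocol(segments=[(0.0, free_ms)])
    trace = integrate(model, stim, dt=dt, v0=v_hyp, gates0=g)
    # prepend the clamp epoch as flat samples so the trace shows the protocol
    n_pre = int(round(hyp_ms / dt))
    t_full = np.arange(len(trace.time) + n_pre) * dt
    v_full = np.r_[np.full(n_pre, v_hyp), trace.v]
    i_full = np.r_[np.zeros(n_pre), trace.i_inj]
    full = VoltageTrace(time=t_full, v=v_full, i_inj=i_full, dt=dt)
    metrics = train_metrics(full)
    if len(metrics.spike_times) > 0:
        metrics.continuous = bool(metrics.spike_times[-1] >= total_ms - 500.0)
    else:
        metrics.continuous = False
    metrics.firing_mode = classify_firing_mode(full)
    return full, metrics


# ---------------------------------------------------------------------------
# Firing-mode taxonomy and spike-shape metrics


def classify_firing_mode(trace: VoltageTrace, threshold: float = -20.0,
                         so_min_epoch_ms: float = 1000.0) -> str:
    """Classify a trace as LTF, SO, LTF+SO, or silent.

    LTF (low-threshold tonic/burst firing): spikes present.  SO (slow
    oscillation): a spike-free epoch of at least 1 s whose mean potential
    stays depolarized (> −60 mV) with a 2–20 mV peak-to-peak subthreshold
    oscillation — the bistable up-state.  Both present → LTF+SO; neither →
    silent.
    """
    if trace.time[-1] - trace.time[0] < 2000.0:
        raise ValueError("need at least 2 s of trace to classify the firing mode")
    spikes = detect_spikes(trace, threshold=threshold)
    has_spikes = len(spikes) > 0
    # spike-free epochs: before first, between, after last (with 50-ms margins)
    bounds = [trace.time[0], *spikes, trace.time[-1]]
    margin = 50.0
    has_so = False
    for a, b in zip(bounds[:-1], bounds[1:]):
        a_in, b_in = a + margin, b - margin
        if b_in - a_in < so_min_epoch_ms:
            continue
        sel = (trace.time >= a_in) & (trace.time <= b_in)
        seg = trace.v[sel]
        if len(seg) < 10:
            continue
        p2p = float(np.max(seg) - np.min(seg))
        if float(np.mean(seg)) > -60.0 and 2.0 <= p2p <= 20.0:
            has_so = True
            break
    if has_spikes and has_so:
        return "LTF+SO"
    if has_spikes:
        return "LTF"
    if has_so:
        return "SO"
    return "silent"


def plateau_area(trace: VoltageTrace, threshold: float) -> tuple[list[float], float]:
    """Area ∫(V − threshold)dt over each contiguous suprathreshold epoch (mV·ms)."""
    v = trace.v
    above = v > threshold
    if not np.any(above):
        return [], 0.0
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(v)]
    areas = []
    for s, e in zip(starts, ends):
        areas.append(float(np.trapezoid(v[s:e] - threshold, trace.time[s:e])))
    return areas, float(sum(areas))


def decay_slope_90_10(trace: VoltageTrace, event: tuple[float, float]) -> float:
    """Chord slope of the falling phase between 90% and 10% of event amplitude.

    ``event`` is a (t_start, t_end) window containing one peak followed by a
    return toward baseline; the baseline is the voltage at the window end.
    The slope is the straight line between the 90% and 10% amplitude
    crossings (a chord, not a tangent); negative for a decay.  Raises if the
    crossings cannot be found.
    """
    t0, t1 = event
    sel = (trace.time >= t0) & (trace.time <= t1)
    t_w, v_w = trace.time[sel], trace.v[sel]
    if len(t_w) < 4:
        raise ValueError("event window too small")
    k_pk = int(np.argmax(v_w))
    baseline = float(v_w[-1])
    amp = float(v_w[k_pk]) - baseline
    if amp <= 0:
        raise ValueError("no peak above baseline in event window")
    lev90 = baseline + 0.9 * amp
    lev10 = baseline + 0.1 * amp

    def crossing(level: float) -> float:
        seg = v_w[k_pk:]
        below = np.nonzero(seg <= level)[0]
        if len(below) == 0:
            raise ValueError(f"falling phase never crosses {level:.2f} mV")
        j = below[0]
        if j == 0:
            return float(t_w[k_pk])
        # linear interpolation between the bracketing samples
        va, vb = seg[j - 1], seg[j]
        ta, tb = t_w[k_pk + j - 1], t_w[k_pk + j]
        return float(ta + (level - va) * (tb - ta) / (vb - va))

    t90 = crossing(lev90)
    t10 = crossing(lev10)
    if t10 <= t90:
        raise ValueError("degenerate 90-10 crossing times")
    return (lev10 - lev90) / (t10 - t90)
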