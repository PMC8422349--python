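"""Voltage-clamp protocol definitions and whole-cell Cav3.3 current synthesis.

This module stands in for the patch-clamp rig: it defines the study's
protocols (current–voltage families, steady-state inactivation, tail-current
deactivation, action-potential-clamp trains) and integrates the gating model
along the command voltage to produce whole-cell current sweeps, optionally
with additive Gaussian recording noise.

Because every step protocol is piecewise-constant in voltage, the first-order
gate equations are solved segment-by-segment in closed form — the simulated
currents are exact, not time-stepped.  The action-potential command, which is
smooth, is discretised into one segment per sample, so halving the sample
interval refines it (a convergence check lives in the test suite).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gating import GatingParams, GateState, h_inf, m_inf

__all__ = [
    "VoltageProtocol",
    "SweepSet",
    "APWaveform",
    "make_iv_protocol",
    "make_ssi_protocol",
    "make_deactivation_protocol",
    "make_ap_train_protocol",
    "simulate_sweeps",
    "add_noise",
    "save_sweeps",
    "load_sweeps",
]

Segment = tuple[float, float]  # (level mV, duration ms)


@dataclass
class VoltageProtocol:
    """A family of command-voltage sweeps, each a list of (level, duration) segments."""

    name: str
    sweeps: list[list[Segment]]
    holding: float = -100.0          # mV, equilibration level before each sweep
    sample_interval: float = 0.5     # ms
    inter_sweep_interval: float = 5000.0  # ms (assumed long enough to re-equilibrate)
    extras: dict = field(default_factory=dict)  # protocol-specific annotations

    def __post_init__(self) -> None:
        if not self.sweeps or any(len(s) == 0 for s in self.sweeps):
            raise ValueError("protocol must contain at least one non-empty sweep")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        for sweep in self.sweeps:
            if any(dur <= 0 for _, dur in sweep):
                raise ValueError("segment durations must be > 0")

    def sweep_duration(self, i: int) -> float:
        return sum(dur for _, dur in self.sweeps[i])

    def command(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Sample times and command voltage for sweep ``i``."""
        total = self.sweep_duration(i)
        t = np.arange(0.0, total + self.sample_interval / 2, self.sample_interval)
        v = np.empty_like(t)
        t0 = 0.0
        for level, dur in self.sweeps[i]:
            sel = (t >= t0 - 1e-9) & (t < t0 + dur - 1e-9)
            v[sel] = level
            t0 += dur
        v[-1] = self.sweeps[i][-1][0]
        return t, v

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "sweeps": [[[lv, du] for lv, du in sw] for sw in self.sweeps],
            "holding": self.holding,
            "sample_interval": self.sample_interval,
            "inter_sweep_interval": self.inter_sweep_interval,
            "extras": self.extras,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        return cls(
            name=d["name"],
            sweeps=[[(float(lv), float(du)) for lv, du in sw] for sw in d["sweeps"]],
            holding=float(d.get("holding", -100.0)),
            sample_interval=float(d.get("sample_interval", 0.5)),
            inter_sweep_interval=float(d.get("inter_sweep_interval", 5000.0)),
            extras=d.get("extras", {}),
        )


@dataclass
class SweepSet:
    """Simulated (or recorded) current sweeps with their protocol attached."""

    protocol: VoltageProtocol
    time: list[np.ndarray]       # ms, per sweep
    current: list[np.ndarray]    # pA, per sweep
    voltage_command: list[np.ndarray]  # mV, per sweep
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, i, v in zip(self.time, self.current, self.voltage_command):
            if not (len(t) == len(i) == len(v)):
                raise ValueError("time/current/voltage lengths differ within a sweep")
            if np.any(np.diff(t) <= 0):
                raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class APWaveform:
    """Piecewise-exponential action-potential-like command waveform.

    Rise: saturating exponential from baseline to peak over ``rise_ms``;
    decay: exponential return to baseline with time constant ``decay_ms``.
    Defaults emulate a thalamic-neuron spike shape (-70 to +20 mV, 1 ms up,
    4 ms down).
    """

    baseline: float = -70.0   # mV
    peak: float = 20.0        # mV
    rise_ms: float = 1.0
    decay_ms: float = 4.0
    sample_interval: float = 0.1  # ms

    def __post_init__(self) -> None:
        if self.peak <= self.baseline:
            raise ValueError("peak must exceed baseline")
        if self.rise_ms <= 0 or self.decay_ms <= 0 or self.sample_interval <= 0:
            raise ValueError("durations must be positive")

    @property
    def duration(self) -> float:
        """Time from onset until the command is back within 0.5 mV of baseline."""
        amp = self.peak - self.baseline
        return self.rise_ms + self.decay_ms * math.log(amp / 0.5)

    def at(self, t) -> np.ndarray:
        """Waveform voltage at time(s) ``t`` (ms from onset)."""
        t = np.asarray(t, dtype=float)
        amp = self.peak - self.baseline
        rise = 1.0 - np.exp(-3.0 * t / self.rise_ms)
        rise /= 1.0 - math.exp(-3.0)  # normalised so v(rise_ms) == peak
        return np.where(
            t < self.rise_ms,
            self.baseline + amp * rise,
            self.baseline + amp * np.exp(-(t - self.rise_ms) / self.decay_ms),
        )

    def samples(self, midpoint: bool = False) -> np.ndarray:
        """Voltage sampled every ``sample_interval`` from onset to return.

        ``midpoint=True`` evaluates at interval midpoints — the second-order
        piecewise-constant representation used by the train builder.
        """
        t = np.arange(0.0, self.duration + self.sample_interval / 2, self.sample_interval)
        if midpoint:
            t = t + self.sample_interval / 2
        return self.at(t)


# ---------------------------------------------------------------------------
# Protocol factories (defaults follow the study's stated protocols)


def make_iv_protocol(
    v_hold: float = -100.0,
    v_start: float = -90.0,
    v_end: float = 30.0,
    step: float = 10.0,
    pulse_ms: float = 500.0,
    sample_interval: float = 0.5,
) -> VoltageProtocol:
    """Current–voltage family: one test pulse per level from a fixed holding.

    Defaults: holding -100 mV, -90..+30 mV in 10-mV steps, 500-ms pulses;
    pass ``pulse_ms=5000`` for the 5-s variant used for inactivation-τ fits.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if v_end < v_start:
        raise ValueError("v_end must be >= v_start")
    levels = np.arange(v_start, v_end + step / 2, step)
    if len(levels) == 0:
        raise ValueError("protocol has zero sweeps")
    sweeps = [[(float(v), pulse_ms)] for v in levels]
    return VoltageProtocol(
        name="iv",
        sweeps=sweeps,
        holding=v_hold,
        sample_interval=sample_interval,
        extras={"levels": [float(v) for v in levels], "pulse_ms": pulse_ms},
    )


def make_ssi_protocol(
    conditioning_ms: float = 5000.0,
    v_cond_start: float = -110.0,
    v_cond_end: float = -40.0,
    step: float = 5.0,
    v_test: float = -30.0,
    test_ms: float = 500.0,
    v_hold: float = -100.0,
    recovery_ms: float = 3000.0,
    sample_interval: float = 0.5,
) -> VoltageProtocol:
    """Steady-state inactivation: reference pulse, recovery, 5-s conditioning, test pulse.

    Fractional availability is the post/pre peak-current ratio per
    conditioning level.  ``v_test`` should sit at the variant's voltage of
    maximal activation.
    """
    if conditioning_ms < 1000.0:
        raise ValueError("conditioning must last at least 1000 ms to approach steady state")
    if step <= 0 or v_cond_end < v_cond_start:
        raise ValueError("bad conditioning range")
    levels = np.arange(v_cond_start, v_cond_end + step / 2, step)
    sweeps = [
        [
            (v_test, test_ms),            # reference (pre) pulse
            (v_hold, recovery_ms),        # recover from reference-pulse inactivation
            (float(vc), conditioning_ms),  # conditioning step
            (v_test, test_ms),            # post pulse
        ]
        for vc in levels
    ]
    return VoltageProtocol(
        name="ssi",
        sweeps=sweeps,
        holding=v_hold,
        sample_interval=sample_interval,
        extras={
            "conditioning_levels": [float(v) for v in levels],
            "v_test": v_test,
            "test_ms": test_ms,
            "pre_window": [0.0, test_ms],
            "post_window": [test_ms + recovery_ms + conditioning_ms,
                            test_ms + recovery_ms + conditioning_ms + test_ms],
        },
    )


def make_deactivation_protocol(
    v_hold: float = -100.0,
    v_act: float = -30.0,
    act_ms: float = 15.0,
    v_tails: list[float] | None = None,
    tail_ms: float = 100.0,
    sample_interval: float = 0.05,
) -> VoltageProtocol:
    """Tail-current protocol: brief maximal-activation step, then repolarization.

    The activation step lasts just long enough for full activation without
    appreciable inactivation (15 ms for wild-type, 50 ms for the slow
    variants); the tail repolarization (default to -100 mV) exposes the
    deactivation time constant.
    """
    if not (1.0 <= act_ms <= 100.0):
        raise ValueError("act_ms must lie in [1, 100] ms")
    if v_tails is None:
        v_tails = [-100.0]
    sweeps = [[(v_act, act_ms), (float(vt), tail_ms)] for vt in v_tails]
    return VoltageProtocol(
        name="deactivation",
        sweeps=sweeps,
        holding=v_hold,
        sample_interval=sample_interval,
        extras={"v_act": v_act, "act_ms": act_ms, "tails": [float(v) for v in v_tails]},
    )


def make_ap_train_protocol(
    waveform: APWaveform | None = None,
    n: int = 99,
    rate_hz: float = 20.0,
) -> VoltageProtocol:
    """Action-potential clamp: ``n`` AP-like depolarizations at ``rate_hz``.

    One continuous sweep; default 99 APs at 20 Hz (50-ms period) plus one
    trailing baseline period.  Onset times are recorded in ``extras`` for
    the charge analysis.
    """
    if waveform is None:
        waveform = APWaveform()
    if n < 1:
        raise ValueError("need at least one AP")
    period = 1000.0 / rate_hz
    if waveform.duration >= period:
        raise ValueError("AP waveform does not fit in the stimulation period")
    dt = waveform.sample_interval
    wave_v = waveform.samples(midpoint=True)
    seg: list[Segment] = []
    for k in range(n):
        for v in wave_v:
            seg.append((float(v), dt))
        pad = period - len(wave_v) * dt
        if pad > 1e-9:
            seg.append((waveform.baseline, pad))
    seg.append((waveform.baseline, period))  # trailing window
    onsets = [k * period for k in range(n)]
    return VoltageProtocol(
        name="ap_train",
        sweeps=[seg],
        holding=waveform.baseline,
        sample_interval=dt,
        extras={
            "n_ap": n,
            "rate_hz": rate_hz,
            "period_ms": period,
            "ap_onsets": onsets,
            "ap_duration_ms": waveform.duration,
            "baseline_mv": waveform.baseline,
        },
    )


# ---------------------------------------------------------------------------
# Forward simulation


def simulate_sweeps(
    params: GatingParams,
    protocol: VoltageProtocol,
    dt: float | None = None,
    g_leak: float = 0.0,
    e_leak: float = 0.0,
) -> SweepSet:
    """Integrate the gating model along the command and record the current.

    Gates start at their steady state for the holding potential (the
    inter-sweep interval is assumed long enough to re-equilibrate).  Within
    each constant-voltage segment the gate relaxation is evaluated in closed
    form, so the result is exact at the sample times regardless of ``dt``
    (``dt`` only overrides the sampling interval).  An optional ohmic leak
    (nS, mV) can be superimposed for fit-robustness work.
    """
    if dt is not None and dt <= 0:
        raise ValueError("dt must be > 0")
    si = dt if dt is not None else protocol.sample_interval
    times, currents, commands = [], [], []
    m_hold = m_inf(protocol.holding, params)
    h_hold = h_inf(protocol.holding, params)
    for idx in range(len(protocol.sweeps)):
        total = protocol.sweep_duration(idx)
        t = np.arange(0.0, total + si / 2, si)
        i_out = np.empty_like(t)
        v_out = np.empty_like(t)
        m, h = m_hold, h_hold
        t0 = 0.0
        n_seg = len(protocol.sweeps[idx])
        tau_m_tab = params._tau_m_table()
        tmv = np.array([p[0] for p in tau_m_tab]); tmt = np.array([p[1] for p in tau_m_tab])
        thv = np.array([p[0] for p in params.tau_inact_table])
        tht = np.array([p[1] for p in params.tau_inact_table])
        vha, ka = params.v_half_act, params.k_act
        vhi, ki = params.v_half_inact, params.k_inact
        gmax, p_act, erev = params.g_max, params.p_act, params.e_rev
        for seg_i, (level, dur) in enumerate(protocol.sweeps[idx]):
            lo = int(np.searchsorted(t, t0 - 1e-9))
            hi_idx = len(t) if seg_i == n_seg - 1 else int(np.searchsorted(t, t0 + dur - 1e-9))
            mi = 1.0 / (1.0 + math.exp(-(level - vha) / ka))
            hi = 1.0 / (1.0 + math.exp((level - vhi) / ki))
            tm = float(np.interp(level, tmv, tmt))
            th = float(np.interp(level, thv, tht))
            if hi_idx > lo:
                trel = t[lo:hi_idx] - t0
                m_t = mi + (m - mi) * np.exp(-trel / tm)
                h_t = hi + (h - hi) * np.exp(-trel / th)
                i_out[lo:hi_idx] = gmax * m_t ** p_act * h_t * (level - erev)
                if g_leak > 0.0:
                    i_out[lo:hi_idx] += g_leak * (level - e_leak)
                v_out[lo:hi_idx] = level
            # exact state at segment end
            m = mi + (m - mi) * math.exp(-dur / tm)
            h = hi + (h - hi) * math.exp(-dur / th)
            t0 += dur
        times.append(t)
        currents.append(i_out)
        commands.append(v_out)
    return SweepSet(
        protocol=protocol,
        time=times,
        current=currents,
        voltage_command=commands,
        meta={"variant": params.name, "noise_sd": 0.0, "seed": None,
              "g_leak": g_leak, "e_leak": e_leak},
    )


def add_noise(sweeps: SweepSet, sd: float, seed: int) -> SweepSet:
    """Superimpose white Gaussian recording noise (pA), reproducibly."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    noisy = [i + rng.normal(0.0, sd, size=i.shape) if sd > 0 else i.copy()
             for i in sweeps.current]
    meta = dict(sweeps.meta, noise_sd=sd, seed=seed)
    return SweepSet(
        protocol=sweeps.protocol,
        time=[t.copy() for t in sweeps.time],
        current=noisy,
        voltage_command=[v.copy() for v in sweeps.voltage_command],
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Serialization: one CSV per sweep set + JSON sidecar for protocol and meta


def save_sweeps(sweeps: SweepSet, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    frames = []
    for k, (t, i, v) in enumerate(zip(sweeps.time, sweeps.current, sweeps.voltage_command)):
        frames.append(pd.DataFrame({"sweep": k, "time_ms": t, "v_mV": v, "i_pA": i}))
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"protocol": sweeps.protocol.to_dict(), "meta": sweeps.meta}, indent=2))


def load_sweeps(csv_path: str | Path) -> SweepSet:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, sep=None, engine="python")  # comma or tab
    required = {"sweep", "time_ms", "v_mV", "i_pA"}
    if not required.issubset(df.columns):
        raise ValueError(f"{csv_path}: expected columns {sorted(required)}")
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    protocol = VoltageProtocol.from_dict(sidecar["protocol"])
    times, currents, commands = [], [], []
    for k, grp in df.groupby("sweep", sort=True):
        times.append(grp["time_ms"].to_numpy())
        currents.append(grp["i_pA"].to_numpy())
        commands.append(grp["v_mV"].to_numpy())
    return SweepSet(protocol=protocol, time=times, current=currents,
                    voltage_command=commands, meta=sidecar["meta"])
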