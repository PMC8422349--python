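"""Hodgkin–Huxley-style gating model of the Cav3.3 (T-type) calcium channel.

The channel is described by an activation gate ``m`` and an inactivation gate
``h``.  Steady states are Boltzmann functions of membrane voltage,

    m_inf(V) = 1 / (1 + exp(-(V - V½_act) / k_act))
    h_inf(V) = 1 / (1 + exp( (V - V½_inact) / k_inact))

and each gate relaxes first-order toward its steady state with a
voltage-dependent time constant supplied as a table of (V, τ) pairs (the
experimental kinetic data are reported at discrete test potentials, so the
model interpolates linearly between them and clamps beyond the table edges).
The open-channel current is ohmic,

    I(V) = g_max · m^p · h · (V - E_rev)

with ``p = 2`` (the standard m²h T-current formulation) and E_rev = +120 mV
by default.  Inward current is negative.

Variant channels (I860N, I860M, I1306T, M1425I) are expressed as parameter
sets of the same form; the shipped file ``params/cav33_variants.yaml`` holds
wild-type and the four disease variants.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "GatingParams",
    "GateState",
    "WindowCurve",
    "m_inf",
    "h_inf",
    "tau_gate",
    "step_gates",
    "channel_current",
    "window_curve",
    "shift_params",
    "load_params",
    "load_shipped_params",
    "save_params",
]

TauTable = Sequence[tuple[float, float]]


def _check_tau_table(table: TauTable, name: str) -> None:
    if len(table) < 2:
        raise ValueError(f"{name} needs at least 2 (voltage, tau) entries")
    volts = [v for v, _ in table]
    taus = [t for _, t in table]
    if any(b <= a for a, b in zip(volts, volts[1:])):
        raise ValueError(f"{name} voltages must be strictly increasing")
    if any(t <= 0 for t in taus):
        raise ValueError(f"{name} time constants must be positive")


@dataclass(frozen=True)
class GatingParams:
    """Boltzmann + time-constant parameterization of one channel variant.

    Conductance units are nS in whole-cell mode and mS/cm² in density mode;
    the model itself is agnostic, the caller owns the convention.
    """

    name: str
    v_half_act: float          # mV
    k_act: float               # mV, > 0
    v_half_inact: float        # mV
    k_inact: float             # mV, > 0
    tau_act_table: TauTable    # (mV, ms) pairs, strictly increasing V
    tau_inact_table: TauTable
    tau_deact_table: TauTable | None = None  # m-gate kinetics at hyperpolarized V
    p_act: int = 2
    g_max: float = 10.0
    e_rev: float = 120.0       # mV

    def __post_init__(self) -> None:
        if self.k_act <= 0 or self.k_inact <= 0:
            raise ValueError("slope factors k_act and k_inact must be > 0")
        if self.p_act < 1:
            raise ValueError("p_act must be >= 1")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        object.__setattr__(self, "tau_act_table", tuple((float(v), float(t)) for v, t in self.tau_act_table))
        object.__setattr__(self, "tau_inact_table", tuple((float(v), float(t)) for v, t in self.tau_inact_table))
        if self.tau_deact_table is not None:
            object.__setattr__(self, "tau_deact_table", tuple((float(v), float(t)) for v, t in self.tau_deact_table))
            _check_tau_table(self.tau_deact_table, "tau_deact_table")
        _check_tau_table(self.tau_act_table, "tau_act_table")
        _check_tau_table(self.tau_inact_table, "tau_inact_table")

    # -- m-gate time constant over the full voltage range: the deactivation
    # table (tail-current kinetics, hyperpolarized V) is spliced below the
    # activation table (test potentials) into one continuous piecewise-linear
    # curve, so the neuron model sees no jump between the two regimes.
    def tau_m(self, v):
        return tau_gate(v, self._tau_m_table())

    def _tau_m_table(self) -> TauTable:
        if self.tau_deact_table is None:
            return self.tau_act_table
        v_low = self.tau_act_table[0][0]
        below = tuple(p for p in self.tau_deact_table if p[0] < v_low)
        return below + tuple(self.tau_act_table)

    def tau_h(self, v):
        return tau_gate(v, self.tau_inact_table)


@dataclass
class GateState:
    """Occupancies of the activation (m) and inactivation (h) gates."""

    m: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.m <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError("gate occupancies must lie in [0, 1]")


@dataclass
class WindowCurve:
    """Window (fraction of channels open at steady state) over a voltage grid."""

    voltages: np.ndarray       # mV
    window: np.ndarray         # m_inf^p * h_inf, in [0, 1]
    peak_voltage: float        # mV, argmax (ties -> most negative)
    peak_value: float
    area: float                # fraction * mV, trapezoid over the grid


def _as_finite(v) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("voltage must be finite")
    return arr


def m_inf(v, params: GatingParams):
    """Steady-state activation, an ascending Boltzmann of voltage."""
    arr = _as_finite(v)
    out = 1.0 / (1.0 + np.exp(-(arr - params.v_half_act) / params.k_act))
    return float(out) if arr.ndim == 0 else out


def h_inf(v, params: GatingParams):
    """Steady-state inactivation (availability), a descending Boltzmann."""
    arr = _as_finite(v)
    out = 1.0 / (1.0 + np.exp((arr - params.v_half_inact) / params.k_inact))
    return float(out) if arr.ndim == 0 else out


def tau_gate(v, table: TauTable):
    """Interpolate a (voltage, tau) table; constant beyond the edges."""
    if len(table) == 0:
        raise ValueError("empty tau table")
    arr = _as_finite(v)
    volts = np.array([p[0] for p in table])
    taus = np.array([p[1] for p in table])
    out = np.interp(arr, volts, taus)
    return float(out) if arr.ndim == 0 else out


def step_gates(state: GateState, v: float, dt: float, params: GatingParams) -> GateState:
    """Advance both gates by ``dt`` ms at constant voltage (exact update).

    x <- x_inf + (x - x_inf) * exp(-dt / tau_x(v)); exact for constant v, so
    composing two half steps equals one full step to machine precision.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    mi = m_inf(v, params)
    hi = h_inf(v, params)
    m = mi + (state.m - mi) * math.exp(-dt / params.tau_m(v))
    h = hi + (state.h - hi) * math.exp(-dt / params.tau_h(v))
    return GateState(m=m, h=h)


def channel_current(v, state: GateState, params: GatingParams):
    """Ohmic open-channel current I = g_max * m^p * h * (V - E_rev).

    Negative (inward) below the reversal potential when gates are open.
    Units follow g_max: nS * mV -> pA (whole-cell), mS/cm² * mV -> µA/cm².
    """
    arr = _as_finite(v)
    out = params.g_max * state.m ** params.p_act * state.h * (arr - params.e_rev)
    return float(out) if arr.ndim == 0 else out


def window_curve(params: GatingParams, v_grid=None) -> WindowCurve:
    """Steady-state window m_inf^p · h_inf over a voltage grid.

    The window is the overlap of the activation and inactivation curves: the
    voltage range in which some channels are open but not yet inactivated,
    carrying a standing calcium current near rest.
    """
    if v_grid is None:
        v_grid = np.linspace(-100.0, 0.0, 1001)
    v_grid = _as_finite(np.asarray(v_grid, dtype=float))
    if v_grid.min() > -100.0 + 1e-6 or v_grid.max() < 0.0 - 1e-6:
        raise ValueError("window grid must span at least [-100, 0] mV")
    spacing = np.diff(v_grid)
    if spacing.max() > 1.0 + 1e-12:
        warnings.warn("window grid spacing > 1 mV; peak location will be coarse")
    w = m_inf(v_grid, params) ** params.p_act * h_inf(v_grid, params)
    i_peak = int(np.argmax(w))  # np.argmax returns the first (most negative) max
    return WindowCurve(
        voltages=v_grid,
        window=w,
        peak_voltage=float(v_grid[i_peak]),
        peak_value=float(w[i_peak]),
        area=float(np.trapezoid(w, v_grid)),
    )


def shift_params(
    params: GatingParams,
    d_act: float = 0.0,
    d_inact: float = 0.0,
    scale_tau_inact: float = 1.0,
    name: str | None = None,
) -> GatingParams:
    """Copy with shifted midpoints and scaled inactivation kinetics.

    Negative shifts are hyperpolarizing.  Zero deltas and unit scale return
    an identical parameter set (the wild-type identity).
    """
    if scale_tau_inact <= 0:
        raise ValueError("scale_tau_inact must be > 0")
    return replace(
        params,
        name=name if name is not None else params.name,
        v_half_act=params.v_half_act + d_act,
        v_half_inact=params.v_half_inact + d_inact,
        tau_inact_table=tuple((v, t * scale_tau_inact) for v, t in params.tau_inact_table),
    )


# ---------------------------------------------------------------------------
# Parameter-file I/O (YAML or JSON; one record per variant)

_FIELDS = (
    "v_half_act", "k_act", "v_half_inact", "k_inact",
    "tau_act_table", "tau_inact_table", "tau_deact_table",
    "p_act", "g_max", "e_rev",
)


def _record_to_params(name: str, rec: dict) -> GatingParams:
    kwargs = {k: rec[k] for k in _FIELDS if k in rec}
    for key in ("tau_act_table", "tau_inact_table", "tau_deact_table"):
        if kwargs.get(key) is not None:
            kwargs[key] = [tuple(p) for p in kwargs[key]]
    return GatingParams(name=name, **kwargs)


def load_params(path: str | Path) -> dict[str, GatingParams]:
    """Load a parameter file (YAML or JSON) into {variant: GatingParams}."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return {name: _record_to_params(name, rec) for name, rec in data.items()}


def load_shipped_params() -> dict[str, GatingParams]:
    """Load the packaged Cav3.3 wild-type + variant parameter file."""
    ref = resources.files("cav33sim").joinpath("params/cav33_variants.yaml")
    data = yaml.safe_load(ref.read_text())
    return {name: _record_to_params(name, rec) for name, rec in data.items()}


def save_params(params: dict[str, GatingParams], path: str | Path) -> None:
    path = Path(path)
    data = {}
    for name, p in params.items():
        rec = {
            "v_half_act": p.v_half_act, "k_act": p.k_act,
            "v_half_inact": p.v_half_inact, "k_inact": p.k_inact,
            "p_act": p.p_act, "g_max": p.g_max, "e_rev": p.e_rev,
            "tau_act_table": [list(t) for t in p.tau_act_table],
            "tau_inact_table": [list(t) for t in p.tau_inact_table],
        }
        if p.tau_deact_table is not None:
            rec["tau_deact_table"] = [list(t) for t in p.tau_deact_table]
        data[name] = rec
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
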