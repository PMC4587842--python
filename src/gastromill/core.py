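"""Membrane, current, synapse, and integration primitives.

Internal unit system (dimensionally closed):

* voltage  mV
* time     ms
* conductance  nS
* capacitance  pF
* current  pA   (nS * mV = pA, pF * mV / ms = pA)

Spike times are reported in seconds at the analysis layer; currents appear
in nA in user-facing tables.  All membrane currents follow the outward-
positive convention ``I = g * (V - E)``, so ``dV/dt = (I_inj - sum I) / C``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import InvalidParameterError, IntegrationDivergedError

__all__ = [
    "IMIChannel",
    "SpikeChannelSet",
    "GradedSynapse",
    "GapJunction",
    "DynClampSpec",
    "IntegratorSettings",
    "NeuronCompartment",
    "imi_activation_steady",
    "imi_current",
    "leak_current",
    "dynamic_clamp_current",
    "imi_iv_minimum",
    "step_compartment",
    "simulate_compartment",
]


# ---------------------------------------------------------------------------
# elementary currents


def imi_activation_steady(V, V0: float = -40.0, s: float = -10.0):
    """Steady-state activation of the modulator-induced current.

    ``a_inf(V) = 1 / (1 + exp((V - V0) / s))``.  With the default slope
    factor ``s = -10`` mV this is monotonically increasing in V, with
    midpoint 0.5 at ``V = V0 = -40`` mV.

    Parameters
    ----------
    V : float or array
        Membrane potential (mV).
    V0 : float
        Half-activation voltage (mV).
    s : float
        Slope factor (mV); must be nonzero.
    """
    if s == 0:
        raise InvalidParameterError("slope factor s must be nonzero")
    return 1.0 / (1.0 + np.exp((np.asarray(V, dtype=float) - V0) / s))


def leak_current(V, g: float, E: float):
    """Instantaneous linear leak current ``I = g * (V - E)`` in pA."""
    if g < 0:
        raise InvalidParameterError(f"leak conductance must be >= 0, got {g}")
    return g * (np.asarray(V, dtype=float) - E)


def dynamic_clamp_current(V, spec: "DynClampSpec", sign: int = +1):
    """Artificial leak current ``I_dyn = sign * delta_leak * (V - E)``.

    ``sign = +1`` adds leak (mimicking warming); ``sign = -1`` subtracts it
    (the "negative leak" rescue).  Returns pA.
    """
    if sign not in (+1, -1):
        raise InvalidParameterError(f"sign must be +1 or -1, got {sign}")
    if spec.delta_leak < 0:
        raise InvalidParameterError(
            "delta_leak must be >= 0; apply sign=-1 for subtraction"
        )
    return sign * spec.delta_leak * (np.asarray(V, dtype=float) - spec.E)


# ---------------------------------------------------------------------------
# channel / synapse state containers


@dataclass
class IMIChannel:
    """Modulator-induced current: noninactivating, voltage-gated, inward.

    ``I = g_max * a**p * (V - E_rev)`` with first-order activation
    ``tau_a * da/dt = a_inf(V) - a``.  Because E_rev = 0 mV and the
    activation is sigmoidal, the steady-state I-V relation is an inverted
    bell; on its falling flank the current behaves as a negative leak
    conductance.
    """

    g_max: float
    a: float = 0.0
    V0: float = -40.0
    s: float = -10.0
    p: int = 1
    E_rev: float = 0.0
    tau_a: float = 50.0

    def __post_init__(self):
        if self.g_max < 0:
            raise InvalidParameterError("g_max must be >= 0")
        if self.s == 0:
            raise InvalidParameterError("slope factor s must be nonzero")
        if self.tau_a <= 0:
            raise InvalidParameterError("tau_a must be > 0")
        if not 0.0 <= self.a <= 1.0:
            raise InvalidParameterError("activation a must lie in [0, 1]")

    def steady_activation(self, V):
        return imi_activation_steady(V, self.V0, self.s)

    def current(self, V: float) -> float:
        return self.g_max * self.a**self.p * (V - self.E_rev)

    def step(self, V: float, dt: float) -> None:
        a_inf = float(self.steady_activation(V))
        self.a += (a_inf - self.a) * -math.expm1(-dt / self.tau_a)


def imi_current(V, ch: IMIChannel):
    """Current through an I_MI channel at its present activation (pA)."""
    return ch.g_max * ch.a**ch.p * (np.asarray(V, dtype=float) - ch.E_rev)


def imi_iv_minimum(ch: IMIChannel) -> tuple[float, float]:
    """Voltage and value of the maximal inward steady-state I_MI.

    Minimises ``g_max * a_inf(V)**p * (V - E_rev)`` over the physiological
    range [-80, 0] mV.  The minimum sits strictly between V0 and E_rev and
    scales linearly with g_max.
    """
    if ch.g_max <= 0:
        raise InvalidParameterError("I-V relation is flat for g_max = 0; minimum undefined")

    def iv(v):
        return float(ch.g_max * ch.steady_activation(v) ** ch.p * (v - ch.E_rev))

    res = minimize_scalar(iv, bounds=(-80.0, 0.0), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x), float(res.fun)


# -- classical spike-generating currents ------------------------------------
#
# The fast inward (m^3 h) and delayed outward (n^4) currents use classical
# squid-axon kinetics expressed in the modern voltage convention (rest near
# -65 mV), rigidly shifted so the spike threshold sits near -40 mV.  The
# activation shift of the outward current can be set independently, which
# keeps its resting "window" conductance small when a cell has to sit
# quasi-statically near threshold.


def _linoid(x: float, k: float) -> float:
    """x / (1 - exp(-x/k)) with the removable singularity handled."""
    r = x / k
    if abs(r) < 1e-7:
        return k * (1.0 + r / 2.0)
    return x / -math.expm1(-r)


def na_rates(V: float, shift: float) -> tuple[float, float, float, float]:
    """(alpha_m, beta_m, alpha_h, beta_h) in 1/ms for a shifted axon sodium current."""
    u = V - shift
    am = 0.1 * _linoid(u + 40.0, 10.0)
    bm = 4.0 * math.exp(-(u + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(u + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(u + 35.0) / 10.0))
    return am, bm, ah, bh


def k_rates(V: float, shift: float) -> tuple[float, float]:
    """(alpha_n, beta_n) in 1/ms for a shifted delayed-rectifier current."""
    u = V - shift
    an = 0.01 * _linoid(u + 55.0, 10.0)
    bn = 0.125 * math.exp(-(u + 65.0) / 80.0)
    return an, bn


@dataclass
class SpikeChannelSet:
    """Fast inward (Na, m^3 h) plus delayed outward (K, n^4) spike currents."""

    g_na: float
    g_k: float
    E_na: float = 50.0
    E_k: float = -80.0
    shift_na: float = 15.0
    shift_k: float = 30.0
    m: float = 0.0
    h: float = 1.0
    n: float = 0.0

    def __post_init__(self):
        if self.g_na < 0 or self.g_k < 0:
            raise InvalidParameterError("spike conductances must be >= 0")
        for x in (self.m, self.h, self.n):
            if not 0.0 <= x <= 1.0:
                raise InvalidParameterError("gating variables must lie in [0, 1]")

    def set_steady(self, V: float) -> None:
        am, bm, ah, bh = na_rates(V, self.shift_na)
        an, bn = k_rates(V, self.shift_k)
        self.m = am / (am + bm)
        self.h = ah / (ah + bh)
        self.n = an / (an + bn)

    def current(self, V: float) -> float:
        ina = self.g_na * self.m**3 * self.h * (V - self.E_na)
        ik = self.g_k * self.n**4 * (V - self.E_k)
        return ina + ik

    def step(self, V: float, dt: float) -> None:
        am, bm, ah, bh = na_rates(V, self.shift_na)
        an, bn = k_rates(V, self.shift_k)
        self.m = _gate_step(self.m, am, bm, dt)
        self.h = _gate_step(self.h, ah, bh, dt)
        self.n = _gate_step(self.n, an, bn, dt)


def _gate_step(x: float, alpha: float, beta: float, dt: float) -> float:
    # exponential Euler: exact for frozen rates, unconditionally in [0, 1]
    tau = 1.0 / (alpha + beta)
    xinf = alpha * tau
    return x + (xinf - x) * -math.expm1(-dt / tau)


@dataclass
class GradedSynapse:
    """Graded chemical transmission with sigmoidal voltage-dependent release.

    ``s_inf(V_pre) = 1 / (1 + exp(-(V_pre - V_th)/k))`` relaxes with time
    constant tau_syn; the postsynaptic current is
    ``g_max * s_syn * (V_post - E_rev)``.
    """

    g_max: float
    E_rev: float
    V_th: float
    k: float
    tau_syn: float
    s_syn: float = 0.0

    def __post_init__(self):
        if self.g_max < 0:
            raise InvalidParameterError("g_max must be >= 0")
        if self.k <= 0:
            raise InvalidParameterError("release slope k must be > 0")
        if self.tau_syn <= 0:
            raise InvalidParameterError("tau_syn must be > 0")
        if not 0.0 <= self.s_syn <= 1.0:
            raise InvalidParameterError("release state must lie in [0, 1]")

    def s_inf(self, V_pre: float) -> float:
        return 1.0 / (1.0 + math.exp(-(V_pre - self.V_th) / self.k))

    def current(self, V_post: float) -> float:
        return self.g_max * self.s_syn * (V_post - self.E_rev)

    def step(self, V_pre: float, dt: float) -> None:
        self.s_syn += (self.s_inf(V_pre) - self.s_syn) * -math.expm1(-dt / self.tau_syn)


@dataclass
class GapJunction:
    """Ohmic (non-rectifying) electrical coupling between two compartments."""

    g_gap: float
    endpoints: tuple[str, str] = ("MCN1_terminal", "LG")

    def __post_init__(self):
        if self.g_gap < 0:
            raise InvalidParameterError("g_gap must be >= 0")

    def currents(self, V1: float, V2: float) -> tuple[float, float]:
        """Outward-positive currents (into junction) at each endpoint.

        Charge conservation: the two returned values are exact negatives.
        """
        i1 = self.g_gap * (V1 - V2)
        return i1, -i1


@dataclass
class DynClampSpec:
    """Artificial leak conductance for dynamic clamp.

    delta_leak is the conductance difference (nS) computed from the 10 vs
    13 degree input-resistance measurements; E is the reversal of the
    artificial leak (taken as the resting potential at 13 degrees in the
    biological protocol).  A negative delta_leak can arise from a cooling
    measurement and is carried as-is; application direction is chosen by
    the ``sign`` argument of the clamp operations.
    """

    delta_leak: float
    E: float


@dataclass
class IntegratorSettings:
    """Fixed-step integration settings: dt in ms, duration in seconds."""

    dt: float = 0.05
    duration: float = 1.0
    method: str = "expeuler"

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidParameterError("dt must be > 0")
        if self.duration <= 0:
            raise InvalidParameterError("duration must be > 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * 1000.0 / self.dt))


@dataclass
class NeuronCompartment:
    """Single isopotential compartment: passive membrane plus channel set."""

    name: str
    C_m: float
    V: float
    g_leak: float
    E_leak: float
    channels: list = field(default_factory=list)

    def __post_init__(self):
        if self.C_m <= 0:
            raise InvalidParameterError(f"{self.name}: C_m must be > 0")
        if self.g_leak < 0:
            raise InvalidParameterError(f"{self.name}: g_leak must be >= 0")

    def membrane_current(self) -> float:
        i = self.g_leak * (self.V - self.E_leak)
        for ch in self.channels:
            i += ch.current(self.V)
        return i


def step_compartment(comp: NeuronCompartment, I_inject: float,
                     settings: IntegratorSettings) -> NeuronCompartment:
    """Advance one fixed step: exponential Euler gating, forward Euler voltage.

    Gating states are updated from the pre-step voltage, then the voltage is
    advanced with the updated channel states.  Raises
    IntegrationDivergedError if the state becomes non-finite.
    """
    dt = settings.dt
    V_pre = comp.V
    for ch in comp.channels:
        ch.step(V_pre, dt)
    i_mem = comp.membrane_current()
    comp.V += dt * (I_inject - i_mem) / comp.C_m
    if not math.isfinite(comp.V):
        raise IntegrationDivergedError(comp.name, float("nan"))
    return comp


def simulate_compartment(comp: NeuronCompartment, settings: IntegratorSettings,
                         I_inject=0.0):
    """Integrate a single compartment; returns (t_ms, V_mV) arrays.

    ``I_inject`` may be a constant (pA) or a callable of time in ms.
    """
    n = settings.n_steps
    dt = settings.dt
    t = np.arange(n + 1) * dt
    v = np.empty(n + 1)
    v[0] = comp.V
    drive = I_inject if callable(I_inject) else (lambda _t, _i=float(I_inject): _i)
    for i in range(n):
        try:
            step_compartment(comp, drive(t[i]), settings)
        except IntegrationDivergedError:
            raise IntegrationDivergedError(comp.name, float(t[i + 1])) from None
        v[i + 1] = comp.V
    return t, v
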