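"""The four-neuron gastric mill network: MCN1 (soma + terminal), LG, Int1, AB.

Connectivity follows the biological circuit: the projection neuron MCN1
excites LG through peptidergic activation of the modulator-induced current
I_MI (modelled as LG's I_MI conductance gated by a transmitter variable
driven by the MCN1 terminal), and excites Int1 through a fast synapse; LG
and Int1 form a reciprocally inhibitory half-center; LG presynaptically
inhibits the MCN1 terminal; terminal and LG are electrically coupled; the
pyloric pacemaker AB rhythmically inhibits Int1 at 1 Hz, producing the
periodic disinhibitions of LG that time its burst onsets.

Temperature never appears explicitly: warming enters solely as an increase
in LG's leak conductance, neuromodulation solely as the I_MI maximal
conductance ``g_mi_nS``.  Those two are the only parameters the sweep
protocols vary.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .core import DynClampSpec
from .errors import ConfigError, IntegrationDivergedError
from .metrics import Burst, SpikeTrain, classify_bursts

NEURON_NAMES = ("LG", "Int1", "AB", "MCN1", "MCN1_terminal")

#: directed edge set of the biological circuit (sign '+' excitatory,
#: '-' inhibitory, 'electrical' for the gap junction)
REQUIRED_EDGES = frozenset({
    ("MCN1", "LG", "+"),
    ("MCN1", "Int1", "+"),
    ("LG", "Int1", "-"),
    ("Int1", "LG", "-"),
    ("LG", "MCN1_terminal", "-"),
    ("MCN1_terminal", "LG", "electrical"),
    ("AB", "Int1", "-"),
})


@dataclass
class NeuronParams:
    """Single-compartment membrane; spike currents absent when g_na_nS = 0."""

    C_pF: float
    g_leak_nS: float
    E_leak_mV: float
    g_na_nS: float = 0.0
    g_k_nS: float = 0.0
    E_na_mV: float = 50.0
    E_k_mV: float = -80.0
    shift_na_mV: float = 15.0
    shift_k_mV: float = 30.0

    def validate(self, name: str) -> None:
        if self.C_pF <= 0:
            raise ConfigError(f"{name}.C_pF must be > 0 (pF)")
        for key in ("g_leak_nS", "g_na_nS", "g_k_nS"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{name}.{key} must be >= 0 (nS)")


@dataclass
class TerminalParams:
    """MCN1 terminal compartment plus its transmitter dynamics.

    Soma spikes invade the terminal as a fast excitatory conductance
    (drive_*); terminal depolarisation builds the transmitter variable T
    (release_*) that gates LG's I_MI conductance.  LG's presynaptic
    inhibition of the terminal interrupts the build-up, closing the slow
    loop that sets the multi-second gastric cycle period.
    """

    C_pF: float
    g_leak_nS: float
    E_leak_mV: float
    drive_g_nS: float
    drive_E_mV: float
    drive_Vth_mV: float
    drive_k_mV: float
    drive_tau_ms: float
    release_Vth_mV: float
    release_k_mV: float
    release_rise_rate_per_s: float
    release_tau_decay_ms: float

    def validate(self, name: str = "terminal") -> None:
        if self.C_pF <= 0:
            raise ConfigError(f"{name}.C_pF must be > 0 (pF)")
        if self.g_leak_nS < 0 or self.drive_g_nS < 0:
            raise ConfigError(f"{name}: conductances must be >= 0 (nS)")
        for key in ("drive_tau_ms", "release_rise_rate_per_s", "release_tau_decay_ms"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{name}.{key} must be > 0 (ms)")


@dataclass
class IMIParams:
    """Modulator-induced current kinetics (fixed to the printed values)."""

    V0_mV: float = -40.0
    s_mV: float = -10.0
    tau_ms: float = 50.0
    E_mV: float = 0.0
    p: int = 1

    def validate(self) -> None:
        if self.s_mV == 0:
            raise ConfigError("imi.s_mV must be nonzero")
        if self.tau_ms <= 0:
            raise ConfigError("imi.tau_ms must be > 0")
        if self.p != 1:
            raise ConfigError("imi.p: only p = 1 is supported")


@dataclass
class SynapseSpec:
    """Graded chemical synapse between named neurons."""

    source: str
    target: str
    g_max_nS: float
    E_mV: float
    V_th_mV: float
    k_mV: float
    tau_ms: float

    @property
    def sign(self) -> str:
        return "+" if self.E_mV >= -40.0 else "-"

    def validate(self) -> None:
        if self.source not in NEURON_NAMES or self.target not in NEURON_NAMES:
            raise ConfigError(
                f"synapse {self.source}->{self.target}: unknown neuron name"
            )
        if self.g_max_nS < 0:
            raise ConfigError(
                f"synapse {self.source}->{self.target}: g_max_nS must be >= 0"
            )
        if self.k_mV <= 0 or self.tau_ms <= 0:
            raise ConfigError(
                f"synapse {self.source}->{self.target}: k_mV and tau_ms must be > 0"
            )


@dataclass
class DriveParams:
    """Extrinsic drive protocols: MCN1 pulse train and AB sinusoid."""

    mcn1_pulse_hz: float = 15.0
    mcn1_pulse_ms: float = 1.0
    mcn1_pulse_pA: float = 3000.0
    ab_freq_hz: float = 1.0
    ab_amp_pA: float = 300.0

    def validate(self) -> None:
        if self.mcn1_pulse_hz <= 0 or self.ab_freq_hz <= 0:
            raise ConfigError("drive frequencies must be > 0 (Hz)")
        if self.mcn1_pulse_ms <= 0:
            raise ConfigError("drives.mcn1_pulse_ms must be > 0 (ms)")


@dataclass
class SimSettings:
    """Fixed-step integration window.

    ``settle_s`` seconds are simulated before the scored window of
    ``duration_s`` seconds; scoring always ignores the settling transient.
    ``trace_stride`` = 1 stores full-resolution traces, larger values
    subsample, 0 disables trace storage (used by sweeps).
    """

    dt_ms: float = 0.025
    duration_s: float = 100.0
    settle_s: float = 10.0
    trace_stride: int = 1
    method: str = "expeuler"

    def validate(self) -> None:
        if self.dt_ms <= 0:
            raise ConfigError("sim.dt_ms must be > 0 (ms)")
        if self.duration_s <= 0 or self.settle_s < 0:
            raise ConfigError("sim.duration_s must be > 0 and settle_s >= 0 (s)")
        if self.trace_stride < 0:
            raise ConfigError("sim.trace_stride must be >= 0")
        if self.method != "expeuler":
            raise ConfigError(f"unknown integration method {self.method!r}")


@dataclass
class ClampTerm:
    """One applied dynamic-clamp term on LG: sign * delta_leak * (V - E)."""

    delta_leak_nS: float
    E_mV: float
    sign: int = +1

    def validate(self) -> None:
        if self.sign not in (+1, -1):
            raise ConfigError("clamp sign must be +1 or -1")
        if self.delta_leak_nS < 0:
            raise ConfigError("clamp delta_leak_nS must be >= 0; use sign=-1")


@dataclass
class CircuitConfig:
    lg: NeuronParams
    int1: NeuronParams
    ab: NeuronParams
    mcn1_soma: NeuronParams
    terminal: TerminalParams
    g_mi_nS: float
    imi: IMIParams
    synapses: list[SynapseSpec]
    gap_junction_nS: float
    drives: DriveParams
    sim: SimSettings
    clamps: list[ClampTerm] = field(default_factory=list)

    def validate(self) -> None:
        self.lg.validate("lg")
        self.int1.validate("int1")
        self.ab.validate("ab")
        self.mcn1_soma.validate("mcn1_soma")
        self.terminal.validate()
        self.imi.validate()
        self.drives.validate()
        self.sim.validate()
        if self.g_mi_nS < 0:
            raise ConfigError("g_mi_nS must be >= 0 (nS)")
        if self.gap_junction_nS < 0:
            raise ConfigError("gap_junction_nS must be >= 0 (nS)")
        for syn in self.synapses:
            syn.validate()
        for clamp in self.clamps:
            clamp.validate()
        validate_connectivity(self)

    def copy(self) -> "CircuitConfig":
        return copy.deepcopy(self)


def audit_edges(config: CircuitConfig) -> set[tuple[str, str, str]]:
    """Directed signed edge list of the configured network.

    The MCN1 -> LG excitation is the soma -> terminal -> I_MI pathway and is
    audited as one '+' edge; it is present when both the terminal drive and
    the I_MI pathway have nonzero conductance paths.
    """
    edges = {(s.source, s.target, s.sign) for s in config.synapses}
    if config.terminal.drive_g_nS > 0:
        edges.add(("MCN1", "LG", "+"))
    if config.gap_junction_nS > 0:
        edges.add(("MCN1_terminal", "LG", "electrical"))
    return edges


def validate_connectivity(config: CircuitConfig) -> None:
    """Check the edge audit against the biological circuit; raise ConfigError."""
    edges = audit_edges(config)
    missing = REQUIRED_EDGES - edges
    extra = edges - REQUIRED_EDGES
    if missing or extra:
        parts = []
        if missing:
            parts.append("missing edges: " + ", ".join(
                f"{s}->{t}:{sg}" for s, t, sg in sorted(missing)))
        if extra:
            parts.append("unexpected edges: " + ", ".join(
                f"{s}->{t}:{sg}" for s, t, sg in sorted(extra)))
        raise ConfigError("connectivity audit failed; " + "; ".join(parts))


def build_circuit(config: CircuitConfig) -> np.ndarray:
    """Validate a configuration and flatten it to the integrator's
    parameter vector."""
    config.validate()
    p = np.zeros(K.N_PARAMS)

    lg = config.lg
    # fused linear leak: leak plus every clamp term, as I = A*V - B.
    # Clamp terms whose reversal equals E_leak fold into a single product
    # so that clamp-vs-parameter equivalence and +/- cancellation are exact.
    A = lg.g_leak_nS + math.fsum(c.sign * c.delta_leak_nS for c in config.clamps)
    if all(c.E_mV == lg.E_leak_mV for c in config.clamps):
        B = A * lg.E_leak_mV
    else:
        B = lg.g_leak_nS * lg.E_leak_mV + math.fsum(
            c.sign * c.delta_leak_nS * c.E_mV for c in config.clamps)
    p[K.LG_C] = lg.C_pF
    p[K.LG_LEAK_A] = A
    p[K.LG_LEAK_B] = B
    p[K.LG_EL] = lg.E_leak_mV
    p[K.LG_GNA] = lg.g_na_nS
    p[K.LG_GK] = lg.g_k_nS
    p[K.LG_ENA] = lg.E_na_mV
    p[K.LG_EK] = lg.E_k_mV
    p[K.LG_SHNA] = lg.shift_na_mV
    p[K.LG_SHK] = lg.shift_k_mV

    p[K.MI_G] = config.g_mi_nS
    p[K.MI_V0] = config.imi.V0_mV
    p[K.MI_S] = config.imi.s_mV
    p[K.MI_TAU] = config.imi.tau_ms
    p[K.MI_E] = config.imi.E_mV

    i1 = config.int1
    p[K.I1_C] = i1.C_pF
    p[K.I1_GL] = i1.g_leak_nS
    p[K.I1_EL] = i1.E_leak_mV
    p[K.I1_GNA] = i1.g_na_nS
    p[K.I1_GK] = i1.g_k_nS
    p[K.I1_ENA] = i1.E_na_mV
    p[K.I1_EK] = i1.E_k_mV
    p[K.I1_SHNA] = i1.shift_na_mV
    p[K.I1_SHK] = i1.shift_k_mV

    mc = config.mcn1_soma
    p[K.MC_C] = mc.C_pF
    p[K.MC_GL] = mc.g_leak_nS
    p[K.MC_EL] = mc.E_leak_mV
    p[K.MC_GNA] = mc.g_na_nS
    p[K.MC_GK] = mc.g_k_nS
    p[K.MC_ENA] = mc.E_na_mV
    p[K.MC_EK] = mc.E_k_mV
    p[K.MC_SHNA] = mc.shift_na_mV
    p[K.MC_SHK] = mc.shift_k_mV

    tm = config.terminal
    p[K.TM_C] = tm.C_pF
    p[K.TM_GL] = tm.g_leak_nS
    p[K.TM_EL] = tm.E_leak_mV
    p[K.AX_G] = tm.drive_g_nS
    p[K.AX_E] = tm.drive_E_mV
    p[K.AX_VTH] = tm.drive_Vth_mV
    p[K.AX_K] = tm.drive_k_mV
    p[K.AX_TAU] = tm.drive_tau_ms
    p[K.T_VTH] = tm.release_Vth_mV
    p[K.T_K] = tm.release_k_mV
    p[K.T_RISE_RATE] = tm.release_rise_rate_per_s / 1000.0  # per ms
    p[K.T_TAU_DECAY] = tm.release_tau_decay_ms

    ab = config.ab
    p[K.AB_C] = ab.C_pF
    p[K.AB_GL] = ab.g_leak_nS
    p[K.AB_EL] = ab.E_leak_mV

    slots = {
        ("Int1", "LG"): K.S_I1LG_G,
        ("LG", "Int1"): K.S_LGI1_G,
        ("LG", "MCN1_terminal"): K.S_LGTM_G,
        ("AB", "Int1"): K.S_ABI1_G,
        ("MCN1", "Int1"): K.S_MCI1_G,
    }
    for syn in config.synapses:
        base = slots[(syn.source, syn.target)]  # connectivity already audited
        p[base + 0] = syn.g_max_nS
        p[base + 1] = syn.E_mV
        p[base + 2] = syn.V_th_mV
        p[base + 3] = syn.k_mV
        p[base + 4] = syn.tau_ms

    p[K.GAP_G] = config.gap_junction_nS

    d = config.drives
    p[K.MC_PERIOD_MS] = 1000.0 / d.mcn1_pulse_hz
    p[K.MC_PULSE_MS] = d.mcn1_pulse_ms
    p[K.MC_PULSE_PA] = d.mcn1_pulse_pA
    p[K.AB_F_HZ] = d.ab_freq_hz
    p[K.AB_AMP_PA] = d.ab_amp_pA

    p[K.SPK_THR] = -20.0
    p[K.SPK_LOCKOUT_MS] = 2.0
    return p


@dataclass
class SimulationResult:
    """Output of one network simulation.

    Times are in seconds; the trace dictionary holds one voltage array per
    compartment (mV) plus the transmitter variable ``T`` (dimensionless).
    ``scored_window`` excludes the settling transient: all rhythm metrics
    are computed on spikes inside it.
    """

    t: np.ndarray
    V: dict
    spikes: dict
    i_dyn_pA: np.ndarray | None
    config: CircuitConfig
    scored_window: tuple[float, float]

    def train(self, neuron: str = "LG") -> SpikeTrain:
        return SpikeTrain(neuron, self.spikes[neuron], self.scored_window)

    def scored_bursts(self, neuron: str = "LG") -> list[Burst]:
        return classify_bursts(self.train(neuron))

    def scored_spike_count(self, neuron: str = "LG") -> int:
        t0, t1 = self.scored_window
        s = self.spikes[neuron]
        return int(np.count_nonzero((s >= t0) & (s <= t1)))


def run_simulation(config: CircuitConfig) -> SimulationResult:
    """Integrate the circuit; deterministic (no random elements).

    Raises IntegrationDivergedError if the state becomes non-finite.
    """
    p = build_circuit(config)
    sim = config.sim
    dt = sim.dt_ms
    total_ms = (sim.settle_s + sim.duration_s) * 1000.0
    n_steps = int(round(total_ms / dt))
    stride = sim.trace_stride
    n_rec = n_steps // stride + 1 if stride > 0 else 1
    vout = np.empty((K.N_ROWS, n_rec)) if stride > 0 else np.empty((K.N_ROWS, 1))

    est_rate_hz = 120.0  # generous cap for spike buffers
    cap = max(1000, int(est_rate_hz * (total_ms / 1000.0)))
    spk_lg = np.empty(cap)
    spk_i1 = np.empty(cap)
    spk_mc = np.empty(cap)

    code, n_lg, n_i1, n_mc = K.integrate(
        p, dt, n_steps, stride if stride > 0 else 0, vout, spk_lg, spk_i1, spk_mc
    )
    if code >= 0:
        raise IntegrationDivergedError("LG/Int1 network", code * dt)

    t = np.arange(n_rec) * (dt * stride) / 1000.0 if stride > 0 else np.empty(0)
    V = {}
    if stride > 0:
        V = {
            "LG": vout[K.ROW_LG],
            "Int1": vout[K.ROW_INT1],
            "MCN1": vout[K.ROW_MCN1],
            "MCN1_terminal": vout[K.ROW_TERM],
            "AB": vout[K.ROW_AB],
            "T": vout[K.ROW_T],
        }
    spikes = {
        "LG": spk_lg[: min(n_lg, cap)].copy() / 1000.0,
        "Int1": spk_i1[: min(n_i1, cap)].copy() / 1000.0,
        "MCN1": spk_mc[: min(n_mc, cap)].copy() / 1000.0,
    }
    i_dyn = None
    if config.clamps and stride > 0:
        i_dyn = np.zeros_like(vout[K.ROW_LG])
        for c in config.clamps:
            i_dyn += c.sign * c.delta_leak_nS * (vout[K.ROW_LG] - c.E_mV)
    return SimulationResult(
        t=t,
        V=V,
        spikes=spikes,
        i_dyn_pA=i_dyn,
        config=config.copy(),
        scored_window=(sim.settle_s, sim.settle_s + sim.duration_s),
    )


def apply_dynamic_clamp(config: CircuitConfig, spec: DynClampSpec,
                        sign: int = +1) -> CircuitConfig:
    """Return a configuration whose LG receives ``sign * delta_leak * (V - E)``.

    Multiple applications accumulate; +delta and -delta with the same E
    cancel exactly.
    """
    out = config.copy()
    out.clamps.append(ClampTerm(delta_leak_nS=spec.delta_leak, E_mV=spec.E,
                                sign=sign))
    out.clamps[-1].validate()
    return out


def with_lg_conductances(config: CircuitConfig, g_leak_nS: float | None = None,
                         g_mi_nS: float | None = None) -> CircuitConfig:
    """Copy of the configuration with LG's leak and/or I_MI conductance replaced.

    These are the only two parameters the sweep protocols touch.
    """
    out = config.copy()
    if g_leak_nS is not None:
        out.lg.g_leak_nS = float(g_leak_nS)
    if g_mi_nS is not None:
        out.g_mi_nS = float(g_mi_nS)
    return out

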