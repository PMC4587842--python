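"""Synthetic electrophysiology with known ground truth.

Three generators emulate the measurement substrates of the study system:
bursting LG spike trains, the linear decline of spikes/burst with
temperature, and passive RC membrane responses to current steps.  Every
generator takes an explicit seed and is bit-reproducible; there is no
hidden global random state.  Noise models are deliberately simple:
additive independent Gaussian noise on voltages and values, uniform jitter
on times and counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .metrics import Burst, SpikeTrain

__all__ = [
    "BurstTrainSpec",
    "TempSeriesSpec",
    "PassiveTraceSpec",
    "TempSeries",
    "gen_burst_train",
    "gen_temperature_series",
    "gen_passive_trace",
]


@dataclass
class BurstTrainSpec:
    """Prescribed burst structure for a surrogate LG spike train.

    The invariants mirror the burst definition used by the classifier:
    intraburst ISI below 1 s, interburst gaps of at least 2 s (also after
    onset jitter), at least four spikes per burst.
    """

    n_bursts: int
    spikes_per_burst: int
    seed: int
    spikes_jitter: int = 0
    isi: float = 0.1  # s, intraburst
    interburst: float = 8.0  # s, offset-to-next-onset
    onset_jitter: float = 0.0  # s, uniform on [-j, +j]
    t_start: float = 1.0  # s, onset of the first burst

    def __post_init__(self):
        if self.n_bursts < 0:
            raise InvalidParameterError("n_bursts must be >= 0")
        if self.n_bursts > 0:
            if self.spikes_per_burst - self.spikes_jitter < 4:
                raise InvalidParameterError(
                    "spikes_per_burst minus jitter must stay >= 4"
                )
            if not 0 < self.isi < 1.0:
                raise InvalidParameterError("intraburst ISI must lie in (0, 1) s")
            if self.interburst - 2 * self.onset_jitter < 2.0:
                raise InvalidParameterError(
                    "interburst interval minus jitter must stay >= 2 s"
                )
        if self.spikes_jitter < 0 or self.onset_jitter < 0:
            raise InvalidParameterError("jitters must be >= 0")


def gen_burst_train(spec: BurstTrainSpec) -> tuple[SpikeTrain, list[Burst]]:
    """Generate a spike train with a known burst decomposition.

    Returns the train plus the ground-truth burst list; by construction the
    burst classifier recovers the ground truth exactly.
    """
    rng = np.random.default_rng(spec.seed)
    times: list[np.ndarray] = []
    bursts: list[Burst] = []
    onset = spec.t_start
    for _ in range(spec.n_bursts):
        n = spec.spikes_per_burst
        if spec.spikes_jitter:
            n += int(rng.integers(-spec.spikes_jitter, spec.spikes_jitter + 1))
        st = onset + spec.isi * np.arange(n)
        times.append(st)
        bursts.append(Burst(onset=float(st[0]), offset=float(st[-1]),
                            n_spikes=n, spike_times=st))
        jitter = rng.uniform(-spec.onset_jitter, spec.onset_jitter) if spec.onset_jitter else 0.0
        onset = float(st[-1]) + spec.interburst + jitter
    all_times = np.concatenate(times) if times else np.empty(0)
    t1 = float(all_times[-1]) + 2.5 if all_times.size else spec.t_start + 1.0
    return SpikeTrain("LG", all_times, (0.0, t1)), bursts


@dataclass
class TempSeriesSpec:
    """Linear temperature trend of spikes/burst with a floor at zero."""

    slope: float  # spikes/burst per degree C
    intercept: float  # spikes/burst at 0 degrees C
    temperatures: np.ndarray  # degrees C
    noise_sd: float
    seed: int

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.temperatures.size < 3:
            raise InvalidParameterError("need at least three temperatures")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


@dataclass
class TempSeries:
    temperature: np.ndarray
    spikes_per_burst: np.ndarray
    cessation_temperature: float  # nan if the line never reaches zero
    spec: TempSeriesSpec = field(repr=False)


# presets mirroring the measured regression slopes: tonic drive at 4 Hz and
# 7 Hz in the isolated preparation, and the shallow in-vivo decline
TEMP_SERIES_PRESETS = {
    "isolated_4hz": dict(slope=-9.81, intercept=45.0 + 9.81 * 8.0,
                         temperatures=np.arange(8.0, 11.51, 0.5), noise_sd=3.0),
    "isolated_7hz": dict(slope=-7.52, intercept=40.0 + 7.52 * 8.0,
                         temperatures=np.arange(8.0, 12.01, 0.5), noise_sd=3.0),
    "in_vivo": dict(slope=-0.46, intercept=6.0 + 0.46 * 9.0,
                    temperatures=np.arange(9.0, 16.01, 0.5), noise_sd=1.0),
}


def temp_series_preset(name: str, seed: int) -> TempSeriesSpec:
    try:
        kw = TEMP_SERIES_PRESETS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown preset {name!r}; choose from {sorted(TEMP_SERIES_PRESETS)}"
        ) from None
    return TempSeriesSpec(seed=seed, **kw)


def gen_temperature_series(spec: TempSeriesSpec) -> TempSeries:
    """(temperature, spikes/burst) pairs on a noisy clipped line.

    The noiseless series lies exactly on ``slope*T + intercept`` clipped at
    zero; the ground-truth cessation temperature is the root of the line
    (nan for non-negative slopes).
    """
    rng = np.random.default_rng(spec.seed)
    line = spec.slope * spec.temperatures + spec.intercept
    noise = rng.normal(0.0, spec.noise_sd, size=line.shape) if spec.noise_sd else 0.0
    y = np.maximum(line + noise, 0.0)
    cease = -spec.intercept / spec.slope if spec.slope < 0 else float("nan")
    return TempSeries(spec.temperatures.copy(), y, float(cease), spec)


@dataclass
class PassiveTraceSpec:
    """Passive RC membrane response to a schedule of current steps.

    R in MOhm, C in nF (tau = R*C in ms), E in mV; pulses are
    (amplitude_nA, onset_s, duration_s) triples; sampling interval in ms.
    """

    R: float
    C: float
    E: float
    pulses: list[tuple[float, float, float]]
    duration: float  # s, total trace length
    dt: float = 0.1  # ms
    noise_sd: float = 0.0  # mV
    seed: int = 0

    def __post_init__(self):
        if self.R <= 0 or self.C <= 0:
            raise InvalidParameterError("R and C must be > 0")
        if self.dt <= 0 or self.duration <= 0:
            raise InvalidParameterError("dt and duration must be > 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        for amp, onset, dur in self.pulses:
            if onset < 0 or dur <= 0 or onset + dur > self.duration:
                raise InvalidParameterError(
                    f"pulse ({amp}, {onset}, {dur}) falls outside the trace"
                )


def gen_passive_trace(spec: PassiveTraceSpec) -> tuple[np.ndarray, np.ndarray]:
    """Exact piecewise-exponential RC solution plus seeded Gaussian noise.

    Returns (t_s, V_mV).  The steady-state deflection of a long pulse is
    R*I exactly (MOhm * nA = mV).
    """
    rng = np.random.default_rng(spec.seed)
    tau_s = spec.R * spec.C / 1000.0  # RC in ms -> s
    t = np.arange(0.0, spec.duration + spec.dt / 2000.0, spec.dt / 1000.0)
    # current schedule edges
    edges = sorted({0.0, spec.duration}
                   | {p[1] for p in spec.pulses}
                   | {p[1] + p[2] for p in spec.pulses})
    v = np.empty_like(t)
    v0 = spec.E
    for lo, hi in zip(edges[:-1], edges[1:]):
        amp = sum(p[0] for p in spec.pulses if p[1] <= lo < p[1] + p[2])
        target = spec.E + spec.R * amp
        seg = (t >= lo) & (t <= hi) if hi == edges[-1] else (t >= lo) & (t < hi)
        v[seg] = target + (v0 - target) * np.exp(-(t[seg] - lo) / tau_s)
        v0 = target + (v0 - target) * np.exp(-(hi - lo) / tau_s)
    if spec.noise_sd:
        v = v + rng.normal(0.0, spec.noise_sd, size=v.shape)
    return t, v
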