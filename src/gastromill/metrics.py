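"""Spike, burst, rhythmicity, input-resistance, and trend analytics.

One code path serves both simulated voltage traces and synthetic or
user-supplied recordings.  Conventions (covered by boundary tests):

* a burst needs at least four spikes;
* consecutive spikes with an interspike interval (ISI) below 1 s belong to
  the same run; runs separated by gaps shorter than 2 s are merged into one
  burst event, so distinct bursts are always at least 2 s apart;
* comparisons are strict: an ISI of exactly 1 s splits a run, a gap of
  exactly 2 s separates bursts;
* a burst straddling the end of the analysis window counts if its onset
  lies inside the window.

All spike times are in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import DynClampSpec
from .errors import InvalidParameterError

MAX_INTRABURST_ISI_S = 1.0
MIN_INTERBURST_GAP_S = 2.0
MIN_SPIKES_PER_BURST = 4
MIN_BURSTS_RHYTHMIC = 3


@dataclass
class SpikeTrain:
    """Ordered spike times of one unit within a recording window."""

    label: str
    times: np.ndarray
    window: tuple[float, float]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise InvalidParameterError("spike times must be a 1-d sequence")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("spike times must be strictly increasing")
        t0, t1 = self.window
        if t1 <= t0:
            raise InvalidParameterError("window must have positive length")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class Burst:
    """One classified burst: onset/offset are first/last spike times (s)."""

    onset: float
    offset: float
    n_spikes: int
    spike_times: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.n_spikes < MIN_SPIKES_PER_BURST:
            raise InvalidParameterError("a burst needs at least four spikes")
        if self.offset < self.onset:
            raise InvalidParameterError("burst offset precedes onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def intraburst_frequency(self) -> float:
        """(n_spikes - 1) / duration, in Hz."""
        if self.duration <= 0:
            raise InvalidParameterError("zero-duration burst has no frequency")
        return (self.n_spikes - 1) / self.duration


@dataclass
class TempMeasurement:
    """Passive characterisation of one cell at one temperature."""

    temperature: float  # degrees C
    R_in: float  # MOhm
    V_rest: float  # mV

    def __post_init__(self):
        if self.R_in <= 0:
            raise InvalidParameterError("input resistance must be > 0")


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    ci95: tuple[float, float]


# ---------------------------------------------------------------------------


def detect_spikes(t, v, label: str = "unit", threshold: float = -20.0,
                  refractory: float = 0.002) -> SpikeTrain:
    """Threshold-crossing spike detection on a uniformly sampled trace.

    One spike per upward crossing of ``threshold`` (mV), with a refractory
    lockout (s) to suppress double counts on noisy flanks.  ``t`` is in
    seconds.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.size != v.size or t.size < 2:
        raise InvalidParameterError("t and v must be equal-length with >= 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise InvalidParameterError("spike detection requires a uniform time grid")
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    times = []
    last = -np.inf
    for i in up:
        if t[i] - last >= refractory:
            times.append(t[i])
            last = t[i]
    return SpikeTrain(label, np.asarray(times), (float(t[0]), float(t[-1])))


def classify_bursts(train: SpikeTrain) -> list[Burst]:
    """Group a spike train into bursts.

    (i) consecutive spikes with ISI < 1 s form candidate runs; (ii) runs
    separated by gaps < 2 s merge into one event; (iii) events with fewer
    than four spikes are discarded.  Spikes outside the train's window are
    ignored, which makes the classification invariant to activity beyond
    the window.
    """
    t0, t1 = train.window
    times = train.times[(train.times >= t0) & (train.times <= t1)]
    if times.size == 0:
        return []
    # (i) runs at ISI < 1 s
    breaks = np.flatnonzero(np.diff(times) >= MAX_INTRABURST_ISI_S) + 1
    runs = np.split(times, breaks)
    # (ii) merge runs separated by < 2 s
    events: list[np.ndarray] = [runs[0]]
    for run in runs[1:]:
        if run[0] - events[-1][-1] < MIN_INTERBURST_GAP_S:
            events[-1] = np.concatenate([events[-1], run])
        else:
            events.append(run)
    # (iii) discard small events
    return [
        Burst(onset=float(ev[0]), offset=float(ev[-1]), n_spikes=int(ev.size),
              spike_times=ev)
        for ev in events
        if ev.size >= MIN_SPIKES_PER_BURST
    ]


def is_rhythmic(bursts: list[Burst], window: float = 100.0) -> bool:
    """True iff at least three bursts start within the analysis window (s)."""
    if window <= 0:
        raise InvalidParameterError("window must be > 0")
    return sum(1 for b in bursts if b.onset <= window) >= MIN_BURSTS_RHYTHMIC


@dataclass
class BurstStatistics:
    n_bursts: int
    bursts_per_100s: float
    mean_spikes_per_burst: float
    mean_intraburst_freq: float  # Hz
    mean_cycle_period: float  # s; nan with fewer than two bursts


def burst_statistics(bursts: list[Burst], window: float) -> BurstStatistics:
    """Rate statistics over an analysis window of ``window`` seconds.

    Cycle period is onset-to-onset of successive bursts and needs at least
    two bursts; with fewer it is reported as nan.
    """
    if window <= 0:
        raise InvalidParameterError("window must be > 0")
    n = len(bursts)
    rate = n * (100.0 / window)
    if n == 0:
        return BurstStatistics(0, 0.0, float("nan"), float("nan"), float("nan"))
    spikes = float(np.mean([b.n_spikes for b in bursts]))
    freq = float(np.mean([b.intraburst_frequency for b in bursts]))
    if n >= 2:
        onsets = np.array([b.onset for b in bursts])
        period = float(np.mean(np.diff(onsets)))
    else:
        period = float("nan")
    return BurstStatistics(n, rate, spikes, freq, period)


def estimate_input_resistance(t, v, amplitude_nA: float, onset: float,
                              duration: float) -> float:
    """Input resistance (MOhm) from a current-step response.

    Baseline is the mean voltage over the 10% of the pulse duration
    immediately before onset; the steady-state deflection is averaged over
    the final 10% of the pulse.  ``R = |dV_steady| / |I|`` with dV in mV
    and I in nA.
    """
    if amplitude_nA == 0:
        raise InvalidParameterError("pulse amplitude must be nonzero")
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if onset < t[0] or onset + duration > t[-1]:
        raise InvalidParameterError("pulse window must lie inside the trace")
    pre = (t >= onset - 0.1 * duration) & (t < onset)
    tail = (t >= onset + 0.9 * duration) & (t <= onset + duration)
    if pre.sum() == 0 or tail.sum() == 0:
        raise InvalidParameterError("trace too short around the pulse")
    dv = float(np.mean(v[tail]) - np.mean(v[pre]))
    return abs(dv) / abs(amplitude_nA)


def delta_leak_from_resistances(
    m_cold: TempMeasurement, m_warm: TempMeasurement
) -> tuple[DynClampSpec, float]:
    """Leak-conductance change between two temperatures.

    Returns the dynamic-clamp spec (delta_leak in nS, reversal = resting
    potential at the warm temperature) and the percent conductance increase
    ``(R_cold / R_warm - 1) * 100``.  A warm resistance above the cold one
    yields a negative delta (cooling case) and a warning rather than an
    error.
    """
    g_cold = 1000.0 / m_cold.R_in  # MOhm -> nS
    g_warm = 1000.0 / m_warm.R_in
    delta = g_warm - g_cold
    if delta < 0:
        warnings.warn(
            "warm input resistance exceeds cold: negative delta_leak (cooling case)",
            stacklevel=2,
        )
    percent = (m_cold.R_in / m_warm.R_in - 1.0) * 100.0
    return DynClampSpec(delta_leak=delta, E=m_warm.V_rest), percent


def fit_temperature_trend(temperatures, values) -> RegressionFit:
    """Ordinary least-squares line through (temperature, spikes/burst) pairs.

    Returns slope, intercept, R^2, the two-sided p-value for slope != 0,
    the slope standard error, and a 95% confidence interval on the slope.
    """
    x = np.asarray(temperatures, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise InvalidParameterError("need at least three (x, y) pairs")
    if np.ptp(x) == 0:
        raise InvalidParameterError("all temperatures identical; slope undefined")
    res = stats.linregress(x, y)
    half = stats.t.ppf(0.975, x.size - 2) * res.stderr
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        ci95=(float(res.slope - half), float(res.slope + half)),
    )


def read_spike_times(path) -> np.ndarray:
    """Read a plain-text spike-time list (one time in seconds per line)."""
    times = np.loadtxt(path, ndmin=1, dtype=float)
    return np.sort(times)
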