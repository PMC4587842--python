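"""In-silico experimental protocols.

* the exhaustive two-parameter sweep over LG's leak and I_MI maximal
  conductances (default grid: 22 x 50 = 1,100 cells, 5 nS spacing, scored
  over 100 s each);
* oscillation-threshold and maximum-rescuable-I_MI boundary extraction
  from sweep records;
* the current-step I-V / input-resistance characterisation protocol.

Sweep cells are independent and deterministic: every cell starts from rest,
runs a discarded settling window, and is scored with the shared burst
classifier, so any execution order yields identical records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import CircuitConfig, run_simulation, with_lg_conductances
from .core import (
    IntegratorSettings,
    NeuronCompartment,
    simulate_compartment,
)
from .errors import IntegrationDivergedError, InvalidParameterError
from .metrics import burst_statistics, classify_bursts, fit_temperature_trend, is_rhythmic

SWEEP_COLUMNS = ["g_leak_nS", "g_mi_nS", "n_bursts", "n_spikes",
                 "rhythmic", "single_burst", "failed"]


@dataclass
class SweepGrid:
    """Cartesian grid of LG (g_leak, g_MI) values, one simulation per cell."""

    g_leak_values: np.ndarray = field(
        default_factory=lambda: 1.0 + 5.0 * np.arange(22))
    g_mi_values: np.ndarray = field(
        default_factory=lambda: 1.0 + 5.0 * np.arange(50))
    duration_s: float = 100.0
    settle_s: float = 10.0

    def __post_init__(self):
        self.g_leak_values = np.asarray(self.g_leak_values, dtype=float)
        self.g_mi_values = np.asarray(self.g_mi_values, dtype=float)
        if self.g_leak_values.size == 0 or self.g_mi_values.size == 0:
            raise InvalidParameterError("grid axes must be non-empty")
        if self.duration_s <= 0 or self.settle_s < 0:
            raise InvalidParameterError("duration must be > 0, settle >= 0")

    @property
    def n_cells(self) -> int:
        return self.g_leak_values.size * self.g_mi_values.size

    @classmethod
    def default(cls) -> "SweepGrid":
        """The full exhaustive grid: g_leak 1-106 nS (22 steps), g_MI 1-246 nS
        (50 steps), 5 nS spacing, 1,100 cells of 100 s each."""
        return cls()

    @classmethod
    def coarse(cls) -> "SweepGrid":
        """Desk-scale subgrid of the default (8 x 13 cells, 50 s windows);
        every value lies on the full grid."""
        return cls(
            g_leak_values=1.0 + 5.0 * np.arange(0, 22, 3),  # 1..106 nS, 8 values
            g_mi_values=1.0 + 20.0 * np.arange(13),  # 1..241 nS
            duration_s=50.0,
        )


@dataclass
class SweepRecord:
    """One sweep cell: conductances, burst/spike counts, classification."""

    g_leak_nS: float
    g_mi_nS: float
    n_bursts: int
    n_spikes: int
    rhythmic: bool
    single_burst: bool
    failed: bool = False


def run_sweep(base_config: CircuitConfig, grid: SweepGrid,
              progress: bool = False) -> list[SweepRecord]:
    """Simulate every grid cell; only LG's g_leak and g_MI differ between cells.

    A diverged cell is recorded with ``failed=True`` rather than dropped.
    """
    records: list[SweepRecord] = []
    total = grid.n_cells
    done = 0
    for gl in grid.g_leak_values:
        for gmi in grid.g_mi_values:
            cfg = with_lg_conductances(base_config, g_leak_nS=gl, g_mi_nS=gmi)
            cfg.sim.duration_s = grid.duration_s
            cfg.sim.settle_s = grid.settle_s
            cfg.sim.trace_stride = 0  # spikes only; no trace storage
            try:
                res = run_simulation(cfg)
            except IntegrationDivergedError:
                records.append(SweepRecord(gl, gmi, 0, 0, False, False, True))
            else:
                bursts = res.scored_bursts("LG")
                n_b = len(bursts)
                rhythmic = is_rhythmic(bursts, window=grid.duration_s
                                       + grid.settle_s)
                records.append(SweepRecord(
                    g_leak_nS=float(gl),
                    g_mi_nS=float(gmi),
                    n_bursts=n_b,
                    n_spikes=res.scored_spike_count("LG"),
                    rhythmic=bool(rhythmic),
                    single_burst=bool((not rhythmic) and n_b == 1),
                ))
            done += 1
            if progress and done % 25 == 0:
                print(f"  sweep {done}/{total}", flush=True)
    return records


def sweep_to_frame(records: list[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=SWEEP_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SweepRecord]:
    missing = set(SWEEP_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"sweep table missing column(s) {sorted(missing)}")
    return [
        SweepRecord(
            float(r.g_leak_nS), float(r.g_mi_nS), int(r.n_bursts),
            int(r.n_spikes), bool(r.rhythmic), bool(r.single_burst),
            bool(r.failed),
        )
        for r in df.itertuples()
    ]


def oscillation_threshold(records: list[SweepRecord], g_leak: float):
    """Smallest tested g_MI (nS) that is rhythmic at this g_leak; None if the
    whole column is silent."""
    col = [r for r in records if r.g_leak_nS == g_leak and not r.failed]
    if not col:
        raise InvalidParameterError(f"no records at g_leak = {g_leak} nS")
    rhythmic = [r.g_mi_nS for r in col if r.rhythmic]
    return min(rhythmic) if rhythmic else None


def threshold_curve(records: list[SweepRecord]) -> pd.DataFrame:
    """Oscillation threshold for every g_leak column (NaN where none exists)."""
    g_leaks = sorted({r.g_leak_nS for r in records})
    thr = [oscillation_threshold(records, gl) for gl in g_leaks]
    return pd.DataFrame({
        "g_leak_nS": g_leaks,
        "threshold_g_mi_nS": [np.nan if t is None else t for t in thr],
    })


def threshold_linearity(records: list[SweepRecord]):
    """OLS fit of threshold g_MI against g_leak; returns a RegressionFit."""
    tc = threshold_curve(records).dropna()
    return fit_temperature_trend(tc["g_leak_nS"], tc["threshold_g_mi_nS"])


@dataclass
class BoundaryCurve:
    """Per-column maximum rescuable I_MI conductance.

    ``max_g_mi_nS`` is NaN where no rhythmic cell exists in the column or
    where the rescaled leak falls outside the tested grid
    (``out_of_range``).
    """

    g_leak_nS: np.ndarray
    max_g_mi_nS: np.ndarray
    threshold_g_mi_nS: np.ndarray
    out_of_range: np.ndarray
    leak_factor: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "g_leak_nS": self.g_leak_nS,
            "max_g_mi_nS": self.max_g_mi_nS,
            "threshold_g_mi_nS": self.threshold_g_mi_nS,
            "out_of_range": self.out_of_range,
        })


def max_rescuable_imi(records: list[SweepRecord],
                      leak_factor: float = 1.52) -> BoundaryCurve:
    """Largest g_MI per column that is rhythmic at g_leak but silent after the
    leak increase.

    A measured warming episode multiplies LG's leak by ``leak_factor``
    (default 1.52, the mean observed increase).  A cell (g_leak, g_MI) lies
    at or below the boundary when it is rhythmic while the cell at the
    nearest tested leak to ``leak_factor * g_leak`` (same g_MI) is not:
    these are exactly the conductance pairings for which that warming
    terminates the rhythm.
    """
    if leak_factor <= 1.0:
        raise InvalidParameterError("leak_factor must be > 1")
    g_leaks = np.array(sorted({r.g_leak_nS for r in records}))
    by_cell = {(r.g_leak_nS, r.g_mi_nS): r for r in records}
    g_mis = sorted({r.g_mi_nS for r in records})
    spacing = np.min(np.diff(g_leaks)) if g_leaks.size > 1 else 0.0
    max_mi = np.full(g_leaks.shape, np.nan)
    thr = np.full(g_leaks.shape, np.nan)
    oor = np.zeros(g_leaks.shape, dtype=bool)
    for i, gl in enumerate(g_leaks):
        target = leak_factor * gl
        j = int(np.argmin(np.abs(g_leaks - target)))
        if abs(g_leaks[j] - target) > spacing / 2 + 1e-9:
            # rescaled leak beyond the tested grid: every rescaled cell is
            # treated as silent (the infinite-factor limit), so the curve
            # degenerates to the column maximum rhythmic g_MI; flagged.
            oor[i] = True
            candidates = [
                gmi for gmi in g_mis
                if (gl, gmi) in by_cell and by_cell[(gl, gmi)].rhythmic
            ]
        else:
            gl_scaled = g_leaks[j]
            candidates = [
                gmi for gmi in g_mis
                if (gl, gmi) in by_cell and (gl_scaled, gmi) in by_cell
                and by_cell[(gl, gmi)].rhythmic
                and not by_cell[(gl_scaled, gmi)].rhythmic
            ]
        if candidates:
            max_mi[i] = max(candidates)
        t = oscillation_threshold(records, gl)
        thr[i] = np.nan if t is None else t
    return BoundaryCurve(g_leaks, max_mi, thr, oor, leak_factor)


def iv_protocol(lg: NeuronCompartment | None = None, *,
                C_pF: float = 1000.0, g_total_nS: float | None = None,
                E_mV: float = -60.0,
                amplitudes_nA: np.ndarray | None = None,
                pulse_s: float = 10.0, dt_ms: float = 0.2) -> pd.DataFrame:
    """Current-step I-V characterisation of a passive membrane.

    Mirrors the biological protocol: steps from -3 to +3 nA in 0.5 nA
    increments, 10 s pulses, with the steady-state deflection measured over
    the last second of each pulse.  Spike channels are stripped before
    integration (the table characterises the passive membrane).  Returns a
    DataFrame with columns I_nA and dV_mV; the fitted slope (MOhm) is
    stored in ``df.attrs['slope_MOhm']``.
    """
    if amplitudes_nA is None:
        amplitudes_nA = np.arange(-3.0, 3.01, 0.5)
    if lg is not None:
        comp0 = NeuronCompartment(lg.name, lg.C_m, lg.E_leak, lg.g_leak,
                                  lg.E_leak, channels=[])
    else:
        if g_total_nS is None:
            raise InvalidParameterError("pass a compartment or g_total_nS")
        comp0 = NeuronCompartment("LG", C_pF, E_mV, g_total_nS, E_mV,
                                  channels=[])
    rows = []
    settings = IntegratorSettings(dt=dt_ms, duration=pulse_s)
    n_tail = max(1, int(1.0 * 1000.0 / dt_ms))  # last 1 s of the pulse
    for amp in amplitudes_nA:
        comp = NeuronCompartment(comp0.name, comp0.C_m, comp0.E_leak,
                                 comp0.g_leak, comp0.E_leak, channels=[])
        _, v = simulate_compartment(comp, settings, I_inject=amp * 1000.0)
        dv = float(np.mean(v[-n_tail:]) - comp0.E_leak)
        rows.append((float(amp), dv))
    df = pd.DataFrame(rows, columns=["I_nA", "dV_mV"])
    nz = df[df.I_nA != 0]
    slope = float(np.polyfit(df.I_nA, df.dV_mV, 1)[0]) if len(nz) else math.nan
    df.attrs["slope_MOhm"] = slope
    return df


def summarize_record(res, window: float) -> dict:
    """Burst statistics of a simulation's LG train as a flat dict."""
    bursts = classify_bursts(res.train("LG"))
    stats = burst_statistics(bursts, window)
    return {
        "n_bursts": stats.n_bursts,
        "bursts_per_100s": stats.bursts_per_100s,
        "mean_spikes_per_burst": stats.mean_spikes_per_burst,
        "mean_intraburst_freq_hz": stats.mean_intraburst_freq,
        "mean_cycle_period_s": stats.mean_cycle_period,
        "rhythmic": is_rhythmic(bursts, window=window),
    }
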