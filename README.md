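# gastromill

Conductance-based model of the crab gastric mill central pattern generator,
built to study how a temperature-induced **leak conductance increase**
silences the LG oscillator and how the neuromodulator-activated inward
current **I_MI** rescues it. The package bundles:

- the four-neuron circuit (MCN1 soma + axon terminal, LG, Int1, AB) with
  the biological connectivity, 15 Hz MCN1 pulse drive, and 1 Hz pyloric
  (AB) feedback;
- the in-silico protocols: dynamic clamp (`I_dyn = ±Δleak·(V − E)`), the
  exhaustive `g_leak × ḡ_MI` sweep (22 × 50 = 1,100 cells, 5 nS spacing),
  oscillation-threshold and maximum-rescuable-I_MI boundary extraction, and
  the current-step input-resistance protocol;
- the quantification layer applied identically to simulated and recorded
  data: burst classification (≥ 4 spikes, ISI < 1 s, interburst ≥ 2 s),
  rhythmicity (≥ 3 bursts / 100 s), intraburst frequency `(n−1)/duration`,
  cycle period, input resistance, `Δleak = 1/R_warm − 1/R_cold`, and OLS
  temperature trends;
- seeded synthetic recordings (burst trains, temperature series, passive
  RC traces) with ground truth, so every estimator is testable end to end.

It is aimed at computational neuroscientists studying rhythm robustness
and neuromodulation in small circuits.

## The model in brief

Leak is `I = g(V − E)`; I_MI is `I = ḡ·a·(V − E)` with `E = 0`,
`a_inf = 1/(1 + e^{(V−V0)/s})`, `V0 = −40 mV`, `s = −10 mV`, τ = 50 ms.
Because I_MI's steady-state I–V is an inverted bell, its falling flank acts
as a *negative leak*, so leak and I_MI trade off almost linearly: for every
leak level there is a threshold ḡ_MI above which the half-center (LG–Int1)
rhythm runs. Warming is modelled purely as extra LG leak; neuromodulator
release purely as ḡ_MI. See `docs/methods.md` for the full account.

## Worked example

```python
import gastromill as gm

cfg = gm.default_config()                      # calibrated, frozen circuit

# reference rhythm: LG leak 20 nS, I_MI 80 nS
res = gm.run_simulation(gm.with_lg_conductances(cfg, 20, 80))
bursts = res.scored_bursts("LG")
stats = gm.burst_statistics(bursts, window=cfg.sim.duration_s)
print(len(bursts), round(stats.mean_cycle_period, 1),
      round(stats.mean_spikes_per_burst, 1))
# 11 9.1 53.8    -> 11 bursts/100 s, ~9 s cycle period, ~54 spikes/burst

# doubling the leak (the modelled 3 degree warming) silences LG ...
silent = gm.run_simulation(gm.with_lg_conductances(cfg, 40, 80))
print(silent.scored_spike_count("LG"))
# 0

# ... and raising I_MI by 50% restores the rhythm
rescued = gm.run_simulation(gm.with_lg_conductances(cfg, 40, 120))
print(len(rescued.scored_bursts("LG")))
# 11
```

The same experiment with the dynamic clamp instead of a parameter change —
adding `+Δleak = 0.52·g_leak` of artificial leak to the rhythmic reference,
or subtracting it from the warmed configuration:

```python
from gastromill import DynClampSpec, apply_dynamic_clamp
spec = DynClampSpec(delta_leak=0.52 * 20, E=cfg.lg.E_leak_mV)
clamped = gm.run_simulation(
    apply_dynamic_clamp(gm.with_lg_conductances(cfg, 20, 80), spec, +1))
print(len(clamped.scored_bursts("LG")))   # 0  -> artificial leak stops it
```

From the measured input resistances, the clamp conductance itself:

```python
from gastromill.metrics import TempMeasurement, delta_leak_from_resistances
spec, pct = delta_leak_from_resistances(
    TempMeasurement(10.0, 12.03, -65.0), TempMeasurement(13.0, 7.92, -68.0))
print(round(spec.delta_leak, 1), round(pct))
# 43.1 52     -> Delta-leak in nS and the percent conductance increase
```

A command-line interface mirrors the library
(`gastromill simulate|sweep|boundary|dynclamp|analyze|synth|render`); every
subcommand writes a provenance manifest next to its outputs. The full
1,100-cell sweep (`gastromill sweep --grid default`) takes on the order of
an hour on one CPU; `--grid coarse` runs the 8 × 13 subgrid in about two
minutes.

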