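# Methods

## The scientific problem

In the crab stomatogastric nervous system, the gastric mill central pattern
generator produces a slow (multi-second) chewing rhythm built on a
half-center oscillator: the lateral gastric neuron (LG) and Interneuron 1
(Int1) inhibit each other, the descending projection neuron MCN1 excites LG
through peptidergic (CabTRP Ia) activation of the modulator-induced inward
current I_MI, LG presynaptically inhibits the MCN1 axon terminal, and the
pyloric pacemaker AB paces Int1 at ~1 Hz. Warming the ganglion by a few
degrees increases LG's leak conductance; that increase alone is sufficient
to stop the rhythm, and increasing I_MI (more neuromodulator) is sufficient
to restore it. This package implements the conductance-based circuit model
of that interaction, the dynamic-clamp and two-parameter sweep protocols
that probe it, the quantification rules applied to spike trains and passive
recordings, and seeded synthetic recordings with known ground truth.

Temperature never appears as an explicit variable: warming enters the model
only as an increase in LG's leak conductance, and neuromodulation only as
the maximal I_MI conductance. Those are the only two parameters any
protocol varies.

## Model

All quantities use a dimensionally closed unit system: mV, ms, nS, pF, pA
(nS·mV = pA, pF·mV/ms = pA). Spike times are reported in seconds; currents
appear in nA in user-facing tables.

**Leak.** Instantaneous linear current `I = g_leak (V − E_leak)`. LG's
`E_leak = −75 mV`, its functional resting potential under tonic Int1
inhibition.

**I_MI.** Noninactivating inward current
`I = ḡ · a · (V − E)` with `E = 0 mV`, activation exponent 1, and
`a_inf(V) = 1 / (1 + exp((V − V0)/s))`, `V0 = −40 mV`, `s = −10 mV`,
activation time constant 50 ms. Its steady-state I–V relation is an
inverted bell with a minimum near −32 mV; on the falling flank the slope
conductance is negative, so I_MI subtracts from the leak (a "negative
leak"), which is the mechanistic core of the rescue.

**Spike currents.** The transient sodium (m³h) and delayed-rectifier (n⁴)
currents use classical squid-axon kinetics in the modern voltage convention,
rigidly shifted so LG's spike threshold sits near −40 mV. The
delayed-rectifier shift is set independently (+25 mV for LG): its
subthreshold "window" conductance then contributes a voltage-dependent
barrier just below threshold, which sharpens the escape threshold and keeps
the silent/rhythmic transition abrupt. LG's sodium conductance (14 µS) was
chosen small enough that its subthreshold window current cannot by itself
sustain depolarised states at very low leak.

**Network.** One compartment per neuron, except MCN1, which has a soma/axon
compartment (driven by 1 ms suprathreshold current pulses at 15 Hz) and a
separate terminal compartment. Soma spikes invade the terminal as a fast
excitatory conductance. The terminal drives a transmitter variable `T ∈
[0, 1]` that scales LG's I_MI conductance (`g_MI,effective = ḡ_MI · T`),
modelling CabTRP Ia release. Graded chemical synapses use a sigmoidal
release function of presynaptic voltage with first-order kinetics;
connectivity is exactly: MCN1→LG (+, via the terminal/I_MI pathway),
MCN1→Int1 (+), LG⊣Int1, Int1⊣LG, LG⊣MCN1 terminal, AB⊣Int1, and a
non-rectifying 10 nS gap junction between terminal and LG. A configuration
whose edge audit differs from this set is rejected.

**Transmitter kinetics.** `T` decays exponentially (τ = 5.5 s) toward a
voltage-dependent target when the terminal is inhibited, and replenishes at
a constant rate (0.045 s⁻¹) when the terminal is active — zero-order
replenishment, as in synaptic resource models. The zero-order rise is a
deliberate choice: with exponential recovery, the time to re-reach a low
escape threshold is nearly independent of depletion depth, and cells far
above the rhythmicity threshold recycle faster than the 2 s interburst
separator, fusing their bursts. With constant-rate recovery the interburst
gap is proportional to how deeply the burst depleted `T`, which yields
multi-second gastric periods across the entire rhythmic region and the
observed gradient of faster rhythms at higher I_MI.

**Rhythm mechanism.** With LG silent, Int1 fires tonically and inhibits LG
(~20–25 nS) while the terminal builds `T`. When `ḡ_MI · T` crosses the
escape threshold set by leak + inhibition + the potassium window, LG
escapes, fires, and its spike-driven synapses (release threshold −25 mV, so
only genuine spiking releases) silence Int1 and clamp the terminal; `T`
then depletes until the burst collapses, Int1 returns, and the cycle
repeats. AB's 1 Hz inhibition of Int1 is kept weak (15 nS): it imposes
pyloric-timed modulation on LG's membrane potential without gating the
escape. (Deep 1 Hz gating mode-locks the gastric rhythm to the pyloric
clock and quantises interburst gaps just below the 2 s separator; the weak
ripple lets the rhythm free-run on the transmitter clock.)

## Dynamic clamp

The artificial leak is `I_dyn = ±Δleak · (V − E)` applied to LG. `Δleak`
is computed from paired input-resistance measurements as
`1/R_warm − 1/R_cold`, with `E` the warm resting potential; the measured
means (12.03 MΩ at 10 °C, 7.92 MΩ at 13 °C) give Δleak ≈ 43.1 nS, a 52%
conductance increase. Internally every clamp term whose reversal equals
LG's `E_leak` is folded into a single fused linear coefficient (`I = A·V −
B`); this makes "clamp +Δ at E = E_leak" bit-identical to "raise g_leak by
Δ" and makes simultaneous +Δ/−Δ clamps cancel exactly, both of which are
asserted in the tests. Clamp terms with a different reversal remain
separate, so the equivalence deliberately fails when E ≠ E_leak.

## Numerics

Fixed-step integration: exponential Euler for all gating/release states
(unconditionally bounded in [0, 1]), forward Euler for voltages. The
network default is dt = 0.025 ms: at this step, halving dt leaves the
reference simulation's burst count unchanged and its spike count identical;
at 0.05 ms the spike count still shifted by ~3%. Simulations are strictly
deterministic — identical configurations produce bit-identical trajectories.
Every simulation runs a 10 s settling window from rest (all gates at steady
state, T = 0) that is excluded from scoring. Spikes are detected in the
integrator as upward crossings of −20 mV with a 2 ms lockout. Non-finite
states abort with an error naming the compartment and time; sweep cells
that diverge are recorded with a `failed` flag rather than dropped.

## Quantification rules

A burst is at least four spikes: consecutive spikes with interspike
intervals below 1 s form runs, runs separated by gaps shorter than 2 s
merge into one event, and events with fewer than four spikes are discarded.
Comparisons are strict (an ISI of exactly 1 s splits; a gap of exactly 2 s
separates). Note the merge step means a classified burst can contain an
internal interval in [1, 2) s. A recording is rhythmic when at least three
bursts start inside the scoring window; a burst straddling the window edge
counts if its onset is inside. Intraburst frequency is (n−1)/duration;
cycle period is onset-to-onset. Input resistance is |ΔV|/|I| with the
steady-state deflection averaged over the final 10% of the pulse. Trends
of spikes/burst against temperature use ordinary least squares with a
two-sided slope test.

## Protocols

The exhaustive sweep covers g_leak = 1–106 nS (22 values) × ḡ_MI = 1–246 nS
(50 values), 5 nS spacing, 1,100 cells of 100 s each, varying only LG's two
conductances. Cells are independent and deterministic, so any execution
order gives identical records. The full sweep takes roughly an hour on one
CPU; the shipped tests and the acceptance script use an 8 × 13 subgrid of
the same cells with 50 s scoring windows, which preserves the structure
being asserted (band structure, threshold monotonicity and linearity,
boundary placement) at desk scale. The oscillation threshold of a column
is the smallest tested ḡ_MI that is rhythmic. The maximum rescuable I_MI
for a leak value is the largest ḡ_MI that is rhythmic at that leak but
silent at the nearest tested leak to 1.52× it (the measured warming
episode); when 1.52× falls outside the grid the column is flagged and the
infinite-factor limit (the column's maximum rhythmic ḡ_MI) is reported.
The current-step I–V protocol applies −3 to +3 nA in 0.5 nA steps, 10 s
pulses, measuring steady state over the last second on the passive
membrane (spike channels stripped).

## Calibration

The paper-fixed quantities (I_MI kinetics, drive frequencies, grid, burst
definitions, 52% leak increase) are hard-coded as defaults. Everything the
source does not print — spike-current densities, synaptic strengths and
kinetics, compartment sizes, transmitter rates — was tuned once against
four constraints and then frozen in `src/gastromill/data/default_circuit.yaml`:
(20, 80) nS rhythmic, (40, 80) completely silent, (40, 120) rhythmic, and
a 52% leak increase from the reference silences LG. `scripts/calibrate.py`
re-verifies the four constraints against the shipped file. All tests run
against these frozen defaults.

## Synthetic recordings

The generators emulate: bursting LG spike trains with prescribed burst
structure (intraburst ISI < 1 s, interburst ≥ 2 s even after onset jitter,
≥ 4 spikes/burst); linear decline of spikes/burst with temperature with a
floor at zero (presets use the measured slopes −9.81, −7.52, and −0.46
spikes·burst⁻¹·°C⁻¹, with grids ending before the line approaches the
floor so least-squares inference is unbiased); and exact piecewise-
exponential RC responses to current steps with additive Gaussian noise.
Every generator takes a required seed and is bit-reproducible. They do not
emulate: multi-unit extracellular mixtures, spike waveform shape, slow
drift, or animal-to-animal variability in anything but the seeded noise —
so passing round-trip tests demonstrates correctness of the analysis code
on data satisfying the stated assumptions, not robustness to real-world
recording artefacts.

## Known limitations

- Synaptic parameters are calibrated stand-ins, so spike-level details of
  the voltage traces match the biological recordings qualitatively only;
  the defended quantities are the rhythmicity classifications, the
  threshold structure of the sweep, and the clamp arithmetic.
- Spikes per 100 s increase with ḡ_MI and fall again only near the
  high-I_MI/low-leak corner, where non-rhythmic single-burst states appear
  (in this calibration, a handful of cells in the lowest-leak column) —
  the same corner reported for the original model, though the exact count
  is tuning-dependent.
- Spikes per 100 s is not strictly decreasing in g_leak here: burst rate
  falls with leak but the per-burst spike rate rises, because higher-leak
  cells escape at higher transmitter levels.
- The gap junction is ohmic; rectification of the biological MCN1–LG
  electrical coupling is out of scope, as are Q10 scaling of channel
  kinetics, the full pyloric network, and MCN5.
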