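"""Verify the frozen calibration of the default circuit.

The free conductances of the network (spike currents, synapse strengths,
transmitter kinetics) were tuned once against four constraints and then
frozen into ``src/gastromill/data/default_circuit.yaml``:

  1. (g_leak, g_MI) = (20, 80) nS  -> rhythmic (>= 3 bursts / 100 s)
  2. (40, 80) nS                   -> completely silent (0 spikes)
  3. (40, 120) nS                  -> rhythmic again (+50% I_MI rescue)
  4. a 52% leak increase from the reference (to 30.4 nS) -> silent

This script re-evaluates the four constraints against the shipped defaults
and prints PASS/FAIL for each; it does not modify the configuration.

Usage: python scripts/calibrate.py
"""

import sys

import gastromill as gm
from gastromill.circuit import run_simulation, with_lg_conductances


def evaluate(cfg, gl, gmi):
    c = with_lg_conductances(cfg, gl, gmi)
    c.sim.duration_s = 100.0
    c.sim.trace_stride = 0
    r = run_simulation(c)
    return len(r.scored_bursts("LG")), r.scored_spike_count("LG")


def main() -> int:
    cfg = gm.default_config()
    checks = []

    nb, ns = evaluate(cfg, 20.0, 80.0)
    checks.append(("reference (20, 80) rhythmic", nb >= 3,
                   f"{nb} bursts, {ns} spikes / 100 s"))
    nb, ns = evaluate(cfg, 40.0, 80.0)
    checks.append(("doubled leak (40, 80) silent", ns == 0,
                   f"{nb} bursts, {ns} spikes / 100 s"))
    nb, ns = evaluate(cfg, 40.0, 120.0)
    checks.append(("+50% I_MI (40, 120) rhythmic", nb >= 3,
                   f"{nb} bursts, {ns} spikes / 100 s"))
    nb, ns = evaluate(cfg, 1.52 * 20.0, 80.0)
    checks.append(("52% leak increase (30.4, 80) silent", ns == 0,
                   f"{nb} bursts, {ns} spikes / 100 s"))

    width = max(len(name) for name, _, _ in checks)
    ok = True
    for name, passed, detail in checks:
        status = "PASS" if passed else "FAIL"
        ok &= passed
        print(f"{name:<{width}}  {status}  ({detail})")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
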