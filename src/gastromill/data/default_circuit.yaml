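# gastromill default circuit configuration (calibrated, frozen)
# units: voltages mV, times ms (keys ending _s are seconds),
#        conductances nS, capacitances pF, currents pA
lg:
  C_pF: 300.0
  g_leak_nS: 20.0        # reference leak; the sweep axis
  E_leak_mV: -75.0       # leak reversal = resting potential under tonic inhibition
  g_na_nS: 14000.0
  g_k_nS: 2500.0
  E_na_mV: 50.0
  E_k_mV: -80.0
  shift_na_mV: 15.0      # spike threshold near -40 mV
  shift_k_mV: 25.0       # delayed rectifier; subthreshold window adds escape hysteresis
g_mi_nS: 80.0            # reference I_MI maximal conductance; the other sweep axis
imi:
  V0_mV: -40.0
  s_mV: -10.0
  tau_ms: 50.0
  E_mV: 0.0
  p: 1
int1:
  C_pF: 400.0
  g_leak_nS: 30.0
  E_leak_mV: -40.0       # depolarised leak reversal -> tonic firing when released
  g_na_nS: 8000.0
  g_k_nS: 2000.0
  E_na_mV: 50.0
  E_k_mV: -80.0
  shift_na_mV: 10.0
  shift_k_mV: 25.0
ab:
  C_pF: 200.0
  g_leak_nS: 20.0
  E_leak_mV: -62.0       # passive; oscillates under the 1 Hz sinusoidal drive
mcn1_soma:
  C_pF: 100.0
  g_leak_nS: 100.0
  E_leak_mV: -65.0
  g_na_nS: 8000.0
  g_k_nS: 2000.0
  E_na_mV: 50.0
  E_k_mV: -80.0
  shift_na_mV: 10.0
  shift_k_mV: 25.0
terminal:
  C_pF: 100.0
  g_leak_nS: 10.0
  E_leak_mV: -60.0
  drive_g_nS: 500.0      # soma spikes invading the terminal
  drive_E_mV: 0.0
  drive_Vth_mV: -20.0
  drive_k_mV: 5.0
  drive_tau_ms: 200.0
  release_Vth_mV: -50.0  # transmitter build-up threshold
  release_k_mV: 5.0
  release_rise_rate_per_s: 0.045   # zero-order transmitter replenishment
  release_tau_decay_ms: 5500.0
synapses:
  - {source: Int1, target: LG, g_max_nS: 34.0, E_mV: -80.0, V_th_mV: -55.0, k_mV: 5.0, tau_ms: 60.0}
  - {source: LG, target: Int1, g_max_nS: 4000.0, E_mV: -80.0, V_th_mV: -25.0, k_mV: 3.0, tau_ms: 200.0}
  - {source: LG, target: MCN1_terminal, g_max_nS: 3000.0, E_mV: -80.0, V_th_mV: -25.0, k_mV: 3.0, tau_ms: 150.0}
  - {source: AB, target: Int1, g_max_nS: 15.0, E_mV: -80.0, V_th_mV: -55.0, k_mV: 4.0, tau_ms: 50.0}
  - {source: MCN1, target: Int1, g_max_nS: 150.0, E_mV: 0.0, V_th_mV: -20.0, k_mV: 5.0, tau_ms: 300.0}
gap_junction_nS: 10.0
drives:
  mcn1_pulse_hz: 15.0
  mcn1_pulse_ms: 1.0
  mcn1_pulse_pA: 5000.0
  ab_freq_hz: 1.0
  ab_amp_pA: 450.0
sim:
  dt_ms: 0.025
  duration_s: 100.0
  settle_s: 10.0
  trace_stride: 1
  method: expeuler
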