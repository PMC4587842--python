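"""Network assembly, connectivity audit, simulation behavior, dynamic clamp."""

import numpy as np
import pytest
from scipy import signal

import gastromill as gm
from gastromill.circuit import (
    REQUIRED_EDGES,
    apply_dynamic_clamp,
    audit_edges,
    run_simulation,
    validate_connectivity,
    with_lg_conductances,
)
from gastromill.configio import config_to_dict, dict_to_config
from gastromill.core import DynClampSpec
from gastromill.errors import ConfigError


def short_sim(cfg, gl=None, gmi=None, duration=20.0, stride=0, settle=10.0):
    c = with_lg_conductances(cfg, gl, gmi)
    c.sim.duration_s = duration
    c.sim.settle_s = settle
    c.sim.trace_stride = stride
    return run_simulation(c)


class TestConnectivity:
    def test_default_audit_matches_biological_circuit(self, default_cfg):
        assert audit_edges(default_cfg) == REQUIRED_EDGES

    def test_missing_edge_rejected(self, default_cfg):
        broken = default_cfg.copy()
        broken.synapses = [s for s in broken.synapses
                           if not (s.source == "Int1" and s.target == "LG")]
        with pytest.raises(ConfigError, match="Int1->LG"):
            validate_connectivity(broken)

    def test_extra_edge_rejected(self, default_cfg):
        from gastromill.circuit import SynapseSpec
        broken = default_cfg.copy()
        broken.synapses.append(SynapseSpec("AB", "LG", 10.0, -80.0, -50.0,
                                           4.0, 50.0))
        with pytest.raises(ConfigError, match="AB->LG"):
            validate_connectivity(broken)

    def test_config_round_trips_through_serialization(self, default_cfg):
        again = dict_to_config(config_to_dict(default_cfg))
        assert config_to_dict(again) == config_to_dict(default_cfg)


class TestSimulation:
    def test_deterministic(self, default_cfg):
        r1 = short_sim(default_cfg, 20, 80, duration=15.0, stride=40)
        r2 = short_sim(default_cfg, 20, 80, duration=15.0, stride=40)
        assert np.array_equal(r1.spikes["LG"], r2.spikes["LG"])
        assert np.array_equal(r1.V["LG"], r2.V["LG"])

    def test_trace_length_invariant(self, default_cfg):
        c = with_lg_conductances(default_cfg, 40, 80)
        c.sim.duration_s = 2.0
        c.sim.settle_s = 1.0
        c.sim.trace_stride = 1
        r = run_simulation(c)
        n_expected = int(round(3.0 * 1000.0 / c.sim.dt_ms)) + 1
        assert len(r.V["LG"]) == n_expected
        assert len(r.t) == n_expected

    def test_ab_oscillates_at_1hz(self, reference_sim):
        t, vab = reference_sim.t, reference_sim.V["AB"]
        sel = t >= 10.0
        f, p = signal.periodogram(vab[sel] - vab[sel].mean(),
                                  fs=1.0 / (t[1] - t[0]))
        assert f[np.argmax(p)] == pytest.approx(1.0, abs=0.02)

    def test_mcn1_fires_at_commanded_rate(self, reference_sim):
        n = reference_sim.scored_spike_count("MCN1")
        assert n == pytest.approx(15.0 * 100.0, rel=0.01)

    def test_spike_times_strictly_increasing(self, reference_sim):
        for unit in ("LG", "Int1", "MCN1"):
            s = reference_sim.spikes[unit]
            assert np.all(np.diff(s) > 0)

    def test_reference_is_rhythmic_in_gastric_range(self, reference_sim):
        from gastromill.metrics import burst_statistics
        bursts = reference_sim.scored_bursts("LG")
        stats = burst_statistics(bursts, 100.0)
        assert stats.n_bursts >= 3
        assert 2.0 < stats.mean_cycle_period < 30.0  # multi-second gastric range
        assert stats.mean_spikes_per_burst >= 4

    def test_half_center_antiphase(self, reference_sim):
        lg = reference_sim.scored_bursts("LG")
        int1 = reference_sim.scored_bursts("Int1")
        assert len(lg) >= 3 and len(int1) >= 3
        max_overlap = 0.0
        for b in lg:
            for ib in int1:
                ov = min(b.offset, ib.offset) - max(b.onset, ib.onset)
                max_overlap = max(max_overlap, ov)
        assert max_overlap <= 1.0  # within one pyloric cycle

    def test_monotone_rescue_in_gmi(self, default_cfg):
        spikes = []
        for gmi in (80.0, 110.0, 140.0):
            r = short_sim(default_cfg, 20.0, gmi, duration=60.0)
            spikes.append(r.scored_spike_count("LG"))
        assert spikes[0] > 0
        assert spikes == sorted(spikes)

    def test_halving_dt_preserves_bursts_and_spikes(self, default_cfg):
        counts = {}
        for dt in (0.025, 0.0125):
            c = with_lg_conductances(default_cfg, 20.0, 80.0)
            c.sim.duration_s = 60.0
            c.sim.dt_ms = dt
            c.sim.trace_stride = 0
            r = run_simulation(c)
            counts[dt] = (len(r.scored_bursts("LG")),
                          r.scored_spike_count("LG"))
        assert counts[0.025][0] == counts[0.0125][0]
        n1, n2 = counts[0.025][1], counts[0.0125][1]
        assert abs(n1 - n2) / max(n1, 1) < 0.02


class TestDynamicClamp:
    def test_zero_delta_is_identity(self, default_cfg):
        base = short_sim(default_cfg, 20, 80, duration=12.0, stride=40)
        clamped_cfg = apply_dynamic_clamp(
            with_lg_conductances(default_cfg, 20, 80),
            DynClampSpec(0.0, default_cfg.lg.E_leak_mV), +1)
        clamped_cfg.sim.duration_s = 12.0
        clamped_cfg.sim.trace_stride = 40
        r = run_simulation(clamped_cfg)
        assert np.array_equal(base.V["LG"], r.V["LG"])

    def test_clamp_equals_parameter_change_when_E_matches(self, default_cfg):
        """+delta at E = E_leak is trajectory-identical (bit-for-bit) to
        raising g_leak by delta; with a different reversal it is not."""
        delta = 8.0
        param = short_sim(default_cfg, 20.0 + delta, 80, duration=12.0,
                          stride=40)
        cfg = apply_dynamic_clamp(with_lg_conductances(default_cfg, 20.0, 80),
                                  DynClampSpec(delta, default_cfg.lg.E_leak_mV),
                                  +1)
        cfg.sim.duration_s = 12.0
        cfg.sim.trace_stride = 40
        clamp = run_simulation(cfg)
        assert np.array_equal(param.V["LG"], clamp.V["LG"])
        assert np.array_equal(param.spikes["LG"], clamp.spikes["LG"])

        cfg2 = apply_dynamic_clamp(with_lg_conductances(default_cfg, 20.0, 80),
                                   DynClampSpec(delta, -60.0), +1)  # E differs
        cfg2.sim.duration_s = 12.0
        cfg2.sim.trace_stride = 40
        other = run_simulation(cfg2)
        assert not np.array_equal(param.V["LG"], other.V["LG"])

    def test_plus_minus_cancellation_bit_for_bit(self, default_cfg):
        base = short_sim(default_cfg, 20, 80, duration=12.0, stride=40)
        E = default_cfg.lg.E_leak_mV
        cfg = with_lg_conductances(default_cfg, 20, 80)
        cfg = apply_dynamic_clamp(cfg, DynClampSpec(10.4, E), +1)
        cfg = apply_dynamic_clamp(cfg, DynClampSpec(10.4, E), -1)
        cfg.sim.duration_s = 12.0
        cfg.sim.trace_stride = 40
        r = run_simulation(cfg)
        assert np.array_equal(base.V["LG"], r.V["LG"])

    def test_idyn_trace_reported(self, default_cfg):
        cfg = apply_dynamic_clamp(with_lg_conductances(default_cfg, 20, 80),
                                  DynClampSpec(10.4, -68.0), +1)
        cfg.sim.duration_s = 5.0
        cfg.sim.trace_stride = 40
        r = run_simulation(cfg)
        assert r.i_dyn_pA is not None
        expected = 10.4 * (r.V["LG"] - (-68.0))
        assert np.allclose(r.i_dyn_pA, expected)
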