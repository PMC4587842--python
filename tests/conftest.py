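import numpy as np
import pytest

import gastromill as gm
from gastromill.circuit import run_simulation, with_lg_conductances


@pytest.fixture(scope="session")
def default_cfg():
    return gm.default_config()


@pytest.fixture(scope="session")
def reference_sim(default_cfg):
    """The calibrated rhythmic reference (g_leak 20 nS, g_MI 80 nS), 100 s
    scored window with 1 ms traces.  Shared across tests for speed."""
    cfg = with_lg_conductances(default_cfg, 20.0, 80.0)
    cfg.sim.duration_s = 100.0
    cfg.sim.trace_stride = 40  # 1 ms samples
    return run_simulation(cfg)


def random_spike_train(rng: np.random.Generator) -> np.ndarray:
    """Mixture of Poisson, bursty, and boundary-aligned spike trains used by
    the classifier-vs-oracle property tests."""
    kind = rng.integers(4)
    if kind == 0:  # homogeneous Poisson
        n = int(rng.integers(0, 60))
        times = np.sort(rng.uniform(0.0, 60.0, size=n))
    elif kind == 1:  # bursty mixture
        times = []
        t = rng.uniform(0.0, 2.0)
        for _ in range(int(rng.integers(1, 8))):
            n = int(rng.integers(1, 12))
            isi = rng.uniform(0.02, 1.4)
            times.extend(t + isi * np.arange(n))
            t = times[-1] + rng.uniform(0.3, 6.0)
        times = np.array(times)
    elif kind == 2:  # grid-aligned: ISIs hit the 1 s and 2 s boundaries
        steps = rng.choice([0.5, 1.0, 1.5, 2.0, 2.5], size=int(rng.integers(1, 40)))
        times = np.cumsum(steps)
    else:  # sparse
        n = int(rng.integers(0, 6))
        times = np.sort(rng.uniform(0.0, 30.0, size=n))
    times = np.unique(np.round(times, 6))
    return times


def oracle_bursts(times: np.ndarray, lo: float, hi: float):
    """Independent burst oracle: recursively split the spike list at its
    largest gap while that gap separates bursts (>= 2 s), then keep the
    maximal groups with at least four spikes.  Structurally different from
    the production left-to-right run-merge implementation."""
    ts = np.asarray([t for t in times if lo <= t <= hi])

    def split(seg):
        if seg.size <= 1:
            return [seg]
        gaps = np.diff(seg)
        k = int(np.argmax(gaps))
        if gaps[k] >= 2.0:
            return split(seg[: k + 1]) + split(seg[k + 1:])
        return [seg]

    if ts.size == 0:
        return []
    return [g for g in split(ts) if g.size >= 4]
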